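"""Synthetic trnL-like records with ground truth for end-to-end testing.

The generator emulates the input regime of a P8 survey without any
download: each record carries the universal c/d primer sites, configurable
P8 border anchors, and a P8 region of 200-700 nt with an A-rich base
composition, tandem repeat arrays (a stand-in for slipped-strand
mispairing expansions, the mechanism invoked to explain P8 length
hypervariability) and enzyme recognition motifs planted at recorded
positions.  Every planted position is re-verified against
:func:`~p8barcode.scan.scan_sites` before the record is emitted, so the
returned truth is a sound oracle for the delimit -> map pipeline.

What it does **not** emulate: real P8 secondary structure, lineage
structure between taxa, sequencing error, or degenerate base calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .delimit import AnchorConfig, PrimerPair, TrnLRecord, default_anchors
from .enzymes import IUPAC_CODES, EnzymeSpec, builtin_core_enzymes, reverse_complement
from .scan import scan_sites

__all__ = ["SyntheticTruth", "generate_synthetic"]

#: A-rich background composition (A, C, G, T) echoing P8 base bias.
BACKGROUND_WEIGHTS = (0.40, 0.16, 0.16, 0.28)

#: Short A-rich motifs used for tandem repeat arrays.
REPEAT_MOTIFS = ("AAAT", "ATAAA", "AAAAG", "TTAAA")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated record.

    ``p8_bounds`` are 1-based inclusive coordinates of the P8 region in
    ``sequence``; ``planted_sites`` maps enzyme name to 1-based positions
    *within the P8 region* where a concrete instance of the recognition
    motif was written.
    """

    sequence: str
    p8_bounds: tuple[int, int]
    planted_sites: dict[str, tuple[int, ...]]
    repeat_events: tuple[tuple[str, int], ...]

    @property
    def p8_sequence(self) -> str:
        s, e = self.p8_bounds
        return self.sequence[s - 1 : e]


def _random_bases(rng: np.random.Generator, n: int, weights=BACKGROUND_WEIGHTS) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=weights))


def _concretize(rng: np.random.Generator, motif: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in motif)


def generate_synthetic(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (200, 700),
    enzymes: Sequence[EnzymeSpec] | None = None,
    sites_per_enzyme: tuple[int, int] = (1, 4),
    repeat_events_per_region: tuple[int, int] = (1, 3),
    repeat_motifs: Sequence[str] = REPEAT_MOTIFS,
    repeat_copy_p: float = 0.5,
    anchors: AnchorConfig | None = None,
    primers: PrimerPair | None = None,
) -> list[tuple[TrnLRecord, SyntheticTruth]]:
    """Generate *n* trnL-like records with recorded ground truth.

    Deterministic for a fixed seed and parameter set.  Each P8 region is
    drawn uniformly from *length_range*, filled with A-rich background,
    overwritten with tandem repeat arrays (geometric copy counts,
    success probability *repeat_copy_p*), and finally planted with a
    uniform number of non-overlapping concrete motif instances per
    enzyme.

    Raises
    ------
    ValueError
        For infeasible parameters (motif longer than the smallest region,
        or more planted footprints than fit).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    enzymes = list(enzymes) if enzymes is not None else builtin_core_enzymes()
    anchors = anchors or default_anchors()
    primers = primers or PrimerPair()
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    longest = max(e.site_length for e in enzymes)
    if longest > lo:
        raise ValueError(
            f"longest recognition motif ({longest} nt) exceeds the smallest "
            f"region length ({lo} nt)"
        )
    if sites_per_enzyme[1] * sum(e.site_length for e in enzymes) > lo:
        raise ValueError("requested planted footprints cannot fit the smallest region")

    rng = np.random.default_rng(seed)
    out: list[tuple[TrnLRecord, SyntheticTruth]] = []
    for idx in range(n):
        p8_len = int(rng.integers(lo, hi + 1))
        p8 = list(_random_bases(rng, p8_len))

        # tandem repeat arrays first, so planted motifs are never overwritten
        repeat_events: list[tuple[str, int]] = []
        n_events = int(rng.integers(repeat_events_per_region[0], repeat_events_per_region[1] + 1))
        for _ in range(n_events):
            motif = str(rng.choice(list(repeat_motifs)))
            copies = int(rng.geometric(repeat_copy_p))
            array = motif * copies
            if len(array) >= p8_len:
                copies = max(1, p8_len // (2 * len(motif)))
                array = motif * copies
            start = int(rng.integers(0, p8_len - len(array) + 1))
            p8[start : start + len(array)] = list(array)
            repeat_events.append((motif, copies))

        occupied: list[tuple[int, int]] = []  # 0-based [start, end) footprints
        planted: dict[str, list[int]] = {}
        for enz in enzymes:
            k = int(rng.integers(sites_per_enzyme[0], sites_per_enzyme[1] + 1))
            positions: list[int] = []
            for _ in range(k):
                placed = False
                for _attempt in range(200):
                    s = int(rng.integers(0, p8_len - enz.site_length + 1))
                    e = s + enz.site_length
                    if all(e <= os or s >= oe for os, oe in occupied):
                        occupied.append((s, e))
                        p8[s:e] = list(_concretize(rng, enz.recognition))
                        positions.append(s + 1)
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"could not place {k} non-overlapping sites of {enz.name} "
                        f"in a {p8_len} nt region"
                    )
            planted[enz.name] = sorted(positions)
        p8_seq = "".join(p8)

        for enz in enzymes:
            found = set(scan_sites(p8_seq, enz))
            missing = [p for p in planted[enz.name] if p not in found]
            if missing:  # overwritten by a later placement — cannot happen
                raise AssertionError(
                    f"planted {enz.name} sites {missing} not recovered by scan"
                )

        left_pad = _random_bases(rng, int(rng.integers(20, 61)), (0.25,) * 4)
        mid_pad = _random_bases(rng, int(rng.integers(30, 81)), (0.25,) * 4)
        right_pad = _random_bases(rng, int(rng.integers(10, 41)), (0.25,) * 4)
        tail_pad = _random_bases(rng, int(rng.integers(0, 21)), (0.25,) * 4)
        prefix = left_pad + primers.c_primer + mid_pad + anchors.left_anchor
        sequence = (
            prefix
            + p8_seq
            + anchors.right_anchor
            + right_pad
            + reverse_complement(primers.d_primer)
            + tail_pad
        )
        p8_start = len(prefix) + 1
        truth = SyntheticTruth(
            sequence=sequence,
            p8_bounds=(p8_start, p8_start + p8_len - 1),
            planted_sites={k: tuple(v) for k, v in planted.items()},
            repeat_events=tuple(repeat_events),
        )
        record = TrnLRecord(
            record_id=f"SYN{idx:04d}",
            taxon_name=f"Synthetic taxon {idx:04d}",
            accession=f"SYN{idx:04d}",
            sequence=sequence,
        )
        out.append((record, truth))
    return out
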