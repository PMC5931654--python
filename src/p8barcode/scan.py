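"""Degenerate recognition-site scanning and per-taxon site profiles.

A site is reported at the 1-based position of the 5'-most base of the
recognition footprint; overlapping occurrences are all reported.  Subject
degeneracy is handled *conservatively*: an ambiguous subject base matches
a motif position only if every base it could resolve to would match
(subject base set is a subset of the motif base set).  This is the
opposite polarity from primer matching, where any shared base suffices —
an ambiguous base in a downloaded record should not conjure a restriction
site that may not exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, TextIO

import pandas as pd

from .delimit import P8Region
from .enzymes import IUPAC_CODES, EnzymeSpec, reverse_complement

__all__ = [
    "SiteProfile",
    "scan_sites",
    "map_all",
    "enzymes_cutting",
    "validate_profile",
    "write_profiles",
    "read_profiles",
]

StrandMode = Literal["forward", "both"]


@dataclass(frozen=True)
class SiteProfile:
    """Per-taxon recognition-site map: enzyme name -> sorted 1-based starts."""

    taxon_name: str
    accession: str
    p8_length: int
    sites: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[int, ...]] = {}
        for enz, positions in self.sites.items():
            pos = tuple(sorted(set(int(p) for p in positions)))
            if any(p < 1 for p in pos):
                raise ValueError(f"{self.taxon_name}/{enz}: positions must be >= 1")
            clean[enz] = pos
        object.__setattr__(self, "sites", clean)
        if self.p8_length < 1:
            raise ValueError(f"{self.taxon_name}: p8_length must be >= 1")


def validate_profile(
    profile: SiteProfile, enzymes: Sequence[EnzymeSpec]
) -> list[str]:
    """Flag positions whose recognition footprint cannot fit in the region.

    Returns human-readable warnings (flag-and-keep: out-of-range positions
    are reported, never silently repaired — survey tables occasionally
    carry them and the discrepancy should stay visible).
    """
    by_name = {e.name: e for e in enzymes}
    warnings: list[str] = []
    for enz, positions in profile.sites.items():
        spec = by_name.get(enz)
        if spec is None:
            warnings.append(f"{profile.taxon_name}: unknown enzyme {enz!r}")
            continue
        limit = profile.p8_length - spec.site_length + 1
        out = [p for p in positions if p > limit]
        if out:
            warnings.append(
                f"{profile.taxon_name}/{enz}: positions {out} exceed the last "
                f"possible footprint start {limit} for region length {profile.p8_length}"
            )
    return warnings


def _motif_matches_at(seq: str, i: int, motif: str) -> bool:
    for j, m in enumerate(motif):
        if not IUPAC_CODES[seq[i + j]] <= IUPAC_CODES[m]:
            return False
    return True


def scan_sites(
    sequence: str,
    enzyme: EnzymeSpec,
    strand_mode: StrandMode = "forward",
) -> list[int]:
    """All 1-based footprint starts of *enzyme*'s motif in *sequence*.

    In ``"both"`` mode the reverse-complement motif is also scanned on
    the forward strand; a reverse-strand hit is reported at the 1-based
    start of its forward-strand footprint, and the merged list is
    deduplicated.  For palindromic motifs the two modes coincide.
    """
    seq = sequence.upper()
    motifs = [enzyme.recognition]
    if strand_mode == "both":
        rc = reverse_complement(enzyme.recognition)
        if rc != enzyme.recognition:
            motifs.append(rc)
    elif strand_mode != "forward":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    hits: set[int] = set()
    for motif in motifs:
        m = len(motif)
        for i in range(len(seq) - m + 1):
            if _motif_matches_at(seq, i, motif):
                hits.add(i + 1)
    return sorted(hits)


def map_all(
    regions: Sequence[P8Region],
    enzymes: Sequence[EnzymeSpec],
    strand_mode: StrandMode = "forward",
) -> list[SiteProfile]:
    """One :class:`SiteProfile` per region, input order preserved.

    Taxon names must be unique — a profile is keyed by taxon downstream.
    """
    seen: dict[str, int] = {}
    for i, r in enumerate(regions):
        if r.taxon_name in seen:
            raise ValueError(
                f"duplicate taxon name {r.taxon_name!r} "
                f"(records {seen[r.taxon_name]} and {i})"
            )
        seen[r.taxon_name] = i
    return [
        SiteProfile(
            taxon_name=r.taxon_name,
            accession=r.accession,
            p8_length=r.length,
            sites={e.name: tuple(scan_sites(r.sequence, e, strand_mode)) for e in enzymes},
        )
        for r in regions
    ]


def enzymes_cutting(profile: SiteProfile) -> int:
    """Number of enzymes with at least one recognition site in the profile."""
    return sum(1 for positions in profile.sites.values() if positions)


# ---------------------------------------------------------------------------
# Profile TSV dialect: accession, taxon, p8_length, then one column per
# enzyme holding comma-separated positions ("" for none).


def write_profiles(
    profiles: Sequence[SiteProfile],
    enzyme_names: Sequence[str],
    path: str | Path | TextIO,
) -> None:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "accession": p.accession,
            "taxon": p.taxon_name,
            "p8_length": p.p8_length,
        }
        for enz in enzyme_names:
            row[enz] = ",".join(str(x) for x in p.sites.get(enz, ()))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["accession", "taxon", "p8_length", *enzyme_names])
    df.to_csv(path, sep="\t", index=False)


def read_profiles(source: str | Path | TextIO) -> tuple[list[SiteProfile], list[str]]:
    """Read a profile TSV; returns (profiles, enzyme column names)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = ["accession", "taxon", "p8_length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns {missing}")
    enzyme_names = [c for c in df.columns if c not in required]
    profiles = []
    for _, row in df.iterrows():
        sites = {}
        for enz in enzyme_names:
            cell = row[enz].strip()
            sites[enz] = tuple(int(x) for x in cell.split(",")) if cell else ()
        profiles.append(
            SiteProfile(
                taxon_name=row["taxon"],
                accession=row["accession"],
                p8_length=int(row["p8_length"]),
                sites=sites,
            )
        )
    return profiles, enzyme_names
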