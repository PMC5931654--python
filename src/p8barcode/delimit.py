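"""Locating the trnL intron amplicon and excising the P8 hypervariable region.

The whole trnL(UAA) intron is amplified with the universal primer pair
``c``/``d``; the P8 stem-loop lies inside the amplicon between two
conserved border motifs.  Because the community has no single printed
definition of those borders, they are configuration
(:class:`AnchorConfig`), not code: the shipped defaults are the anchors
used by the synthetic-sequence generator and should be replaced with
literature-derived motifs for real surveys.

Primer and anchor matching is degeneracy-aware and *permissive*: a subject
base matches a pattern base whenever their IUPAC base sets intersect,
mirroring the tolerance of primer binding.  All coordinates are 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO

from Bio import SeqIO

from .enzymes import IUPAC_CODES, reverse_complement

__all__ = [
    "PrimerPair",
    "TrnLRecord",
    "P8Region",
    "AnchorConfig",
    "Delimitation",
    "locate_amplicon",
    "delimit_p8",
    "delimit_records",
    "filter_complete",
    "read_fasta",
    "write_p8_fasta",
    "write_delimitation_report",
    "load_anchor_config",
    "default_anchors",
]

#: Universal trnL intron primers, stored 5'->3'.
PRIMER_C = "CGAAATCGGTAGACGCTACG"
PRIMER_D = "GGGGATAGAGGGACTTGAAC"


@dataclass(frozen=True)
class PrimerPair:
    """The universal c/d primer pair flanking the trnL intron."""

    c_primer: str = PRIMER_C
    d_primer: str = PRIMER_D

    def __post_init__(self) -> None:
        for label, p in (("c", self.c_primer), ("d", self.d_primer)):
            bad = sorted({ch for ch in p.upper() if ch not in IUPAC_CODES})
            if not p or bad:
                raise ValueError(f"primer {label!r}: invalid sequence {p!r}")
        object.__setattr__(self, "c_primer", self.c_primer.upper())
        object.__setattr__(self, "d_primer", self.d_primer.upper())


@dataclass(frozen=True)
class TrnLRecord:
    """One input sequence record (typically a whole trnL region)."""

    record_id: str
    taxon_name: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = sorted({c for c in seq if c not in IUPAC_CODES})
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {bad} in sequence"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class P8Region:
    """A delimited P8 hypervariable region.

    ``start``/``end`` are 1-based inclusive coordinates within the parent
    sequence the region was excised from.
    """

    taxon_name: str
    accession: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid P8 coordinates [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"P8 sequence length {len(self.sequence)} inconsistent with "
                f"coordinates [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnchorConfig:
    """IUPAC motifs flanking the P8 region, plus a mismatch budget."""

    left_anchor: str
    right_anchor: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for label, a in (("left", self.left_anchor), ("right", self.right_anchor)):
            bad = sorted({ch for ch in a.upper() if ch not in IUPAC_CODES})
            if not a or bad:
                raise ValueError(f"{label} anchor: invalid sequence {a!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        object.__setattr__(self, "left_anchor", self.left_anchor.upper())
        object.__setattr__(self, "right_anchor", self.right_anchor.upper())


@dataclass(frozen=True)
class Delimitation:
    """Outcome of one P8 delimitation: a region, or a reason it is absent."""

    region: Optional[P8Region] = None
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.region is not None


def _bases_intersect(subject: str, pattern: str) -> bool:
    return bool(IUPAC_CODES[subject] & IUPAC_CODES[pattern])


def find_pattern_matches(sequence: str, pattern: str, max_mismatches: int = 0) -> list[int]:
    """All 1-based starts where *pattern* matches *sequence* within the
    Hamming mismatch budget, under intersection semantics."""
    seq = sequence.upper()
    pat = pattern.upper()
    m = len(pat)
    hits: list[int] = []
    for i in range(len(seq) - m + 1):
        mismatches = 0
        for j in range(m):
            if not _bases_intersect(seq[i + j], pat[j]):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            hits.append(i + 1)
    return hits


def locate_amplicon(
    sequence: str,
    primers: PrimerPair | None = None,
    max_mismatches: int = 0,
) -> Optional[tuple[int, int]]:
    """Locate the c/d amplicon span within *sequence*.

    Returns 1-based inclusive bounds from the start of the outermost
    c-primer match to the end of the outermost reverse-complemented
    d-primer match, or ``None`` when either site is missing within the
    mismatch budget.  If the forward orientation yields nothing, the
    reverse complement of the input is searched and the span is mirrored
    back into input coordinates, so records deposited in either
    orientation are handled symmetrically.
    """
    primers = primers or PrimerPair()

    def _scan(seq: str) -> Optional[tuple[int, int]]:
        c_hits = find_pattern_matches(seq, primers.c_primer, max_mismatches)
        d_rc = reverse_complement(primers.d_primer)
        d_hits = find_pattern_matches(seq, d_rc, max_mismatches)
        if not c_hits or not d_hits:
            return None
        start = min(c_hits)
        end = max(d_hits) + len(primers.d_primer) - 1
        if end <= start:
            return None
        return start, end

    span = _scan(sequence)
    if span is not None:
        return span
    n = len(sequence)
    mirrored = _scan(reverse_complement(sequence))
    if mirrored is None:
        return None
    s, e = mirrored
    return n - e + 1, n - s + 1


def delimit_p8(
    intron_sequence: str,
    anchors: AnchorConfig,
    *,
    taxon_name: str = "",
    accession: str = "",
    offset: int = 0,
) -> Delimitation:
    """Excise the P8 region strictly between the innermost anchor matches.

    The left border is the left-anchor match ending furthest 3'; the right
    border is the nearest right-anchor match beyond it.  Absence of either
    anchor, or an out-of-order/overlapping pair, yields an empty
    :class:`Delimitation` carrying a diagnostic reason.  *offset* shifts
    reported coordinates (used when the sequence is a slice of a larger
    record).
    """
    seq = intron_sequence.upper()
    left_hits = find_pattern_matches(seq, anchors.left_anchor, anchors.max_mismatches)
    if not left_hits:
        return Delimitation(reason="left anchor not found")
    right_hits = find_pattern_matches(seq, anchors.right_anchor, anchors.max_mismatches)
    if not right_hits:
        return Delimitation(reason="right anchor not found")
    left_end = max(left_hits) + len(anchors.left_anchor) - 1
    inner_right = [p for p in right_hits if p > left_end]
    if not inner_right:
        return Delimitation(reason="anchors overlapping or out of order")
    right_start = min(inner_right)
    if right_start - left_end <= 1:
        return Delimitation(reason="empty region between anchors")
    start, end = left_end + 1, right_start - 1
    region = P8Region(
        taxon_name=taxon_name,
        accession=accession,
        start=start + offset,
        end=end + offset,
        sequence=seq[start - 1 : end],
    )
    return Delimitation(region=region)


def delimit_records(
    records: Iterable[TrnLRecord],
    anchors: AnchorConfig,
    primers: PrimerPair | None = None,
    primer_mismatches: int = 0,
    use_primers: bool = True,
) -> list[tuple[TrnLRecord, Delimitation]]:
    """Delimit the P8 region of each record.

    When *use_primers* is true and both primer sites are found, the anchor
    search is confined to the amplicon; otherwise the whole record is
    searched (coordinates always refer to the input sequence).
    """
    out: list[tuple[TrnLRecord, Delimitation]] = []
    for rec in records:
        seq, offset = rec.sequence, 0
        if use_primers:
            span = locate_amplicon(rec.sequence, primers, primer_mismatches)
            if span is not None:
                seq = rec.sequence[span[0] - 1 : span[1]]
                offset = span[0] - 1
        out.append(
            (
                rec,
                delimit_p8(
                    seq,
                    anchors,
                    taxon_name=rec.taxon_name,
                    accession=rec.accession,
                    offset=offset,
                ),
            )
        )
    return out


def filter_complete(
    delimited: Sequence[tuple[TrnLRecord, Delimitation]],
) -> tuple[list[P8Region], list[tuple[str, str]]]:
    """Keep records with a complete P8; log the rest.

    Returns the retained regions (input order) and an exclusion log of
    ``(accession, reason)`` for every record without a delimited P8.
    """
    kept: list[P8Region] = []
    log: list[tuple[str, str]] = []
    for rec, res in delimited:
        if res.region is not None:
            kept.append(res.region)
        else:
            log.append((rec.accession, res.reason or "no complete P8 region"))
    return kept, log


# ---------------------------------------------------------------------------
# I/O


def read_fasta(source: str | Path | TextIO) -> list[TrnLRecord]:
    """Read FASTA records; headers are parsed as ``accession taxon_name``.

    The first whitespace-delimited token of the header is the accession
    (also the record id); the remainder, if any, is the taxon name.
    Sequences are validated against the IUPAC alphabet; a violation raises
    ``ValueError`` naming the record.
    """
    records: list[TrnLRecord] = []
    for rec in SeqIO.parse(source, "fasta"):
        taxon = rec.description.split(None, 1)[1].strip() if " " in rec.description else rec.id
        records.append(
            TrnLRecord(
                record_id=rec.id,
                taxon_name=taxon,
                accession=rec.id,
                sequence=str(rec.seq),
            )
        )
    return records


def write_p8_fasta(regions: Iterable[P8Region], path: str | Path) -> None:
    """Write delimited P8 regions as FASTA (``>accession taxon``)."""
    with open(path, "w") as fh:
        for r in regions:
            header = f"{r.accession} {r.taxon_name}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def write_delimitation_report(
    delimited: Sequence[tuple[TrnLRecord, Delimitation]], path: str | Path
) -> None:
    """Tab-delimited delimitation report: accession, taxon, start, end,
    length, status."""
    with open(path, "w") as fh:
        fh.write("accession\ttaxon\tstart\tend\tlength\tstatus\n")
        for rec, res in delimited:
            if res.region is not None:
                r = res.region
                fh.write(
                    f"{rec.accession}\t{rec.taxon_name}\t{r.start}\t{r.end}\t{r.length}\tcomplete\n"
                )
            else:
                fh.write(f"{rec.accession}\t{rec.taxon_name}\t\t\t\t{res.reason}\n")


def load_anchor_config(source: str | Path | TextIO) -> AnchorConfig:
    """Read an anchor configuration file (``key<TAB>value`` lines)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"anchor config line {lineno}: expected key<TAB>value")
        values[parts[0].strip()] = parts[1].strip()
    try:
        return AnchorConfig(
            left_anchor=values["left_anchor"],
            right_anchor=values["right_anchor"],
            max_mismatches=int(values.get("max_mismatches", "0")),
        )
    except KeyError as exc:
        raise ValueError(f"anchor config missing key {exc.args[0]!r}") from None


def default_anchors() -> AnchorConfig:
    """The bundled default anchor configuration (see module docstring)."""
    with resources.files("p8barcode.data").joinpath("anchors_default.tsv").open() as fh:
        return load_anchor_config(fh)
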