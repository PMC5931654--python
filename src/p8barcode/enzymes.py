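"""Restriction enzymes as IUPAC-degenerate recognition motifs.

A restriction endonuclease is represented purely by its recognition
sequence written in the IUPAC nucleotide alphabet (e.g. ApoI = RAATTY,
with R = A or G and Y = C or T).  Cut offsets, overhangs and methylation
sensitivity are irrelevant to presence/absence site mapping and are not
modelled.

Only motifs of at least :data:`MIN_SITE_LENGTH` nucleotides are accepted,
matching the minimum site length used when the recognition maps for the
P8 survey were generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "IUPAC_CODES",
    "MIN_SITE_LENGTH",
    "EnzymeSpec",
    "expand_iupac",
    "builtin_core_enzymes",
    "load_enzyme_table",
    "serialize_enzyme_table",
    "extended_enzymes",
]

#: Minimum accepted recognition-site length, in nucleotides.
MIN_SITE_LENGTH = 5

#: IUPAC nucleotide code -> set of concrete bases it denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of concrete bases denoted by one IUPAC character.

    Concrete bases map to singleton sets, N to {A, C, G, T}.  Lowercase
    input is accepted.  An unknown character raises ``ValueError`` naming
    the offending character.
    """
    try:
        return IUPAC_CODES[code.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def reverse_complement(sequence: str) -> str:
    """Reverse-complement an IUPAC DNA string (degeneracy-aware)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(sequence.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC nucleotide code: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class EnzymeSpec:
    """A named restriction endonuclease recognition motif.

    Attributes
    ----------
    name:
        Enzyme identifier, e.g. ``"AgsI"``.
    recognition:
        Recognition motif in IUPAC DNA code, length >= 5.
    """

    name: str
    recognition: str
    site_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be non-empty")
        motif = self.recognition.upper()
        object.__setattr__(self, "recognition", motif)
        bad = sorted({c for c in motif if c not in IUPAC_CODES})
        if bad:
            raise ValueError(
                f"enzyme {self.name}: invalid IUPAC characters {bad} in motif {motif!r}"
            )
        if len(motif) < MIN_SITE_LENGTH:
            raise ValueError(
                f"enzyme {self.name}: recognition site {motif!r} shorter than "
                f"the minimum site length of {MIN_SITE_LENGTH} nucleotides"
            )
        object.__setattr__(self, "site_length", len(motif))

    @property
    def is_palindromic(self) -> bool:
        """True when the motif equals its own reverse complement."""
        return self.recognition == reverse_complement(self.recognition)


def builtin_core_enzymes() -> list[EnzymeSpec]:
    """The four enzymes with recognition sites across the whole P8 panel.

    AgsI (TTSAA), ApoI (RAATTY), TspDTI (ATGAA) and VspI (ATTAAT) — the
    five- and six-base cutters on which the discrimination analysis rests.
    """
    return [
        EnzymeSpec("AgsI", "TTSAA"),
        EnzymeSpec("ApoI", "RAATTY"),
        EnzymeSpec("TspDTI", "ATGAA"),
        EnzymeSpec("VspI", "ATTAAT"),
    ]


def load_enzyme_table(source: str | Path) -> list[EnzymeSpec]:
    """Parse a 2-column tab-delimited enzyme table into validated specs.

    The format is ``name<TAB>recognition``, one enzyme per line; an
    optional ``name<TAB>recognition`` header and ``#`` comment lines are
    ignored.  *source* may be a path or the table text itself (anything
    containing a newline or a tab is treated as text).

    Raises
    ------
    ValueError
        Listing every malformed row by line number, or any duplicated
        enzyme name.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" in source or "\t" in source:
        text = source
    else:
        text = Path(source).read_text()

    specs: list[EnzymeSpec] = []
    errors: list[str] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            errors.append(f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}")
            continue
        name, motif = (p.strip() for p in parts)
        if not specs and (name.lower(), motif.lower()) == ("name", "recognition"):
            continue
        if name in seen:
            errors.append(f"line {lineno}: duplicate enzyme name {name!r} (first at line {seen[name]})")
            continue
        try:
            specs.append(EnzymeSpec(name, motif))
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        seen[name] = lineno
    if errors:
        raise ValueError("invalid enzyme table:\n" + "\n".join(errors))
    return specs


def serialize_enzyme_table(specs: Iterable[EnzymeSpec]) -> str:
    """Render specs in the tab-delimited table format read by
    :func:`load_enzyme_table`."""
    lines = ["name\trecognition"]
    lines.extend(f"{s.name}\t{s.recognition}" for s in specs)
    return "\n".join(lines) + "\n"


def extended_enzymes(include_core: bool = True) -> list[EnzymeSpec]:
    """The bundled 35-enzyme panel observed to cut P8 regions.

    The four core enzymes carry motifs as printed in the source dataset;
    the remaining 31 commercial enzymes carry recognition motifs taken
    from standard REBASE definitions.  The exact enzyme definitions used
    by historical web mappers cannot be reconstructed, so this panel is
    for exploratory scans, not for the headline discrimination counts.
    """
    with resources.files("p8barcode.data").joinpath("enzymes_extended.tsv").open() as fh:
        extra = load_enzyme_table(fh.read())
    if include_core:
        return builtin_core_enzymes() + extra
    return extra
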