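"""The bundled 98-taxon P8 restriction-site survey dataset.

The dataset pairs each orchid taxon (tribe Vandeae; GenBank accession
retained) with its P8 region length and the mapped recognition-site
positions of the four core enzymes AgsI, ApoI, TspDTI and VspI.  It ships
inside the package so every analysis is reproducible offline; the
accessions allow re-deriving profiles from sequence should a user wish,
but nothing here requires network access.

Two cells of the printed source table are malformed (duplicated runs);
the bundled file carries the curated values and
:func:`curation_log` documents each repair.  One row (Phalaenopsis
inscriptiosinensis) lists site positions beyond its stated region length;
it is kept as printed and flagged, never silently repaired.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources

from .enzymes import builtin_core_enzymes
from .scan import SiteProfile, read_profiles, validate_profile

__all__ = ["CurationEntry", "load_table1", "curation_log", "TABLE1_SHA256"]

#: Frozen checksum of the bundled profile table; load_table1 refuses to
#: proceed if the file on disk has been altered.
TABLE1_SHA256 = "fe75eba5198a6f89190a3eb3989ea138e5be3dc5c23ef3e6d82e7821fdd75b84"


@dataclass(frozen=True)
class CurationEntry:
    """One documented repair of a printed table cell."""

    taxon: str
    column: str
    printed: str
    curated: str
    reason: str


def curation_log() -> list[CurationEntry]:
    """Every cell of the bundled table that differs from the printed source."""
    entries = []
    with resources.files("p8barcode.data").joinpath("table1_curation.txt").open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            taxon, column, printed, curated, reason = line.split("\t")
            entries.append(CurationEntry(taxon, column, printed, curated, reason))
    return entries


def load_table1(verify_checksum: bool = True, warn: bool = True) -> list[SiteProfile]:
    """Load the bundled 98-taxon survey as :class:`SiteProfile` objects.

    Positions are deduplicated and sorted on load.  Profiles whose listed
    positions cannot fit within the stated region length are flagged with
    a ``UserWarning`` when *warn* is true (flag-and-keep).

    Raises
    ------
    ValueError
        If the bundled file's checksum does not match the frozen value.
    """
    data = resources.files("p8barcode.data").joinpath("table1_profiles.tsv").read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != TABLE1_SHA256:
            raise ValueError(
                f"bundled table checksum mismatch: {digest} != {TABLE1_SHA256}"
            )
    with resources.files("p8barcode.data").joinpath("table1_profiles.tsv").open() as fh:
        profiles, _ = read_profiles(fh)
    if warn:
        enzymes = builtin_core_enzymes()
        for p in profiles:
            for msg in validate_profile(p, enzymes):
                warnings.warn(msg, UserWarning, stacklevel=2)
    return profiles
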