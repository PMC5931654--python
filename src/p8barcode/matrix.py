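"""Binary presence/absence feature matrix over (enzyme, position) sites.

Features are *global* positions shared across taxa of different lengths —
no alignment or length normalisation is applied.  That is deliberate:
two regions of unequal length that list identical site positions score as
identical rows, which is exactly the behaviour of presence/absence
scoring of mapped positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .scan import SiteProfile

__all__ = ["BinaryMatrix", "build_matrix", "matrix_summary", "write_matrix"]


@dataclass(frozen=True)
class BinaryMatrix:
    """Taxa x (enzyme, position) 0/1 matrix.

    ``features`` are sorted by (enzyme name, position); every feature is
    present in at least one taxon.  Rows preserve profile input order.
    """

    taxa: tuple[str, ...]
    features: tuple[tuple[str, int], ...]
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.uint8)
        if cells.shape != (len(self.taxa), len(self.features)):
            raise ValueError(
                f"cells shape {cells.shape} inconsistent with "
                f"{len(self.taxa)} taxa x {len(self.features)} features"
            )
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise ValueError("cells must be 0/1")
        object.__setattr__(self, "cells", cells)

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(taxon)]


def build_matrix(
    profiles: Sequence[SiteProfile], enzyme_subset: Sequence[str]
) -> BinaryMatrix:
    """Score profiles over the union of observed sites of the selected
    enzymes.

    Columns are exactly the (enzyme, position) pairs present in at least
    one profile; a taxon with no sites for the subset keeps an all-zero
    row rather than being dropped.
    """
    if not enzyme_subset:
        raise ValueError("enzyme_subset must be non-empty")
    known = set().union(*(p.sites.keys() for p in profiles)) if profiles else set()
    unknown = [e for e in enzyme_subset if e not in known]
    if unknown:
        raise ValueError(f"unknown enzyme name(s) {unknown}; profiles carry {sorted(known)}")
    features = sorted(
        {(enz, pos) for p in profiles for enz in enzyme_subset for pos in p.sites.get(enz, ())}
    )
    index = {f: j for j, f in enumerate(features)}
    cells = np.zeros((len(profiles), len(features)), dtype=np.uint8)
    for i, p in enumerate(profiles):
        for enz in enzyme_subset:
            for pos in p.sites.get(enz, ()):
                cells[i, index[(enz, pos)]] = 1
    return BinaryMatrix(
        taxa=tuple(p.taxon_name for p in profiles),
        features=tuple(features),
        cells=cells,
    )


def matrix_summary(matrix: BinaryMatrix) -> tuple[int, int, float]:
    """(taxa count, feature count, fill fraction); fill is 0 for an empty
    feature set."""
    n, m = matrix.cells.shape
    fill = float(matrix.cells.mean()) if m and n else 0.0
    return n, m, fill


def write_matrix(matrix: BinaryMatrix, path: str | Path | TextIO) -> None:
    """Export as a tab-delimited 0/1 table with ``enzyme:position`` headers."""
    df = pd.DataFrame(
        matrix.cells,
        index=pd.Index(matrix.taxa, name="taxon"),
        columns=[f"{enz}:{pos}" for enz, pos in matrix.features],
    )
    df.to_csv(path, sep="\t")
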