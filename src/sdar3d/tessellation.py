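"""Regular tessellation of the 3D-SDAR space into bins and occupancy counting.

The shift–shift–distance space is cut by a regular rectangular grid anchored
at the origin (0 ppm, 0 ppm, 0 Å).  Bins are half-open on every axis,
``[edge, edge + width)``, so a value sitting exactly on an edge belongs to
the upper bin.  A bin is identified by its integer index triple (i, j, k),
which makes bins comparable across training subsets and grids.

Occupancy of a bin for a compound is the number of its fingerprint elements
falling inside the bin, counted with multiplicity; the occupancy rows of a
dataset form the m × n matrix the regression engines consume (m compounds,
n occupied bins).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fingerprint import FingerprintElement, FingerprintSet

__all__ = [
    "GridSpec",
    "OccupancyMatrix",
    "CANONICAL_XY_WIDTHS",
    "CANONICAL_Z_HEIGHTS",
    "enumerate_grids",
    "canonical_grids",
    "bin_index",
    "build_occupancy_matrix",
]

#: XY widths (ppm) and Z heights (Å) of the canonical 50-grid scan.
CANONICAL_XY_WIDTHS: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
CANONICAL_Z_HEIGHTS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class GridSpec:
    """One regular grid: square XY bins of ``dx`` ppm and Z bins of ``dz`` Å."""

    dx: float
    dz: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dz <= 0:
            raise ValueError("grid widths must be positive")

    @property
    def dy(self) -> float:
        return self.dx

    def label(self) -> str:
        return f"{self.dx:g} ppm x {self.dy:g} ppm x {self.dz:g} A"


def enumerate_grids(
    xy_widths: Iterable[float] = CANONICAL_XY_WIDTHS,
    z_heights: Iterable[float] = CANONICAL_Z_HEIGHTS,
) -> list[GridSpec]:
    """Cartesian product of XY widths and Z heights, xy-major ascending order."""
    xs = sorted(float(x) for x in xy_widths)
    zs = sorted(float(z) for z in z_heights)
    if not xs or not zs:
        raise ValueError("width lists must be non-empty")
    if xs[0] <= 0 or zs[0] <= 0:
        raise ValueError("grid widths must be positive")
    return [GridSpec(dx, dz) for dx, dz in itertools.product(xs, zs)]


def canonical_grids() -> list[GridSpec]:
    """The 50 grids of the canonical granularity scan (2–20 ppm × 0.5–2.5 Å)."""
    return enumerate_grids()


def bin_index(element: FingerprintElement, grid: GridSpec) -> tuple[int, int, int]:
    """Integer (i, j, k) bin of a fingerprint element under ``grid``.

    Floor division against the half-open convention [edge, edge + width).
    """
    if element.shift_x < 0 or element.shift_y < 0 or element.distance <= 0:
        raise ValueError("element outside the 3D-SDAR domain")
    return (
        int(np.floor(element.shift_x / grid.dx)),
        int(np.floor(element.shift_y / grid.dy)),
        int(np.floor(element.distance / grid.dz)),
    )


@dataclass
class OccupancyMatrix:
    """Per-compound bin-occupancy rows for one grid.

    ``counts`` is m × n with m compounds and n occupied bins; ``bin_labels``
    carries the (i, j, k) identity of each column in lexicographic order.
    Row sums equal each compound's fingerprint element count.
    """

    grid: GridSpec
    compound_ids: list[str]
    bin_labels: list[tuple[int, int, int]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.compound_ids), len(self.bin_labels)):
            raise ValueError("counts shape does not match labels")

    @property
    def m(self) -> int:
        return len(self.compound_ids)

    @property
    def n(self) -> int:
        return len(self.bin_labels)

    def to_frame(self) -> pd.DataFrame:
        """Dense export: rows = compounds, columns = "i,j,k" labels."""
        cols = [f"{i},{j},{k}" for i, j, k in self.bin_labels]
        return pd.DataFrame(self.counts, index=self.compound_ids, columns=cols)

    def to_triplets(self) -> pd.DataFrame:
        """Sparse export: (compound_id, i, j, k, count) for nonzero cells."""
        rows, cols = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "compound_id": [self.compound_ids[r] for r in rows],
                "i": [self.bin_labels[c][0] for c in cols],
                "j": [self.bin_labels[c][1] for c in cols],
                "k": [self.bin_labels[c][2] for c in cols],
                "count": self.counts[rows, cols],
            }
        )


def build_occupancy_matrix(
    fingerprints: Sequence[FingerprintSet], grid: GridSpec
) -> OccupancyMatrix:
    """Count fingerprint elements per bin for every compound.

    Columns are restricted to bins occupied by at least one compound and
    ordered lexicographically by (i, j, k).
    """
    if not fingerprints:
        raise ValueError("no fingerprints given")
    per_compound: list[dict[tuple[int, int, int], int]] = []
    occupied: set[tuple[int, int, int]] = set()
    for fp in fingerprints:
        counts: dict[tuple[int, int, int], int] = {}
        for e in fp.elements:
            b = bin_index(e, grid)
            counts[b] = counts.get(b, 0) + 1
        per_compound.append(counts)
        occupied.update(counts)
    labels = sorted(occupied)
    col = {b: idx for idx, b in enumerate(labels)}
    mat = np.zeros((len(fingerprints), len(labels)), dtype=np.int64)
    for r, counts in enumerate(per_compound):
        for b, c in counts.items():
            mat[r, col[b]] = c
    return OccupancyMatrix(
        grid=grid,
        compound_ids=[fp.compound_id for fp in fingerprints],
        bin_labels=labels,
        counts=mat,
    )
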