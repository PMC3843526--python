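"""3D-SDAR fingerprints: carbon shift-pair / distance triplets.

A molecule's 3D-SDAR fingerprint is the set of all (δ(Cᵢ), δ(Cⱼ), dᵢⱼ)
triplets over unordered pairs of its carbon atoms: two ¹³C chemical shifts
on the X/Y axes and the Euclidean inter-atomic distance on Z.  Only carbon
atoms participate; heteroatoms influence the fingerprint solely through
their effect on the input shifts.  A molecule with N_C carbons therefore
yields exactly N_C(N_C − 1)/2 fingerprint elements, and symmetric molecules
produce coincident elements that are retained with multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "FingerprintElement",
    "FingerprintSet",
    "build_fingerprint",
    "element_count",
    "fingerprints_to_frame",
]


@dataclass(frozen=True)
class Compound:
    """A compound ready for fingerprinting.

    Parameters
    ----------
    id:
        Compound identifier, unique within a dataset.
    element_symbols:
        Chemical symbol per atom, e.g. ``["C", "C", "O", ...]``.
    coordinates:
        ``(n_atoms, 3)`` Cartesian coordinates in Å.
    carbon_shifts:
        One ¹³C chemical shift (ppm) per carbon atom, in atom order.
    activity:
        log(1/EC50); ``None`` for compounds without a measured activity.
    """

    id: str
    element_symbols: tuple[str, ...]
    coordinates: np.ndarray
    carbon_shifts: tuple[float, ...]
    activity: Optional[float] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "element_symbols", tuple(self.element_symbols))
        object.__setattr__(self, "carbon_shifts", tuple(float(s) for s in self.carbon_shifts))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"{self.id}: coordinates must be (n_atoms, 3)")
        if len(self.element_symbols) != coords.shape[0]:
            raise ValueError(f"{self.id}: {len(self.element_symbols)} symbols for {coords.shape[0]} coordinates")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        n_c = self.n_carbons
        if len(self.carbon_shifts) != n_c:
            raise ValueError(
                f"{self.id}: {len(self.carbon_shifts)} carbon shifts for {n_c} carbon atoms"
            )
        if any(not math.isfinite(s) or s < 0 for s in self.carbon_shifts):
            raise ValueError(f"{self.id}: shifts must be finite and >= 0 ppm")

    @property
    def n_carbons(self) -> int:
        return sum(1 for s in self.element_symbols if s == "C")

    @property
    def carbon_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.element_symbols) if s == "C")


@dataclass(frozen=True)
class FingerprintElement:
    """One (shift, shift, distance) triplet for a carbon pair.

    Shifts are canonicalized so ``shift_x <= shift_y``; ``atom_pair`` holds
    the two carbon atom indices ordered to match (the atom carrying shift_x
    first).
    """

    shift_x: float
    shift_y: float
    distance: float
    atom_pair: tuple[int, int]

    def triplet(self) -> tuple[float, float, float]:
        return (self.shift_x, self.shift_y, self.distance)


@dataclass
class FingerprintSet:
    """All fingerprint elements of one compound (multiplicity preserved)."""

    compound_id: str
    elements: list[FingerprintElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.elements)


def element_count(n_carbons: int) -> int:
    """Number of fingerprint elements for a molecule with ``n_carbons`` carbons.

    Equals the number of unordered carbon pairs, n(n−1)/2.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return n_carbons * (n_carbons - 1) // 2


def build_fingerprint(compound: Compound, mirror: bool = False) -> FingerprintSet:
    """Build the 3D-SDAR fingerprint of a compound.

    One element is produced per unordered carbon pair: the two shifts
    canonicalized as (min, max) and the Euclidean distance between the
    carbons.  Coincident elements arising from molecular symmetry are all
    retained.  With ``mirror=True`` every off-diagonal pair additionally
    contributes its (max, min) reflection across the X=Y plane, so the shift
    plane is symmetric instead of canonicalized.
    """
    carbons = compound.carbon_indices
    if len(carbons) < 2:
        raise ValueError(f"degenerate compound {compound.id!r}: fewer than 2 carbon atoms")
    shifts = dict(zip(carbons, compound.carbon_shifts))
    coords = compound.coordinates
    elements: list[FingerprintElement] = []
    for a in range(len(carbons)):
        for b in range(a + 1, len(carbons)):
            i, j = carbons[a], carbons[b]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            si, sj = shifts[i], shifts[j]
            if si <= sj:
                lo, hi, pair = si, sj, (i, j)
            else:
                lo, hi, pair = sj, si, (j, i)
            elements.append(FingerprintElement(lo, hi, d, pair))
            if mirror and lo != hi:
                elements.append(FingerprintElement(hi, lo, d, (pair[1], pair[0])))
    return FingerprintSet(compound.id, elements)


def fingerprints_to_frame(fingerprints: Sequence[FingerprintSet]) -> pd.DataFrame:
    """Tabulate fingerprints for CSV export.

    Columns: compound_id, atom_i, atom_j, shift_x_ppm, shift_y_ppm, distance_A.
    """
    records = [
        (fp.compound_id, e.atom_pair[0], e.atom_pair[1], e.shift_x, e.shift_y, e.distance)
        for fp in fingerprints
        for e in fp.elements
    ]
    return pd.DataFrame(
        records,
        columns=["compound_id", "atom_i", "atom_j", "shift_x_ppm", "shift_y_ppm", "distance_A"],
    )
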