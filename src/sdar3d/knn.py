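"""Tanimoto-similarity KNN regression on raw occupancy vectors.

The similarity between two compounds is the generalized (vector-form)
Tanimoto coefficient of their bin-occupancy rows,

    T(a, b) = a·b / (‖a‖² + ‖b‖² − a·b),

computed on the raw, non-standardized counts so that T is an invariant of
the compound pair at a fixed grid: it does not depend on which training
subset the pair appears in.  Activity of a query compound is the
similarity-weighted mean of the activities of its k most similar training
compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tessellation import OccupancyMatrix

__all__ = ["KNNConfig", "tanimoto", "similarity_matrix", "tanimoto_cross", "knn_predict"]


@dataclass(frozen=True)
class KNNConfig:
    """Neighbor count for KNN prediction (both odd and even k are valid)."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Generalized Tanimoto similarity of two non-negative occupancy vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share the same bin label set")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("occupancy vectors must be non-negative")
    ab = float(a @ b)
    denom = float(a @ a) + float(b @ b) - ab
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two all-zero vectors")
    return ab / denom


def tanimoto_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise T between the rows of ``A`` and the rows of ``B``.

    Entries involving an all-zero row are NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    dot = A @ B.T
    na = np.einsum("ij,ij->i", A, A)
    nb = np.einsum("ij,ij->i", B, B)
    denom = na[:, None] + nb[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), np.nan)
    T[na == 0, :] = np.nan
    T[:, nb == 0] = np.nan
    # identical nonzero rows: denom == dot, T exactly 1
    return T


def similarity_matrix(occ: OccupancyMatrix) -> pd.DataFrame:
    """Symmetric all-pairs Tanimoto matrix, compound ids on both axes.

    Rows with zero total occupancy yield NaN entries (flagged with a
    warning) since T is undefined for them.
    """
    if occ.m < 2:
        raise ValueError("need at least 2 compounds")
    T = tanimoto_cross(occ.counts, occ.counts)
    zero = np.asarray(occ.counts).sum(axis=1) == 0
    if zero.any():
        ids = [occ.compound_ids[i] for i in np.nonzero(zero)[0]]
        warnings.warn(f"all-zero occupancy rows, similarity undefined: {ids}", stacklevel=2)
    return pd.DataFrame(T, index=occ.compound_ids, columns=occ.compound_ids)


def knn_predict(
    train_occ: np.ndarray,
    train_y: np.ndarray,
    query_occ: np.ndarray,
    config: KNNConfig,
    train_ids: list[str] | None = None,
) -> float:
    """Similarity-weighted activity from the k nearest training compounds.

    Neighbors are ranked by T descending; ties are broken by training
    compound id (stable ascending) for cross-platform determinism.  If the
    selected neighbors all have zero similarity the prediction falls back to
    their unweighted mean.
    """
    train_occ = np.atleast_2d(np.asarray(train_occ, dtype=float))
    train_y = np.asarray(train_y, dtype=float).ravel()
    m = train_occ.shape[0]
    if config.k > m:
        raise ValueError(f"k={config.k} exceeds training size {m}")
    sims = tanimoto_cross(np.atleast_2d(np.asarray(query_occ, dtype=float)), train_occ)[0]
    sims = np.where(np.isnan(sims), 0.0, sims)
    if train_ids is None:
        train_ids = [str(i) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-sims[i], train_ids[i]))
    top = order[: config.k]
    w = sims[top]
    if w.sum() == 0.0:
        warnings.warn("all top-k similarities are zero; using unweighted mean", stacklevel=2)
        return float(train_y[top].mean())
    return float((w * train_y[top]).sum() / w.sum())
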