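"""SIMPLS partial least squares on standardized occupancy matrices.

The PLS engine standardizes every descriptor column (z-score on the
training rows), centers the response, and fits latent variables by the
SIMPLS construction: the cross-product vector s = Xᵀy is deflated directly
by projecting out an orthonormal basis of the X-loading space, which yields
mutually orthogonal scores and one x-weight vector per latent variable.
With as many latent variables as the rank of X the fit coincides with
ordinary least squares; with fewer it is a shrunken, more stable model.

For a univariate response the SIMPLS weight direction of each component is
unique up to scale; weights exposed for interpretation are normalized to
unit length so only their relative pattern across bins carries meaning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StandardizationParams",
    "PLSModel",
    "standardize",
    "simpls_fit",
    "pls_predict",
    "extract_lv_weights",
    "model_to_json",
    "model_from_json",
]

_RANK_TOL = 1e-10


@dataclass
class StandardizationParams:
    """Column means/SDs learned on training rows (sample SD, n−1 denominator)."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean mask of constant columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sd = np.where(self.zero_variance, 1.0, self.sd)
        Z = (X - self.mean) / sd
        Z[:, self.zero_variance] = 0.0
        return Z


def standardize(
    X: np.ndarray, params: Optional[StandardizationParams] = None
) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score columns; fit on ``X`` when ``params`` is None, else apply stored params.

    Zero-variance columns map to 0 but are retained, so bin labels stay
    aligned across training subsets.
    """
    X = np.asarray(X, dtype=float)
    if params is None:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit standardization")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd <= _RANK_TOL * (1.0 + np.abs(mean))
        params = StandardizationParams(mean=mean, sd=sd, zero_variance=zero)
    return params.apply(X), params


@dataclass
class PLSModel:
    """A fitted SIMPLS model over labeled occupancy bins.

    ``coef_path[:, a]`` holds the regression coefficients (standardized X
    scale) using a+1 latent variables; ``coef`` is the column for ``n_lv``.
    ``weights[:, a]`` is the unit-norm x-weight vector of LV a+1.
    """

    n_lv: int
    bin_labels: list[tuple[int, int, int]]
    coef_path: np.ndarray
    weights: np.ndarray
    std_params: StandardizationParams
    y_mean: float

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[:, self.n_lv - 1]


def simpls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    bin_labels: Optional[Sequence[tuple[int, int, int]]] = None,
) -> PLSModel:
    """Fit SIMPLS with ``n_lv`` latent variables on raw occupancy rows.

    ``X`` is standardized internally (fit on these rows) and ``y`` centered.
    If ``n_lv`` exceeds the effective rank of the standardized X the model is
    truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if bin_labels is None:
        bin_labels = [(c, 0, 0) for c in range(X.shape[1])]
    Z, params = standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    n = Z.shape[1]
    s = Z.T @ yc
    scale0 = float(np.linalg.norm(Z @ s)) if n else 0.0
    R = np.zeros((n, n_lv))
    W = np.zeros((n, n_lv))
    Q = np.zeros(n_lv)
    V = np.zeros((n, n_lv))
    a = 0
    while a < n_lv:
        r = s.copy()
        t = Z @ r
        tt = float(np.linalg.norm(t))
        if tt <= _RANK_TOL * max(scale0, 1.0):
            break  # rank of X (or X'y) exhausted
        t /= tt
        r /= tt
        p = Z.T @ t
        q = float(yc @ t)
        v = p - V[:, :a] @ (V[:, :a].T @ p)
        nv = float(np.linalg.norm(v))
        if nv <= _RANK_TOL:
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a] = r
        nr = float(np.linalg.norm(r))
        W[:, a] = r / nr if nr > 0 else r
        Q[a] = q
        V[:, a] = v
        a += 1
    if a == 0:
        # y uncorrelated with X (e.g. constant response): null model
        a = 1
    elif a < n_lv:
        warnings.warn(
            f"requested {n_lv} latent variables but rank supports only {a}; truncated",
            stacklevel=2,
        )
    coef_path = np.cumsum(R[:, :a] * Q[:a], axis=1)
    return PLSModel(
        n_lv=a,
        bin_labels=list(bin_labels),
        coef_path=coef_path,
        weights=W[:, :a],
        std_params=params,
        y_mean=y_mean,
    )


def _align_columns(
    model: PLSModel, X_new: np.ndarray, bin_labels: Optional[Sequence[tuple[int, int, int]]]
) -> np.ndarray:
    """Map query columns onto the training bin layout.

    Unseen bins are dropped; training bins missing from the query are
    imputed as zero occupancy.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if bin_labels is None:
        if X_new.shape[1] != len(model.bin_labels):
            raise ValueError("column count mismatch and no bin labels to align on")
        return X_new
    pos = {b: idx for idx, b in enumerate(model.bin_labels)}
    out = np.zeros((X_new.shape[0], len(model.bin_labels)))
    hits = 0
    for c, b in enumerate(bin_labels):
        idx = pos.get(tuple(b))
        if idx is not None:
            out[:, idx] = X_new[:, c]
            hits += 1
    if hits == 0:
        raise ValueError("no overlap between query bins and training bins")
    return out


def pls_predict(
    model: PLSModel,
    X_new: np.ndarray,
    bin_labels: Optional[Sequence[tuple[int, int, int]]] = None,
    n_lv: Optional[int] = None,
) -> np.ndarray:
    """Predict activities for occupancy rows ``X_new``.

    Applies the stored standardization, then the coefficients for ``n_lv``
    components (defaults to the model's), and adds back the training mean of
    the response.
    """
    X_aligned = _align_columns(model, X_new, bin_labels)
    Z = model.std_params.apply(X_aligned)
    k = model.n_lv if n_lv is None else n_lv
    if not 1 <= k <= model.coef_path.shape[1]:
        raise ValueError(f"n_lv {k} outside fitted range 1..{model.coef_path.shape[1]}")
    return Z @ model.coef_path[:, k - 1] + model.y_mean


def extract_lv_weights(model: PLSModel, lv: int) -> np.ndarray:
    """Unit-norm x-weight vector of latent variable ``lv`` (1-based)."""
    if not 1 <= lv <= model.n_lv:
        raise ValueError(f"lv must be in 1..{model.n_lv}")
    return model.weights[:, lv - 1].copy()


def model_to_json(model: PLSModel) -> str:
    """Serialize a fitted model to a self-describing JSON document."""
    return json.dumps(
        {
            "n_lv": model.n_lv,
            "bin_labels": [list(b) for b in model.bin_labels],
            "coef_path": model.coef_path.tolist(),
            "weights": model.weights.tolist(),
            "std_mean": model.std_params.mean.tolist(),
            "std_sd": model.std_params.sd.tolist(),
            "std_zero_variance": model.std_params.zero_variance.tolist(),
            "y_mean": model.y_mean,
        }
    )


def model_from_json(doc: str) -> PLSModel:
    d = json.loads(doc)
    return PLSModel(
        n_lv=d["n_lv"],
        bin_labels=[tuple(b) for b in d["bin_labels"]],
        coef_path=np.asarray(d["coef_path"], dtype=float),
        weights=np.asarray(d["weights"], dtype=float),
        std_params=StandardizationParams(
            mean=np.asarray(d["std_mean"], dtype=float),
            sd=np.asarray(d["std_sd"], dtype=float),
            zero_variance=np.asarray(d["std_zero_variance"], dtype=bool),
        ),
        y_mean=d["y_mean"],
    )
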