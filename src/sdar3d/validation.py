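"""Randomized hold-out validation, composite statistics, and the granularity scan.

A composite model is one engine (PLS or KNN) on one grid, evaluated over
many randomized ~20% hold-out cycles drawn from a seeded :class:`SplitPlan`.
The same plan is shared between engines so their per-cycle hold-out R²
values form matched pairs — the basis of the orthogonality diagnostic.
Reported statistics are means and SDs over cycles and therefore mix "good"
and "bad" splits by construction.

Y-scrambling: on every cycle (PLS only) the training activities are
permuted with a cycle-specific sub-seed, the model refit, and the true test
activities predicted; the resulting R²_scrambling traces the chance-
correlation baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .knn import KNNConfig, tanimoto_cross
from .pls import PLSModel, pls_predict, simpls_fit
from .tessellation import GridSpec, OccupancyMatrix, build_occupancy_matrix

logger = logging.getLogger("sdar3d")

__all__ = [
    "SplitPlan",
    "PLSEngineConfig",
    "CompositeResult",
    "MatchedPairReport",
    "ScanResult",
    "make_split_plan",
    "compute_r2",
    "run_composite",
    "convergence_curve",
    "matched_pair_analysis",
    "scan_hyperparameters",
]


@dataclass(frozen=True)
class SplitPlan:
    """Seeded sequence of train/test index pairs, shared across engines.

    All randomness of a validation run flows from ``seed``: the per-cycle
    partitions and the per-cycle Y-scrambling sub-seeds are drawn from a
    single generator in a fixed order, so the identical plan (and identical
    scrambles) is reproduced bit-exactly from the same arguments.
    """

    m: int
    n_cycles: int
    test_fraction: float
    seed: int
    splits: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    scramble_seeds: tuple[int, ...]

    @property
    def test_size(self) -> int:
        return len(self.splits[0][1])

    def same_plan(self, other: "SplitPlan") -> bool:
        return (
            self.m == other.m
            and self.n_cycles == other.n_cycles
            and self.test_fraction == other.test_fraction
            and self.seed == other.seed
        )


def make_split_plan(m: int, n_cycles: int, test_fraction: float, seed: int) -> SplitPlan:
    """Draw ``n_cycles`` uniform train/test partitions of ``m`` compounds.

    Test size is ``round(test_fraction * m)`` (19 of 94 at the canonical 20%).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if m < 5:
        raise ValueError("need at least 5 compounds")
    n_test = int(round(test_fraction * m))
    if n_test < 1:
        raise ValueError("test fraction yields an empty test set")
    rng = np.random.default_rng(seed)
    splits = []
    scramble_seeds = []
    for _ in range(n_cycles):
        perm = rng.permutation(m)
        test = tuple(sorted(int(i) for i in perm[:n_test]))
        train = tuple(sorted(int(i) for i in perm[n_test:]))
        splits.append((train, test))
        scramble_seeds.append(int(rng.integers(0, 2**31)))
    return SplitPlan(
        m=m,
        n_cycles=n_cycles,
        test_fraction=test_fraction,
        seed=seed,
        splits=tuple(splits),
        scramble_seeds=tuple(scramble_seeds),
    )


def compute_r2(
    predicted: np.ndarray, observed: np.ndarray, mode: str = "pearson_sq"
) -> float:
    """Coefficient of determination between predictions and observations.

    ``pearson_sq`` (default) is the squared Pearson correlation — the R² of
    the best-fit line through a predicted-vs-observed plot.  ``one_minus_ss``
    is 1 − SSE/SST about the observed mean; it can be negative and penalizes
    bias, which pearson_sq does not.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape or p.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("R2 undefined: observed values are constant")
    if mode == "one_minus_ss":
        return 1.0 - float(((o - p) ** 2).sum()) / sst
    if mode == "pearson_sq":
        if float(((p - p.mean()) ** 2).sum()) == 0.0:
            raise ValueError("pearson_sq undefined: predictions are constant")
        r = np.corrcoef(p, o)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown mode {mode!r}")


def _safe_r2(p: np.ndarray, o: np.ndarray, mode: str) -> float:
    try:
        return compute_r2(p, o, mode)
    except ValueError:
        return float("nan")


@dataclass(frozen=True)
class PLSEngineConfig:
    """Latent-variable count for the PLS engine."""

    n_lv: int

    def __post_init__(self) -> None:
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")


EngineConfig = Union[PLSEngineConfig, KNNConfig]


@dataclass
class CompositeResult:
    """Cycle-level and aggregated statistics of one engine on one grid."""

    engine: str  # "PLS" | "KNN"
    grid: GridSpec
    hyperparameter: int  # n_lv or k
    plan: SplitPlan
    r2_train: Optional[np.ndarray]  # PLS only
    r2_test: np.ndarray  # default (pearson_sq) per cycle
    r2_test_ss: np.ndarray  # one_minus_ss per cycle
    r2_scrambling: Optional[np.ndarray]  # PLS only
    cycle_predictions: list[np.ndarray]  # hold-out predictions per cycle
    compound_ids: list[str]
    mean_prediction: np.ndarray  # per-compound average over its hold-out appearances
    times_predicted: np.ndarray
    models: Optional[list[PLSModel]] = None  # retained per-cycle PLS fits

    @property
    def mean_r2_test(self) -> float:
        return float(np.nanmean(self.r2_test))

    @property
    def sd_r2_test(self) -> float:
        return float(np.nanstd(self.r2_test, ddof=1))

    @property
    def mean_r2_scrambling(self) -> float:
        if self.r2_scrambling is None:
            raise ValueError("scrambling recorded for PLS composites only")
        return float(np.nanmean(self.r2_scrambling))

    def summary(self) -> dict:
        out = {
            "engine": self.engine,
            "bin_size": self.grid.label(),
            "hyperparameter": self.hyperparameter,
            "mean_r2_test": self.mean_r2_test,
            "sd_r2_test": self.sd_r2_test,
            "mean_r2_test_ss": float(np.nanmean(self.r2_test_ss)),
            "n_undefined_cycles": int(np.isnan(self.r2_test).sum()),
        }
        if self.r2_train is not None:
            out["mean_r2_train"] = float(np.nanmean(self.r2_train))
        if self.r2_scrambling is not None:
            out["mean_r2_scrambling"] = self.mean_r2_scrambling
            out["sd_r2_scrambling"] = float(np.nanstd(self.r2_scrambling, ddof=1))
        return out


def _pls_cycle_sweep(
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    lv_list: Sequence[int],
    bin_labels,
    keep_models: bool = False,
):
    """Run every cycle once at max(lv_list); read off predictions per LV count.

    SIMPLS coefficient paths are nested, so a single fit per cycle serves
    all smaller LV counts.  Returns per-LV cycle arrays for train/test/
    scrambling R² (both test modes) plus per-LV hold-out predictions.
    """
    max_lv = max(lv_list)
    C = plan.n_cycles
    out = {
        lv: {
            "r2_train": np.full(C, np.nan),
            "r2_test": np.full(C, np.nan),
            "r2_test_ss": np.full(C, np.nan),
            "r2_scr": np.full(C, np.nan),
            "preds": [],
        }
        for lv in lv_list
    }
    models: list[PLSModel] = []
    import warnings as _w

    for c, (train, test) in enumerate(plan.splits):
        tr = np.asarray(train)
        te = np.asarray(test)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # rank truncation is expected on small splits
            model = simpls_fit(X[tr], y[tr], max_lv, bin_labels)
            scr_rng = np.random.default_rng(plan.scramble_seeds[c])
            y_scr = scr_rng.permutation(y[tr])
            model_scr = simpls_fit(X[tr], y_scr, max_lv, bin_labels)
        if keep_models:
            models.append(model)
        for lv in lv_list:
            k = min(lv, model.n_lv)
            p_tr = pls_predict(model, X[tr], n_lv=k)
            p_te = pls_predict(model, X[te], n_lv=k)
            p_scr = pls_predict(model_scr, X[te], n_lv=min(lv, model_scr.n_lv))
            cell = out[lv]
            cell["r2_train"][c] = _safe_r2(p_tr, y[tr], "pearson_sq")
            cell["r2_test"][c] = _safe_r2(p_te, y[te], "pearson_sq")
            cell["r2_test_ss"][c] = _safe_r2(p_te, y[te], "one_minus_ss")
            cell["r2_scr"][c] = _safe_r2(p_scr, y[te], "pearson_sq")
            cell["preds"].append(p_te)
    return out, models


def _knn_cycle_sweep(X: np.ndarray, y: np.ndarray, plan: SplitPlan, k_list: Sequence[int], ids):
    """One similarity computation per cycle serves every neighbor count."""
    C = plan.n_cycles
    out = {
        k: {"r2_test": np.full(C, np.nan), "r2_test_ss": np.full(C, np.nan), "preds": []}
        for k in k_list
    }
    for c, (train, test) in enumerate(plan.splits):
        tr = np.asarray(train)
        te = np.asarray(test)
        T = tanimoto_cross(X[te], X[tr])
        T = np.where(np.isnan(T), 0.0, T)
        # rank by similarity descending, ties by training compound id
        tie = np.argsort([ids[i] for i in tr], kind="stable")
        tie_rank = np.empty(len(tr), dtype=int)
        tie_rank[tie] = np.arange(len(tr))
        order = np.lexsort((tie_rank[None, :].repeat(len(te), 0), -T), axis=1)
        for k in k_list:
            top = order[:, :k]
            w = np.take_along_axis(T, top, axis=1)
            yy = y[tr][top]
            wsum = w.sum(axis=1)
            preds = np.where(wsum > 0, (w * yy).sum(axis=1) / np.where(wsum > 0, wsum, 1.0), yy.mean(axis=1))
            cell = out[k]
            cell["r2_test"][c] = _safe_r2(preds, y[te], "pearson_sq")
            cell["r2_test_ss"][c] = _safe_r2(preds, y[te], "one_minus_ss")
            cell["preds"].append(preds)
    return out


def _aggregate_predictions(plan: SplitPlan, preds: list[np.ndarray], m: int):
    total = np.zeros(m)
    count = np.zeros(m, dtype=int)
    for (train, test), p in zip(plan.splits, preds):
        te = np.asarray(test)
        total[te] += p
        count[te] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.where(count > 0, count, 1), np.nan)
    return mean, count


def run_composite(
    occ: OccupancyMatrix,
    y: np.ndarray,
    plan: SplitPlan,
    engine: EngineConfig,
    keep_models: bool = False,
) -> CompositeResult:
    """Evaluate one engine on one grid over all cycles of ``plan``.

    PLS: standardization is refit on each cycle's training rows; the
    hold-out is predicted and R²_train / R²_test recorded, plus one
    Y-scrambling replicate per cycle.  KNN: raw occupancies, similarity-
    weighted neighbor mean, R²_test only.  Cycles whose R² is undefined
    (e.g. constant predictions) are recorded as NaN and excluded from means
    with a logged count.
    """
    y = np.asarray(y, dtype=float).ravel()
    if plan.m != occ.m or y.size != occ.m:
        raise ValueError("plan, occupancy matrix, and activities disagree on m")
    X = np.asarray(occ.counts, dtype=float)
    if isinstance(engine, PLSEngineConfig):
        sweep, models = _pls_cycle_sweep(
            X, y, plan, [engine.n_lv], occ.bin_labels, keep_models=keep_models
        )
        cell = sweep[engine.n_lv]
        mean_pred, count = _aggregate_predictions(plan, cell["preds"], occ.m)
        result = CompositeResult(
            engine="PLS",
            grid=occ.grid,
            hyperparameter=engine.n_lv,
            plan=plan,
            r2_train=cell["r2_train"],
            r2_test=cell["r2_test"],
            r2_test_ss=cell["r2_test_ss"],
            r2_scrambling=cell["r2_scr"],
            cycle_predictions=cell["preds"],
            compound_ids=list(occ.compound_ids),
            mean_prediction=mean_pred,
            times_predicted=count,
            models=models if keep_models else None,
        )
    elif isinstance(engine, KNNConfig):
        sweep = _knn_cycle_sweep(X, y, plan, [engine.k], occ.compound_ids)
        cell = sweep[engine.k]
        mean_pred, count = _aggregate_predictions(plan, cell["preds"], occ.m)
        result = CompositeResult(
            engine="KNN",
            grid=occ.grid,
            hyperparameter=engine.k,
            plan=plan,
            r2_train=None,
            r2_test=cell["r2_test"],
            r2_test_ss=cell["r2_test_ss"],
            r2_scrambling=None,
            cycle_predictions=cell["preds"],
            compound_ids=list(occ.compound_ids),
            mean_prediction=mean_pred,
            times_predicted=count,
        )
    else:
        raise TypeError(f"unknown engine config {engine!r}")
    n_undef = int(np.isnan(result.r2_test).sum())
    if n_undef:
        logger.info(
            "%s composite on %s: %d/%d cycles with undefined R2 excluded from means",
            result.engine,
            occ.grid.label(),
            n_undef,
            plan.n_cycles,
        )
    return result


def convergence_curve(per_cycle_r2: Sequence[float], checkpoints: Sequence[int]) -> np.ndarray:
    """Running mean of per-cycle R² at each checkpoint N (in cycle order)."""
    r2 = np.asarray(per_cycle_r2, dtype=float)
    if r2.size == 0:
        raise ValueError("empty R2 sequence")
    checkpoints = list(checkpoints)
    if any(n < 1 or n > r2.size for n in checkpoints):
        raise ValueError("checkpoints must lie in 1..len(per_cycle_r2)")
    csum = np.nancumsum(r2)
    cnt = np.cumsum(~np.isnan(r2))
    return np.array([csum[n - 1] / max(cnt[n - 1], 1) for n in checkpoints])


@dataclass
class MatchedPairReport:
    """Per-cycle matched hold-out R² of two composites on a shared plan.

    ``delta`` is R²(a) − R²(b) per cycle; ``n_beyond_1sd`` counts cycles
    whose delta deviates from the mean delta by at least one SD — the
    cycles on which one engine found structure the other missed.  A low
    ``matched_r2`` (squared correlation of the paired R² sequences) is the
    signature of partially orthogonal engines.
    """

    pairs: np.ndarray  # (n_cycles, 2)
    delta: np.ndarray
    mean_delta: float
    sd_delta: float
    n_beyond_1sd: int
    n_a_better: int
    n_b_better: int
    matched_r2: float


def matched_pair_analysis(a: CompositeResult, b: CompositeResult) -> MatchedPairReport:
    """Compare two composites cycle-by-cycle on their shared split plan."""
    if not a.plan.same_plan(b.plan):
        raise ValueError("composites were not run on the same split plan")
    ok = ~np.isnan(a.r2_test) & ~np.isnan(b.r2_test)
    ra, rb = a.r2_test[ok], b.r2_test[ok]
    delta = ra - rb
    mean_d = float(delta.mean())
    sd_d = float(delta.std(ddof=1)) if delta.size > 1 else 0.0
    beyond = np.abs(delta - mean_d) >= sd_d if sd_d > 0 else np.zeros(delta.size, bool)
    if np.std(ra) > 0 and np.std(rb) > 0:
        r = float(np.corrcoef(ra, rb)[0, 1])
        matched_r2 = float(np.sign(r) * r * r)  # signed so anti-correlation is visible
    else:
        matched_r2 = 1.0 if np.allclose(ra, rb) else float("nan")
    return MatchedPairReport(
        pairs=np.column_stack([ra, rb]),
        delta=delta,
        mean_delta=mean_d,
        sd_delta=sd_d,
        n_beyond_1sd=int(beyond.sum()),
        n_a_better=int((beyond & (delta > mean_d)).sum()),
        n_b_better=int((beyond & (delta < mean_d)).sum()),
        matched_r2=matched_r2,
    )


@dataclass
class ScanResult:
    """Granularity scan output: one row per grid with the best LV and best k."""

    table: pd.DataFrame
    best_pls: tuple[GridSpec, int]
    best_knn: tuple[GridSpec, int]


def scan_hyperparameters(
    fingerprints,
    y: np.ndarray,
    grids: Sequence[GridSpec],
    plan: SplitPlan,
    lv_range: Sequence[int] = range(1, 11),
    k_range: Sequence[int] = range(1, 11),
) -> ScanResult:
    """Sweep grids × hyperparameters with one shared split plan.

    For every grid the LV count and neighbor count maximizing mean hold-out
    R² are reported together with their cycle statistics (ties go to the
    smaller hyperparameter).  The best PLS and best KNN cells over all
    grids are returned alongside the per-grid table.
    """
    if not grids:
        raise ValueError("empty grid list")
    y = np.asarray(y, dtype=float).ravel()
    lv_list = sorted(set(int(v) for v in lv_range))
    k_list = sorted(set(int(v) for v in k_range))
    rows = []
    for grid in grids:
        occ = build_occupancy_matrix(fingerprints, grid)
        X = np.asarray(occ.counts, dtype=float)
        pls_sweep, _ = _pls_cycle_sweep(X, y, plan, lv_list, occ.bin_labels)
        knn_sweep = _knn_cycle_sweep(X, y, plan, [k for k in k_list if k <= len(plan.splits[0][0])], occ.compound_ids)
        best_lv = max(lv_list, key=lambda lv: (np.nanmean(pls_sweep[lv]["r2_test"]), -lv))
        avail_k = sorted(knn_sweep)
        best_k = max(avail_k, key=lambda k: (np.nanmean(knn_sweep[k]["r2_test"]), -k))
        pc, kc = pls_sweep[best_lv], knn_sweep[best_k]
        rows.append(
            {
                "bin_size": grid.label(),
                "dx_ppm": grid.dx,
                "dz_A": grid.dz,
                "optimal_lvs": best_lv,
                "avg_r2_test_pls": float(np.nanmean(pc["r2_test"])),
                "std_r2_test_pls": float(np.nanstd(pc["r2_test"], ddof=1)),
                "avg_r2_scr_pls": float(np.nanmean(pc["r2_scr"])),
                "std_r2_scr_pls": float(np.nanstd(pc["r2_scr"], ddof=1)),
                "optimal_k": best_k,
                "avg_r2_test_knn": float(np.nanmean(kc["r2_test"])),
                "std_r2_test_knn": float(np.nanstd(kc["r2_test"], ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    i_pls = int(table["avg_r2_test_pls"].idxmax())
    i_knn = int(table["avg_r2_test_knn"].idxmax())
    best_pls = (grids[i_pls], int(table.loc[i_pls, "optimal_lvs"]))
    best_knn = (grids[i_knn], int(table.loc[i_knn, "optimal_k"]))
    return ScanResult(table=table, best_pls=best_pls, best_knn=best_knn)
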