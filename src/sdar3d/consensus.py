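"""Pairwise consensus prediction and interpretive bin attribution.

A consensus model averages, compound by compound, the mean hold-out
predictions of two composite models.  Its hold-out R² typically exceeds the
mean of the members' R² when the members capture complementary structure —
the improvement is accounted for in percent over the member average.

Interpretation extracts, from every per-cycle PLS fit of a composite, the
bins carrying the largest positive and largest negative x-weights on each
latent variable, ranks unique bins by how often they recur across cycles
and LVs, keeps the top fraction per sign, and back-projects the surviving
bins onto the concrete (compound, atom-pair) fingerprint elements that
occupy them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprint import FingerprintSet
from .tessellation import GridSpec, bin_index
from .validation import CompositeResult, compute_r2

__all__ = [
    "ConsensusResult",
    "BinAttribution",
    "round_half_up",
    "consensus_predict",
    "improvement_pct",
    "build_consensus",
    "extract_top_bins",
    "rank_and_select_bins",
    "back_project",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero), for display.

    The value is first snapped to 9 decimal places so binary-float noise
    around an exact tie (e.g. the mean of two 2-decimal numbers landing on
    x.xx5) does not flip the rounding direction.
    """
    snapped = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-9))
    return float(snapped.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def consensus_predict(pred_a: pd.Series, pred_b: pd.Series) -> pd.Series:
    """Element-wise arithmetic mean of two per-compound prediction series.

    The returned series is full precision; apply :func:`round_half_up` for
    display.  Compound id sets must match exactly.
    """
    if set(pred_a.index) != set(pred_b.index):
        raise ValueError("consensus members predict different compound sets")
    b = pred_b.reindex(pred_a.index)
    return (pred_a + b) / 2.0


def improvement_pct(r2_consensus: float, r2_members: tuple[float, float]) -> float:
    """Percent gain of the consensus R² over the members' average R²."""
    mean_member = (r2_members[0] + r2_members[1]) / 2.0
    if mean_member <= 0:
        raise ValueError("member mean R2 must be positive")
    return round(100.0 * (r2_consensus - mean_member) / mean_member, 1)


@dataclass
class ConsensusResult:
    """A pairwise consensus model and its improvement accounting."""

    member_tags: tuple[str, str]
    prediction: pd.Series
    r2_consensus: float
    r2_members: tuple[float, float]
    pct_improvement: float


def build_consensus(
    a: CompositeResult, b: CompositeResult, observed: np.ndarray
) -> ConsensusResult:
    """Average two composites' per-compound mean predictions and score them.

    Member R² values are the squared Pearson correlations between each
    member's averaged hold-out predictions and the observed activities, on
    the same scale as the consensus R².
    """
    pa = pd.Series(a.mean_prediction, index=a.compound_ids)
    pb = pd.Series(b.mean_prediction, index=b.compound_ids)
    obs = pd.Series(np.asarray(observed, dtype=float), index=a.compound_ids)
    kept = pa.notna() & pb.reindex(pa.index).notna()
    if not kept.all():
        logging.getLogger("sdar3d").info(
            "consensus: %d compounds never held out by a member, excluded", int((~kept).sum())
        )
    pa, obs = pa[kept], obs[kept]
    pb = pb.reindex(pa.index)
    cons = consensus_predict(pa, pb)
    r2_a = compute_r2(pa.to_numpy(), obs.to_numpy())
    r2_b = compute_r2(pb.to_numpy(), obs.to_numpy())
    r2_c = compute_r2(cons.to_numpy(), obs.to_numpy())
    tag_a = f"{a.engine} {a.grid.label()}"
    tag_b = f"{b.engine} {b.grid.label()}"
    return ConsensusResult(
        member_tags=(tag_a, tag_b),
        prediction=cons,
        r2_consensus=r2_c,
        r2_members=(r2_a, r2_b),
        pct_improvement=improvement_pct(r2_c, (r2_a, r2_b)),
    )


@dataclass
class BinAttribution:
    """A selected signed bin, its recurrence frequency, and its occupants."""

    bin: tuple[int, int, int]
    sign: str  # "positive" | "negative"
    frequency: float  # occurrences / total extractions of this sign
    occurrences: int
    support: list[tuple[str, int, int]] = field(default_factory=list)  # (compound, atom_i, atom_j)


def extract_top_bins(composite: CompositeResult, n_top: int = 10) -> list[tuple[tuple[int, int, int], str]]:
    """Largest-weight bins per cycle per LV, both signs, as a signed multiset.

    For every retained per-cycle PLS model and every latent variable, the
    ``n_top`` bins with the most positive weights and the ``n_top`` with the
    most negative weights are extracted; at full settings (100 cycles × 7
    LVs × top-10 × 2 signs) that is 14000 entries.  Models with fewer bins
    than ``n_top`` contribute all their bins (shortfall logged).
    """
    if composite.models is None:
        raise ValueError("composite was run without keep_models=True")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    out: list[tuple[tuple[int, int, int], str]] = []
    for model in composite.models:
        labels = model.bin_labels
        take = min(n_top, len(labels))
        for lv in range(model.n_lv):
            w = model.weights[:, lv]
            order = np.argsort(w, kind="stable")
            for idx in order[::-1][:take]:
                out.append((labels[idx], "positive"))
            for idx in order[:take]:
                out.append((labels[idx], "negative"))
    return out


def rank_and_select_bins(
    multiset: Sequence[tuple[tuple[int, int, int], str]], top_fraction: float = 0.2
) -> list[BinAttribution]:
    """Rank unique bins per sign by recurrence and keep the top fraction.

    Frequency is occurrences divided by the total number of extractions of
    that sign.  Per sign, ``ceil(top_fraction × unique bins)`` are kept;
    ties break on (frequency desc, bin triple lexicographic asc).
    """
    if not multiset:
        raise ValueError("empty bin multiset")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    selected: list[BinAttribution] = []
    for sign in ("positive", "negative"):
        entries = [b for b, s in multiset if s == sign]
        if not entries:
            continue
        total = len(entries)
        counts: dict[tuple[int, int, int], int] = {}
        for b in entries:
            counts[b] = counts.get(b, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = math.ceil(top_fraction * len(ranked))
        for b, c in ranked[:keep]:
            selected.append(BinAttribution(bin=b, sign=sign, frequency=c / total, occurrences=c))
    return selected


def back_project(
    bins: Sequence[BinAttribution],
    fingerprints: Sequence[FingerprintSet],
    grid: GridSpec,
) -> pd.DataFrame:
    """Map selected bins back to the atom pairs whose elements occupy them.

    Every (compound, atom_i, atom_j) whose fingerprint element falls in a
    selected bin yields one attribution row (coincident symmetric elements
    yield one row each).  The ``support`` list of each attribution is
    filled in place.
    """
    wanted: dict[tuple[int, int, int], list[BinAttribution]] = {}
    for attr in bins:
        attr.support = []
        wanted.setdefault(tuple(attr.bin), []).append(attr)
    rows = []
    for fp in fingerprints:
        for e in fp.elements:
            b = bin_index(e, grid)
            for attr in wanted.get(b, ()):
                attr.support.append((fp.compound_id, e.atom_pair[0], e.atom_pair[1]))
                rows.append(
                    (
                        attr.sign,
                        b[0],
                        b[1],
                        b[2],
                        attr.frequency,
                        fp.compound_id,
                        e.atom_pair[0],
                        e.atom_pair[1],
                        e.shift_x,
                        e.shift_y,
                        e.distance,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sign",
            "i",
            "j",
            "k",
            "frequency",
            "compound_id",
            "atom_i",
            "atom_j",
            "shift_x",
            "shift_y",
            "distance",
        ],
    )
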