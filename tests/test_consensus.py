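import numpy as np
import pandas as pd
import pytest

from sdar3d import (
    GridSpec,
    PLSEngineConfig,
    back_project,
    build_consensus,
    build_fingerprint,
    build_occupancy_matrix,
    consensus_predict,
    extract_top_bins,
    improvement_pct,
    make_split_plan,
    rank_and_select_bins,
    round_half_up,
    run_composite,
)
from sdar3d.consensus import BinAttribution
from sdar3d.pls import PLSModel, StandardizationParams
from sdar3d.tessellation import bin_index


class TestConsensusPredict:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (7.66, 7.10, 7.38),  # strongest dioxin binder
            (6.04, 7.83, 6.94),
            (5.61, 3.30, 4.46),  # half-up rounding of 4.455
            (5.50, 6.49, 6.00),
        ],
    )
    def test_published_spot_values(self, a, b, expected):
        cons = consensus_predict(pd.Series({"x": a}), pd.Series({"x": b}))
        assert round_half_up(cons["x"]) == expected

    def test_exact_mean_full_precision(self):
        rng = np.random.default_rng(1)
        ids = [f"c{i}" for i in range(20)]
        a = pd.Series(rng.normal(size=20), index=ids)
        b = pd.Series(rng.normal(size=20), index=ids)
        cons = consensus_predict(a, b)
        assert np.max(np.abs(cons - (a + b) / 2)) == 0.0

    def test_identical_members(self):
        a = pd.Series({"p": 5.0, "q": 6.0})
        assert consensus_predict(a, a).equals(a)

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            consensus_predict(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


def test_round_half_up():
    assert round_half_up(4.455) == 4.46
    assert round_half_up(5.995) == 6.00
    assert round_half_up(2.675) == 2.68  # decimal, not binary-float, rounding


class TestImprovement:
    @pytest.mark.parametrize(
        "cons,members,expected",
        [
            (0.685, (0.620, 0.620), 10.5),
            (0.673, (0.609, 0.609), 10.5),
            (0.658, (0.603, 0.603), 9.1),
            (0.654, (0.614, 0.614), 6.5),
            (0.640, (0.612, 0.612), 4.6),
            (0.633, (0.611, 0.611), 3.6),
        ],
    )
    def test_published_improvement_rows(self, cons, members, expected):
        assert improvement_pct(cons, members) == expected

    def test_no_improvement_is_zero(self):
        assert improvement_pct(0.5, (0.4, 0.6)) == 0.0

    def test_nonpositive_member_mean_rejected(self):
        with pytest.raises(ValueError):
            improvement_pct(0.5, (0.0, 0.0))


def _toy_composite_with_weights(weights, labels):
    """Composite carrying a single hand-built PLS model for extraction tests."""
    import dataclasses

    from sdar3d.validation import CompositeResult

    n, n_lv = weights.shape
    model = PLSModel(
        n_lv=n_lv,
        bin_labels=labels,
        coef_path=np.zeros((n, n_lv)),
        weights=weights,
        std_params=StandardizationParams(np.zeros(n), np.ones(n), np.zeros(n, bool)),
        y_mean=0.0,
    )
    plan = make_split_plan(10, 1, 0.2, 0)
    return CompositeResult(
        engine="PLS",
        grid=GridSpec(10, 0.5),
        hyperparameter=n_lv,
        plan=plan,
        r2_train=np.array([1.0]),
        r2_test=np.array([1.0]),
        r2_test_ss=np.array([1.0]),
        r2_scrambling=np.array([0.0]),
        cycle_predictions=[np.zeros(2)],
        compound_ids=[f"c{i}" for i in range(10)],
        mean_prediction=np.zeros(10),
        times_predicted=np.ones(10, dtype=int),
        models=[model],
    )


class TestExtraction:
    def test_single_cycle_single_lv_counts(self):
        comp = _toy_composite_with_weights(
            np.random.default_rng(0).normal(size=(30, 1)), [(i, 0, 0) for i in range(30)]
        )
        assert len(extract_top_bins(comp, 10)) == 20  # 2 · 1 cycle · 1 LV · 10

    def test_argmax_argmin_selection(self):
        comp = _toy_composite_with_weights(
            np.array([[3.0], [-1.0], [2.0]]), [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        )
        out = extract_top_bins(comp, 1)
        assert ((0, 0, 0), "positive") in out
        assert ((1, 0, 0), "negative") in out
        assert len(out) == 2

    def test_full_scale_count(self, synth_clean):
        """100 cycles × 7 LVs × top-10 on both signs extracts 14000 bins."""
        _, _, occ, y, _ = synth_clean
        plan = make_split_plan(occ.m, 100, 0.2, 42)
        comp = run_composite(occ, y, plan, PLSEngineConfig(7), keep_models=True)
        assert all(m.n_lv == 7 for m in comp.models)
        assert len(extract_top_bins(comp, 10)) == 14000

    def test_requires_kept_models(self, synth_clean):
        _, _, occ, y, _ = synth_clean
        plan = make_split_plan(occ.m, 2, 0.2, 1)
        comp = run_composite(occ, y, plan, PLSEngineConfig(2))
        with pytest.raises(ValueError):
            extract_top_bins(comp)


class TestRankAndSelect:
    def test_single_unique_bin(self):
        sel = rank_and_select_bins([((1, 1, 1), "positive")], 0.2)
        assert len(sel) == 1 and sel[0].frequency == 1.0

    def test_top_fraction_ceiling(self):
        ms = (
            [((0, 0, 0), "positive")] * 5
            + [((1, 0, 0), "positive")] * 3
            + [((2, 0, 0), "positive")] * 2
        )
        sel = rank_and_select_bins(ms, 0.2)  # ceil(0.2·3) = 1 bin kept
        assert [s.bin for s in sel] == [(0, 0, 0)]
        assert sel[0].frequency == 0.5

    def test_frequency_denominator_is_per_sign(self):
        ms = [((0, 0, 0), "positive")] * 4 + [((5, 5, 5), "negative")] * 1
        sel = rank_and_select_bins(ms, 1.0)
        by_sign = {s.sign: s for s in sel}
        assert by_sign["positive"].frequency == 1.0
        assert by_sign["negative"].frequency == 1.0

    def test_deterministic_tie_break(self):
        ms = [((2, 0, 0), "positive"), ((1, 0, 0), "positive")]
        sel = rank_and_select_bins(ms, 0.5)
        assert sel[0].bin == (1, 0, 0)  # equal frequency → lexicographic

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select_bins([], 0.2)

    def test_signs_disjoint_on_planted_signal(self, synth_clean):
        """Positive and negative selections separate cleanly when the planted
        effects are themselves separated — mirrors the published observation."""
        _, _, occ, y, _ = synth_clean
        plan = make_split_plan(occ.m, 50, 0.2, 42)
        comp = run_composite(occ, y, plan, PLSEngineConfig(7), keep_models=True)
        sel = rank_and_select_bins(extract_top_bins(comp, 10), 0.2)
        pos = {s.bin for s in sel if s.sign == "positive"}
        neg = {s.bin for s in sel if s.sign == "negative"}
        assert not pos & neg


class TestBackProjection:
    def test_empty_bin_list(self, toy3):
        table = back_project([], [build_fingerprint(toy3)], GridSpec(10, 0.5))
        assert table.empty

    def test_toy_attribution(self, toy3):
        fp = build_fingerprint(toy3)
        grid = GridSpec(10, 0.5)
        target = bin_index(fp.elements[0], grid)  # element (10, 20, 1.5) → atoms (0, 1)
        attr = BinAttribution(bin=target, sign="positive", frequency=1.0, occurrences=1)
        table = back_project([attr], [fp], grid)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.compound_id, row.atom_i, row.atom_j) == ("toy3", 0, 1)
        assert attr.support == [("toy3", 0, 1)]

    def test_multiplicity_yields_multiple_rows(self):
        from sdar3d import Compound

        c = Compound(
            id="sym4",
            element_symbols=("C",) * 4,
            coordinates=[[0, 0, 0], [0, 2, 0], [5, 0, 0], [5, 2, 0]],
            carbon_shifts=(120.0, 120.0, 120.0, 120.0),
        )
        fp = build_fingerprint(c)
        grid = GridSpec(10, 0.5)
        b = bin_index(fp.elements[0], grid)  # the two vertical 2 Å pairs coincide
        attr = BinAttribution(bin=b, sign="positive", frequency=1.0, occurrences=1)
        table = back_project([attr], [fp], grid)
        assert len(table) == 2
        assert set(map(tuple, table[["atom_i", "atom_j"]].to_numpy())) == {(0, 1), (2, 3)}

    def test_round_trip_rebinning(self, synth_small):
        _, fps, y, truth = synth_small
        occ = build_occupancy_matrix(fps, truth.grid)
        plan = make_split_plan(len(y), 5, 0.2, 3)
        comp = run_composite(occ, y, plan, PLSEngineConfig(3), keep_models=True)
        sel = rank_and_select_bins(extract_top_bins(comp, 5), 0.2)
        table = back_project(sel, fps, truth.grid)
        assert len(table) > 0
        for _, row in table.iterrows():
            from sdar3d.fingerprint import FingerprintElement

            e = FingerprintElement(row.shift_x, row.shift_y, row.distance, (row.atom_i, row.atom_j))
            assert bin_index(e, truth.grid) == (row.i, row.j, row.k)


class TestBuildConsensus:
    def test_improves_or_matches_members_on_shared_plan(self, synth_clean):
        _, fps, occ, y, _ = synth_clean
        from sdar3d import KNNConfig

        plan = make_split_plan(occ.m, 30, 0.2, 42)
        pls = run_composite(occ, y, plan, PLSEngineConfig(8))
        fine = build_occupancy_matrix(fps, GridSpec(2.0, 0.5))
        knn = run_composite(fine, y, plan, KNNConfig(4))
        cons = build_consensus(pls, knn, y)
        member_mean = pd.Series(
            (pls.mean_prediction + knn.mean_prediction) / 2, index=pls.compound_ids
        )
        assert np.allclose(
            cons.prediction.to_numpy(),
            member_mean.reindex(cons.prediction.index).to_numpy(),
        )
        mean_member = np.mean(cons.r2_members)
        assert cons.pct_improvement == pytest.approx(
            round(100 * (cons.r2_consensus - mean_member) / mean_member, 1)
        )
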