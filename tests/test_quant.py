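"""Scoring: frequencies, log-ratio score, filters, medians, lethality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tlscan.quant import (
    FilterConfig,
    aggregate_replicates,
    apply_filters,
    calibrate_lethality,
    classify_fitness,
    frequencies,
    phenotype_score,
    score_counts,
    score_screen,
)
from tlscan.readproc import AlleleCountTable
from tlscan.synthetic_data import WT_ID, simulate_screen


def _table(counts: dict, pool="SC-Leu", conditions=("5FOA",), reps=(1,)):
    """Build an AlleleCountTable from {variant: {(cond, rep): count}}."""
    samples = [(pool, r) for r in reps] + [
        (c, r) for c in conditions for r in reps
    ]
    names = [f"{c}_rep{r}" for c, r in samples]
    df = pd.DataFrame(0, index=sorted(counts), columns=names)
    for v, per in counts.items():
        for (c, r), n in per.items():
            df.loc[v, f"{c}_rep{r}"] = n
    sheet = pd.DataFrame(
        [{"sample": f"{c}_rep{r}", "condition": c, "replicate": r,
          "role": "unselected" if c == pool else "selected"}
         for c, r in samples]
    ).set_index("sample", drop=False)
    rejected = pd.DataFrame(index=pd.Index([], name="reason"), columns=names)
    return AlleleCountTable(counts=df, rejected=rejected.fillna(0), samples=sheet)


class TestFrequencies:
    def test_fraction_of_mapped_reads(self):
        t = _table({WT_ID: {("SC-Leu", 1): 950, ("5FOA", 1): 100},
                    "A1G": {("SC-Leu", 1): 50, ("5FOA", 1): 0}})
        f = frequencies(t)
        assert f.freq.loc["A1G", "SC-Leu_rep1"] == pytest.approx(0.05)

    def test_scale_invariance(self):
        t1 = _table({WT_ID: {("SC-Leu", 1): 900}, "A1G": {("SC-Leu", 1): 100}})
        t2 = _table({WT_ID: {("SC-Leu", 1): 9000}, "A1G": {("SC-Leu", 1): 1000}})
        with pytest.raises(ValueError):
            frequencies(t1)  # the 5FOA sample has zero mapped reads
        t1.counts["5FOA_rep1"] = 1
        t2.counts["5FOA_rep1"] = 1
        assert frequencies(t1).freq["SC-Leu_rep1"].equals(
            frequencies(t2).freq["SC-Leu_rep1"]
        )

    def test_frequencies_sum_to_one(self, rng):
        vals = rng.integers(1, 100, size=8)
        t = _table({f"V{i}A": {("SC-Leu", 1): int(v), ("5FOA", 1): 1}
                    for i, v in enumerate(vals)})
        f = frequencies(t)
        assert f.freq["SC-Leu_rep1"].sum() == pytest.approx(1.0)


class TestPhenotypeScore:
    def test_equal_fold_change_scores_zero(self):
        assert phenotype_score(0.02, 0.01, 0.50, 0.25) == pytest.approx(0.0)

    def test_fourfold_enrichment_scores_two(self):
        assert phenotype_score(0.04, 0.01, 0.50, 0.50) == pytest.approx(2.0)

    @given(
        st.lists(st.floats(1e-6, 0.9), min_size=4, max_size=4)
    )
    def test_swapping_samples_negates_score(self, fs):
        a, b, c, d = fs
        assert phenotype_score(a, b, c, d) == pytest.approx(
            -phenotype_score(b, a, d, c)
        )

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            phenotype_score(0.0, 0.1, 0.5, 0.5)

    def test_score_counts_depth_invariance_for_positive_counts(self):
        a = score_counts(40, 20, 500, 500)
        b = score_counts(400, 200, 5000, 5000)
        assert a == b == pytest.approx(1.0)

    def test_score_counts_zero_handling_is_finite_and_symmetric(self):
        s = score_counts(0, 20, 500, 500)
        assert np.isfinite(s)
        assert s == pytest.approx(np.log2(0.5 / 20.5) - np.log2(500.5 / 500.5))


class TestFilters:
    def test_pool_below_200_drops_variant_everywhere(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 100000, ("5FOA", 1): 100000},
             "A1G": {("SC-Leu", 1): 199, ("5FOA", 1): 5000}},
        )
        keep = apply_filters(t)
        assert not keep.loc["A1G"].any()

    def test_pool_at_200_is_kept(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 100000, ("5FOA", 1): 100000},
             "A1G": {("SC-Leu", 1): 200, ("5FOA", 1): 5000}},
        )
        assert apply_filters(t).loc["A1G", ("5FOA", 1)]

    def test_both_below_50_masks_cell(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 100000, ("5FOA", 1): 100000},
             "A1G": {("SC-Leu", 1): 30, ("5FOA", 1): 40}},
            )
        cfg = FilterConfig(min_pool_reads=0)
        assert not apply_filters(t, cfg).loc["A1G", ("5FOA", 1)]

    def test_one_side_above_50_retained(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 100000, ("5FOA", 1): 100000},
             "A1G": {("SC-Leu", 1): 10, ("5FOA", 1): 60}},
        )
        cfg = FilterConfig(min_pool_reads=0)
        assert apply_filters(t, cfg).loc["A1G", ("5FOA", 1)]
        strict = FilterConfig(min_pool_reads=0, require_both_below=False)
        assert not apply_filters(t, strict).loc["A1G", ("5FOA", 1)]

    def test_filter_monotonicity(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 10000, ("5FOA", 1): 10000},
             "A1G": {("SC-Leu", 1): 210, ("5FOA", 1): 55},
             "A2G": {("SC-Leu", 1): 150, ("5FOA", 1): 45}},
        )
        loose = apply_filters(t, FilterConfig(200, 50))
        tight = apply_filters(t, FilterConfig(300, 80))
        assert (tight.to_numpy() <= loose.to_numpy()).all()

    def test_missing_pool_condition_raises(self):
        t = _table({WT_ID: {("5FOA", 1): 100}}, pool="5FOA", conditions=())
        with pytest.raises(ValueError):
            apply_filters(t, FilterConfig(pool_condition="SC-Leu"))


class TestAggregation:
    def _reps(self, values, mask=None):
        cols = pd.MultiIndex.from_tuples(
            [("5FOA", r) for r in (1, 2, 3)], names=["condition", "replicate"]
        )
        reps = pd.DataFrame([values], index=["A1G"], columns=cols)
        keep = pd.DataFrame([[True] * 3 if mask is None else mask],
                            index=["A1G"], columns=cols)
        return reps, keep

    def test_median_of_three(self):
        reps, keep = self._reps([1.0, 2.0, 9.0])
        m = aggregate_replicates(reps, keep)
        assert m.scores.loc["A1G", "5FOA"] == 2.0
        assert m.mask.loc["A1G", "5FOA"] == "measured"

    def test_median_with_masked_replicate(self):
        reps, keep = self._reps([1.0, 5.0, 3.0], mask=[True, False, True])
        m = aggregate_replicates(reps, keep)
        assert m.scores.loc["A1G", "5FOA"] == 2.0

    def test_all_replicates_masked_is_filtered(self):
        reps, keep = self._reps([1.0, 2.0, 3.0], mask=[False] * 3)
        m = aggregate_replicates(reps, keep)
        assert m.mask.loc["A1G", "5FOA"] == "filtered"
        assert np.isnan(m.scores.loc["A1G", "5FOA"])

    def test_replicate_order_irrelevant(self):
        reps, keep = self._reps([3.0, 1.0, 2.0])
        perm = reps[[("5FOA", 2), ("5FOA", 3), ("5FOA", 1)]]
        assert aggregate_replicates(reps, keep).scores.equals(
            aggregate_replicates(perm, keep[perm.columns]).scores
        )


class TestScoreScreen:
    def test_wt_scores_zero_and_depth_invariance(self):
        t = _table(
            {WT_ID: {("SC-Leu", 1): 5000, ("5FOA", 1): 4000},
             "A1G": {("SC-Leu", 1): 400, ("5FOA", 1): 100},
             "A2G": {("SC-Leu", 1): 300, ("5FOA", 1): 600}},
        )
        m = score_screen(t, FilterConfig(min_pool_reads=0, min_condition_reads=0))
        assert m.scores.loc[WT_ID, "5FOA"] == 0.0
        t10 = _table(
            {WT_ID: {("SC-Leu", 1): 50000, ("5FOA", 1): 40000},
             "A1G": {("SC-Leu", 1): 4000, ("5FOA", 1): 1000},
             "A2G": {("SC-Leu", 1): 3000, ("5FOA", 1): 6000}},
        )
        m10 = score_screen(t10, FilterConfig(min_pool_reads=0, min_condition_reads=0))
        pd.testing.assert_frame_equal(m.scores, m10.scores)
        # closed-form check: A1G enriches 100/400 vs WT 4000/5000
        want = np.log2((100 / 400) / (4000 / 5000))
        assert m.scores.loc["A1G", "5FOA"] == pytest.approx(want)

    def test_planted_effects_recovered_from_counts(self):
        sim = simulate_screen(n_variants=120, depth=100_000, n_replicates=3,
                              make_reads=False, seed=4)
        table = _counts_to_table(sim)
        m = score_screen(table)
        common = m.scores.index.intersection(sim.true_effects.index)
        err = (m.scores.loc[common] - sim.true_effects.loc[common]).abs()
        measured = m.mask.loc[common] == "measured"
        assert err[measured].stack().mean() < 0.3


def _counts_to_table(sim):
    rejected = pd.DataFrame(index=pd.Index([], name="reason"),
                            columns=sim.counts.columns).fillna(0)
    return AlleleCountTable(counts=sim.counts, rejected=rejected,
                            samples=sim.sample_sheet)


class TestLethality:
    def test_separable_sets_split_at_gap_midpoint(self):
        scores = pd.Series(
            {"v1": 0.5, "v2": 1.0, "v3": 0.2, "l1": -5.0, "l2": -4.5}
        )
        model = calibrate_lethality(scores, ["v1", "v2", "v3"], ["l1", "l2"])
        assert model.balanced_error == 0.0
        assert model.threshold == pytest.approx((-4.5 + 0.2) / 2)

    def test_threshold_matches_grid_search_oracle(self, rng):
        viable = rng.normal(0.0, 1.0, 163)
        lethal = rng.normal(-3.0, 1.2, 16)
        ids_v = [f"v{i}" for i in range(163)]
        ids_l = [f"l{i}" for i in range(16)]
        scores = pd.Series(
            np.concatenate([viable, lethal]), index=ids_v + ids_l
        )
        model = calibrate_lethality(scores, ids_v, ids_l)
        grid = np.linspace(scores.min(), scores.max(), 20001)
        errs = [
            0.5 * (viable < t).mean() + 0.5 * (lethal >= t).mean() for t in grid
        ]
        assert model.balanced_error == pytest.approx(min(errs), abs=1e-9)

    def test_empty_calibration_rejected(self):
        scores = pd.Series({"a": 1.0})
        with pytest.raises(ValueError):
            calibrate_lethality(scores, ["a"], ["missing"])

    def test_boundary_score_is_viable(self):
        scores = pd.Series({"v": 1.0, "l": -1.0})
        model = calibrate_lethality(scores, ["v"], ["l"])
        labels = classify_fitness(
            pd.Series({"x": model.threshold, "y": model.threshold - 1e-9}), model
        )
        assert labels["x"] == "viable"
        assert labels["y"] == "predicted_lethal"

    def test_planted_lethal_class_recalled(self):
        """Variants with a strong planted 5FOA depletion are recalled >= 95%."""
        rng = np.random.default_rng(42)
        sim = simulate_screen(n_variants=200, depth=100_000, n_replicates=3,
                              make_reads=False, seed=7,
                              true_effects=None)
        ids = list(sim.pool_fractions.index)
        lethal_ids = set(rng.choice(ids, size=40, replace=False))
        effects = pd.DataFrame(
            {"5FOA": [(-6.0 if v in lethal_ids else 0.0)
                      + rng.normal(0, 0.2) for v in ids]},
            index=ids,
        )
        sim = simulate_screen(n_variants=200, depth=100_000, n_replicates=3,
                              make_reads=False, seed=7, true_effects=effects)
        m = score_screen(_counts_to_table(sim))
        fitness = m.scores["5FOA"]
        calib_v = [v for v in ids if v not in lethal_ids][:163]
        calib_l = sorted(lethal_ids)[:16]
        model = calibrate_lethality(fitness, calib_v, calib_l)
        labels = classify_fitness(m, model)
        rest_l = [v for v in lethal_ids if v not in calib_l and v in labels.index]
        recall = (labels[rest_l] == "predicted_lethal").mean()
        assert recall >= 0.95
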