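import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from chromkit import (
    TableError,
    TestConfig,
    bh_adjust,
    multi_sample_anova,
    paired_normalized_ttest,
    sam_ttest,
)
from chromkit.io_tables import IntensityMatrix, SampleDesign

from conftest import make_matrix, make_two_group_design

NA = np.nan


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain loops, exhaustive label assignments)
# ---------------------------------------------------------------------------

def oracle_q(X, n_a, s0=1.0, sides="two"):
    def dstat(xa, xb):
        xa = [v for v in xa if np.isfinite(v)]
        xb = [v for v in xb if np.isfinite(v)]
        if len(xa) < 2 or len(xb) < 2:
            return np.nan
        ma, mb = np.mean(xa), np.mean(xb)
        va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
        sp2 = ((len(xa) - 1) * va + (len(xb) - 1) * vb) / (len(xa) + len(xb) - 2)
        se = (sp2 * (1 / len(xa) + 1 / len(xb))) ** 0.5
        return (ma - mb) / (se + s0)

    P, n = X.shape
    d_obs = np.array([dstat(X[i, :n_a], X[i, n_a:]) for i in range(P)])
    combos = list(itertools.combinations(range(n), n_a))
    d_perm = np.empty((P, len(combos)))
    for j, combo in enumerate(combos):
        rest = [i for i in range(n) if i not in combo]
        for i in range(P):
            d_perm[i, j] = dstat(X[i, list(combo)], X[i, rest])
    s_obs = np.abs(d_obs) if sides == "two" else d_obs
    s_perm = np.abs(d_perm) if sides == "two" else d_perm
    finite_obs = s_obs[np.isfinite(s_obs)]
    qs = np.full(P, np.nan)
    for i in range(P):
        if not np.isfinite(s_obs[i]):
            continue
        best = np.inf
        for cutoff in finite_obs:
            if cutoff <= s_obs[i]:
                n_obs = int(np.sum(finite_obs >= cutoff))
                counts = [
                    int(np.sum(s_perm[np.isfinite(s_perm[:, j]), j] >= cutoff))
                    for j in range(len(combos))
                ]
                best = min(best, min(1.0, float(np.median(counts)) / n_obs))
        qs[i] = best
    return qs


class TestSamTTest:
    def test_flat_protein_not_significant(self):
        design, cols = make_two_group_design()
        m = make_matrix([[10.0] * 6, [10, 11, 12, 10, 11, 12]], cols)
        res = sam_ttest(m, design, "A", "B")
        assert res.table["difference"].iloc[0] == 0.0
        assert res.table["d"].iloc[0] == 0.0
        assert not res.table["significant"].iloc[0]

    def test_moderated_statistic_formula(self):
        # meanA - meanB = 2, pooled se = 1, s0 = 1 -> d = 1.0
        design, cols = make_two_group_design()
        s3 = np.sqrt(3.0)
        row = [12 - s3, 12.0, 12 + s3, 10.0, 10.0, 10.0]
        res = sam_ttest(make_matrix([row], cols), design, "A", "B")
        assert res.table["difference"].iloc[0] == pytest.approx(2.0)
        assert res.table["d"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("sides", ["two", "one"])
    def test_q_matches_bruteforce_oracle(self, sides):
        design, cols = make_two_group_design()
        rng = np.random.default_rng(42)
        X = rng.normal(20, 1, (25, 6))
        X[:4, 3:] += 3.0  # strong effects
        X[7, 0] = NA  # missingness handled identically
        res = sam_ttest(make_matrix(X, cols), design, "A", "B",
                        TestConfig(sides=sides, seed=0))
        expected = oracle_q(X, 3, sides=sides)
        np.testing.assert_allclose(res.table["q"].to_numpy(), expected)

    def test_power_at_effect_two(self):
        # Monte-Carlo power: 3 vs 3, noise 0.3, 10% effects of 2 log2 units
        design, cols = make_two_group_design()
        rng = np.random.default_rng(7)
        X = rng.normal(20, 0.3, (1000, 6))
        X[:100, :3] += 2.0
        res = sam_ttest(make_matrix(X, cols), design, "A", "B", TestConfig(seed=1))
        sig = res.table["significant"].to_numpy()
        assert sig[:100].mean() > 0.9

    def test_global_null_fdr_control(self):
        design, cols = make_two_group_design()
        rng = np.random.default_rng(11)
        X = rng.normal(20, 0.5, (1000, 6))
        res = sam_ttest(make_matrix(X, cols), design, "A", "B", TestConfig(seed=2))
        assert (res.table["q"] <= 0.05).mean() <= 0.05

    def test_s0_zero_recovers_t_ordering(self):
        design, cols = make_two_group_design()
        rng = np.random.default_rng(3)
        X = rng.normal(20, 1, (50, 6))
        res = sam_ttest(make_matrix(X, cols), design, "A", "B",
                        TestConfig(s0=0.0, seed=0))
        t = sp_stats.ttest_ind(X[:, :3], X[:, 3:], axis=1).statistic
        order_d = np.argsort(-np.abs(res.table["d"].to_numpy()))
        order_t = np.argsort(-np.abs(t))
        np.testing.assert_array_equal(order_d, order_t)

    def test_larger_s0_shrinks_d(self):
        design, cols = make_two_group_design()
        rng = np.random.default_rng(4)
        X = rng.normal(20, 1, (50, 6))
        m = make_matrix(X, cols)
        d_small = sam_ttest(m, design, "A", "B", TestConfig(s0=0.5)).table["d"]
        d_large = sam_ttest(m, design, "A", "B", TestConfig(s0=2.0)).table["d"]
        assert (np.abs(d_large) <= np.abs(d_small) + 1e-12).all()

    def test_group_overlap_rejected(self, two_group):
        m, design, cols = two_group
        with pytest.raises(TableError, match="overlap"):
            sam_ttest(m, design, cols[:3], cols[2:])

    def test_significance_requires_fold_change(self):
        design, cols = make_two_group_design()
        rng = np.random.default_rng(5)
        # clear signal but |difference| = 0.5 < fc_threshold_log2 = 1
        X = rng.normal(20, 0.01, (30, 6))
        X[0, :3] += 0.5
        res = sam_ttest(make_matrix(X, cols), design, "A", "B")
        assert res.table["q"].iloc[0] <= 0.05
        assert not res.table["significant"].iloc[0]


class TestPairedNormalized:
    def _design(self, n_conditions=2, n_replicates=3):
        rows, ids = [], []
        for cond in ["A", "B", "C"][:n_conditions]:
            for r in range(1, n_replicates + 1):
                ids += [f"chrom_{cond}_{r}", f"prot_{cond}_{r}"]
                rows += [
                    {"fraction": "chromatome_w3", "condition": cond, "replicate": r},
                    {"fraction": "proteome", "condition": cond, "replicate": r},
                ]
        return SampleDesign(pd.DataFrame(rows, index=pd.Index(ids, name="sample_id")))

    def test_identical_layers_give_zero(self):
        design = self._design()
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 1, (20, 6))
        chrom_cols = [s for s in design.sample_ids if s.startswith("chrom")]
        prot_cols = [s for s in design.sample_ids if s.startswith("prot")]
        chrom = make_matrix(vals, chrom_cols)
        prot = make_matrix(vals, prot_cols)
        res = paired_normalized_ttest(chrom, prot, design, "A", "B")
        assert (res.table["difference"] == 0).all()
        assert not res.table["significant"].any()

    def test_chromatome_only_shift_recovered_exactly(self):
        design = self._design()
        vals = np.full((5, 6), 20.0)
        chrom_cols = [s for s in design.sample_ids if s.startswith("chrom")]
        prot_cols = [s for s in design.sample_ids if s.startswith("prot")]
        chrom_vals = vals.copy()
        chrom_vals[2, 3:] += 2.0  # +2 in condition B, chromatome only
        chrom = make_matrix(chrom_vals, chrom_cols)
        prot = make_matrix(vals, prot_cols)
        res = paired_normalized_ttest(chrom, prot, design, "B", "A")
        assert res.table["difference"].iloc[2] == pytest.approx(2.0)

    def test_unequal_replicates_rejected(self):
        design = self._design()
        chrom_cols = [s for s in design.sample_ids if s.startswith("chrom")]
        prot_cols = [s for s in design.sample_ids if s.startswith("prot")]
        chrom = make_matrix(np.full((3, 6), 20.0), chrom_cols)
        prot = make_matrix(np.full((3, 4), 20.0), prot_cols[:4])
        with pytest.raises(TableError, match="replicate counts"):
            paired_normalized_ttest(chrom, prot, design, "A", "B")


class TestMultiSampleAnova:
    def _design3(self):
        ids = [f"{g}_{r}" for g in "XYZ" for r in (1, 2)]
        rows = [
            {"fraction": "proteome", "condition": g, "replicate": r}
            for g in "XYZ" for r in (1, 2)
        ]
        return SampleDesign(pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))), ids

    def test_identical_group_means_nothing_significant(self):
        design, ids = self._design3()
        rng = np.random.default_rng(0)
        base = rng.normal(20, 0.2, (50, 2))
        res = multi_sample_anova(make_matrix(np.tile(base, 3), ids), design)
        assert not res.table["significant"].any()

    def test_degenerate_f_matches_hand_computation(self):
        # groups (1,1), (2,2), (3,3): zero within-group variance -> F = inf
        design, ids = self._design3()
        res = multi_sample_anova(make_matrix([[1, 1, 2, 2, 3, 3]], ids), design)
        assert np.isinf(res.table["F"].iloc[0])
        assert res.table["p"].iloc[0] == 0.0
        assert res.table["max_abs_difference"].iloc[0] == pytest.approx(2.0)

    def test_f_matches_scipy_oneway(self):
        design, ids = self._design3()
        rng = np.random.default_rng(1)
        X = rng.normal(20, 1, (40, 6))
        res = multi_sample_anova(make_matrix(X, ids), design)
        expected = sp_stats.f_oneway(X[:, :2], X[:, 2:4], X[:, 4:], axis=1)
        np.testing.assert_allclose(res.table["F"].to_numpy(), expected.statistic)
        np.testing.assert_allclose(res.table["p"].to_numpy(), expected.pvalue)

    def test_fold_change_filter_excludes_small_effects(self):
        # tiny p but max pairwise FC 1.2 < 1.5 -> excluded
        design, ids = self._design3()
        rng = np.random.default_rng(2)
        shift = np.log2(1.2)
        X = rng.normal(0, 1e-4, (30, 6))
        X[:, 2:4] += shift
        X += 20.0
        res = multi_sample_anova(make_matrix(X, ids), design, min_fc=1.5)
        assert (res.table["q"] <= 0.05).any()
        assert not res.table["significant"].any()

    def test_group_with_single_replicate_rejected(self):
        ids = ["X_1", "X_2", "Y_1", "Y_2", "Z_1"]
        rows = [
            {"fraction": "proteome", "condition": c, "replicate": r}
            for c, r in [("X", 1), ("X", 2), ("Y", 1), ("Y", 2), ("Z", 1)]
        ]
        design = SampleDesign(pd.DataFrame(rows, index=pd.Index(ids, name="sample_id")))
        with pytest.raises(TableError, match="< 2 replicates"):
            multi_sample_anova(make_matrix(np.ones((2, 5)) + 1, ids), design)

    def test_needs_three_groups(self):
        design, cols = make_two_group_design()
        with pytest.raises(TableError, match=">= 3 groups"):
            multi_sample_anova(make_matrix(np.ones((2, 6)), cols), design)


class TestBHAdjust:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, pvals):
        q = bh_adjust(pvals)
        assert (q <= 1.0).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p
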