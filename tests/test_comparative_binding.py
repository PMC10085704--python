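import numpy as np
import pandas as pd
import pytest

from chromkit import (
    SimulationParams,
    TableError,
    TestConfig,
    pearson_correlate,
    rank_by_fold_change,
    rcb_anova_cluster,
    relative_chromatin_binding,
    row_normalize,
    sam_ttest,
    simulate_phase_experiment,
)
from chromkit.differential_stats import DifferentialResult

from conftest import make_matrix, make_two_group_design


def phase_layers(n=20, n_conditions=3, noise=0.0, seed=0, **kwargs):
    params = SimulationParams(n_proteins=n, n_conditions=n_conditions,
                              noise_sd=noise, condition_effect_sd=0.0,
                              mnar_midpoint=None, seed=seed, **kwargs)
    return simulate_phase_experiment(params)


class TestRelativeChromatinBinding:
    def test_direct_formula(self):
        chrom, prot, design, _ = phase_layers(n=5)
        chrom.values.iloc[0, :] = 12.0
        prot.values.iloc[0, :] = 10.0
        profile = relative_chromatin_binding(chrom, prot, design)
        assert (profile.values.iloc[0] == 2.0).all()

    def test_identical_layers_zero(self):
        chrom, prot, design, _ = phase_layers(n=10)
        prot2 = prot.copy()
        prot2.values.loc[:, :] = chrom.values.values[:, : prot.values.shape[1]]
        # simpler: chromatome equal to matched proteome means
        chrom2 = chrom.copy()
        chrom2.values.loc[:, :] = 15.0
        prot2.values.loc[:, :] = 15.0
        profile = relative_chromatin_binding(chrom2, prot2, design)
        assert (profile.values.values == 0.0).all()

    def test_location_shift_invariance(self):
        chrom, prot, design, _ = phase_layers(n=15, noise=0.2, seed=3)
        base = relative_chromatin_binding(chrom, prot, design)
        chrom_shift = chrom.copy()
        prot_shift = prot.copy()
        chrom_shift.values.iloc[4] += 7.5
        prot_shift.values.iloc[4] += 7.5
        shifted = relative_chromatin_binding(chrom_shift, prot_shift, design)
        np.testing.assert_allclose(shifted.values.iloc[4], base.values.iloc[4])

    def test_missing_proteome_filled_and_flagged(self):
        chrom, prot, design, _ = phase_layers(n=6)
        pid = prot.values.index[2]
        prot.values.loc[pid, :] = np.nan
        profile = relative_chromatin_binding(chrom, prot, design, proteome_fill=0.0)
        assert pid in profile.filled
        assert (profile.values.loc[pid] == 0.0).all()

    def test_no_shared_proteins_rejected(self):
        chrom, prot, design, _ = phase_layers(n=4)
        prot.values.index = [f"other{i}" for i in range(4)]
        with pytest.raises(TableError, match="shared"):
            relative_chromatin_binding(chrom, prot, design)


class TestRcbAnovaCluster:
    def test_null_simulation_nothing_significant(self):
        chrom, prot, design, _ = phase_layers(n=300, noise=0.1, seed=2)
        profile = relative_chromatin_binding(chrom, prot, design)
        anova, assignment = rcb_anova_cluster(
            profile, frozenset(profile.values.index), k=5, n_restarts=5
        )
        assert not anova.table["significant"].any()
        assert len(assignment.assignments) == 0

    def test_high_confidence_filter_is_respected(self):
        n = 100
        aff = np.zeros((n, 3))
        aff[:30, 1] = 2.0
        params = SimulationParams(n_proteins=n, n_conditions=3, noise_sd=0.2,
                                  condition_effect_sd=0.0, mnar_midpoint=None,
                                  seed=5)
        chrom, prot, design, _ = simulate_phase_experiment(params, affinity_effects=aff)
        profile = relative_chromatin_binding(chrom, prot, design)
        allowed = frozenset(profile.values.index[:50])
        anova, _ = rcb_anova_cluster(profile, allowed, k=3, n_restarts=5)
        assert set(anova.table.index) <= set(allowed)

    def test_peak_condition_clusters_recovered(self):
        n = 300
        aff = np.zeros((n, 3))
        aff[:60, 1] = 2.0  # formative peak
        aff[60:120, 2] = 2.0  # primed peak
        params = SimulationParams(n_proteins=n, n_conditions=3, noise_sd=0.2,
                                  condition_effect_sd=0.0, mnar_midpoint=None,
                                  seed=6)
        chrom, prot, design, truth = simulate_phase_experiment(
            params, affinity_effects=aff
        )
        profile = relative_chromatin_binding(chrom, prot, design)
        anova, assignment = rcb_anova_cluster(
            profile, frozenset(profile.values.index), k=2, n_restarts=10
        )
        sig = set(anova.significant_proteins)
        formative = set(profile.values.index[:60])
        primed = set(profile.values.index[60:120])
        assert len(sig & formative) / 60 >= 0.9
        assert len(sig & primed) / 60 >= 0.9
        # the two effect groups separate into distinct clusters
        got_f = assignment.assignments.reindex(sorted(formative & sig)).mode()[0]
        got_p = assignment.assignments.reindex(sorted(primed & sig)).mode()[0]
        assert got_f != got_p
        labels = {assignment.labels[int(got_f)], assignment.labels[int(got_p)]}
        assert labels == {"formative-peak", "primed-peak"}

    def test_empty_intersection_rejected(self):
        chrom, prot, design, _ = phase_layers(n=10)
        profile = relative_chromatin_binding(chrom, prot, design)
        with pytest.raises(TableError, match="intersect"):
            rcb_anova_cluster(profile, frozenset({"nope"}))


class TestRankByFoldChange:
    def _result(self, diffs):
        table = pd.DataFrame({
            "difference": diffs,
            "significant": [False] * len(diffs),
        }, index=[f"p{i}" for i in range(len(diffs))])
        return DifferentialResult(table, TestConfig())

    def test_basic_order(self):
        ranks = rank_by_fold_change(self._result([2.0, 0.0, -1.0]))
        assert ranks.loc["p0", "rank"] == 1
        assert ranks.loc["p1", "rank"] == 2
        assert ranks.loc["p2", "rank"] == 3

    def test_ties_get_average_rank(self):
        ranks = rank_by_fold_change(self._result([1.0, 1.0]))
        assert (ranks["rank"] == 1.5).all()

    def test_ranks_are_average_rank_permutation(self):
        rng = np.random.default_rng(0)
        ranks = rank_by_fold_change(self._result(list(rng.normal(size=40))))
        np.testing.assert_allclose(sorted(ranks["rank"]), np.arange(1, 41))

    def test_inverse_ordering_recovers_input(self):
        diffs = [0.5, -2.0, 3.0, 1.0]
        ranks = rank_by_fold_change(self._result(diffs))
        restored = ranks.loc[[f"p{i}" for i in range(4)], "fold_change_log2"]
        np.testing.assert_allclose(restored, diffs)


class TestRowNormalize:
    def test_basic(self):
        out = row_normalize(pd.DataFrame([[1.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 1.0]])

    def test_centered_rows_unchanged(self):
        frame = pd.DataFrame([[-1.0, 0.0, 1.0], [2.0, -2.0, 0.0]])
        pd.testing.assert_frame_equal(row_normalize(frame), frame)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        out = row_normalize(pd.DataFrame(rng.normal(size=(20, 5))))
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)


class TestPearsonCorrelate:
    def test_identical_vectors(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, n = pearson_correlate(a, a)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_antiproportional(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        r, _ = pearson_correlate(a, -2 * a)
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=n)
        idx = [f"p{i}" for i in range(n)]
        r, used = pearson_correlate(pd.Series(x, index=idx), pd.Series(y, index=idx))
        assert used == n
        assert r == pytest.approx(0.6, abs=0.08)

    def test_pairwise_complete_only(self):
        a = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0], index=list("abcde"))
        b = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan], index=list("abcde"))
        _, n = pearson_correlate(a, b)
        assert n == 3

    def test_subset_panel(self):
        a = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        r, n = pearson_correlate(a, a * 2, subset=[f"p{i}" for i in range(5)])
        assert n == 5

    def test_too_few_pairs_rejected(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(TableError, match=">= 3"):
            pearson_correlate(a, a)
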