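import numpy as np
import pytest

from wakemap.stats import (_cluster_stats, _gls_walds, cluster_permutation,
                           fit_unit_lmm, paired_cluster_test, stage_contrasts,
                           timecourse_cluster_correct, tod_bins)


def _grouped_data(seed=7, n_subj=12, n_per=8, slope=0.5):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), n_per)
    x = rng.normal(0, 1, subj.size)
    y = 2.0 + slope * x + rng.normal(0, 0.7, n_subj)[subj] \
        + rng.normal(0, 0.8, subj.size)
    return y, x, subj


class TestUnitLmm:
    def test_recovers_slope(self):
        y, x, subj = _grouped_data()
        r = fit_unit_lmm(y, x, subj)
        assert r.converged and r.estimate == pytest.approx(0.5, abs=0.2)
        assert 0 < r.p < 0.01 and r.wald == (r.estimate / r.se) ** 2

    def test_self_predictor_gives_unit_slope_huge_wald(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(6), 5)
        y = rng.normal(0, 1, 30) + rng.normal(0, 1, 6)[subj]
        x = y - np.mean(y) + rng.normal(0, 0.02, 30)
        r = fit_unit_lmm(y, x, subj)
        assert r.estimate == pytest.approx(1.0, abs=0.05)
        assert r.wald > 100

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fit_unit_lmm(np.ones(12), np.ones(12), np.zeros(12))

    def test_fast_fitter_matches_mixedlm(self):
        """Independent cross-check: the vectorized GLS agrees with the
        statsmodels MixedLM reference on estimate and standard error."""
        y, x, subj = _grouped_data(seed=3)
        ref = fit_unit_lmm(y, x, subj)
        codes, gidx = np.unique(subj, return_inverse=True)
        b, se, w, p = _gls_walds(y, x[:, None], gidx, codes.size)
        assert b[0] == pytest.approx(ref.estimate, rel=0.05)
        assert se[0] == pytest.approx(ref.se, rel=0.10)


class TestClusterPermutation:
    def _chain(self, n):
        adj = np.zeros((n, n), bool)
        i = np.arange(n - 1)
        adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_singleton_cluster_stat_equals_wald(self):
        walds = np.array([1.0, 9.0, 2.0])
        pvals = np.array([0.5, 0.01, 0.5])
        cs = _cluster_stats(walds, pvals, self._chain(3), alpha=0.05)
        assert len(cs) == 1
        units, stat = cs[0]
        assert list(units) == [1] and stat == 9.0

    def test_disconnected_patches_never_merge(self):
        walds = np.array([9.0, 9.0, 1.0, 9.0, 9.0])
        pvals = np.array([0.01, 0.01, 0.9, 0.01, 0.01])
        cs = _cluster_stats(walds, pvals, self._chain(5), alpha=0.05)
        assert len(cs) == 2
        assert [list(u) for u, _ in cs] in ([[0, 1], [3, 4]], [[3, 4], [0, 1]])

    def test_localized_effect_detected(self):
        rng = np.random.default_rng(5)
        n_subj, n_per, n_units = 12, 8, 20
        subj = np.repeat(np.arange(n_subj), n_per)
        X = rng.normal(0, 1, (subj.size, n_units))
        y = 2.0 + rng.normal(0, 0.5, n_subj)[subj] + rng.normal(0, 0.5, subj.size)
        y = y + X[:, 8:12].mean(axis=1) * 1.5       # effect in a 4-unit patch
        res = cluster_permutation(y, X, subj, self._chain(n_units),
                                  n_perm=200, seed=2)
        assert res.any_significant
        sig_units = np.flatnonzero(res.mask)
        assert set(range(9, 11)).issubset(set(sig_units))

    def test_deterministic_given_seed(self):
        y, x, subj = _grouped_data()
        X = np.column_stack([x, -x, x + 0.1])
        a = cluster_permutation(y, X, subj, self._chain(3), n_perm=150, seed=9)
        b = cluster_permutation(y, X, subj, self._chain(3), n_perm=150, seed=9)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        assert a.threshold == b.threshold

    def test_low_n_perm_warns(self):
        y, x, subj = _grouped_data()
        with pytest.warns(UserWarning):
            cluster_permutation(y, x[:, None], subj, np.zeros((1, 1), bool),
                                n_perm=50, seed=0)


class TestTimecourseCorrection:
    def test_all_significant_series_forms_one_spanning_cluster(self):
        rng = np.random.default_rng(0)
        d = 1.0 + 0.1 * rng.standard_normal((10, 30))
        res = timecourse_cluster_correct(d, n_perm=200, seed=1)
        assert res.mask.all()
        assert len(res.clusters) == 1

    def test_single_epoch_series(self):
        rng = np.random.default_rng(0)
        d = 2.0 + 0.1 * rng.standard_normal((10, 1))
        res = timecourse_cluster_correct(d, n_perm=200, seed=1)
        assert res.clusters[0][0].size == 1

    def test_identical_groups_nothing_significant(self):
        res = paired_cluster_test(np.ones((6, 8)), np.ones((6, 8)),
                                  np.eye(8, dtype=bool) ^ True, n_perm=150, seed=0)
        assert not res.any_significant
        assert np.all(res.stat_values == 0)


class TestStageContrasts:
    def _cohort(self, seed=0, effects=(0.0, 0.6, 1.0)):
        rng = np.random.default_rng(seed)
        n_subj, n_per = 12, 4
        rows_y, rows_stage, rows_subj = [], [], []
        u = rng.normal(0, 0.4, n_subj)
        for s in range(n_subj):
            for st, eff in zip(("N2", "N3", "REM"), effects):
                for _ in range(n_per):
                    rows_y.append(2.0 + eff + u[s] + rng.normal(0, 0.6))
                    rows_stage.append(st)
                    rows_subj.append(s)
        return (np.array(rows_y), np.array(rows_stage), np.array(rows_subj))

    def test_ordering_recovered_and_significant(self):
        y, stage, subj = self._cohort()
        res = stage_contrasts(y, stage, subj)
        assert res.df == 2 and res.p < 0.001
        m = res.stage_means
        assert m["N2"] < m["N3"] < m["REM"]

    def test_two_stage_restriction(self):
        y, stage, subj = self._cohort()
        keep = stage != "REM"
        res = stage_contrasts(y[keep], stage[keep], subj[keep])
        assert set(res.pairwise) == {("N2", "N3")} and res.df == 1

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_contrasts(np.ones(10), np.array(["N2"] * 10), np.arange(10))


def test_tod_bins_cover_range():
    t = np.linspace(0, 8, 50)
    bins = tod_bins(t)
    assert set(bins) == {0, 1, 2}
    assert np.all(np.diff(bins) >= 0)
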