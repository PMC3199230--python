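import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bprsig.diffexpr import (bh_adjust, moderated_t, pvalue_histogram,
                             student_t_rank)

from conftest import make_matrix


def pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestStudentT:
    def test_matches_hand_pooled_formula(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(3, 8))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = student_t_rank(make_matrix(vals), y)
        for f, row in res.table.set_index("feature").iterrows():
            g = vals[int(f[1:]) - 1]
            expected = pooled_t(g[y == 0], g[y == 1])
            assert row["t"] == pytest.approx(expected, abs=1e-12)
            assert row["effect"] == pytest.approx(
                g[y == 1].mean() - g[y == 0].mean(), abs=1e-12)

    def test_flat_feature_ranks_last(self):
        vals = np.vstack([np.array([0, 0, 2, 2.0]),  # strong difference
                          np.array([1, 2, 1, 2.0])])  # identical class means
        res = student_t_rank(make_matrix(vals), np.array([0, 0, 1, 1]))
        assert res.table["feature"].iloc[-1] == "g2"
        assert res.table["t"].iloc[-1] == 0.0

    def test_label_flip_negates_t_keeps_ranking(self):
        rng = np.random.default_rng(6)
        X = make_matrix(rng.normal(size=(10, 8)))
        y = np.array([0, 1] * 4)
        r1 = student_t_rank(X, y)
        r2 = student_t_rank(X, 1 - y)
        m1 = r1.table.set_index("feature")
        m2 = r2.table.set_index("feature")
        np.testing.assert_allclose(m1["t"], -m2.loc[m1.index, "t"], atol=1e-12)
        assert list(m1.index) == list(r2.table["feature"])

    def test_small_class_rejected(self):
        # one class empty, or fewer than 3 samples total: no residual df
        X3 = make_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError):
            student_t_rank(X3, np.array([1, 1, 1]))
        X2 = make_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            student_t_rank(X2, np.array([0, 1]))

    def test_singleton_class_tolerated_for_loo_folds(self):
        """2-vs-1 split (minimal leave-one-out fold) runs and the singleton
        contributes zero to the pooled variance."""
        vals = np.array([[1.0, 3.0, 7.0], [2.0, 2.0, 2.0]])
        res = student_t_rank(make_matrix(vals), np.array([0, 0, 1]))
        row = res.table.set_index("feature").loc["g1"]
        sp2 = ((1 - 2) ** 2 + (3 - 2) ** 2) / 1  # df = 3 - 2 = 1
        expected = (7 - 2) / np.sqrt(sp2 * (1 / 2 + 1 / 1))
        assert row["t"] == pytest.approx(expected, abs=1e-12)

    def test_moderated_requires_two_per_class(self):
        X = make_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError):
            moderated_t(X, np.array([0, 0, 1]))

    def test_top_features_stable_ties(self):
        vals = np.vstack([[0, 0, 1, 1.0]] * 3)  # identical t for all
        res = student_t_rank(make_matrix(vals), np.array([0, 0, 1, 1]))
        assert res.top_features(2) == ["g1", "g2"]


class TestModeratedT:
    def test_constant_variance_reduces_to_ordinary_t(self):
        """When every feature has the same residual variance, shrinkage
        to the common value leaves the statistics unchanged."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=8)
        base = (base - base.mean()) / base.std(ddof=1)
        # same residuals everywhere, different means -> identical s_g^2
        shifts = rng.normal(size=(20, 1))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        offs = np.where(y == 1, 1.0, 0.0) * rng.normal(size=(20, 1))
        vals = base[None, :] + shifts + offs
        X = make_matrix(vals)
        mod = moderated_t(X, y)
        ord_ = student_t_rank(X, y).table.set_index("feature")
        m = mod.table.set_index("feature")
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(m["t"], ord_.loc[m.index, "t"], rtol=1e-9)

    def test_effects_identical_to_student(self):
        rng = np.random.default_rng(8)
        X = make_matrix(rng.normal(size=(50, 10)))
        y = np.array([0] * 5 + [1] * 5)
        m = moderated_t(X, y).table.set_index("feature")["effect"]
        s = student_t_rank(X, y).table.set_index("feature")["effect"]
        np.testing.assert_allclose(m, s.loc[m.index], atol=1e-12)

    def test_null_pvalues_uniform(self):
        """delta = 0: the fraction of p < 0.05 stays inside the binomial
        99% interval around 0.05 (no excess of nominal significance)."""
        rng = np.random.default_rng(9)
        X = make_matrix(rng.normal(8, 1, size=(1000, 10)))
        y = np.array([0] * 5 + [1] * 5)
        res = moderated_t(X, y)
        frac = float((res.table["p"] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_shrinkage_between_feature_and_prior(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(200, 10)) * rng.uniform(0.2, 3, size=(200, 1))
        y = np.array([0] * 5 + [1] * 5)
        res = moderated_t(make_matrix(vals), y)
        assert np.isfinite(res.d0) and res.d0 > 0
        assert res.s0_sq > 0

    def test_paired_design_degenerate_difference(self):
        """lower = upper + constant per feature: zero residual variance is
        floored and flagged, giving very large |t| rather than NaN."""
        rng = np.random.default_rng(11)
        # integer-valued data so lower - upper is exactly constant per feature
        upper = rng.integers(4, 12, size=(30, 4)).astype(float)
        const = rng.integers(1, 4, size=(30, 1)).astype(float)
        vals = np.hstack([upper, upper + const])
        # one feature with real noise so a positive floor exists
        vals[0, 4:] = upper[0] + const[0] + rng.normal(0, 0.1, size=4)
        X = make_matrix(vals)
        pairs = [f"p{i}" for i in range(4)] * 2
        y = np.array([0] * 4 + [1] * 4)
        res = moderated_t(X, y, design="paired", pairs=pairs)
        assert res.table["var_floored"].iloc[1:].all()
        assert np.isfinite(res.table["t"]).all()
        assert (res.table["t"].abs().iloc[1:] > 10).all()

    def test_paired_matches_one_sample_t_when_no_shrinkage_needed(self):
        rng = np.random.default_rng(12)
        upper = rng.normal(size=(40, 5))
        lower = upper + rng.normal(0.3, 1.0, size=(40, 5))
        X = make_matrix(np.hstack([upper, lower]))
        pairs = [f"p{i}" for i in range(5)] * 2
        y = np.array([0] * 5 + [1] * 5)
        res = moderated_t(X, y, design="paired", pairs=pairs)
        d = lower - upper
        np.testing.assert_allclose(res.table["effect"], d.mean(axis=1),
                                   atol=1e-12)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_statsmodels_reference(self, p):
        got = bh_adjust(p)
        _, expected, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40),
           st.floats(0.01, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_threshold_consistency_with_step_up_rule(self, p, alpha):
        """Features with q <= alpha are exactly those selected by the
        classic BH step-up rule at level alpha."""
        p = np.asarray(p)
        q = bh_adjust(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        passing = np.where(ranked <= alpha * np.arange(1, n + 1) / n)[0]
        selected = np.zeros(n, bool)
        if len(passing):
            selected[order[:passing[-1] + 1]] = True
        np.testing.assert_array_equal(q <= alpha + 1e-15, selected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPvalueHistogram:
    def test_uniform_grid_fills_bins(self):
        p = (np.arange(20) + 0.5) / 20
        out = pvalue_histogram(p, 0.05)
        assert np.all(out["counts"] == 1)
        assert out["excess_below_0.05"] == pytest.approx(0.0)

    def test_all_significant(self):
        out = pvalue_histogram(np.full(100, 0.01))
        assert out["excess_below_0.05"] == pytest.approx(0.95)

    def test_alternative_shows_excess(self):
        rng = np.random.default_rng(13)
        t = rng.normal(3, 1, size=500)
        p = 2 * stats.norm.sf(np.abs(t))
        out = pvalue_histogram(p)
        assert out["excess_below_0.05"] > 0.5
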