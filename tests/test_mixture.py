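"""Gaussian fits, AIC model comparison, and the separation statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from switchscan import (
    InsufficientDataError,
    ValidationError,
    delta_aic,
    fit_single_gaussian,
    fit_two_gaussian_em,
    score_matrix,
    separation_D,
)
from switchscan.mixture import _canonicalize, _em_run


class TestSingleGaussian:
    def test_rejects_fewer_than_three_values(self):
        with pytest.raises(InsufficientDataError):
            fit_single_gaussian([-1.0, 1.0])

    def test_symmetric_example_closed_form(self):
        fit = fit_single_gaussian([-1.0, 0.0, 1.0])
        assert fit.means[0] == 0.0
        assert fit.variances[0] == pytest.approx(2.0 / 3.0)
        # -(3/2)(ln(2*pi*2/3) + 1); the AIC is 4 - 2 logL
        assert fit.log_likelihood == pytest.approx(-3.648617937451771, abs=1e-9)
        assert fit.aic == pytest.approx(11.297235874903542, abs=1e-9)

    def test_loglik_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.2, 4), rng.integers(3, 60))
            fit = fit_single_gaussian(x)
            oracle = stats.norm.logpdf(x, x.mean(), x.std()).sum()
            assert fit.log_likelihood == pytest.approx(oracle, abs=1e-8)
            assert fit.aic == pytest.approx(4 - 2 * oracle, abs=1e-8)

    def test_affine_transform_shifts_loglik_by_jacobian(self):
        x = np.array([-1.0, 0.0, 1.0])
        base = fit_single_gaussian(x)
        moved = fit_single_gaussian(3 * x + 5)
        assert moved.means[0] == pytest.approx(3 * base.means[0] + 5)
        assert moved.variances[0] == pytest.approx(9 * base.variances[0])
        assert moved.log_likelihood == pytest.approx(base.log_likelihood - 3 * math.log(3))
        assert moved.aic == pytest.approx(base.aic + 6 * math.log(3))

    def test_zero_variance_floored_and_flagged(self):
        fit = fit_single_gaussian([2.0, 2.0, 2.0, 2.0])
        assert fit.variance_floored
        assert fit.variances[0] > 0


class TestTwoGaussianEM:
    def test_rejects_fewer_than_six_values(self):
        with pytest.raises(InsufficientDataError):
            fit_two_gaussian_em([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_recovers_well_separated_mixture(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])
        fit = fit_two_gaussian_em(x, rng=11)
        assert fit.means[0] == pytest.approx(0.0, abs=0.2)
        assert fit.means[1] == pytest.approx(6.0, abs=0.2)
        assert fit.weights[1] == pytest.approx(0.5, abs=0.05)
        assert fit.converged
        assert fit.means[0] < fit.means[1]  # sorted by mean

    def test_mixture_never_worse_than_single(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            f1 = fit_single_gaussian(x)
            f2 = fit_two_gaussian_em(x, rng=0)
            assert f2.log_likelihood >= f1.log_likelihood - 1e-9

    def test_tight_cluster_collapses_to_single(self):
        rng = np.random.default_rng(5)
        x = 4.0 + 1e-5 * rng.normal(size=40)
        res = delta_aic(x, rng=5)
        assert res.delta_aic <= 1e-6

    def test_em_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1.5, 60)])
        z, *_ = _canonicalize(x)
        *_, trace = _em_run(z, 10, 1e-8, 500, np.random.default_rng(0), 1e-6)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_agrees_with_sklearn_oracle(self):
        """Independent EM implementation finds the same mixture."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1.5, 200)])
        ours = fit_two_gaussian_em(x, rng=2)
        ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8, reg_covar=1e-10)
        ref.fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.weights, ref.weights_[order], atol=0.02)


class TestDeltaAIC:
    def test_well_separated_mixture_scores_high(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100)])
        res = delta_aic(x, rng=3)
        assert res.delta_aic > 50
        assert res.delta_aic == res.fit1.aic - res.fit2.aic

    def test_single_gaussian_rarely_flagged(self):
        hits = 0
        for s in range(50):
            x = np.random.default_rng(100 + s).normal(5, 1, 1000)
            if delta_aic(x, rng=s).delta_aic < 6:
                hits += 1
        assert hits >= 45  # >= 90% of replicates below the strong-support cutoff

    def test_affine_invariance_including_reflection(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(4, 2, 40)])
        base = delta_aic(x, rng=0).delta_aic
        for a, b in [(3.0, 5.0), (-3.0, 5.0), (0.25, -2.0), (-1.0, 0.0)]:
            assert delta_aic(a * x + b, rng=0).delta_aic == pytest.approx(base, abs=1e-6)

    def test_mode_assignment_high_is_larger_mean(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.5, 50), rng.normal(5, 0.5, 50)])
        res = delta_aic(x, rng=1)
        assert set(np.unique(res.mode_assignment)) == {"low", "high"}
        assert x[res.high_mode].mean() > x[~res.high_mode].mean()
        assert res.high_mode.sum() == 50

    def test_kurtosis_is_plugin_estimator(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        res = delta_aic(x, rng=4)
        m2 = ((x - x.mean()) ** 2).mean()
        m4 = ((x - x.mean()) ** 4).mean()
        assert res.kurtosis == pytest.approx(m4 / m2**2 - 3, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_delta_aic_lower_bound_property(self, seed):
        """The collapsed restart guarantees delta_AIC >= -6 on any profile."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 60))
        kind = seed % 3
        if kind == 0:
            x = rng.normal(rng.uniform(-10, 10), rng.uniform(0.01, 5), n)
        elif kind == 1:
            x = rng.exponential(2.0, n)
        else:
            x = np.round(rng.normal(0, 1, n), 1)  # heavy ties
        res = delta_aic(x, rng=int(seed))
        assert res.delta_aic >= -6 - 1e-9


class TestSeparationD:
    def test_printed_examples(self):
        r = separation_D([1.0, 3.0, 1.0, 3.0], [True, True, False, False])
        assert r.D == 0.0  # equal group means
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 1, 50_000)
        g2 = rng.normal(2, 1, 50_000)
        r = separation_D(np.concatenate([g1, g2]), np.arange(100_000) < 50_000)
        assert r.D == pytest.approx(2.0, abs=0.02)

    def test_exact_formula(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 12.0, 14.0])
        mask = np.array([True, True, True, False, False, False])
        r = separation_D(x, mask)
        mu1, s1 = x[:3].mean(), x[:3].std()
        mu2, s2 = x[3:].mean(), x[3:].std()
        assert r.D == pytest.approx(abs(mu1 - mu2) / math.sqrt((s1**2 + s2**2) / 2))

    def test_symmetric_in_groups_and_affine_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 40)
        mask = np.arange(40) % 3 == 0
        d = separation_D(x, mask).D
        assert separation_D(x, ~mask).D == pytest.approx(d)
        assert separation_D(-2.5 * x + 7, mask).D == pytest.approx(d)

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            separation_D([1.0, 2.0, 3.0], [True, False, False])

    def test_degenerate_equal_groups(self):
        r = separation_D([5.0, 5.0, 5.0, 5.0], [True, True, False, False])
        assert r.D == 0.0


class TestScoreMatrix:
    def test_requires_six_samples(self, gaussian_matrix):
        import pandas as pd

        from switchscan.io import ExpressionMatrix

        small = ExpressionMatrix(gaussian_matrix.data.iloc[:, :5])
        with pytest.raises(ValidationError):
            score_matrix(small)

    def test_sample_permutation_leaves_scores_unchanged(self, gaussian_matrix):
        from switchscan.io import ExpressionMatrix

        scores = score_matrix(gaussian_matrix, seed=1).set_index("gene_id")
        rng = np.random.default_rng(0)
        perm = rng.permutation(gaussian_matrix.shape[1])
        shuffled = ExpressionMatrix(gaussian_matrix.data.iloc[:, perm])
        scores_p = score_matrix(shuffled, seed=1).set_index("gene_id")
        assert (scores["delta_aic"] == scores_p["delta_aic"]).all()

    def test_unfittable_gene_reported_with_reason(self, gaussian_matrix):
        from switchscan.io import ExpressionMatrix

        data = gaussian_matrix.data.copy()
        data.iloc[0, 5:] = np.nan
        scores = score_matrix(ExpressionMatrix(data), seed=0).set_index("gene_id")
        bad = scores.iloc[0]
        assert np.isnan(bad["delta_aic"])
        assert "insufficient" in bad["reason"]
        assert scores["delta_aic"].notna().sum() == 19

    def test_ranks_descend_with_ties_broken_by_gene_id(self, gaussian_matrix):
        scores = score_matrix(gaussian_matrix, seed=1)
        ranked = scores.sort_values("rank")
        assert (ranked["delta_aic"].diff().dropna() <= 1e-12).all()
        assert ranked["rank"].tolist() == list(range(1, 21))

    def test_planted_toggle_genes_outrank_graded(self, toggle_graded_dataset):
        scores = score_matrix(toggle_graded_dataset.matrix, seed=0).set_index("gene_id")
        toggles = scores.loc[["A", "B"], "delta_aic"]
        graded = scores.loc[[g for g in scores.index if g.startswith("G")], "delta_aic"]
        assert (toggles > 0).all()
        assert toggles.min() > graded.max()
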