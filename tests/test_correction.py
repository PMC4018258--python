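import numpy as np
import pytest

from icdmr.correction import (
    adjustment_constant,
    centralize,
    certainty_weights,
    correct_matrix,
    remove_discrete,
    wls_residuals,
)
from icdmr.mixture import MixtureFit, fit_all, fit_probe_mixture
from icdmr.simulate import SimulationConfig, simulate_dataset

from .conftest import make_matrix


def _fit(pi, mu_u, mu_m, degenerate=False):
    return MixtureFit(
        pi=pi, mu_u=mu_u, mu_m=mu_m, sigma2=1.0, loglik=0.0, converged=True, degenerate=degenerate
    )


class TestCentralize:
    def test_symmetric_mixture_shifts_by_zero(self, rng):
        v = rng.normal(size=6)
        np.testing.assert_allclose(centralize(v, _fit(0.5, -2.0, 2.0)), v)

    def test_weighted_mean_shift(self):
        v = np.zeros(4)
        np.testing.assert_allclose(centralize(v, _fit(0.2, 0.0, 2.0)), -0.4)

    def test_degenerate_uses_dominant_component_mean(self):
        v = np.zeros(3)
        np.testing.assert_allclose(centralize(v, _fit(0.99, 0.0, 3.0, degenerate=True)), -3.0)
        np.testing.assert_allclose(centralize(v, _fit(0.01, -1.0, 3.0, degenerate=True)), 1.0)

    def test_refit_is_shift_invariant(self, bimodal_values):
        """A scalar shift leaves the clustering and posteriors unchanged."""
        fit = fit_probe_mixture(bimodal_values)
        shifted = centralize(bimodal_values, fit)
        refit = fit_probe_mixture(shifted)
        assert refit.pi == pytest.approx(fit.pi, abs=1e-6)
        assert refit.mu_m - refit.mu_u == pytest.approx(fit.mu_m - fit.mu_u, abs=1e-6)


class TestAdjustmentConstant:
    def test_binary_posteriors_give_methylated_mean(self):
        # arithmetic average of the methylated group's intensity
        assert adjustment_constant(
            np.array([3.0, 5.0, 0.2, -0.2]), np.array([1.0, 1.0, 0.0, 0.0])
        ) == pytest.approx(4.0)

    def test_all_zero_posteriors(self):
        assert adjustment_constant(np.array([1.0, 2.0]), np.zeros(2)) == 0.0

    def test_closed_form_no_intercept_regression(self):
        assert adjustment_constant(
            np.array([1.0, 3.0]), np.array([0.5, 0.5])
        ) == pytest.approx(4.0)

    def test_matches_lstsq_oracle(self, rng):
        m = rng.normal(size=9)
        p = rng.uniform(size=9)
        oracle = np.linalg.lstsq(p[:, None], m, rcond=None)[0][0]
        assert adjustment_constant(m, p) == pytest.approx(oracle, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjustment_constant(np.zeros(3), np.zeros(4))


class TestRemoveDiscrete:
    def test_binary_example(self):
        r = remove_discrete(
            np.array([3.0, 5.0, 0.2, -0.2]), np.array([1.0, 1.0, 0.0, 0.0]), 4.0
        )
        np.testing.assert_allclose(r, [-1.0, 1.0, 0.2, -0.2])

    def test_zero_posteriors_identity(self):
        m = np.array([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(remove_discrete(m, np.zeros(3), 5.0), m)

    def test_residual_orthogonality(self, rng):
        """After removal, the no-intercept coefficient of r on p is zero."""
        m = rng.normal(size=12)
        p = rng.uniform(size=12)
        kappa = adjustment_constant(m, p)
        r = remove_discrete(m, p, kappa)
        assert adjustment_constant(r, p) == pytest.approx(0.0, abs=1e-10)


class TestCertaintyWeights:
    @pytest.mark.parametrize("p,w", [(0.9, 0.9), (0.1, 0.9), (0.5, 0.5), (0.0, 1.0)])
    def test_rule(self, p, w):
        assert certainty_weights(np.array([p]))[0] == pytest.approx(w)

    def test_range(self, rng):
        w = certainty_weights(rng.uniform(size=100))
        assert np.all((w >= 0.5) & (w <= 1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            certainty_weights(np.array([1.2]))


class TestWlsResiduals:
    def test_exact_linear_fit(self, rng):
        x = rng.normal(size=8)
        y = 2 * x + 1
        b0, b1, res = wls_residuals(y, x, rng.uniform(0.5, 1.0, size=8))
        assert b1 == pytest.approx(2.0, abs=1e-10)
        assert b0 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_constant_predictor_degenerates_to_weighted_mean(self, rng):
        y = rng.normal(size=6)
        w = rng.uniform(0.5, 1.0, size=6)
        b0, b1, res = wls_residuals(y, np.full(6, 3.0), w)
        assert b1 == 0.0
        assert b0 == pytest.approx(np.sum(w * y) / np.sum(w))
        np.testing.assert_allclose(res, y - b0)

    def test_matches_normal_equations_oracle(self, rng):
        y, x = rng.normal(size=6), rng.normal(size=6)
        w = rng.uniform(0.2, 2.0, size=6)
        # closed-form 2x2 weighted normal equations
        A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        b = np.array([(w * y).sum(), (w * x * y).sum()])
        beta0, beta1 = np.linalg.solve(A, b)
        b0, b1, res = wls_residuals(y, x, w)
        assert b0 == pytest.approx(beta0, abs=1e-10)
        assert b1 == pytest.approx(beta1, abs=1e-10)
        # weighted residual orthogonality
        assert np.sum(w * res) == pytest.approx(0.0, abs=1e-8)
        assert np.sum(w * x * res) == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            wls_residuals(np.ones(4), np.ones(4), np.zeros(4))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            wls_residuals(np.ones(2), np.ones(2), np.ones(2))


class TestCorrectMatrix:
    def test_identical_rows_correct_to_zero(self, rng):
        """A row regressed on its own copy (flat posteriors) leaves ~0 residuals."""
        row = rng.normal(size=10)
        m = make_matrix(np.vstack([row, row]))
        fits = [_fit(0.5, row.mean() - 0.1, row.mean() + 0.1) for _ in range(2)]
        from icdmr.mixture import PosteriorMatrix

        post = PosteriorMatrix(
            probe_ids=m.probe_ids,
            chrom=m.chrom,
            samples=m.samples,
            p=np.full((2, 10), 0.5),
            pos=m.pos,
        )
        out = correct_matrix(m, fits, post)
        np.testing.assert_allclose(out.values[0], row)  # first probe untouched
        np.testing.assert_allclose(out.values[1], 0.0, atol=1e-9)

    def test_independent_rows_nearly_unchanged(self, rng):
        """With an uninformative predictor the corrected row stays ~centralised."""
        vals = rng.normal(size=(2, 400))
        m = make_matrix(vals, samples=[f"s{j}" for j in range(400)])
        fits, post = fit_all(m)
        out = correct_matrix(m, fits, post)
        corr = np.corrcoef(out.values[1], vals[1] - vals[1].mean())[0, 1]
        assert corr > 0.9

    def test_decorrelates_ar_background(self):
        """Corrected null rows lose most of the lag-1 correlation."""
        matrix, _ = simulate_dataset(
            SimulationConfig(n_probes=4000, rho=0.7, dmr_proportion=0.0, seed=7)
        )
        fits, post = fit_all(matrix)
        out = correct_matrix(matrix, fits, post)
        v = out.values[1:]
        lag1 = [np.corrcoef(v[i], v[i + 1])[0, 1] for i in range(0, 3000, 7)]
        assert abs(np.mean(lag1)) < 0.1

    def test_preserves_discrete_signal(self):
        """The case/control gap at a shared DMR survives correction."""
        cfg = SimulationConfig(
            n_probes=2000, rho=0.5, effect=2.0, mf=1.0, dmr_proportion=0.2, seed=3
        )
        matrix, truth = simulate_dataset(cfg)
        fits, post = fit_all(matrix)
        out = correct_matrix(matrix, fits, post)
        gaps = []
        for k, (s, e) in enumerate(truth.dmr_intervals):
            meth = truth.methylated_samples_per_dmr[k]
            unmeth = np.setdiff1d(np.arange(matrix.n_samples), meth)
            for d in range(s + 1, e + 1):  # rows that underwent correction
                gaps.append(out.values[d][meth].mean() - out.values[d][unmeth].mean())
        assert np.mean(gaps) > 1.0  # most of the effect E=2 survives
        assert np.min(gaps) > 0.0

    def test_respects_chromosome_boundaries(self, rng):
        vals = rng.normal(size=(4, 12))
        m = make_matrix(vals, chrom=["chr1", "chr1", "chr2", "chr2"])
        fits, post = fit_all(m)
        out = correct_matrix(m, fits, post)
        # first probe of each chromosome passes through raw
        np.testing.assert_array_equal(out.values[0], vals[0])
        np.testing.assert_array_equal(out.values[2], vals[2])

    def test_requires_matching_fits(self, rng):
        m = make_matrix(rng.normal(size=(3, 6)))
        fits, post = fit_all(m)
        with pytest.raises(ValueError):
            correct_matrix(m, fits[:2], post)


class TestCorrectionDiagnostics:
    def test_scalar_path_matches_vectorised_correction(self, rng):
        """The per-pair diagnostics recompute the same regression the
        vectorised matrix correction applies."""
        from icdmr.correction import (
            adjustment_constant,
            centralize,
            certainty_weights,
            correction_diagnostics,
            remove_discrete,
            wls_residuals,
        )
        from icdmr.simulate import SimulationConfig, simulate_dataset

        matrix, _ = simulate_dataset(
            SimulationConfig(n_probes=40, rho=0.5, dmr_proportion=0.0, seed=31)
        )
        fits, post = fit_all(matrix)
        out = correct_matrix(matrix, fits, post)
        df = correction_diagnostics(matrix, fits, post)
        assert len(df) == 39
        d = 5
        kappa = adjustment_constant(matrix.values[d], post.p[d])
        r = remove_discrete(centralize(matrix.values[d], fits[d]), post.p[d], kappa)
        _, _, res = wls_residuals(
            centralize(matrix.values[d + 1], fits[d + 1]), r, certainty_weights(post.p[d])
        )
        np.testing.assert_allclose(out.values[d + 1], res, atol=1e-10)
        assert df.iloc[d]["kappa"] == pytest.approx(kappa)

    def test_correction_reduces_lag1_correlation_on_average(self):
        from icdmr.correction import correction_diagnostics
        from icdmr.simulate import SimulationConfig, simulate_dataset

        matrix, _ = simulate_dataset(
            SimulationConfig(n_probes=300, rho=0.7, dmr_proportion=0.0, seed=32)
        )
        fits, post = fit_all(matrix)
        df = correction_diagnostics(matrix, fits, post)
        assert df["lag1_corr_before"].mean() > 0.5
        assert abs(df["lag1_corr_after"].mean()) < 0.15
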