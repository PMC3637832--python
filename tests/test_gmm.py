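import math

import numpy as np
import pytest

from gmmfilt import (
    DegenerateDataError,
    GMMFit,
    bic,
    component_density,
    em_fit,
    log_likelihood,
    map_assign,
    mixture_density,
    select_model,
)


def _fit(weights, means, sds):
    w = np.asarray(weights, dtype=float)
    return GMMFit(K=len(w), weights=w / w.sum(), means=np.asarray(means, float),
                  sds=np.asarray(sds, float), logL=0.0, bic=0.0)


def _two_mode_signal(rng, n=500, mu=(0.0, 10.0), sd=1.0):
    half = n // 2
    return np.r_[rng.normal(mu[0], sd, half), rng.normal(mu[1], sd, n - half)]


class TestDensities:
    def test_standard_normal_mode(self):
        assert component_density(0.0, 0.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_symmetry(self):
        for d in (0.3, 1.0, 2.5):
            assert component_density(2 + d, 2, 0.7) == pytest.approx(
                component_density(2 - d, 2, 0.7)
            )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            component_density(0.0, 0.0, 0.0)

    def test_densities_integrate_to_one(self):
        grid = np.linspace(-30, 40, 200_001)
        assert np.trapezoid(component_density(grid, 2.0, 1.5), grid) == pytest.approx(1, abs=1e-4)
        fit = _fit([0.5, 0.5], [-3.0, 3.0], [1.0, 1.0])
        assert np.trapezoid(mixture_density(grid, fit), grid) == pytest.approx(1, abs=1e-4)

    def test_single_component_mixture_equals_component(self):
        fit = _fit([1.0], [1.3], [0.8])
        x = np.linspace(-2, 4, 11)
        np.testing.assert_allclose(mixture_density(x, fit), component_density(x, 1.3, 0.8))

    def test_symmetric_mixture(self):
        fit = _fit([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0])
        assert mixture_density(1.7, fit) == pytest.approx(mixture_density(-1.7, fit))


class TestLogLikelihood:
    def test_single_point_at_mean(self):
        fit = _fit([1.0], [0.0], [1.0])
        assert log_likelihood(np.array([0.0]), fit) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_additivity_under_duplication(self, rng):
        x = rng.normal(0, 1, 40)
        fit = _fit([0.3, 0.7], [-1.0, 2.0], [1.0, 0.5])
        assert log_likelihood(np.r_[x, x], fit) == pytest.approx(2 * log_likelihood(x, fit))

    def test_matches_naive_double_loop(self, rng):
        x = rng.normal(1, 2, 20)
        fit = _fit([0.2, 0.5, 0.3], [-1.0, 0.5, 3.0], [0.4, 1.2, 2.0])
        naive = sum(
            math.log(
                sum(
                    w * component_density(xi, mu, sd)
                    for w, mu, sd in zip(fit.weights, fit.means, fit.sds)
                )
            )
            for xi in x
        )
        assert log_likelihood(x, fit) == pytest.approx(naive, abs=1e-10)


class TestBic:
    def test_hand_values(self):
        assert bic(0.0, 1, 1) == pytest.approx(0.0)
        assert bic(-100.0, 2, 1000) == pytest.approx(234.53877639491068)

    def test_penalty_step_between_adjacent_K(self):
        assert bic(-5.0, 4, 777) - bic(-5.0, 3, 777) == pytest.approx(3 * math.log(777))


class TestEmFit:
    def test_k1_closed_form(self, rng):
        x = rng.normal(3, 2, 200)
        fit = em_fit(x, 1, seed=99)
        assert fit.means[0] == pytest.approx(x.mean())
        assert fit.sds[0] == pytest.approx(x.std())  # MLE (1/N) standard deviation
        assert fit.weights[0] == 1.0
        # seed-independent
        fit2 = em_fit(x, 1, seed=1234)
        np.testing.assert_array_equal(fit.means, fit2.means)

    def test_two_component_parameter_recovery(self, rng):
        x = _two_mode_signal(rng, 500)
        fit = em_fit(x, 2, seed=7, n_restarts=5)
        assert abs(fit.means[0] - 0.0) < 0.3 and abs(fit.means[1] - 10.0) < 0.3
        assert abs(fit.weights[0] - 0.5) < 0.05

    def test_determinism(self, rng):
        x = _two_mode_signal(rng, 300)
        f1 = em_fit(x, 3, seed=42, n_restarts=3)
        f2 = em_fit(x, 3, seed=42, n_restarts=3)
        np.testing.assert_array_equal(f1.means, f2.means)
        np.testing.assert_array_equal(f1.weights, f2.weights)
        assert f1.logL == f2.logL

    def test_monotone_loglik_trace(self, rng):
        x = _two_mode_signal(rng, 400)
        fit = em_fit(x, 3, seed=0, n_restarts=2)
        assert np.all(np.diff(fit.logL_trace) > -1e-8)

    def test_stored_loglik_matches_recomputation(self, rng):
        x = _two_mode_signal(rng, 300)
        fit = em_fit(x, 2, seed=3)
        assert log_likelihood(x, fit) == pytest.approx(fit.logL, abs=1e-6)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_data(self):
        with pytest.raises(DegenerateDataError):
            em_fit(np.ones(50), 2)
        with pytest.raises(ValueError):
            em_fit(np.arange(3.0), 5)

    def test_binned_fit_close_to_exact(self, rng):
        x = _two_mode_signal(rng, 5000)
        exact = em_fit(x, 2, seed=1, n_restarts=3)
        binned = em_fit(x, 2, seed=1, n_restarts=3, n_bins=512)
        np.testing.assert_allclose(binned.means, exact.means, atol=0.05)
        np.testing.assert_allclose(binned.weights, exact.weights, atol=0.01)

    def test_agrees_with_sklearn_reference(self, rng):
        """Independent EM implementation reaches the same optimum."""
        from sklearn.mixture import GaussianMixture

        x = _two_mode_signal(rng, 800, mu=(0.0, 6.0))
        ours = em_fit(x, 2, seed=5, n_restarts=5)
        ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8, reg_covar=1e-10).fit(
            x[:, None]
        )
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.weights, ref.weights_[order], atol=0.01)
        assert ours.logL == pytest.approx(ref.score(x[:, None]) * x.size, rel=1e-4)


class TestSelectModel:
    def test_well_separated_two_components(self, rng):
        x = _two_mode_signal(rng, 2000)  # separation 10 sigma
        fit = select_model(x, 1, 6, seed=2, n_restarts=3)
        assert fit.K == 2

    def test_near_constant_signal_selects_one(self, rng):
        x = 5.0 + rng.normal(0, 1e-3, 500)
        fit = select_model(x, 1, 4, seed=2, n_restarts=2)
        assert fit.K == 1

    def test_fixed_K_bypasses_search(self, rng):
        x = _two_mode_signal(rng, 400)
        fit = select_model(x, 3, 3, seed=2, n_restarts=2)
        assert fit.K == 3


class TestMapAssign:
    def test_nearer_mean_wins(self):
        fit = _fit([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        assert map_assign(np.array([1.0]), fit)[0] == 0
        assert map_assign(np.array([9.0]), fit)[0] == 1

    def test_midpoint_tie_goes_to_lower_component(self):
        fit = _fit([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        assert map_assign(np.array([5.0]), fit)[0] == 0

    def test_matches_brute_force_argmax(self, rng):
        fit = _fit([0.2, 0.3, 0.5], [-2.0, 1.0, 4.0], [0.5, 1.5, 0.8])
        x = rng.normal(1, 3, 100)
        brute = np.array(
            [
                int(
                    np.argmax(
                        [
                            w * component_density(xi, mu, sd)
                            for w, mu, sd in zip(fit.weights, fit.means, fit.sds)
                        ]
                    )
                )
                for xi in x
            ]
        )
        np.testing.assert_array_equal(map_assign(x, fit), brute)

    def test_invariant_under_common_rescaling(self, rng):
        x = rng.normal(0, 3, 200)
        base = _fit([0.25, 0.75], [-1.0, 2.0], [1.0, 1.0])
        # scaling all alpha_k f_k by a constant cannot change the argmax;
        # the weights constructor renormalizes, which is exactly that rescaling
        same = _fit([1.0, 3.0], [-1.0, 2.0], [1.0, 1.0])
        np.testing.assert_array_equal(map_assign(x, base), map_assign(x, same))


class TestSerialization:
    def test_json_round_trip(self, rng):
        fit = em_fit(_two_mode_signal(rng, 300), 2, seed=11)
        back = GMMFit.from_json(fit.to_json())
        np.testing.assert_allclose(back.means, fit.means)
        np.testing.assert_allclose(back.weights, fit.weights)
        assert back.bic == pytest.approx(fit.bic)
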