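"""Fitting checks: priors, MLE vs grid oracle, MCMC recovery, BGR diagnostic."""

import numpy as np
import pytest

from cjshet.inference import (
    InferenceError,
    bgr_diagnostic,
    fit_mle,
    make_priors,
    run_mcmc,
)
from cjshet.likelihood import loglik_constant
from cjshet.scenarios import ScenarioSpec, simulate_dataset

from .conftest import make_history_matrix


class TestPriors:
    def test_uniform_densities(self):
        pr = make_priors()
        assert pr.density("phi", 0.5) == 1.0
        assert pr.density("phi", 1.2) == 0.0
        assert pr.density("sigma", 11.0) == 0.0
        assert pr.density("sigma", 5.0) == pytest.approx(0.1)

    def test_prior_draws_centered(self):
        pr = make_priors()
        rng = np.random.default_rng(0)
        draws = [pr.sample("p_mean", rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)


class TestFitMLE:
    def test_matches_grid_oracle(self):
        spec = ScenarioSpec("constant", n_occasions=8, n_new_per_occasion=25,
                            p_mean=0.4, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=21)
        grid = np.arange(0.01, 1.0, 0.01)
        lls = np.array([[loglik_constant(d, phi, p) for p in grid] for phi in grid])
        i, j = np.unravel_index(lls.argmax(), lls.shape)
        fit = fit_mle(d, "constant_p")
        assert fit.point("phi") == pytest.approx(grid[i], abs=0.011)
        assert fit.point("p") == pytest.approx(grid[j], abs=0.011)
        assert fit.loglik >= lls.max() - 1e-6

    def test_two_occasion_product_identifiable(self):
        """With T = 2 only phi*p is identifiable: the fitted product equals
        the observed recapture fraction of first-occasion releases."""
        spec = ScenarioSpec("constant", n_occasions=2, n_new_per_occasion=200,
                            p_mean=0.5, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=22)
        released = d.first_capture == 0
        frac = d.detections[released, 1].mean()
        fit = fit_mle(d, "constant_p")
        assert fit.point("phi") * fit.point("p") == pytest.approx(frac, abs=1e-4)

    def test_sigma_boundary_flag_under_homogeneous_truth(self):
        spec = ScenarioSpec("constant", n_occasions=10, n_new_per_occasion=40,
                            p_mean=0.4, p_sd=0.0)
        flags = []
        for seed in range(8):
            d = simulate_dataset(spec, rng_seed=300 + seed)
            fit = fit_mle(d, "re_p")
            flags.append(fit.boundary_sigma or fit.point("sigma") < 0.35)
        assert sum(flags) >= 5

    def test_recovers_generating_parameters(self, scenarios):
        d = simulate_dataset(scenarios["symmetric"], rng_seed=23)
        fit = fit_mle(d, "re_p")
        assert fit.point("phi") == pytest.approx(0.7, abs=3 * fit.sd("phi"))
        assert fit.point("p_mean") == pytest.approx(0.4, abs=0.06)

    def test_time_varying_fit(self):
        spec = ScenarioSpec("constant", n_occasions=5, n_new_per_occasion=150,
                            p_mean=0.5, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=24)
        fit = fit_mle(d, "time_varying")
        # interior parameters are identifiable; terminal phi*p only jointly
        assert fit.point("phi_1") == pytest.approx(0.7, abs=0.12)
        assert fit.point("p_3") == pytest.approx(0.5, abs=0.12)


class TestBGR:
    def test_identical_chains(self):
        x = np.random.default_rng(1).normal(size=(1, 500))
        chains = np.vstack([x, x, x])
        assert bgr_diagnostic(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains(self):
        rng = np.random.default_rng(2)
        chains = np.vstack([rng.normal(0, 1, 400), rng.normal(50, 1, 400)])
        assert bgr_diagnostic(chains) > 5

    def test_single_chain_rejected(self):
        with pytest.raises(InferenceError):
            bgr_diagnostic(np.zeros((1, 100)))

    def test_agrees_with_arviz_on_mixed_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(3, 1000))
        ours = bgr_diagnostic(chains)
        theirs = float(arviz.rhat(chains[None].transpose(1, 2, 0)[..., 0]).values) \
            if hasattr(arviz.rhat(chains), "values") else float(arviz.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.02)


class TestRunMCMC:
    def test_kept_sample_accounting(self):
        d = simulate_dataset(
            ScenarioSpec("constant", n_occasions=6, n_new_per_occasion=10,
                         p_mean=0.4, p_sd=0.0), rng_seed=25)
        fit = run_mcmc(d, "constant_p", iterations=600, burn_in=200, thin=4, seed=0)
        assert fit.n_kept_samples == (600 - 200) // 4
        q = fit.params
        assert (q["q2.5"] <= q["q50"]).all() and (q["q50"] <= q["q97.5"]).all()

    def test_invalid_configurations(self):
        d = simulate_dataset(
            ScenarioSpec("constant", n_occasions=4, n_new_per_occasion=5,
                         p_mean=0.4, p_sd=0.0), rng_seed=26)
        with pytest.raises(InferenceError):
            run_mcmc(d, "constant_p", iterations=100, burn_in=100)
        with pytest.raises(InferenceError):
            run_mcmc(d, "constant_p", iterations=101, burn_in=100, thin=5)

    def test_parameter_recovery_constant_model(self):
        spec = ScenarioSpec("constant", n_occasions=15, n_new_per_occasion=50,
                            p_mean=0.4, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=27)
        fit = run_mcmc(d, "constant_p", iterations=4000, burn_in=1500, thin=2, seed=1)
        assert fit.point("phi") == pytest.approx(0.7, abs=3 * fit.sd("phi"))
        assert fit.point("p") == pytest.approx(0.4, abs=3 * fit.sd("p"))

    def test_posterior_mode_agrees_with_mle(self):
        spec = ScenarioSpec("constant", n_occasions=15, n_new_per_occasion=50,
                            p_mean=0.4, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=28)
        mle = fit_mle(d, "constant_p")
        mc = run_mcmc(d, "constant_p", iterations=5000, burn_in=2000, thin=1, seed=2)
        # flat priors: posterior mean within ~2 posterior SDs of the MLE
        for name in ("phi", "p"):
            assert mc.point(name) == pytest.approx(mle.point(name), abs=2 * mc.sd(name))

    def test_degenerate_all_ones_concentrates_near_one(self):
        d = make_history_matrix([(1,) * 15] * 60)
        fit = run_mcmc(d, "constant_p", iterations=3000, burn_in=1000, thin=1, seed=3)
        assert fit.point("phi") > 0.95
        assert fit.point("p") > 0.95

    def test_chain_halving_stability(self):
        spec = ScenarioSpec("constant", n_occasions=10, n_new_per_occasion=30,
                            p_mean=0.4, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=29)
        long = run_mcmc(d, "constant_p", iterations=6000, burn_in=2000, thin=1, seed=4)
        short = run_mcmc(d, "constant_p", iterations=4000, burn_in=2000, thin=1, seed=5)
        for name in ("phi", "p"):
            # MC standard error approximated from the long chain with a
            # conservative autocorrelation inflation factor
            mcse = long.sd(name) / np.sqrt(long.n_kept_samples / 20)
            assert abs(long.point(name) - short.point(name)) < 3 * mcse

    def test_determinism(self):
        d = simulate_dataset(
            ScenarioSpec("constant", n_occasions=6, n_new_per_occasion=10,
                         p_mean=0.4, p_sd=0.0), rng_seed=30)
        a = run_mcmc(d, "constant_p", iterations=500, burn_in=200, thin=1, seed=6)
        b = run_mcmc(d, "constant_p", iterations=500, burn_in=200, thin=1, seed=6)
        assert np.array_equal(a.samples["phi"], b.samples["phi"])
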