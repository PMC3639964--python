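"""Generator checks: moment matching, scenario draws, dataset structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cjshet.scenarios import (
    CaptureHistoryMatrix,
    InvalidMomentsError,
    ScenarioSpec,
    beta_from_moments,
    draw_individual_p,
    default_scenarios,
    simulate_dataset,
    simulate_study,
)


class TestBetaFromMoments:
    def test_symmetric_scenario_shapes(self):
        # frozen from the closed-form inversion, cross-checked by sampling below
        a, b = beta_from_moments(0.4, 0.148)
        assert a == pytest.approx(3.982757, abs=1e-5)
        assert b == pytest.approx(5.974135, abs=1e-5)

    @pytest.mark.parametrize("mean,sd", [(0.4, 0.148), (0.2, 0.163), (0.8, 0.163), (0.5, 0.2)])
    def test_moments_recovered(self, mean, sd):
        a, b = beta_from_moments(mean, sd)
        assert a / (a + b) == pytest.approx(mean, abs=1e-10)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(sd**2, abs=1e-10)

    def test_mean_half_gives_equal_shapes(self):
        for sd in (0.05, 0.2, 0.4):
            a, b = beta_from_moments(0.5, sd)
            assert a == pytest.approx(b, rel=1e-12)

    def test_variance_bound_violation(self):
        with pytest.raises(InvalidMomentsError, match="0.49"):
            beta_from_moments(0.4, 0.49)

    def test_monte_carlo_agreement(self):
        a, b = beta_from_moments(0.4, 0.148)
        x = np.random.default_rng(1).beta(a, b, 200_000)
        assert x.mean() == pytest.approx(0.4, abs=3 * 0.148 / np.sqrt(200_000))


class TestDrawIndividualP:
    def test_two_group_values(self, scenarios):
        p, group = draw_individual_p(scenarios["two_group"], 500, rng_seed=0)
        assert set(np.unique(p)) <= {0.2, 0.8}
        assert set(np.unique(group)) == {1, 2}
        assert np.all((p == 0.2) == (group == 1))

    def test_beta_mean_matches_spec(self, scenarios):
        spec = scenarios["right_skewed"]
        p, group = draw_individual_p(spec, 1_000_000, rng_seed=2)
        assert group is None
        mc_se = spec.p_sd / np.sqrt(p.size)
        assert p.mean() == pytest.approx(0.2, abs=3 * mc_se)

    def test_single_draw_in_unit_interval(self, scenarios):
        p, _ = draw_individual_p(scenarios["symmetric"], 1, rng_seed=3)
        assert p.shape == (1,) and 0 < p[0] < 1

    def test_invalid_n(self, scenarios):
        with pytest.raises(ValueError):
            draw_individual_p(scenarios["symmetric"], 0)


class TestSimulateDataset:
    def test_perfect_survival_and_detection(self):
        spec = ScenarioSpec("constant", n_occasions=6, n_new_per_occasion=4,
                            phi_true=1 - 1e-12, p_mean=1 - 1e-12, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=0)
        for i in range(d.n_individuals):
            assert np.all(d.detections[i, d.first_capture[i]:] == 1)

    def test_zero_survival(self):
        spec = ScenarioSpec("constant", n_occasions=8, n_new_per_occasion=20,
                            phi_true=1e-12, p_mean=0.9, p_sd=0.0)
        d = simulate_dataset(spec, rng_seed=0)
        for i in range(d.n_individuals):
            assert d.detections[i, d.first_capture[i] + 1:].sum() == 0

    def test_recapture_rate_matches_phi_times_mean_p(self, scenarios):
        # fraction re-detected one occasion after release ~ phi * E[p] = 0.28
        spec = ScenarioSpec("symmetric", n_occasions=15, n_new_per_occasion=2000,
                            phi_true=0.7, p_mean=0.4, p_sd=0.148)
        d = simulate_dataset(spec, rng_seed=4)
        sel = d.first_capture < spec.n_occasions - 1
        nxt = d.detections[sel, d.first_capture[sel] + 1]
        se = np.sqrt(0.28 * 0.72 / nxt.size)
        assert nxt.mean() == pytest.approx(0.28, abs=4 * se)

    def test_structural_invariants(self, symmetric_dataset):
        d = symmetric_dataset
        rows = np.arange(d.n_individuals)
        assert np.all(d.detections[rows, d.first_capture] == 1)
        before = np.arange(d.n_occasions) < d.first_capture[:, None]
        assert np.all(d.detections[before] == 0)
        assert set(np.unique(d.detections)) <= {0, 1}
        assert d.true_p is not None and np.all((0 < d.true_p) & (d.true_p < 1))

    def test_detection_frequency_converges_to_true_p(self):
        # with latent states retained, per-individual detection frequency over
        # occasions alive approaches true_p for a long study
        spec = ScenarioSpec("symmetric", n_occasions=200, n_new_per_occasion=30,
                            phi_true=0.97, p_mean=0.4, p_sd=0.148)
        d = simulate_dataset(spec, rng_seed=5, keep_latent=True)
        alive_after_first = d.latent_alive.copy()
        cols = np.arange(d.n_occasions)
        alive_after_first[cols <= d.first_capture[:, None]] = False
        n_alive = alive_after_first.sum(axis=1)
        sel = n_alive >= 50
        freq = (d.detections & alive_after_first).sum(axis=1)[sel] / n_alive[sel]
        band = 4 * np.sqrt(d.true_p[sel] * (1 - d.true_p[sel]) / n_alive[sel])
        assert np.mean(np.abs(freq - d.true_p[sel]) <= band) > 0.95

    def test_two_group_population_sd(self, scenarios):
        p, _ = draw_individual_p(scenarios["two_group"], 200_000, rng_seed=6)
        assert p.std() == pytest.approx(0.3, abs=0.005)
        assert scenarios["two_group"].detection_sd_true == pytest.approx(0.3)


class TestSimulateStudy:
    def test_single_replicate_matches_derived_subseed(self, scenarios):
        spec = scenarios["symmetric"]
        (d,) = simulate_study(spec, 1, rng_seed=7)
        child = np.random.SeedSequence(7).spawn(1)[0]
        assert d == simulate_dataset(spec, child)

    def test_determinism(self, scenarios):
        spec = scenarios["two_group"]
        a = simulate_study(spec, 3, rng_seed=8)
        b = simulate_study(spec, 3, rng_seed=8)
        assert all(x == y for x, y in zip(a, b))

    def test_production_dimensions(self, scenarios):
        reps = simulate_study(scenarios["symmetric"], 4, rng_seed=9)
        assert len(reps) == 4
        for d in reps:
            assert d.detections.shape == (750, 15)

    def test_replicates_differ(self, scenarios):
        a, b = simulate_study(scenarios["symmetric"], 2, rng_seed=10)
        assert not np.array_equal(a.detections, b.detections)


class TestScenarioSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(label="nope"),
            dict(label="symmetric", phi_true=0.0),
            dict(label="symmetric", p_mean=0.4, p_sd=0.49),
            dict(label="symmetric", n_occasions=1),
            dict(label="two_group", p_mean=0.4),
            dict(label="constant", p_mean=0.4, p_sd=0.1),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            ScenarioSpec(**kwargs)

    def test_matrix_invariants_enforced(self):
        det = np.array([[0, 1], [1, 0]], dtype=np.int8)
        with pytest.raises(ValueError):
            CaptureHistoryMatrix(detections=det, first_capture=np.array([0, 0]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    k=st.integers(2, 8),
    m=st.integers(1, 6),
    label=st.sampled_from(["symmetric", "right_skewed", "left_skewed", "two_group"]),
)
def test_simulated_matrices_always_valid(seed, k, m, label):
    """Every simulated matrix satisfies the construction invariants."""
    base = default_scenarios(n_occasions=k, n_new_per_occasion=m)[label]
    d = simulate_dataset(base, rng_seed=seed)
    assert d.detections.shape == (k * m, k)
    rows = np.arange(d.n_individuals)
    assert np.all(d.detections[rows, d.first_capture] == 1)
    before = np.arange(k) < d.first_capture[:, None]
    assert np.all(d.detections[before] == 0)
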