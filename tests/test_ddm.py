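"""First-passage numerics: exact contracts, symmetries, and agreement with
the brute-force path simulator."""

import numpy as np
import pytest
from scipy.integrate import quad

from socddm import (DegenerateCellError, DiffusionParams, ParameterError,
                    bin_probabilities, choice_probability, fpt_cdf,
                    fpt_density, fpt_quantiles, simulate_trials)
from conftest import random_valid_params

QPROBS = [0.1, 0.3, 0.5, 0.7, 0.9]


class TestChoiceProbability:
    def test_zero_drift_symmetric_start_is_half(self):
        p = DiffusionParams(v=0.0, a=0.11, z_rel=0.5, ter=0.2)
        assert choice_probability(p, "upper") == pytest.approx(0.5, abs=1e-12)

    def test_zero_drift_absorption_equals_relative_start(self):
        # zero-drift diffusion is a martingale: P(upper) = z_rel
        p = DiffusionParams(v=0.0, a=0.2, z_rel=0.7, ter=0.2)
        assert choice_probability(p, "upper") == pytest.approx(0.7, abs=1e-10)

    def test_upper_and_lower_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_valid_params(rng)
            s = choice_probability(p, "upper") + choice_probability(p, "lower")
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_matches_simulated_upper_fraction(self):
        p = DiffusionParams(v=0.2, a=0.12, z_rel=0.5, ter=0.2)
        n = 200_000
        sim = simulate_trials(p, n, seed=11)
        frac = (sim.response == "left").mean()
        pu = choice_probability(p, "upper")
        assert abs(frac - pu) < 3 * np.sqrt(pu * (1 - pu) / n)

    def test_monotone_in_drift_and_start(self):
        base = dict(a=0.12, ter=0.3)
        ps = [choice_probability(DiffusionParams(v=v, z_rel=0.5, **base), "upper")
              for v in (-0.2, 0.0, 0.2, 0.4)]
        assert np.all(np.diff(ps) > 0)
        ps = [choice_probability(DiffusionParams(v=0.1, z_rel=z, **base), "upper")
              for z in (0.3, 0.45, 0.6, 0.75)]
        assert np.all(np.diff(ps) > 0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            choice_probability(DiffusionParams(v=0.1, a=-0.1, ter=0.3), "upper")
        with pytest.raises(ParameterError):
            choice_probability(DiffusionParams(v=0.1, a=0.1, z_rel=1.2, ter=0.3))
        with pytest.raises(ParameterError):
            DiffusionParams(v=0.1, a=0.1, z_rel=0.5, ter=0.05, st=0.2).validate()
        with pytest.raises(ParameterError):
            DiffusionParams(v=0.1, a=0.1, z_rel=0.9, ter=0.3, sz=0.05).validate()


class TestDensity:
    def test_zero_before_nondecision_time(self, var_params):
        t0 = var_params.ter - var_params.st / 2
        assert fpt_density(var_params.ter / 2, "upper", var_params) == 0.0
        assert fpt_density(t0 - 1e-6, "upper", var_params) == 0.0
        assert fpt_density(t0 + 0.05, "upper", var_params) > 0.0

    def test_reflection_symmetry(self):
        rng = np.random.default_rng(7)
        ts = np.linspace(0.25, 3.0, 12)
        for _ in range(6):
            p = random_valid_params(rng)
            q = p.replace(v=-p.v, z_rel=1.0 - p.z_rel)
            fu = fpt_density(ts, "upper", p)
            fl = fpt_density(ts, "lower", q)
            np.testing.assert_allclose(fu, fl, atol=1e-9)

    def test_conservation_random_sweep(self):
        rng = np.random.default_rng(1)
        for _ in range(8):
            p = random_valid_params(rng)
            total = quad(lambda t: fpt_density(t, "upper", p)
                         + fpt_density(t, "lower", p), 0.0, 60.0, limit=300)[0]
            assert total == pytest.approx(1.0, abs=1e-4)

    def test_scaling_invariance(self, var_params):
        # multiplying (v, a, z_abs, sz, eta, s) by a common factor leaves all
        # observable distributions unchanged
        c = 3.7
        p = var_params
        q = DiffusionParams(v=c * p.v, a=c * p.a, z_rel=p.z_rel, ter=p.ter,
                            eta=c * p.eta, sz=c * p.sz, st=p.st, s=c * p.s)
        ts = np.linspace(0.25, 2.5, 15)
        np.testing.assert_allclose(fpt_density(ts, "upper", p),
                                   fpt_density(ts, "upper", q), rtol=1e-9, atol=1e-12)
        assert choice_probability(p, "upper") == pytest.approx(
            choice_probability(q, "upper"), abs=1e-12)


class TestCdf:
    def test_zero_at_zero_and_conserves(self, var_params):
        assert fpt_cdf(0.0, "upper", var_params) == 0.0
        total = fpt_cdf(50.0, "upper", var_params) + fpt_cdf(50.0, "lower", var_params)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_monotone_and_limits_to_choice_probability(self, var_params):
        ts = np.linspace(0.0, 6.0, 200)
        F = fpt_cdf(ts, "upper", var_params)
        assert np.all(np.diff(F) >= -1e-12)
        assert F[-1] == pytest.approx(choice_probability(var_params, "upper"),
                                      abs=1e-6)

    def test_consistent_with_integrated_density(self, var_params):
        for t in (0.35, 0.6, 1.2):
            F_int = quad(lambda u: fpt_density(u, "upper", var_params),
                         0.0, t, limit=200)[0]
            assert fpt_cdf(t, "upper", var_params) == pytest.approx(F_int, abs=1e-7)

    def test_ks_distance_to_simulation(self, var_params):
        n = 50_000
        sim = simulate_trials(var_params, n, seed=5)
        pu = choice_probability(var_params, "upper")
        rts = np.sort(sim.loc[sim.response == "left", "rt"].to_numpy())
        F = fpt_cdf(rts, "upper", var_params) / pu
        emp_hi = np.arange(1, len(rts) + 1) / len(rts)
        ks = max(np.max(np.abs(F - emp_hi)),
                 np.max(np.abs(F - (emp_hi - 1 / len(rts)))))
        assert ks < 0.01


class TestQuantiles:
    def test_monotone_and_median_symmetry(self, plain_params):
        q = fpt_quantiles("upper", plain_params, QPROBS)
        assert np.all(np.diff(q) > 0)
        sym = plain_params.replace(v=0.0)
        mu = fpt_quantiles("upper", sym, [0.5])[0]
        ml = fpt_quantiles("lower", sym, [0.5])[0]
        assert mu == pytest.approx(ml, rel=1e-6)

    def test_median_speeds_up_with_stronger_drift(self):
        meds = [fpt_quantiles("upper",
                              DiffusionParams(v=v, a=0.12, ter=0.3), [0.5])[0]
                for v in (0.1, 0.3, 0.6)]
        assert np.all(np.diff(meds) < 0)

    def test_agree_with_empirical_quantiles(self, var_params):
        sim = simulate_trials(var_params, 100_000, seed=21)
        rts = sim.loc[sim.response == "left", "rt"].to_numpy()
        emp = np.quantile(rts, QPROBS)
        ana = fpt_quantiles("upper", var_params, QPROBS)
        np.testing.assert_allclose(ana, emp, rtol=0.01)

    def test_degenerate_boundary_raises(self):
        p = DiffusionParams(v=1.5, a=0.25, z_rel=0.7, ter=0.3)  # P(lower) ~ 0
        with pytest.raises(DegenerateCellError):
            fpt_quantiles("lower", p, QPROBS)

    def test_bad_probs_raise(self, plain_params):
        with pytest.raises(ValueError):
            fpt_quantiles("upper", plain_params, [0.5, 0.3])


class TestBinProbabilities:
    def test_model_own_quantiles_give_canonical_proportions(self, var_params):
        eu = fpt_quantiles("upper", var_params, QPROBS)
        el = fpt_quantiles("lower", var_params, QPROBS)
        probs = bin_probabilities(var_params, eu, el)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        pu = choice_probability(var_params, "upper")
        np.testing.assert_allclose(probs[:6] / pu, [.1, .2, .2, .2, .2, .1],
                                   atol=1e-6)
        np.testing.assert_allclose(probs[6:] / (1 - pu), [.1, .2, .2, .2, .2, .1],
                                   atol=1e-5)

    def test_match_simulated_bin_counts(self, var_params):
        eu = fpt_quantiles("upper", var_params, QPROBS)
        el = fpt_quantiles("lower", var_params, QPROBS)
        probs = bin_probabilities(var_params, eu, el)
        n = 200_000
        sim = simulate_trials(var_params, n, seed=9)
        rts = sim.rt.to_numpy()
        left = (sim.response == "left").to_numpy()
        counts = []
        for is_up, edges in ((True, eu), (False, el)):
            r = rts[left == is_up]
            counts.extend(np.diff(np.concatenate(
                [[0], np.searchsorted(np.sort(r), edges, side="right"), [len(r)]])))
        counts = np.array(counts, dtype=float)
        sd = np.sqrt(n * probs * (1 - probs))
        assert np.all(np.abs(counts - n * probs) < 3.5 * sd)

    def test_unordered_edges_raise(self, var_params):
        with pytest.raises(ValueError):
            bin_probabilities(var_params, [0.5, 0.4], [0.4, 0.5])


class TestSimulator:
    def test_seeded_repeatability(self, var_params):
        a = simulate_trials(var_params, 500, seed=42)
        b = simulate_trials(var_params, 500, seed=42)
        assert a.equals(b)
        c = simulate_trials(var_params, 500, seed=43)
        assert not a.rt.equals(c.rt)

    def test_symmetric_params_split_evenly(self):
        p = DiffusionParams(v=0.0, a=0.12, z_rel=0.5, ter=0.3, eta=0.05)
        n = 50_000
        sim = simulate_trials(p, n, seed=3)
        frac = (sim.response == "left").mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_rt_exceeds_minimum_nondecision_time(self, var_params):
        sim = simulate_trials(var_params, 2000, seed=8)
        assert (sim.rt > var_params.ter - var_params.st / 2).all()

    def test_step_size_convergence_of_mean_rt(self, var_params):
        m1 = simulate_trials(var_params, 30_000, seed=14, dt=2e-4).rt.mean()
        m2 = simulate_trials(var_params, 30_000, seed=15, dt=1e-4).rt.mean()
        assert abs(m1 / m2 - 1) < 0.005

    def test_nonterminated_paths_flagged_not_dropped(self):
        p = DiffusionParams(v=0.0, a=0.3, z_rel=0.5, ter=0.1)
        sim = simulate_trials(p, 300, seed=2, t_max=0.5)
        assert len(sim) == 300
        assert (~sim.terminated).any()
        assert sim.loc[~sim.terminated, "response"].isna().all()

    def test_seed_required(self, plain_params):
        with pytest.raises(ValueError):
            simulate_trials(plain_params, 10, seed=None)
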