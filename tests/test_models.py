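"""Model specs, BIC arithmetic, fitting machinery and comparison logic.

Fits here use small three-disparity datasets to keep the optimizer quick;
full seven-disparity, study-scale recovery runs live in the acceptance
suite.
"""

import math

import numpy as np
import pandas as pd
import pytest

from socddm import DiffusionParams, simulate_trials
from socddm.models import (FitOptions, bic, build_model, compare_models,
                           fit_all_models, fit_model, parameter_cis,
                           split_by_conformity, fit_diagnostics)

LEVELS3 = (-1.0, 0.0, 1.0)


def make_trials(n_per_cell=120, k_v=0.25, dv=0.0, dz=0.0, seed=0,
                levels=LEVELS3):
    """Trial table from a known generator: v = k_v d + s_adv dv,
    z = 0.5 + s_adv dz."""
    rows = []
    sub = 0
    for d in levels:
        for adv, s_adv in (("left", 1), ("right", -1)):
            p = DiffusionParams(v=k_v * d + s_adv * dv, a=0.14,
                                z_rel=0.5 + s_adv * dz, ter=0.35,
                                eta=0.08, sz=0.02, st=0.2)
            sim = simulate_trials(p, n_per_cell, seed=seed * 1000 + sub)
            sub += 1
            for r in sim.itertuples():
                rows.append({"participant": "pool", "disparity_norm": d,
                             "advice": adv, "response": r.response,
                             "rt_s": r.rt, "terminated": r.terminated,
                             "conformed": r.response == adv})
    return pd.DataFrame(rows)


class TestModelSpecs:
    def test_free_parameter_counts_with_seven_disparities(self):
        levels7 = np.linspace(-1, 1, 7)
        ks = [build_model(m, levels7).k for m in (1, 2, 3, 4, 5)]
        assert ks == [13, 14, 20, 21, 26]

    def test_advice_key_placement(self):
        levels7 = np.linspace(-1, 1, 7)
        m1 = build_model(1, levels7).tying
        assert all("advice" not in keys for keys in m1.values())
        m2 = build_model(2, levels7).tying
        assert m2["z"] == {"advice"}
        assert all("advice" not in m2[p] for p in ("v", "a", "ter", "eta", "sz", "st"))
        m3 = build_model(3, levels7).tying
        assert "advice" in m3["v"] and m3["z"] == set()
        m5 = build_model(5, levels7).tying
        assert all("advice" in keys for keys in m5.values())

    def test_unknown_model_id(self):
        with pytest.raises(ValueError):
            build_model(6, LEVELS3)


class TestBic:
    def test_direct_arithmetic(self):
        assert bic(0.0, 0, 1000) == 0.0
        assert bic(-5000.0, 13, 3570) == pytest.approx(13 * math.log(3570) + 10000)

    def test_extra_parameter_must_earn_half_log_n(self):
        n, ll, k = 2000, -800.0, 10
        gain = math.log(n) / 2
        assert bic(ll + gain * 0.9, k + 1, n) > bic(ll, k, n)
        assert bic(ll + gain * 1.1, k + 1, n) < bic(ll, k, n)


@pytest.fixture(scope="module")
def m4_trials():
    # 1500 trials over three disparities: enough to separate the drift and
    # starting-point advice effects, while keeping optimizer runtime low
    return make_trials(n_per_cell=250, dv=0.05, dz=0.04, seed=3)


@pytest.fixture(scope="module")
def chained_fits(m4_trials):
    return fit_all_models(m4_trials, model_ids=(1, 2, 3, 4),
                          options=FitOptions(n_restarts=1, seed=0, xtol=1e-3))


class TestFitting:
    def test_loglik_monotone_along_nesting_chains(self, chained_fits):
        f = chained_fits
        tol = 1e-3
        assert f[2].loglik >= f[1].loglik - tol
        assert f[3].loglik >= f[1].loglik - tol
        assert f[4].loglik >= f[2].loglik - tol
        assert f[4].loglik >= f[3].loglik - tol

    def test_fit_beats_generating_parameters(self, m4_trials, chained_fits):
        # optimizer sanity: the fitted likelihood is no worse than the truth
        from socddm.models import _Packing, _prepare_cells, _make_objective
        spec = chained_fits[4].spec
        opts = chained_fits[4].options
        packing = _Packing(spec, opts.bounds, opts.fixed)
        cells, _ = _prepare_cells(m4_trials, spec, opts)
        nll = _make_objective(cells, packing, opts)
        truth = np.empty(packing.size)
        for d_idx, d in enumerate(spec.disparity_levels):
            for a_idx, s_adv in ((0, 1), (1, -1)):
                truth[packing.v_index(d_idx, a_idx)] = 0.25 * d + s_adv * 0.05
        for a_idx, s_adv in ((0, 1), (1, -1)):
            truth[packing.z_index(a_idx)] = 0.5 + s_adv * 0.04
        for p, val in (("a", 0.14), ("ter", 0.35), ("eta", 0.08),
                       ("sz", 0.02), ("st", 0.2)):
            truth[packing.nuis_index(p, 0, 0)] = val
            truth[packing.nuis_index(p, 0, 1)] = val
        assert chained_fits[4].loglik >= -nll(truth) - 1e-3

    def test_estimates_recover_generator_roughly(self, chained_fits):
        est = chained_fits[4].estimates
        vL = est[est.advice == "left"].sort_values("disparity_norm").v.to_numpy()
        vR = est[est.advice == "right"].sort_values("disparity_norm").v.to_numpy()
        assert np.mean(vL - vR) == pytest.approx(0.10, abs=0.08)
        zL = est[est.advice == "left"].z_rel.iloc[0]
        zR = est[est.advice == "right"].z_rel.iloc[0]
        assert zL - zR == pytest.approx(0.08, abs=0.06)

    def test_estimates_invariant_to_trial_order(self, m4_trials):
        opts = FitOptions(n_restarts=1, seed=0, xtol=1e-3, maxfev=4000)
        spec = build_model(2, LEVELS3)
        f1 = fit_model(m4_trials, spec, opts)
        shuffled = m4_trials.sample(frac=1.0, random_state=11).reset_index(drop=True)
        f2 = fit_model(shuffled, spec, opts)
        np.testing.assert_allclose(f1.theta, f2.theta, atol=1e-12)

    def test_empty_cell_raises(self, m4_trials):
        bad = m4_trials[~((m4_trials.disparity_norm == 0.0)
                          & (m4_trials.advice == "left"))]
        with pytest.raises(ValueError, match="empty condition cell"):
            fit_model(bad, build_model(1, LEVELS3), FitOptions(n_restarts=1))

    def test_sparse_boundary_collapses_bins_with_warning(self):
        # strong drift: very few lower-boundary responses per cell
        t = make_trials(n_per_cell=60, k_v=0.9, seed=5, levels=(-1.0, 1.0))
        from socddm.models import _prepare_cells
        cells, warns = _prepare_cells(t, build_model(1, (-1.0, 1.0)), FitOptions())
        assert len(warns) > 0
        assert any(len(c.counts) < 12 for c in cells)


class TestComparison:
    def test_ranking_and_tie_detection(self, chained_fits):
        out = compare_models(chained_fits)
        assert set(out["table"].model) == {1, 2, 3, 4}
        assert out["selected"] == out["table"].model.iloc[0]
        dup = compare_models([chained_fits[4], chained_fits[4]])
        assert dup["selected"] is None
        assert dup["tied"] == [4, 4]

    def test_mismatched_trial_sets_rejected(self, chained_fits):
        other = make_trials(n_per_cell=40, seed=9)
        f_other = fit_model(other, build_model(1, LEVELS3),
                            FitOptions(n_restarts=1, maxfev=1500))
        with pytest.raises(ValueError):
            compare_models([chained_fits[1], f_other])

    def test_advice_sensitive_models_preferred(self, chained_fits):
        # the generator carries a dominant drift bias plus a starting-point
        # bias: the no-advice model must lose and the drift-only model must
        # beat the starting-point-only model (full model-recovery runs at
        # study scale live in the acceptance suite)
        out = compare_models(chained_fits)
        assert out["selected"] in (3, 4)
        assert chained_fits[3].bic < chained_fits[2].bic < chained_fits[1].bic


class TestConformitySplit:
    def test_partition_covers_all_trials(self, m4_trials):
        t = split_by_conformity(m4_trials)
        done = t[t.terminated]
        assert done.cell.notna().all()
        assert set(t.cell.dropna().unique()) <= {
            "left_conform", "left_nonconform", "right_conform", "right_nonconform"}
        assert t.attrs["caveat"]

    def test_full_conformity_flags_empty_cells(self):
        t = pd.DataFrame({"advice": ["left", "right"], "response": ["left", "right"],
                          "conformed": [True, True]})
        out = split_by_conformity(t)
        assert out.attrs["empty_cells"] == ["left_nonconform", "right_nonconform"]


class TestParameterCis:
    def test_seeded_reproducibility_and_flags(self, m4_trials, chained_fits):
        spec = chained_fits[4].spec
        opts = chained_fits[4].options
        c1 = parameter_cis(m4_trials, spec, n_boot=60, seed=4, options=opts,
                           point_fit=chained_fits[4])
        c2 = parameter_cis(m4_trials, spec, n_boot=60, seed=4, options=opts,
                           point_fit=chained_fits[4])
        pd.testing.assert_frame_equal(c1, c2)
        # the dominant drift bias must be flagged at this n
        assert bool(c1.loc[c1.quantity == "dv_mean", "significant"].iloc[0])


class TestDiagnostics:
    def test_overlays_internally_consistent(self, m4_trials, chained_fits):
        out = fit_diagnostics(chained_fits[4], m4_trials, n_grid=30)
        choice = out["choice"]
        assert len(choice) == 6
        np.testing.assert_allclose(choice.p_left_pred + 0.0, choice.p_left_pred)
        assert ((choice.p_left_pred >= 0) & (choice.p_left_pred <= 1)).all()
        # predicted and observed choice fractions agree on fitted data
        assert np.max(np.abs(choice.p_left_pred - choice.p_left_obs)) < 0.1
        cdfs = out["rt_cdf"]
        g = cdfs.groupby(["disparity_norm", "advice", "response"])
        assert (g.cdf_pred.apply(lambda s: (np.diff(s) >= -1e-9).all())).all()
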