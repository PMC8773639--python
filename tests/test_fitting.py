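"""Likelihood, genetic algorithm, condition fitting and profiles."""

import numpy as np
import pandas as pd
import pytest

from psmsr import (
    GAConfig,
    GrowthDataset,
    PhenotypeParams,
    SeedingDesign,
    free_parameter_names,
    ga_optimize,
    neg_log_likelihood,
    profile_likelihood,
)
from psmsr.fitting import condition_lock, fit_condition, simulate_series_batch
from psmsr.params import PRESETS
from psmsr.synth import ConditionSpec, NoiseModel, StudyDesign, generate_dataset


def _monotypic_dataset(counts, times_h, condition="mono", seeding=None):
    frame = pd.DataFrame(
        {
            "condition": condition,
            "ratio": "1:0",
            "time_h": times_h,
            "channel": "red",
            "count": counts,
            "replicate": 1,
        }
    )
    meta = {condition: {}}
    if seeding is not None:
        meta[condition]["seeding"] = {("1:0", 1): seeding}
    return GrowthDataset(frame, meta)


class TestFreeParameters:
    def test_drug_free_model_has_nine(self):
        assert len(free_parameter_names(False)) == 9

    def test_drug_model_has_sixteen(self):
        assert len(free_parameter_names(True)) == 16

    def test_drug_condition_mask_pins_cooperation_off(self):
        lock = condition_lock({"drug": True})
        assert lock == {"Kb": 0.0, "Kstrd": 0.0, "a": 0.0}
        assert condition_lock({"drug": False}) == {}


class TestNegLogLikelihood:
    def test_hand_computed_three_point_series(self):
        """Fixed sigma = 1 on a 3-point flat series: NLL is the hand-summed
        Gaussian log-density of the log-count residuals."""
        # all rates zero -> model count stays at the 100-cell seeding
        p = PhenotypeParams(K0=0, Kb=0, KGs0=0, KGt0=0, Kstr=0, Kstrd=0, a=0, b=0, g=0)
        obs = np.array([100.0, 110.0, 90.0])
        data = _monotypic_dataset(obs, [0.0, 24.0, 48.0], seeding=(100.0, 0.0))
        got = neg_log_likelihood(p, data, sigma=1.0)
        resid = np.log(obs) - np.log(100.0)
        expected = 3 * 0.5 * np.log(2 * np.pi) + 0.5 * np.sum(resid**2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_truth_minimises_on_noise_free_data(self, het_params):
        design = StudyDesign(
            conditions=(ConditionSpec("het", het_params),),
            panel=SeedingDesign(ratios=((1, 1), (4, 1)), sample_every_h=6.0),
            replicates=1,
        )
        data = generate_dataset(design, NoiseModel("none", 0.0, 0))
        base = neg_log_likelihood(het_params, data)
        from dataclasses import replace

        for name in ("K0", "Kb", "KGs0", "KGt0", "Kstr", "Kstrd", "a", "b", "g"):
            bumped = replace(het_params, **{name: getattr(het_params, name) * 1.05 + 1e-4})
            assert neg_log_likelihood(bumped, data) >= base - 1e-6, name

    def test_extinct_simulation_gets_finite_penalty(self):
        # absurd stress coupling drives counts to (clipped) zero: penalty,
        # never NaN
        theta = np.array([0.1, 5.0, 0.0, 0.0, 1e-3, 0.0, 0.1, 0.1, 0.1])
        data = _monotypic_dataset([100.0, 120.0, 140.0], [0.0, 24.0, 48.0])
        val = neg_log_likelihood(theta, data)
        assert np.isfinite(val)

    def test_deterministic(self, tiny_dataset, het_params):
        a = neg_log_likelihood(het_params, tiny_dataset)
        b = neg_log_likelihood(het_params, tiny_dataset)
        assert a == b


class TestBatchSimulator:
    def test_matches_adaptive_integrator(self, het_params, het_panel):
        """The vectorised fixed-step RK4 engine agrees with the adaptive
        reference to a tolerance far below the noise floor."""
        theta = np.array([getattr(het_params, n) for n in free_parameter_names(False)])
        ref = het_panel[0]
        got = simulate_series_batch(theta, ref.times, 2500.0, 2500.0)[0]
        rel = np.abs(got[:, :4] - ref.states[:, :4]) / np.maximum(ref.states[:, :4], 1.0)
        assert rel.max() < 1e-4

    def test_batch_rows_independent(self, het_params):
        names = free_parameter_names(False)
        t1 = np.array([getattr(het_params, n) for n in names])
        t2 = t1 * 1.1
        times = np.linspace(0, 6, 25)
        both = simulate_series_batch(np.vstack([t1, t2]), times, 2500.0, 2500.0)
        solo = simulate_series_batch(t2, times, 2500.0, 2500.0)[0]
        np.testing.assert_array_equal(both[1], solo)


class TestGA:
    def test_sphere_benchmark(self):
        """Standard 9-D sphere on [-5, 5]: the default-sized GA gets within
        1e-2 of the global optimum at zero."""
        bounds = [(-5.0, 5.0)] * 9
        cfg = GAConfig(seed=42)
        res = ga_optimize(lambda P: np.sum(P**2, axis=1), bounds, cfg, vectorized=True)
        assert res.fun < 1e-2

    def test_one_dimensional_quadratic(self):
        cfg = GAConfig(pop_size=40, generations=60, seed=3)
        res = ga_optimize(lambda x: (x[0] - 1.3) ** 2, [(-5.0, 5.0)], cfg)
        assert res.x[0] == pytest.approx(1.3, abs=0.05)

    def test_determinism_under_fixed_seed(self):
        bounds = [(-5.0, 5.0)] * 4
        cfg = GAConfig(pop_size=30, generations=25, seed=7)
        f = lambda P: np.sum((P - 0.5) ** 2, axis=1)
        r1 = ga_optimize(f, bounds, cfg, vectorized=True)
        r2 = ga_optimize(f, bounds, cfg, vectorized=True)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_trace_is_monotone_nonincreasing(self):
        cfg = GAConfig(pop_size=30, generations=40, seed=1)
        res = ga_optimize(
            lambda P: np.sum(P**2, axis=1), [(-3.0, 3.0)] * 5, cfg, vectorized=True
        )
        assert np.all(np.diff(res.trace) <= 0)
        assert res.fun <= res.trace[0]

    def test_init_injection(self):
        cfg = GAConfig(pop_size=20, generations=5, seed=0)
        res = ga_optimize(
            lambda P: np.sum(P**2, axis=1), [(-5.0, 5.0)] * 3, cfg,
            vectorized=True, init=np.zeros(3),
        )
        assert res.fun == pytest.approx(0.0, abs=1e-12)


class TestFitCondition:
    def test_drug_mask_applied(self, tiny_dataset):
        data = tiny_dataset
        data.conditions["heterotypic-12h"]["drug"] = False
        res = fit_condition(data, "heterotypic-12h", GAConfig(pop_size=12, generations=3, elitism=2, seed=0), polish=False)
        assert len(res.names) == 9 and res.fixed == {}

    def test_fixture_refits_near_truth(self, tiny_dataset):
        """The committed tiny fixture refits to its own generating
        parameters: the two baseline growth rates are the well-identified
        ones and land within 10%."""
        res = fit_condition(
            tiny_dataset, "heterotypic-12h",
            GAConfig(pop_size=48, generations=40, elitism=4, seed=2),
        )
        truth = PRESETS["heterotypic"]
        est = res.as_dict()
        assert est["KGs0"] == pytest.approx(truth.KGs0, rel=0.10)
        assert est["KGt0"] == pytest.approx(truth.KGt0, rel=0.10)

    def test_condition_fit_determinism(self, tiny_dataset):
        cfg = GAConfig(pop_size=16, generations=5, elitism=2, seed=9)
        r1 = fit_condition(tiny_dataset, "heterotypic-12h", cfg)
        r2 = fit_condition(tiny_dataset, "heterotypic-12h", cfg)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun


class TestProfileLikelihood:
    def test_gaussian_case_matches_analytic_interval(self):
        """With a single free parameter the profile is the raw NLL slice;
        for (near-)quadratic NLL the chi-square cutoff reproduces the
        analytic +/-1.96 SE interval."""
        p = PRESETS["heterotypic"]
        design = StudyDesign(
            conditions=(ConditionSpec("het", p),),
            panel=SeedingDesign(ratios=((1, 1),), sample_every_h=12.0),
            replicates=1,
        )
        data = generate_dataset(design, NoiseModel(sigma=0.05, seed=3))
        fixed = {n: getattr(p, n) for n in free_parameter_names(False) if n != "KGs0"}
        res = fit_condition(
            data, "het", GAConfig(pop_size=30, generations=30, seed=0), fixed=fixed
        )
        assert res.names == ("KGs0",)
        est = res.x[0]
        grid = np.linspace(est - 0.03, est + 0.03, 41)
        prof = profile_likelihood(data, res, "KGs0", grid)
        # curvature -> SE -> analytic CI
        h = grid[1] - grid[0]
        i = np.argmin(np.abs(grid - est))
        i = int(np.clip(i, 1, len(grid) - 2))
        curv = (prof.nll[i + 1] - 2 * prof.nll[i] + prof.nll[i - 1]) / h**2
        se = 1.0 / np.sqrt(curv)
        assert prof.ci[0] == pytest.approx(est - 1.96 * se, abs=0.25 * se)
        assert prof.ci[1] == pytest.approx(est + 1.96 * se, abs=0.25 * se)
        assert prof.ci[0] <= est <= prof.ci[1]
        assert not prof.flat

    def test_structurally_flat_direction_flagged(self):
        """When both phenotypes grow at the same rate and only one channel
        is observed, the switching equilibrium K0 drops out of the
        observable dynamics; its profile is flat and flagged."""
        p = PhenotypeParams(K0=0.05, Kb=3.0, KGs0=0.5, KGt0=0.5, Kstr=0, Kstrd=0, a=0, b=0, g=0)
        times = np.arange(0.0, 145.0, 12.0)
        counts = 1000.0 * np.exp(0.5 * times / 24.0)
        data = _monotypic_dataset(counts, times, seeding=(1000.0, 0.0))
        fixed = {n: getattr(p, n) for n in free_parameter_names(False) if n not in ("K0",)}
        res = fit_condition(
            data, "mono", GAConfig(pop_size=16, generations=10, seed=0), fixed=fixed
        )
        grid = np.linspace(0.0, 0.1, 11)
        prof = profile_likelihood(data, res, "K0", grid)
        assert prof.flat
        assert prof.ci == (0.0, 0.1)
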