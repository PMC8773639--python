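"""Rate laws, kill sigmoid and ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmsr import LineageState, PhenotypeParams, sigmoid_kill, stress_coupled_rates
from psmsr.model import death_rates, rhs_vector
from psmsr.params import DRUG_PRESETS, PRESETS, DrugParams, params_from_config, params_to_config


class TestStressCoupledRates:
    def test_zero_stress_returns_baselines(self, het_params):
        r = stress_coupled_rates(het_params, 0.0)
        assert r.KGS == pytest.approx(0.713)  # published heterotypic value
        assert r.KGT == pytest.approx(het_params.KGt0)
        assert r.K == pytest.approx(het_params.K0)
        assert r.Ka == pytest.approx(het_params.K0 * het_params.Kb)

    def test_linear_coupling_at_stress_ten(self, het_params):
        # arithmetic on the published values: K = 0.049 + 0.018*10
        r = stress_coupled_rates(het_params, 10.0)
        assert r.K == pytest.approx(0.229)
        assert r.Ka == pytest.approx(0.81753)
        assert r.KGS == pytest.approx(0.713 - 0.046 * 10.0)

    def test_negative_stress_rejected(self, het_params):
        with pytest.raises(ValueError):
            stress_coupled_rates(het_params, -0.1)

    def test_unknown_coupling_rejected(self, het_params):
        with pytest.raises(ValueError):
            stress_coupled_rates(het_params, 1.0, coupling="cubic")

    @pytest.mark.parametrize("coupling", ["linear", "sigmoidal"])
    def test_monotone_contract(self, het_params, coupling):
        """Growth rates never increase and the switch equilibrium never
        decreases with stress, in both coupling modes."""
        grid = np.linspace(0.0, 50.0, 101)
        rates = [stress_coupled_rates(het_params, c, coupling) for c in grid]
        kgs = np.array([r.KGS for r in rates])
        kgt = np.array([r.KGT for r in rates])
        kk = np.array([r.K for r in rates])
        ka = np.array([r.Ka for r in rates])
        assert np.all(np.diff(kgs) <= 1e-12)
        assert np.all(np.diff(kgt) <= 1e-12)
        assert np.all(np.diff(kk) >= -1e-12)
        assert np.all(np.diff(ka) >= -1e-12)

    def test_sigmoidal_matches_linear_value_and_slope_at_zero(self, het_params):
        eps = 1e-6
        lin0 = stress_coupled_rates(het_params, 0.0, "linear")
        sig0 = stress_coupled_rates(het_params, 0.0, "sigmoidal")
        assert sig0.KGS == pytest.approx(lin0.KGS)
        assert sig0.K == pytest.approx(lin0.K)
        lin1 = stress_coupled_rates(het_params, eps, "linear")
        sig1 = stress_coupled_rates(het_params, eps, "sigmoidal")
        assert (sig1.KGS - sig0.KGS) / eps == pytest.approx((lin1.KGS - lin0.KGS) / eps, rel=1e-4)
        assert (sig1.K - sig0.K) / eps == pytest.approx((lin1.K - lin0.K) / eps, rel=1e-4)

    def test_sigmoidal_saturates(self, het_params):
        r = stress_coupled_rates(het_params, 1e6, "sigmoidal")
        # excursion bounded by one baseline unit (saturation=1)
        assert r.KGS == pytest.approx(0.0, abs=1e-9)
        assert r.K == pytest.approx(2 * het_params.K0, rel=1e-9)


class TestSigmoidKill:
    @given(
        auc5=st.floats(1.0, 499.0),
        width=st.floats(1.0, 1400.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_anchors(self, auc5, width):
        """The kill curve passes through 5% at AUC5 and 95% at AUC95 for
        any admissible parameter pair."""
        auc95 = auc5 + width
        assert sigmoid_kill(auc5, auc5, auc95) == pytest.approx(0.05, abs=1e-12)
        assert sigmoid_kill(auc95, auc5, auc95) == pytest.approx(0.95, abs=1e-12)

    def test_midpoint_and_limits(self):
        assert sigmoid_kill(0.5 * (239 + 1153), 239, 1153) == pytest.approx(0.5)
        assert sigmoid_kill(1e9, 239, 1153) == pytest.approx(1.0)
        assert sigmoid_kill(-1e9, 239, 1153) == pytest.approx(0.0)

    def test_strictly_increasing(self):
        auc = np.linspace(-500, 3000, 400)
        vals = sigmoid_kill(auc, 239.0, 1153.0)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_kill(100.0, 500.0, 500.0)

    def test_no_kill_before_any_exposure(self, drug_params):
        assert death_rates(drug_params, 0.0) == (0.0, 0.0)
        dS, dT = death_rates(drug_params, drug_params.AUC5_s)
        assert dS == pytest.approx(0.05 * drug_params.SCALE_s)
        assert dT > 0


class TestRHS:
    def test_switching_conserves_total(self, rng):
        """With growth, stress-coupling of growth and drug all off, the
        switching terms cancel pairwise and d(total)/dt = 0."""
        p = PhenotypeParams(K0=0.05, Kb=3.0, KGs0=0, KGt0=0, Kstr=1e-4, Kstrd=1e-3, a=0, b=0, g=0.02)
        for _ in range(10):
            y = np.concatenate([rng.uniform(0, 1e4, size=4), rng.uniform(0, 5, size=1), [0.0]])
            dy = rhs_vector(y, p)
            assert dy[:4].sum() == pytest.approx(0.0, abs=1e-9)

    def test_stress_generation_rate(self, het_params):
        # Kstr*S - Kstrd*T with S=5000, T=0: 7.14e-4 * 5000 = 3.57
        y = np.array([5000.0, 0, 0, 0, 1.0, 0])
        dy = rhs_vector(y, het_params)
        assert dy[4] == pytest.approx(3.57)

    def test_single_term_switch_flux(self):
        # only Gt populated, growth off, K0=g=0 so Ka=0: flux into Gs is Kb*Gt
        p = PhenotypeParams(K0=0.0, Kb=3.57, KGs0=0, KGt0=0, Kstr=0, Kstrd=0, a=0, b=0, g=0)
        y = np.array([0, 0, 0, 1000.0, 0, 0])
        dy = rhs_vector(y, p)
        assert dy[2] == pytest.approx(3570.0)
        assert dy[3] == pytest.approx(-3570.0)

    @given(
        rs=st.floats(0, 1e5), rt=st.floats(0, 1e5),
        gs=st.floats(0, 1e5), gt=st.floats(0, 1e5),
        c=st.floats(0, 20), auc=st.floats(0, 2000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_sums_reproduce_phenotype_equations(self, rs, rt, gs, gt, c, auc):
        """Summing the lineage-resolved equations over labels gives exactly
        the two-variable phenotype model (independent re-implementation)."""
        p = PRESETS["heterotypic-cisplatin"]
        d = DRUG_PRESETS["heterotypic-cisplatin"]
        y = np.array([rs, rt, gs, gt, c, auc])
        dy = rhs_vector(y, p, d, conc=5.0)
        # two-variable oracle, straight from the printed equations
        S, T = rs + gs, rt + gt
        KGS = p.KGs0 - p.a * c
        KGT = p.KGt0 - p.b * c
        Ka = (p.K0 + p.g * c) * p.Kb
        dthS, dthT = death_rates(d, auc)
        dS = -Ka * S + p.Kb * T + KGS * S - dthS * S
        dT = +Ka * S - p.Kb * T + KGT * T - dthT * T
        assert dy[0] + dy[2] == pytest.approx(dS, rel=1e-12, abs=1e-7)
        assert dy[1] + dy[3] == pytest.approx(dT, rel=1e-12, abs=1e-7)

    def test_auc_accumulation_rate(self, het_params, drug_params):
        y = np.zeros(6)
        y[0] = 100.0
        dy = rhs_vector(y, het_params, drug_params, conc=5.0)
        assert dy[5] == pytest.approx(24.0 * 5.0)  # uM*h per day
        dy0 = rhs_vector(y, het_params, drug_params, conc=0.0)
        assert dy0[5] == 0.0

    def test_sdrug_optional_stress_source(self, het_params, drug_params):
        y = np.array([1000.0, 0, 0, 0, 0, 0])
        base = rhs_vector(y, het_params, drug_params, conc=5.0)
        with_src = rhs_vector(y, het_params, drug_params, conc=5.0, sdrug_stress=True)
        assert with_src[4] - base[4] == pytest.approx(drug_params.Sdrug)

    def test_stress_removal_saturates_at_zero(self):
        p = PhenotypeParams(K0=0.05, Kb=3.0, KGs0=0.5, KGt0=0.5, Kstr=0.0, Kstrd=1e-2, a=0, b=0, g=0)
        y = np.array([0, 0, 0, 5000.0, 0.0, 0])  # tolerant only, no stress
        assert rhs_vector(y, p)[4] == 0.0
        y[4] = 2.0  # with stress present, removal proceeds
        assert rhs_vector(y, p)[4] == pytest.approx(-50.0)


class TestLineageState:
    def test_bookkeeping_identity(self):
        s = LineageState(Rs=10, Rt=3, Gs=7, Gt=20, Cstr=1.0)
        assert s.R + s.G == s.S + s.T == s.total

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LineageState(Rs=-1.0)

    def test_seeding_is_pure_phenotype(self):
        s = LineageState.from_seeding(red=100, green=50)
        assert (s.Rs, s.Rt, s.Gs, s.Gt) == (100, 0, 0, 50)


class TestParamsConfig:
    def test_roundtrip_with_drug_block(self, het_params):
        d = DRUG_PRESETS["heterotypic-cisplatin"]
        cfg = params_to_config(het_params, d, coupling="sigmoidal", auc_mode="decay")
        p2, d2, coupling, auc_mode = params_from_config(cfg)
        assert p2 == het_params
        assert d2 == d
        assert (coupling, auc_mode) == ("sigmoidal", "decay")
        # keys follow the published table's column names
        assert {"K", "Kb", "KGs0", "Kstr", "Kstrd", "AUCs5", "SCALEt"} <= set(cfg)

    def test_missing_key_rejected(self):
        with pytest.raises(KeyError):
            params_from_config({"K": 0.05})

    def test_invalid_auc_order_rejected(self):
        with pytest.raises(ValueError):
            DrugParams(Sdrug=1, AUC5_s=500, AUC95_s=400, SCALE_s=1,
                       AUC5_t=100, AUC95_t=200, SCALE_t=1)

    def test_drug_locking(self, het_params):
        locked = het_params.locked_for_drug()
        assert locked.Kb == 0.0 and locked.Kstrd == 0.0 and locked.a == 0.0
        assert locked.KGs0 == het_params.KGs0
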