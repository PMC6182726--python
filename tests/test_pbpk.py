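"""PBPK engine: structure, dosing arithmetic, oracles and conservation."""

import numpy as np
import pytest

from cardiotwin import DoseEvent, PbpkModel
from cardiotwin.params import AbsorptionParams, CompoundParams, PhysiologySpec
from cardiotwin.pbpk import (ConfigurationError, apply_oral_dose, build_model,
                             mass_balance, simulate, simulate_to_steady_state)

AB_MEAN = dict(ka=0.24, t_lag=1.33, F=0.459, fa_Fg=0.832)


class TestBuildModel:
    def test_layout_has_depots_tissues_and_metabolite_leg(self, model):
        sys_ = model.system()
        names = sys_.names
        assert names[:2] == ("depot_parent", "depot_met")
        assert "heart" in names and "liver" in names and "venous" in names
        assert "met_central" in names and "met_rest" in names

    def test_missing_heart_is_a_configuration_error(self, model):
        phys = model.physiology.model_copy(update={
            "tissues": [t for t in model.physiology.tissues if t.name != "heart"]})
        with pytest.raises(ConfigurationError, match="heart"):
            build_model(phys, model.parent, model.metabolite, model.absorption)

    def test_zero_state_is_an_equilibrium(self, model):
        sys_ = model.system()
        assert np.allclose(sys_.rhs(0.0, np.zeros(sys_.n_states)), 0.0)

    def test_collapse_rhs_matches_handwritten_two_state_system(self, collapse_model):
        """With a lumped single compartment the parent dynamics reduce to a
        hand-written depot + central pair; compare at random states."""
        sys_ = collapse_model.system()
        idx = sys_.index
        ka, ke = 0.8, 10.0 / 50.0
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = np.zeros(sys_.n_states)
            depot, central = rng.uniform(0, 100, 2)
            x[idx["depot_parent"]], x[idx["central"]] = depot, central
            dx = sys_.rhs(0.0, x)
            assert dx[idx["depot_parent"]] == pytest.approx(-ka * depot, rel=1e-12)
            assert dx[idx["central"]] == pytest.approx(ka * depot - ke * central, rel=1e-12)


class TestApplyOralDose:
    def test_depot_increments_match_hand_arithmetic(self, model):
        ab = AbsorptionParams(**AB_MEAN)
        state = np.zeros(model.system().n_states)
        out = apply_oral_dose(state, DoseEvent(time=0, dose_po=75.0), ab,
                              model.parent, model.metabolite, model.system().index)
        assert out[0] == pytest.approx(0.459 * 75, abs=1e-12)  # 34.425 mg
        expected_nt = (263.384 / 277.4) * (1 - 0.459 / 0.832) * 0.832 * 75
        assert out[1] == pytest.approx(expected_nt, rel=1e-12)
        assert out[1] == pytest.approx(26.56, abs=0.005)

    def test_no_hepatic_loss_means_no_first_pass_metabolite(self, model):
        ab = AbsorptionParams(ka=0.24, t_lag=1.33, F=0.5, fa_Fg=0.5)  # Fh = 1
        out = apply_oral_dose(np.zeros(4), DoseEvent(time=0, dose_po=75.0), ab,
                              model.parent, model.metabolite)
        assert out[1] == pytest.approx(0.0, abs=1e-15)

    def test_dosing_is_additive(self, model):
        ab = AbsorptionParams(**AB_MEAN)
        ev = DoseEvent(time=0, dose_po=40.0)
        once = apply_oral_dose(np.zeros(4), ev, ab, model.parent, model.metabolite)
        twice = apply_oral_dose(once, ev, ab, model.parent, model.metabolite)
        assert np.allclose(twice, 2 * once)


class TestSimulate:
    def test_single_dose_has_one_maximum_after_lag(self, model, single_dose_75):
        t = np.linspace(0.1, 48, 240)
        s = model.simulate(single_dose_75, t, method="expm")
        at = s["AT", "plasma"]
        assert np.all(at[t < 1.33] == 0.0)
        k = int(np.argmax(at))
        assert t[k] > 1.33
        assert np.all(np.diff(at[:k]) >= 0) and np.all(np.diff(at[k:]) <= 0)

    def test_empty_regimen_rejected(self, model):
        with pytest.raises(ValueError, match="regimen"):
            model.simulate([], np.linspace(0.1, 10, 10))

    def test_bateman_closed_form_oracle(self, collapse_model):
        """Collapse configuration against the analytic first-order
        absorption/elimination solution."""
        t = np.linspace(0.05, 48, 300)
        s = collapse_model.simulate([DoseEvent(time=0.0, dose_po=100.0)], t,
                                    method="lsoda")
        ka, ke, V, FD = 0.8, 0.2, 50.0, 50.0
        bateman = FD * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000
        dev = np.abs(s["AT", "plasma"] - bateman) / bateman.max()
        assert dev.max() < 1e-4

    def test_expm_and_lsoda_agree(self, model, single_dose_75):
        t = np.linspace(0.1, 48, 60)
        a = model.simulate(single_dose_75, t, method="lsoda")["AT", "plasma"]
        b = model.simulate(single_dose_75, t, method="expm")["AT", "plasma"]
        assert np.max(np.abs(a - b)) / a.max() < 1e-6

    def test_dose_proportionality(self, model):
        t = np.linspace(0.1, 72, 200)
        lo = model.simulate([DoseEvent(time=0, dose_po=25.0)], t, method="expm")
        hi = model.simulate([DoseEvent(time=0, dose_po=100.0)], t, method="expm")
        auc_lo = np.trapezoid(lo["AT", "plasma"], t)
        auc_hi = np.trapezoid(hi["AT", "plasma"], t)
        assert auc_hi / auc_lo == pytest.approx(4.0, rel=5e-3)

    def test_superposition_of_shifted_single_doses(self, model):
        """Linearity: the multi-dose profile equals the sum of the three
        individually simulated single-dose profiles on the same grid."""
        t = np.linspace(0.1, 96, 400)
        multi = model.simulate([DoseEvent(time=float(24 * i), dose_po=50.0)
                                for i in range(3)], t, method="expm")["AT", "plasma"]
        total = np.zeros_like(t)
        for i in range(3):
            total += model.simulate([DoseEvent(time=float(24 * i), dose_po=50.0)],
                                    t, method="expm")["AT", "plasma"]
        assert np.max(np.abs(multi - total)) / multi.max() < 5e-3


class TestSteadyState:
    def test_fast_washout_converges_immediately(self):
        phys = PhysiologySpec(lumped=True, V_venous=10.0)
        parent = CompoundParams(name="AT", MW=277.4, Kp_ht=1.0, fu_ht=1.0,
                                CL_other=5000.0)
        met = CompoundParams(name="NT", MW=263.384, Kp_ht=1.0, fu_ht=1.0,
                             Kp_re=1.0, V_central=10.0, V_re=5.0, Q_re=5.0,
                             CL_other=5000.0)
        ab = AbsorptionParams(ka=5.0, t_lag=0.1, F=0.5, fa_Fg=0.6)
        m = PbpkModel(phys, parent, met, ab)
        _, cycles = m.simulate_to_steady_state([DoseEvent(time=0, dose_po=75.0)], 24.0)
        assert cycles <= 2

    def test_steady_state_auc_equals_single_dose_auc_to_infinity(self, model):
        """Linear-kinetics superposition: AUC over one steady-state interval
        equals the single-dose AUC extrapolated to infinity."""
        reg = [DoseEvent(time=0.0, dose_po=75.0)]
        t_long = np.linspace(0.05, 2000.0, 8000)
        single = model.simulate(reg, t_long, method="expm")["AT", "plasma"]
        auc_inf = np.trapezoid(single, t_long)
        x_ss, _ = model.simulate_to_steady_state(reg, 24.0, tolerance=1e-8)
        t_tau = np.linspace(0.01, 24.0, 600)
        ss = model.simulate(reg, t_tau, x0=x_ss, method="expm")["AT", "plasma"]
        auc_tau = np.trapezoid(ss, t_tau)
        assert auc_tau == pytest.approx(auc_inf, rel=0.01)

    def test_daily_75mg_reaches_positive_trough(self, model, single_dose_75):
        x, cycles = model.simulate_to_steady_state(single_dose_75, 24.0)
        assert cycles > 1
        assert x[model.system().index["venous"]] > 0


class TestMassBalance:
    @pytest.mark.parametrize("regimen", [
        [DoseEvent(time=0.0, dose_po=75.0)],
        [DoseEvent(time=0.0, dose_po=25.0), DoseEvent(time=8.0, dose_po=25.0),
         DoseEvent(time=16.0, dose_po=25.0)],
    ], ids=["single", "multi"])
    def test_conservation_within_tolerance(self, model, regimen):
        t = np.linspace(0.1, 72, 300)
        s = model.simulate(regimen, t, method="expm")
        rep = model.mass_balance(s, regimen)
        assert rep.ok, str(rep)
        assert rep.max_rel_residual_parent < 1e-6
        assert rep.max_rel_residual_metabolite < 1e-6

    def test_first_pass_metabolite_mass_recovered(self, model, single_dose_75):
        t = np.linspace(0.1, 72, 300)
        s = model.simulate(single_dose_75, t, method="expm")
        rep = model.mass_balance(s, single_dose_75)
        assert rep.first_pass_metabolite_mg == pytest.approx(26.56, abs=0.005)
        assert rep.systemic_parent_mg == pytest.approx(34.425, abs=1e-9)

    def test_states_are_nonnegative(self, model, single_dose_75):
        t = np.linspace(0.1, 72, 300)
        s = model.simulate(single_dose_75, t, method="lsoda")
        assert s.states.min() >= -1e-9 * s.states.max()
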