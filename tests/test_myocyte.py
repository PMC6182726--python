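"""Paced ventricular cell: published-model behavior, block, QT extraction."""

import numpy as np
import pytest

from cardiotwin.myocyte import (ChannelBlockSpec, PacingProtocol, initial_state,
                                _pace_loop, block_scalers, paced_qt, qtc,
                                run_case)
from cardiotwin.params import IndividualParams, AbsorptionParams


def _twin(**kw):
    return IndividualParams(
        id="t", age=40, sex="F",
        absorption=AbsorptionParams(ka=0.24, t_lag=1.33, F=0.459, fa_Fg=0.832),
        RR_baseline_ms=kw.pop("RR_baseline_ms", 1000.0), **kw)


@pytest.fixture(scope="module")
def control_qt():
    return paced_qt(PacingProtocol(rr_ms=1000.0, beats=30))


class TestRestingBehavior:
    def test_unstimulated_cell_stays_at_rest(self):
        """30 s without stimulus: resting potential drifts < 1 mV and the
        final dV/dt is negligible."""
        y = initial_state()
        t, v, _, y_end = _pace_loop(y.copy(), 1, 30_000.0, 0.02, 0.0, 1.0,
                                    14.838, 3.98e-5, 0.153, 0.392, 5.405, 0.294,
                                    5.4, 140.0, 2.0, False, 0, 5)
        assert abs(v[-1] - v[0]) < 1.0
        dvdt = (v[-1] - v[-2]) / (t[-1] - t[-2])
        assert abs(dvdt) < 0.02


class TestControlActionPotential:
    def test_apd90_matches_published_model(self, control_qt):
        # epicardial cell at 1000 ms cycle length: published APD90 ~ 301 ms
        assert control_qt.apd90_ms == pytest.approx(301.0, rel=0.10)
        assert control_qt.arrhythmia_type == "none"

    def test_qt_in_physiological_band(self, control_qt):
        assert 300.0 <= control_qt.qt_ms <= 450.0

    def test_rate_dependence_of_apd(self, control_qt):
        fast = paced_qt(PacingProtocol(rr_ms=600.0, beats=30))
        assert fast.apd90_ms < control_qt.apd90_ms


class TestBlockScalers:
    BLOCKS = ChannelBlockSpec.from_dict({
        "AT": {"IKr": {"ic50_uM": 3.0, "hill": 1.0}},
        "NT": {"IKr": {"ic50_uM": 4.0, "hill": 1.0}},
    })

    def test_half_block_at_ic50(self):
        s = block_scalers({"AT": 3.0, "NT": 0.0}, self.BLOCKS)
        assert s["IKr"] == pytest.approx(0.5)

    def test_no_drug_no_block(self):
        s = block_scalers({"AT": 0.0, "NT": 0.0}, self.BLOCKS)
        assert all(v == 1.0 for v in s.values())

    def test_two_analytes_at_ic50_multiply(self):
        s = block_scalers({"AT": 3.0, "NT": 4.0}, self.BLOCKS)
        assert s["IKr"] == pytest.approx(0.25)

    def test_unknown_current_rejected(self):
        bad = ChannelBlockSpec.from_dict({"AT": {"IFunny": {"ic50_uM": 1.0}}})
        with pytest.raises(ValueError, match="unknown current"):
            block_scalers({"AT": 1.0}, bad)


class TestBlockEffects:
    def test_apd_monotone_under_ikr_block_ladder(self, control_qt):
        apds = [control_qt.apd90_ms]
        for sc in (0.7, 0.5, 0.3):
            apds.append(paced_qt(PacingProtocol(rr_ms=1000.0, beats=30),
                                 {"IKr": sc}).apd90_ms)
        assert all(b >= a for a, b in zip(apds, apds[1:]))

    def test_severe_repolarization_block_raises_arrhythmia_flag(self):
        r = paced_qt(PacingProtocol(rr_ms=2000.0, beats=12),
                     {"IKr": 1e-4, "IKs": 1e-4})
        assert r.arrhythmia
        assert r.arrhythmia_type in ("EAD", "repolarization_failure")


class TestQtc:
    def test_bazett_identity_at_one_second(self):
        assert qtc(400.0, 1000.0, "bazett") == pytest.approx(400.0, abs=1e-12)

    def test_bazett_tachycardia_value(self):
        assert qtc(400.0, 600.0, "bazett") == pytest.approx(400.0 / np.sqrt(0.6),
                                                            abs=1e-12)
        assert qtc(400.0, 600.0, "bazett") == pytest.approx(516.4, abs=0.05)

    def test_fridericia_and_passthrough(self):
        assert qtc(400.0, 600.0, "fridericia") == pytest.approx(
            400.0 / 0.6 ** (1 / 3), abs=1e-12)
        assert qtc(400.0, 600.0, "none") == 400.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            qtc(-1.0, 600.0)


class TestRunCase:
    BLOCKS = ChannelBlockSpec.from_dict({
        "AT": {"IKr": {"ic50_uM": 3.0, "hill": 1.0}},
    })

    def test_zero_exposure_control(self):
        s = run_case({"AT": 0.0}, _twin(), self.BLOCKS, n_runs=4, seed=1111,
                     beats=10)
        assert s.arrhythmia_count == 0
        assert s.qt_sd > 0  # population variability alone

    def test_seeded_protocol_bit_reproducible(self):
        a = run_case({"AT": 1.0}, _twin(), self.BLOCKS, n_runs=3, seed=1111, beats=8)
        b = run_case({"AT": 1.0}, _twin(), self.BLOCKS, n_runs=3, seed=1111, beats=8)
        assert [r.qt_ms for r in a.results] == [r.qt_ms for r in b.results]
        assert a.qt_mean == b.qt_mean and a.arrhythmia_count == b.arrhythmia_count

    def test_runs_differ_within_a_summary(self):
        s = run_case({"AT": 1.0}, _twin(), self.BLOCKS, n_runs=3, seed=1111, beats=8)
        qts = [r.qt_ms for r in s.results]
        assert len(set(qts)) == 3
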