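import numpy as np
import pytest

from helpers_oracles import loglinear_tau

from cin_ephys.passive import (
    PassiveFeatureError,
    compute_capacitance,
    compute_passive_features,
    fit_time_constant,
    measure_input_resistance,
    measure_rmp,
    measure_sag,
)
from cin_ephys.synth import PassiveGroundTruth, make_passive_protocol
from cin_ephys.traces import CurrentStep, StepProtocol, Sweep


def protocol(gt, steps=(-5.0, -10.0, -15.0, -20.0), **kw):
    return make_passive_protocol(gt, list(steps), **kw)


class TestRMP:
    def test_constant_sweep_reads_exactly(self):
        gt = PassiveGroundTruth(rmp=-79.0, noise_sd=0.0)
        assert measure_rmp(protocol(gt)) == pytest.approx(-79.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        gt = PassiveGroundTruth(rmp=-65.4, noise_sd=0.2, seed=4)
        assert measure_rmp(protocol(gt)) == pytest.approx(-65.4, abs=0.05)

    def test_missing_zero_sweep_is_an_error(self):
        sw = Sweep(t=np.arange(100) * 0.02, v=np.full(100, -70.0),
                   step=CurrentStep(-10.0, 0.5, 1.5))
        prot = StepProtocol("c", "a", "g", [sw])
        with pytest.raises(PassiveFeatureError, match="zero-current"):
            measure_rmp(prot)


class TestInputResistance:
    def test_ohms_law_from_generated_deflection(self):
        gt = PassiveGroundTruth(rmp=-79.0, rin=100.0, tau_m=18.0,
                                sag_mV=0.0, noise_sd=0.0)
        assert measure_input_resistance(protocol(gt)) == pytest.approx(100.0,
                                                                       abs=1e-6)

    def test_recovery_of_high_rin_cell(self):
        gt = PassiveGroundTruth(rin=250.0, sag_mV=0.0, noise_sd=0.0)
        assert measure_input_resistance(protocol(gt)) == pytest.approx(250.0,
                                                                       abs=1e-6)

    def test_linear_cell_gives_same_rin_from_each_sweep(self):
        gt = PassiveGroundTruth(rin=150.0, sag_mV=0.0, noise_sd=0.0)
        prot = protocol(gt, steps=(-10.0, -20.0))
        both = measure_input_resistance(prot)
        only10 = measure_input_resistance(prot, lo_pA=-10.0, hi_pA=-10.0)
        only20 = measure_input_resistance(prot, lo_pA=-20.0, hi_pA=-20.0)
        assert only10 == pytest.approx(only20, rel=1e-9)
        assert both == pytest.approx(only10, rel=1e-9)

    def test_no_qualifying_sweep_is_an_error(self):
        gt = PassiveGroundTruth(sag_mV=0.0, noise_sd=0.0)
        prot = protocol(gt, steps=(-40.0,))
        with pytest.raises(PassiveFeatureError, match="Rin"):
            measure_input_resistance(prot)


class TestTimeConstant:
    def test_noiseless_fit_matches_loglinear_oracle(self):
        gt = PassiveGroundTruth(rin=100.0, tau_m=18.0, sag_mV=0.0,
                                noise_sd=0.0)
        prot = protocol(gt)
        tau, diag = fit_time_constant(prot)
        sw = prot.sweep_at(-20.0)
        sl = sw.window(sw.step.onset_ms + 1.0, sw.step.onset_ms + 200.0)
        v_ss = gt.rmp + gt.rin * (-20.0) / 1000.0
        tau_oracle = loglinear_tau(sw.t[sl] - sw.step.onset_ms, sw.v[sl], v_ss)
        assert tau == pytest.approx(tau_oracle, rel=1e-6)
        assert tau == pytest.approx(18.0, rel=0.005)
        assert not diag["flagged"]

    def test_noisy_fit_within_3_percent(self):
        gt = PassiveGroundTruth(rin=150.0, tau_m=18.0, sag_mV=0.0,
                                noise_sd=0.2, seed=5)
        tau, _ = fit_time_constant(protocol(gt))
        assert tau == pytest.approx(18.0, rel=0.03)

    def test_window_below_1ms_is_an_error(self):
        gt = PassiveGroundTruth(sag_mV=0.0, noise_sd=0.0)
        with pytest.raises(PassiveFeatureError, match="1 ms"):
            fit_time_constant(protocol(gt), fit_window_ms=0.5)


class TestCapacitance:
    @pytest.mark.parametrize("tau,rin,expected",
                             [(20.0, 200.0, 100.0), (18.0, 90.0, 200.0)])
    def test_unit_identity(self, tau, rin, expected):
        assert compute_capacitance(tau, rin) == pytest.approx(expected)

    def test_nonpositive_rin_rejected(self):
        with pytest.raises(ValueError):
            compute_capacitance(20.0, 0.0)


class TestSag:
    def test_generated_sag_recovered(self):
        gt = PassiveGroundTruth(rmp=-79.0, rin=200.0, tau_m=15.0,
                                sag_mV=3.5, noise_sd=0.0)
        prot = protocol(gt, steps=(-10.0, -20.0, -100.0))
        assert measure_sag(prot) == pytest.approx(3.5, abs=0.05)

    def test_pure_rc_sweep_has_no_sag(self):
        gt = PassiveGroundTruth(sag_mV=0.0, noise_sd=0.0)
        prot = protocol(gt, steps=(-10.0, -100.0))
        assert measure_sag(prot) == pytest.approx(0.0, abs=0.02)

    def test_trough_vs_steady_state_definition(self):
        # hand-built trace: steady −99 mV with a −101 mV trough → sag 2.0
        t = np.arange(60_000) * 0.02  # 1.2 s
        v = np.full(t.size, -79.0)
        on, off = 100.0, 1100.0
        i0, i1 = 5000, 55_000
        v[i0:i1] = -99.0
        peak_i = 15_000
        x = (np.arange(i0, i1) - peak_i) * 0.02
        v[i0:i1] -= 2.0 * np.exp(-0.5 * (x / 25.0) ** 2)
        sw = Sweep(t=t, v=v, step=CurrentStep(-80.0, on, off))
        prot = StepProtocol("c", "a", "g", [sw])
        assert measure_sag(prot) == pytest.approx(2.0, abs=0.01)

    def test_no_hyperpolarizing_sweep_is_an_error(self):
        sw = Sweep(t=np.arange(100) * 0.02, v=np.full(100, -70.0),
                   step=CurrentStep(0.0, 0.5, 1.5))
        with pytest.raises(PassiveFeatureError):
            measure_sag(StepProtocol("c", "a", "g", [sw]))


class TestRecoveryProperties:
    def test_rin_and_tau_invariant_under_junction_offset(self):
        gt = PassiveGroundTruth(rin=120.0, tau_m=14.0, sag_mV=0.0,
                                noise_sd=0.1, seed=9)
        prot = protocol(gt)
        shifted = StepProtocol(
            prot.cell_id, prot.animal_id, prot.group_label,
            [Sweep(t=s.t, v=s.v - 14.0, step=s.step,
                   holding_pA=s.holding_pA, sample_khz=s.sample_khz)
             for s in prot.sweeps],
            holding_potential_mV=prot.holding_potential_mV)
        assert measure_input_resistance(prot) == pytest.approx(
            measure_input_resistance(shifted), rel=1e-12)
        assert fit_time_constant(prot)[0] == pytest.approx(
            fit_time_constant(shifted)[0], rel=1e-6)

    def test_parameter_recovery_grid_median_errors(self):
        # reduced grid here; the full ≥100-cell grid runs in acceptance
        rng = np.random.default_rng(17)
        errs = {"rin": [], "tau": [], "cin": []}
        for i in range(20):
            rin = float(rng.uniform(50, 500))
            tau = float(rng.uniform(5, 40))
            noise = (0.05, 0.15, 0.3, 0.3)[i % 4]
            gt = PassiveGroundTruth(rin=rin, tau_m=tau, sag_mV=0.0,
                                    noise_sd=noise, seed=2000 + i)
            pf = compute_passive_features(protocol(gt))
            errs["rin"].append(abs(pf.rin - rin) / rin)
            errs["tau"].append(abs(pf.tau_m - tau) / tau)
            errs["cin"].append(abs(pf.cin - 1000 * tau / rin) / (1000 * tau / rin))
            # convention formula vs base-SI arithmetic, every cell
            cin_si = (pf.tau_m * 1e-3) / (pf.rin * 1e6) / 1e-12
            assert pf.cin == pytest.approx(cin_si, rel=1e-9)
        assert np.median(errs["rin"]) < 0.02
        assert np.median(errs["tau"]) < 0.02
        assert np.median(errs["cin"]) < 0.04
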