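import numpy as np
import pytest

from cin_ephys.spikes import APFeatures, aps_in_step, extract_ap_features
from cin_ephys.synth import simulate_cell
from cin_ephys.traces import CurrentStep, StepProtocol, Sweep
from cin_ephys.trains import (
    TrainFeatureError,
    compute_accommodation,
    compute_adaptation_ratio,
    compute_fi_slope,
    compute_train_features,
    measure_mahp,
    select_analysis_sweep,
)


def fake_events(first_isi_ms: float, n: int, t0: float = 700.0,
                amplitudes=None) -> list[APFeatures]:
    """Event list with a given first ISI and total count (20 ms tail ISIs)."""
    times = [t0, t0 + first_isi_ms]
    while len(times) < n:
        times.append(times[-1] + 5.0)
    evs = []
    for k, t in enumerate(times[:n]):
        ev = APFeatures(index=k, i_threshold=round(t / 0.02), t_threshold=t,
                        v_threshold=-41.0)
        ev.amplitude = 60.0 if amplitudes is None else amplitudes[k]
        evs.append(ev)
    return evs


def fake_protocol(amps):
    sweeps = [Sweep(t=np.arange(100_000) * 0.02, v=np.full(100_000, -79.0),
                    step=CurrentStep(a, 600.0, 1600.0)) for a in amps]
    return StepProtocol("c", "a", "g", sweeps)


class TestAnalysisSweepSelection:
    def test_first_sweep_clearing_both_thresholds_selected(self):
        prot = fake_protocol([100.0, 150.0, 200.0])
        events = {0: fake_events(1000 / 120, 80),
                  1: fake_events(1000 / 160, 110),
                  2: fake_events(1000 / 220, 140)}
        assert select_analysis_sweep(prot, events) == (1, True)

    def test_fallback_to_max_count_when_nothing_qualifies(self):
        prot = fake_protocol([100.0, 150.0])
        events = {0: fake_events(1000 / 120, 40),
                  1: fake_events(1000 / 140, 60)}
        assert select_analysis_sweep(prot, events) == (1, False)

    def test_initial_frequency_at_threshold_does_not_qualify(self):
        # the rule is a strict inequality: a cell exactly at the cutoff fails
        from cin_ephys.trains import TrainConfig

        prot = fake_protocol([100.0])
        events = {0: fake_events(5.0, 120)}     # exactly 200.0 Hz
        cfg = TrainConfig(min_initial_hz=200.0)
        idx, qualifies = select_analysis_sweep(prot, events, cfg)
        assert not qualifies
        cfg = TrainConfig(min_initial_hz=199.99)
        assert select_analysis_sweep(prot, events, cfg) == (0, True)


class TestFISlope:
    def test_exact_line_recovered_to_machine_precision(self):
        prot = fake_protocol([100.0, 150.0, 200.0])
        events = {0: fake_events(10.0, 20), 1: fake_events(1000 / 150, 20),
                  2: fake_events(5.0, 20)}
        assert compute_fi_slope(prot, events) == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_flat_fi_curve_gives_zero_slope(self):
        prot = fake_protocol([100.0, 150.0, 200.0])
        events = {k: fake_events(10.0, 20) for k in range(3)}
        assert compute_fi_slope(prot, events) == pytest.approx(0.0, abs=1e-12)

    def test_programmed_gain_recovered_from_simulated_cell(self, presets):
        fs, _ = presets
        params = fs.mean_cell()
        from dataclasses import replace
        params = replace(params, fi_gain=0.8)
        prot, truth = simulate_cell(params, noise_sd=0.0, seed=3)
        events = {k: aps_in_step(sw, extract_ap_features(sw))
                  for k, sw in enumerate(prot.sweeps)
                  if sw.step.amplitude_pA > 0}
        events = {k: ev for k, ev in events.items() if ev}
        assert compute_fi_slope(prot, events) == pytest.approx(0.8, abs=0.02)

    def test_fewer_than_two_points_is_an_error(self):
        prot = fake_protocol([100.0])
        with pytest.raises(TrainFeatureError):
            compute_fi_slope(prot, {0: fake_events(10.0, 20)})


class TestAdaptationRatio:
    def test_constant_train_has_unit_ratio(self):
        evs = fake_events(5.0, 20)
        ar, f0, steady = compute_adaptation_ratio(evs)
        assert ar == pytest.approx(1.0, abs=1e-12)
        assert f0 == pytest.approx(200.0)

    def test_initial_200_last5_60_gives_0p3(self):
        times = [700.0, 705.0] + [705.0 + k * 1000 / 60 for k in range(1, 6)]
        evs = [APFeatures(index=k, i_threshold=round(t / 0.02),
                          t_threshold=t, v_threshold=-41.0)
               for k, t in enumerate(times)]
        ar, _, _ = compute_adaptation_ratio(evs)
        assert ar == pytest.approx(0.3, abs=1e-9)

    def test_too_few_aps_flagged_absent(self):
        ar, _, _ = compute_adaptation_ratio(fake_events(5.0, 6))
        assert ar is None

    def test_fs_preset_recovered_through_full_extraction(self, fs_cell):
        prot, truth = fs_cell
        tf = compute_train_features(prot)
        assert tf.adaptation_ratio == pytest.approx(truth["adaptation_ratio"],
                                                    abs=0.01)

    def test_invariant_under_constant_voltage_offset(self, fs_cell):
        prot, _ = fs_cell
        k = 11
        sw = prot.sweeps[k]
        shifted = Sweep(t=sw.t, v=sw.v + 7.0, step=sw.step,
                        holding_pA=sw.holding_pA, sample_khz=sw.sample_khz)
        ar0, _, _ = compute_adaptation_ratio(
            aps_in_step(sw, extract_ap_features(sw)))
        ar1, _, _ = compute_adaptation_ratio(
            aps_in_step(shifted, extract_ap_features(shifted)))
        assert ar0 == pytest.approx(ar1, abs=1e-9)


class TestAccommodation:
    def test_equal_amplitudes_give_unity(self):
        assert compute_accommodation(fake_events(5.0, 10)) == pytest.approx(1.0)

    def test_amplitude_drop_60_to_45_gives_0p75(self):
        amps = list(np.linspace(60.0, 45.0, 10))
        evs = fake_events(5.0, 10, amplitudes=amps)
        assert compute_accommodation(evs) == pytest.approx(0.75, abs=1e-12)

    def test_template_ratio_recovered(self, presets):
        fs, _ = presets
        from dataclasses import replace
        params = replace(fs.mean_cell(), accommodation=0.9)
        prot, truth = simulate_cell(params, noise_sd=0.0, seed=4)
        tf = compute_train_features(prot)
        assert tf.accommodation == pytest.approx(0.9, abs=0.01)

    def test_single_ap_flagged_absent(self):
        assert compute_accommodation(fake_events(5.0, 1)) is None


class TestMahp:
    def test_baseline_minus_trough_on_hand_built_trace(self):
        # −79 baseline, post-train trough −84 → mAHP 5
        t = np.arange(140_000) * 0.02  # 2.8 s
        v = np.full(t.size, -79.0)
        off_i = 80_000
        x = (t[off_i:] - t[off_i]) / 50.0
        v[off_i:] = -79.0 - 5.0 * x * np.exp(1.0 - x)
        sw = Sweep(t=t, v=v, step=CurrentStep(150.0, 600.0, 1600.0))
        assert measure_mahp(sw) == pytest.approx(5.0, abs=0.05)

    def test_template_depth_recovered(self, presets):
        fs, _ = presets
        from dataclasses import replace
        params = replace(fs.mean_cell(), mahp_depth=7.2)
        prot, truth = simulate_cell(params, noise_sd=0.0, seed=5)
        tf = compute_train_features(prot)
        assert tf.mahp == pytest.approx(7.2, abs=0.1)

    def test_no_post_step_hyperpolarization_flagged_absent(self):
        t = np.arange(140_000) * 0.02
        v = np.full(t.size, -79.0)
        sw = Sweep(t=t, v=v, step=CurrentStep(150.0, 600.0, 1600.0))
        assert measure_mahp(sw) is None

    def test_short_baseline_is_an_error(self):
        t = np.arange(20_000) * 0.02  # only 100 ms before onset
        v = np.full(t.size, -79.0)
        sw = Sweep(t=t, v=v, step=CurrentStep(150.0, 100.0, 300.0))
        with pytest.raises(TrainFeatureError, match="baseline"):
            measure_mahp(sw)


class TestScheduleLevelDistribution:
    def test_mean_extracted_ar_matches_programmed_over_fs_cohort(self, presets):
        # schedule-level closed forms for 200 sampled FS cells, plus a
        # handful of full trace extractions
        from cin_ephys.synth import make_train_schedule

        fs, _ = presets
        rng = np.random.default_rng(8)
        ars, targets = [], []
        for _ in range(200):
            c = fs.sample(rng)
            sched = make_train_schedule(
                initial_hz=c.initial_hz, adaptation_ratio=c.adaptation_ratio,
                window_ms=1000.0).snapped(0.02)
            ars.append(sched.adaptation_ratio())
            targets.append(c.adaptation_ratio)
        assert abs(np.mean(ars) - np.mean(targets)) < 0.02
        assert abs(np.mean(ars) - 0.75) < 0.02
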