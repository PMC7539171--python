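import numpy as np
import pandas as pd
import pytest

from cin_ephys.classify import classify_fs
from cin_ephys.synth import (
    APTemplate,
    CohortSpec,
    GeneratorError,
    GroupSpec,
    PassiveGroundTruth,
    TrainSchedule,
    band_limited_noise,
    make_fs_and_nonfs_presets,
    make_passive_protocol,
    make_spiking_sweep,
    make_train_schedule,
    paper_matched_cohort,
    simulate_cohort,
)


class TestPassiveProtocol:
    def test_steady_state_deflection_follows_ohms_law(self):
        gt = PassiveGroundTruth(rmp=-79.0, rin=100.0, tau_m=18.0,
                                sag_mV=0.0, noise_sd=0.0)
        prot = make_passive_protocol(gt, [-20.0])
        sw = prot.sweep_at(-20.0)
        v_end = sw.v[sw.index_at(sw.step.offset_ms) - 1]
        # rin·I = −2.0 mV; the transient is fully decayed after 1 s
        assert v_end - gt.rmp == pytest.approx(-2.0, abs=1e-9)

    def test_same_seed_reproduces_traces_bit_for_bit(self):
        gt = PassiveGroundTruth(noise_sd=0.3, seed=42)
        a = make_passive_protocol(gt, [-10.0])
        b = make_passive_protocol(gt, [-10.0])
        for sa, sb in zip(a.sweeps, b.sweeps):
            assert np.array_equal(sa.v, sb.v)

    def test_noise_has_zero_mean_over_many_samples(self):
        gt0 = PassiveGroundTruth(rmp=-65.0, rin=100.0, tau_m=18.0,
                                 sag_mV=0.0, noise_sd=0.0, seed=11)
        gt = PassiveGroundTruth(rmp=-65.0, rin=100.0, tau_m=18.0,
                                sag_mV=0.0, noise_sd=0.2, seed=11)
        clean = make_passive_protocol(gt0, [-10.0]).sweep_at(-10.0)
        noisy = make_passive_protocol(gt, [-10.0]).sweep_at(-10.0)
        resid = noisy.v - clean.v
        # zero mean over the sweep by construction
        assert abs(resid.mean()) < 1e-12
        # a 10^4-sample window obeys the law of large numbers with the
        # band-limited effective sample size (integrated autocorrelation
        # 2·√π·σ_kernel ≈ 0.53 ms ≈ 26.6 samples at 50 kHz)
        n, n_eff = 10_000, 10_000 / 26.6
        assert abs(resid[:n].mean()) < 3.0 * 0.2 / np.sqrt(n_eff)

    def test_step_shorter_than_tau_is_an_error(self):
        gt = PassiveGroundTruth(tau_m=30.0)
        with pytest.raises(GeneratorError):
            make_passive_protocol(gt, [-10.0], step_ms=20.0)

    def test_step_shorter_than_5_tau_warns(self):
        gt = PassiveGroundTruth(tau_m=30.0)
        with pytest.warns(UserWarning, match="5·τm"):
            make_passive_protocol(gt, [-10.0], step_ms=100.0)


class TestBandLimitedNoise:
    def test_realized_sd_and_mean_are_exact(self):
        rng = np.random.default_rng(0)
        x = band_limited_noise(rng, 50_000, 0.25, 0.02)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(0.25, rel=1e-9)

    def test_band_limiting_suppresses_derivative_noise(self):
        rng = np.random.default_rng(1)
        x = band_limited_noise(rng, 50_000, 0.2, 0.02)
        white = rng.standard_normal(50_000) * 0.2
        d_band = np.std(np.gradient(x, 0.02))
        d_white = np.std(np.gradient(white, 0.02))
        assert d_band < 0.3 * d_white


class TestAPTemplate:
    def test_half_width_is_mean_of_rise_and_fall(self):
        t = APTemplate(rise_ms=0.2, fall_ms=0.3)
        assert t.half_width_ms == pytest.approx(0.25)

    def test_amplitude_below_rise_guard_rejected(self):
        with pytest.raises(GeneratorError):
            APTemplate(amplitude_mV=20.0)


class TestSpikingSweep:
    def test_template_identity_threshold_and_peak(self):
        template = APTemplate(v_threshold=-40.0, amplitude_mV=60.0,
                              rise_ms=0.2, fall_ms=0.3)
        sched = make_train_schedule(initial_hz=50.0, adaptation_ratio=0.8,
                                    window_ms=1000.0, amplitude_mV=60.0)
        sweep, truth = make_spiking_sweep(template, sched,
                                          PassiveGroundTruth(), 100.0)
        assert truth.half_width_ms == pytest.approx(0.25)
        # first spike takes off at the approach plateau, just below threshold
        assert truth.takeoff_mV[0] == pytest.approx(-40.0, abs=0.1)
        peak = truth.takeoff_mV[0] + truth.amplitudes_mV[0]
        assert peak == pytest.approx(20.0, abs=0.1)
        i0 = round(truth.spike_times_ms[0] / sweep.dt_ms)
        assert sweep.v[i0] == pytest.approx(truth.takeoff_mV[0], abs=1e-9)

    def test_adaptation_ratio_from_explicit_isi_sequence(self):
        # 200 Hz first ISI, last-five-AP ISIs at 60 Hz → AR = 0.3
        sched = TrainSchedule(first_spike_ms=85.0,
                              isi_sequence=(5.0,) + (1000.0 / 60.0,) * 4,
                              amplitude_sequence=(60.0,) * 6)
        assert sched.adaptation_ratio() == pytest.approx(0.3, abs=1e-12)
        snapped = sched.snapped(0.02)
        assert snapped.adaptation_ratio() == pytest.approx(0.3, abs=0.005)

    def test_accommodation_from_amplitude_sequence(self):
        sched = TrainSchedule(first_spike_ms=85.0, isi_sequence=(10.0,) * 5,
                              amplitude_sequence=tuple(
                                  np.linspace(60.0, 45.0, 6)))
        assert sched.accommodation() == pytest.approx(0.75, abs=1e-12)

    def test_overlapping_spikes_rejected(self):
        template = APTemplate()
        sched = TrainSchedule(first_spike_ms=85.0, isi_sequence=(0.8,) * 6,
                              amplitude_sequence=(60.0,) * 7)
        with pytest.raises(GeneratorError, match="overlap|short"):
            make_spiking_sweep(template, sched, PassiveGroundTruth(), 100.0)

    def test_ground_truth_is_closed_form_not_remeasured(self):
        # emitted truth must match the analytic schedule exactly
        sched = make_train_schedule(initial_hz=200.0, adaptation_ratio=0.75,
                                    window_ms=1000.0, accommodation=0.9)
        _, truth = make_spiking_sweep(APTemplate(), sched,
                                      PassiveGroundTruth(), 150.0)
        snapped = sched.snapped(0.02)
        assert truth.initial_hz == snapped.initial_hz()
        assert truth.adaptation_ratio == snapped.adaptation_ratio()
        assert truth.accommodation == snapped.accommodation()


class TestPresets:
    def test_fs_mean_cell_meets_all_three_classifier_conditions(self):
        fs, _ = make_fs_and_nonfs_presets()
        cell = fs.mean_cell()
        label, met = classify_fs(cell.half_width_ms, cell.fahp_depth,
                                 cell.adaptation_ratio)
        assert (label, met) == ("FS", 3)

    def test_nonfs_mean_cell_meets_no_condition(self):
        _, nonfs = make_fs_and_nonfs_presets()
        cell = nonfs.mean_cell()
        label, met = classify_fs(cell.half_width_ms, cell.fahp_depth,
                                 cell.adaptation_ratio)
        assert (label, met) == ("non-FS", 0)

    def test_500_sampled_cells_per_preset_classify_without_error(self):
        fs, nonfs = make_fs_and_nonfs_presets()
        rng = np.random.default_rng(3)
        wrong = 0
        for dists, expected in ((fs, "FS"), (nonfs, "non-FS")):
            for _ in range(500):
                c = dists.sample(rng)
                label, _ = classify_fs(c.half_width_ms, c.fahp_depth,
                                       c.adaptation_ratio)
                wrong += label != expected
        assert wrong == 0


class TestCohort:
    def test_cohort_counts_and_determinism(self, presets):
        fs, nonfs = presets
        groups = {g: GroupSpec(n_animals=4, cells_per_animal=4,
                               fraction_fs=0.5, fs=fs, nonfs=nonfs)
                  for g in ("G1", "G2")}
        spec = CohortSpec(groups=groups, seed=5, noise_sd=0.0,
                          sample_khz=20.0)
        protocols, truth = simulate_cohort(spec)
        assert len(protocols) == 32 and len(truth) == 32
        protocols2, truth2 = simulate_cohort(spec)
        pd.testing.assert_frame_equal(truth, truth2)
        assert np.array_equal(protocols[0].sweeps[-1].v,
                              protocols2[0].sweeps[-1].v)

    def test_paper_matched_cohort_structure(self):
        spec = paper_matched_cohort(seed=1)
        assert set(spec.groups) == {"WT_hTSC1", "S403L"}
        wt, s4 = spec.groups["WT_hTSC1"], spec.groups["S403L"]
        assert (wt.n_animals, s4.n_animals) == (5, 4)
        assert wt.fs.dists["fahp_depth"].mean == pytest.approx(23.7)
        assert s4.fs.dists["fahp_depth"].mean == pytest.approx(20.1)
        assert wt.fs.dists["mahp_depth"].mean == pytest.approx(7.2)
        assert s4.fs.dists["mahp_depth"].mean == pytest.approx(5.2)
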