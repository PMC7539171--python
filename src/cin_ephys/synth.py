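"""Synthetic current-clamp protocols with exact, closed-form ground truth.

The generator is template-based: every sweep is assembled from analytic
segments (RC responses, piecewise-linear action potentials with a smooth
parabolic afterhyperpolarization trough, exponential interspike recovery,
an alpha-function post-train mAHP, a Gaussian sag bump), all aligned to the
sample grid.  Because every segment is closed-form, the true value of every
feature the analysis measures — threshold, amplitude, half-width, fAHP,
initial/steady frequency, adaptation ratio, accommodation, mAHP, RMP, Rin,
τm, sag — is computed from the construction parameters and emitted alongside
the traces.  The generator never re-measures its own output.

Key waveform conventions (all rates in mV/ms):

* the depolarizing approach to the first spike and the interspike recovery
  are exponentials whose slopes stay well below the 10 mV/ms spike-detection
  criterion, so derivative-based detection is exact on these traces;
* spikes take off from the instantaneous value of the interspike trajectory
  (as in real fast-spiking trains, where short intervals prevent full
  recovery to threshold); per-spike takeoff voltages are closed-form;
* the AHP trough is a parabola (curvature ``TROUGH_KAPPA``) so that local
  quadratic refinement of the trough is unbiased;
* additive noise is band-limited Gaussian (white noise smoothed with a
  Gaussian kernel and rescaled), emulating hardware low-pass filtering;
  white noise at 50 kHz would make a 10 mV/ms derivative criterion
  meaningless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .traces import CurrentStep, StepProtocol, Sweep

# Waveform shape constants (mV/ms unless noted).
APPROACH_SLOPE = 3.0        # depolarizing approach to the first spike
DESCENT_SLOPE = 60.0        # AHP descent from takeoff to the trough shoulder
TROUGH_KAPPA = 7.0          # trough parabola curvature, mV/ms^2
TROUGH_HALF_MS = 0.72       # half-width of the parabolic trough region
RECOVERY_SLOPE = TROUGH_KAPPA * TROUGH_HALF_MS  # slope at trough shoulder (5)
EDGE_DV = 0.5 * TROUGH_KAPPA * TROUGH_HALF_MS ** 2  # shoulder height above trough
NOISE_KERNEL_MS = 0.15      # correlation scale of band-limited noise

DEFAULT_SAMPLE_KHZ = 50.0
DEFAULT_ONSET_MS = 600.0    # leaves a full 500 ms mAHP baseline
DEFAULT_STEP_MS = 1000.0
DEFAULT_TAIL_MS = 600.0


class GeneratorError(ValueError):
    """Inconsistent synthetic-waveform specification."""


# ---------------------------------------------------------------------------
# ground-truth parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APTemplate:
    """Stereotyped action-potential waveform parameters.

    ``amplitude_mV`` is peak minus takeoff; ``fahp_depth_mV`` is nominal
    threshold minus trough (positive).  The piecewise-linear rise/fall makes
    the half-width exactly ``(rise_ms + fall_ms) / 2``.
    """

    v_threshold: float = -41.0
    amplitude_mV: float = 60.0
    rise_ms: float = 0.16
    fall_ms: float = 0.24
    fahp_depth_mV: float = 20.0
    fahp_decay_ms: float = 4.0

    def __post_init__(self) -> None:
        if self.amplitude_mV < 25.0:
            raise GeneratorError(
                "AP amplitude must be at least 25 mV to clear the 20 mV "
                "detection rise guard")
        if self.rise_ms <= 0 or self.fall_ms <= 0:
            raise GeneratorError("rise_ms and fall_ms must be positive")
        if self.fahp_depth_mV <= EDGE_DV:
            raise GeneratorError(
                f"fAHP depth must exceed the trough shoulder ({EDGE_DV} mV)")

    @property
    def half_width_ms(self) -> float:
        return 0.5 * (self.rise_ms + self.fall_ms)

    def snapped(self, dt_ms: float) -> "APTemplate":
        """Template with rise/fall durations aligned to the sample grid."""
        rise = max(2, round(self.rise_ms / dt_ms)) * dt_ms
        fall = max(2, round(self.fall_ms / dt_ms)) * dt_ms
        return replace(self, rise_ms=rise, fall_ms=fall)


@dataclass(frozen=True)
class TrainSchedule:
    """Spike timing and per-spike amplitude program for one sweep."""

    first_spike_ms: float                  # relative to step onset
    isi_sequence: tuple[float, ...]        # ms, len = n_spikes - 1
    amplitude_sequence: tuple[float, ...]  # mV, len = n_spikes
    mahp_depth_mV: float = 0.0
    mahp_decay_ms: float = 50.0

    def __post_init__(self) -> None:
        if len(self.amplitude_sequence) != len(self.isi_sequence) + 1:
            raise GeneratorError(
                "amplitude_sequence must have one more entry than isi_sequence")
        if any(d <= 0 for d in self.isi_sequence):
            raise GeneratorError("ISIs must be positive")

    @property
    def n_spikes(self) -> int:
        return len(self.amplitude_sequence)

    def spike_times_ms(self) -> np.ndarray:
        """Spike takeoff times relative to step onset."""
        return self.first_spike_ms + np.concatenate(
            [[0.0], np.cumsum(self.isi_sequence)])

    def snapped(self, dt_ms: float) -> "TrainSchedule":
        """Schedule with spike times aligned to the sample grid."""
        times = self.spike_times_ms()
        snapped = np.round(times / dt_ms) * dt_ms
        return replace(
            self,
            first_spike_ms=float(snapped[0]),
            isi_sequence=tuple(np.diff(snapped).tolist()),
        )

    # -- closed-form train features ----------------------------------------

    def initial_hz(self) -> float:
        return 1000.0 / self.isi_sequence[0]

    def steady_hz(self) -> float:
        """Mean instantaneous rate over the ISIs among the last five spikes."""
        tail = self.isi_sequence[-4:]
        return float(np.mean([1000.0 / d for d in tail]))

    def adaptation_ratio(self) -> float:
        return self.steady_hz() / self.initial_hz()

    def accommodation(self) -> float:
        return self.amplitude_sequence[-1] / self.amplitude_sequence[0]


def make_train_schedule(*, initial_hz: float, adaptation_ratio: float,
                        window_ms: float, first_spike_ms: float = 85.0,
                        amplitude_mV: float = 60.0, accommodation: float = 1.0,
                        n_transition: int = 5, mahp_depth_mV: float = 0.0,
                        mahp_decay_ms: float = 50.0,
                        end_margin_ms: float = 6.0) -> TrainSchedule:
    """Build an ISI schedule with programmed initial rate and adaptation.

    The first ISI is ``1000/initial_hz``; ISIs then ramp linearly over
    ``n_transition`` intervals to the steady value ``isi0/adaptation_ratio``
    and stay constant until the step window is filled (leaving
    ``end_margin_ms`` so the last AP and its AHP complete inside the step).
    Spike amplitudes interpolate linearly from ``amplitude_mV`` down to
    ``amplitude_mV * accommodation``.
    """
    if not 0 < adaptation_ratio:
        raise GeneratorError("adaptation ratio must be positive")
    d0 = 1000.0 / initial_hz
    ds = d0 / adaptation_ratio
    isis = [d0]
    for k in range(1, n_transition + 1):
        isis.append(d0 + (ds - d0) * k / n_transition)
    t = first_spike_ms + sum(isis)
    while t + ds <= window_ms - end_margin_ms:
        isis.append(ds)
        t += ds
    while isis and t > window_ms - end_margin_ms:
        t -= isis.pop()
    if not isis:
        raise GeneratorError("step window too short for even two spikes")
    n = len(isis) + 1
    amps = tuple(np.linspace(amplitude_mV, amplitude_mV * accommodation, n))
    return TrainSchedule(first_spike_ms=first_spike_ms,
                         isi_sequence=tuple(isis),
                         amplitude_sequence=amps,
                         mahp_depth_mV=mahp_depth_mV,
                         mahp_decay_ms=mahp_decay_ms)


@dataclass(frozen=True)
class PassiveGroundTruth:
    """True passive membrane parameters for one synthetic cell."""

    rmp: float = -65.0       # mV
    rin: float = 150.0       # MΩ
    tau_m: float = 12.0      # ms
    sag_mV: float = 2.0
    noise_sd: float = 0.0    # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rin <= 0 or self.tau_m <= 0 or self.noise_sd < 0:
            raise GeneratorError("rin, tau_m must be > 0 and noise_sd >= 0")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def band_limited_noise(rng: np.random.Generator, n: int, sd_mV: float,
                       dt_ms: float, kernel_ms: float = NOISE_KERNEL_MS,
                       ) -> np.ndarray:
    """Zero-mean Gaussian noise low-pass shaped to ``kernel_ms`` correlation.

    White Gaussian samples are smoothed with a Gaussian kernel and rescaled
    so the realized trace has exactly zero mean and standard deviation
    ``sd_mV``; this emulates the band-limited noise of filtered recordings.
    """
    if sd_mV == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    shaped = gaussian_filter1d(white, sigma=kernel_ms / dt_ms, mode="reflect")
    shaped -= shaped.mean()
    shaped *= sd_mV / shaped.std()
    return shaped


# ---------------------------------------------------------------------------
# passive sweeps
# ---------------------------------------------------------------------------

def _time_axis(duration_ms: float, dt_ms: float) -> np.ndarray:
    n = round(duration_ms / dt_ms)
    return np.arange(n + 1) * dt_ms


def _rc_sweep(*, baseline_mV: float, rin: float, tau_m: float, step_pA: float,
              onset_ms: float, offset_ms: float, duration_ms: float,
              dt_ms: float, sample_khz: float, holding_pA: float,
              sag_mV: float = 0.0, sag_width_ms: float = 25.0) -> Sweep:
    """Single-compartment RC response, optionally with a Gaussian sag bump.

    The sag bump is centred at ``max(8·τm, 120)`` ms after onset (grid
    aligned), by which time the RC transient has decayed to < 1e-3 of ΔV, so
    the sampled minimum equals steady state minus ``sag_mV`` to high
    accuracy.
    """
    t = _time_axis(duration_ms, dt_ms)
    v = np.full(t.size, baseline_mV, dtype=float)
    dv = rin * step_pA / 1000.0
    on = round(onset_ms / dt_ms)
    off = round(offset_ms / dt_ms)
    ts = t[on:off] - t[on]
    v[on:off] = baseline_mV + dv * (1.0 - np.exp(-ts / tau_m))
    if sag_mV:
        t_sag = round(max(8.0 * tau_m, 120.0) / dt_ms) * dt_ms
        v[on:off] -= sag_mV * np.exp(-0.5 * ((ts - t_sag) / sag_width_ms) ** 2)
    v_end = baseline_mV + dv * (1.0 - math.exp(-(offset_ms - onset_ms) / tau_m))
    v[off:] = baseline_mV + (v_end - baseline_mV) * np.exp(
        -(t[off:] - t[off]) / tau_m)
    return Sweep(t=t, v=v, step=CurrentStep(step_pA, onset_ms, offset_ms),
                 holding_pA=holding_pA, sample_khz=sample_khz)


def make_passive_protocol(gt: PassiveGroundTruth, steps_pA: Sequence[float],
                          *, cell_id: str = "cell", animal_id: str = "animal",
                          group_label: str = "group",
                          onset_ms: float = DEFAULT_ONSET_MS,
                          step_ms: float = DEFAULT_STEP_MS,
                          tail_ms: float = DEFAULT_TAIL_MS,
                          sample_khz: float = DEFAULT_SAMPLE_KHZ,
                          ) -> StepProtocol:
    """Passive protocol: a zero-current sweep plus RC responses to steps.

    Sweeps are generated from rest (baseline = true RMP, no holding
    current).  If the ground truth carries a sag, the bump is applied to the
    most hyperpolarizing sweep, provided that sweep is stronger than −20 pA
    (so the small steps used for Rin/τm stay purely RC).
    """
    if not any(abs(a) < 1e-9 for a in steps_pA):
        steps_pA = [0.0, *steps_pA]
    if not any(a < 0 for a in steps_pA):
        raise GeneratorError("passive protocol needs at least one negative step")
    if step_ms < gt.tau_m:
        raise GeneratorError("step window shorter than τm cannot be fitted")
    if step_ms < 5.0 * gt.tau_m:
        warnings.warn("step window shorter than 5·τm: exponential fit may be "
                      "biased", stacklevel=2)
    dt = 1.0 / sample_khz
    duration = onset_ms + step_ms + tail_ms
    rng = np.random.default_rng(gt.seed)
    sag_target = min(steps_pA)
    sweeps = []
    for amp in sorted(steps_pA):
        sag = gt.sag_mV if (amp == sag_target and amp < -20.0) else 0.0
        sw = _rc_sweep(baseline_mV=gt.rmp, rin=gt.rin, tau_m=gt.tau_m,
                       step_pA=amp, onset_ms=onset_ms,
                       offset_ms=onset_ms + step_ms, duration_ms=duration,
                       dt_ms=dt, sample_khz=sample_khz, holding_pA=0.0,
                       sag_mV=sag)
        if gt.noise_sd:
            sw = replace(sw, v=sw.v + band_limited_noise(
                rng, sw.n_samples, gt.noise_sd, dt))
        sweeps.append(sw)
    return StepProtocol(cell_id=cell_id, animal_id=animal_id,
                        group_label=group_label, sweeps=sweeps,
                        holding_potential_mV=gt.rmp)


# ---------------------------------------------------------------------------
# spiking sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikingTruth:
    """Closed-form ground truth for one spiking sweep."""

    spike_times_ms: np.ndarray      # takeoff times (absolute sweep time)
    takeoff_mV: np.ndarray          # per-spike takeoff (= measured threshold)
    amplitudes_mV: np.ndarray       # per-spike peak − takeoff
    half_width_ms: float
    max_rise: float                 # mV/ms
    max_decay: float                # mV/ms, negative
    fahp_mV: np.ndarray             # per-spike takeoff − trough
    trough_mV: float
    initial_hz: float
    steady_hz: float | None
    adaptation_ratio: float | None
    accommodation: float
    mahp_mV: float
    n_spikes: int


def make_spiking_sweep(template: APTemplate, schedule: TrainSchedule,
                       passive: PassiveGroundTruth, step_pA: float, *,
                       holding_mV: float = -79.0,
                       onset_ms: float = DEFAULT_ONSET_MS,
                       step_ms: float = DEFAULT_STEP_MS,
                       tail_ms: float = DEFAULT_TAIL_MS,
                       sample_khz: float = DEFAULT_SAMPLE_KHZ,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[Sweep, SpikingTruth]:
    """Paint a spike train onto a held-baseline sweep; return trace + truth.

    The membrane depolarizes exponentially from the holding level toward
    threshold at ``APPROACH_SLOPE``; each spike takes off from the
    instantaneous trajectory value, rises/falls piecewise-linearly, descends
    to a parabolic trough at ``template.v_threshold − fahp_depth``, and
    recovers exponentially toward threshold.  After the step the voltage
    returns to the holding level with an alpha-function mAHP whose sampled
    minimum is exactly ``mahp_depth_mV`` below baseline.
    """
    dt = 1.0 / sample_khz
    template = template.snapped(dt)
    schedule = schedule.snapped(dt)
    offset_ms = onset_ms + step_ms
    duration = offset_ms + tail_ms
    t = _time_axis(duration, dt)
    n = t.size
    i_on = round(onset_ms / dt)
    i_off = round(offset_ms / dt)

    thr = template.v_threshold
    trough = thr - template.fahp_depth_mV
    edge_v = trough + EDGE_DV
    tau_rec = max((thr - edge_v) / RECOVERY_SLOPE, template.fahp_decay_ms)
    tau_app = (thr - holding_mV) / APPROACH_SLOPE
    if tau_app <= 0:
        raise GeneratorError("holding level must be below AP threshold")

    r_n = round(template.rise_ms / dt)
    f_n = round(template.fall_ms / dt)
    h_n = max(2, round(TROUGH_HALF_MS / dt))

    times = schedule.spike_times_ms() + onset_ms
    idx = np.round(times / dt).astype(int)
    if idx[0] <= i_on or (idx[-1] * dt + template.rise_ms + template.fall_ms
                          + 2 * h_n * dt) >= offset_ms:
        raise GeneratorError("spike train does not fit inside the step window")

    v = np.full(n, holding_mV, dtype=float)
    # approach from holding toward threshold
    seg = t[i_on:idx[0] + 1] - t[i_on]
    v[i_on:idx[0] + 1] = thr - (thr - holding_mV) * np.exp(-seg / tau_app)

    takeoffs = np.empty(len(idx))
    fahps = np.empty(len(idx))
    takeoffs[0] = thr - (thr - holding_mV) * math.exp(
        -(idx[0] - i_on) * dt / tau_app)

    prev_rec_i = None
    for k, i0 in enumerate(idx):
        if k > 0:
            gap = (i0 - prev_rec_i) * dt
            if gap <= 0:
                raise GeneratorError(
                    f"spikes {k} and {k + 1} overlap (ISI too short for the "
                    f"AP waveform)")
            takeoffs[k] = thr - (thr - edge_v) * math.exp(-gap / tau_rec)
        v_to = takeoffs[k]
        if v_to <= edge_v + 1.0:
            raise GeneratorError("ISI too short: takeoff below AHP shoulder")
        peak = v_to + schedule.amplitude_sequence[k]
        d_n = max(1, round((v_to - edge_v) / DESCENT_SLOPE / dt))
        i_pk = i0 + r_n
        i_fe = i_pk + f_n
        i_le = i_fe + d_n            # left shoulder of the trough parabola
        i_tr = i_le + h_n            # trough vertex (on the grid)
        i_re = i_tr + h_n            # right shoulder, start of recovery
        if k + 1 < len(idx) and i_re >= idx[k + 1]:
            raise GeneratorError(
                f"spikes {k + 1} and {k + 2} overlap (ISI too short for the "
                f"AP waveform)")
        v[i0:i_pk + 1] = np.linspace(v_to, peak, r_n + 1)
        v[i_pk:i_fe + 1] = np.linspace(peak, v_to, f_n + 1)
        v[i_fe:i_le + 1] = np.linspace(v_to, edge_v, d_n + 1)
        para = (np.arange(i_le, i_re + 1) - i_tr) * dt
        v[i_le:i_re + 1] = trough + 0.5 * TROUGH_KAPPA * para ** 2
        # recovery toward threshold until the next spike (or step offset)
        i_stop = idx[k + 1] if k + 1 < len(idx) else i_off
        rec = (np.arange(i_re, i_stop + 1) - i_re) * dt
        v[i_re:i_stop + 1] = thr - (thr - edge_v) * np.exp(-rec / tau_rec)
        fahps[k] = v_to - trough
        prev_rec_i = i_re

    # post-step return with alpha-function mAHP (sampled minimum is exact)
    tail = t[i_off:] - t[i_off]
    v[i_off:] = holding_mV
    if schedule.mahp_depth_mV:
        t_m = max(1, round(schedule.mahp_decay_ms / dt)) * dt
        x = tail / t_m
        v[i_off:] = holding_mV - schedule.mahp_depth_mV * x * np.exp(1.0 - x)

    if passive.noise_sd:
        if rng is None:
            rng = np.random.default_rng(passive.seed)
        v = v + band_limited_noise(rng, n, passive.noise_sd, dt)

    sweep = Sweep(t=t, v=v, step=CurrentStep(step_pA, onset_ms, offset_ms),
                  holding_pA=(holding_mV - passive.rmp) / passive.rin * 1000.0,
                  sample_khz=sample_khz)
    isis = np.array(schedule.isi_sequence)
    n_spk = schedule.n_spikes
    truth = SpikingTruth(
        spike_times_ms=idx * dt,
        takeoff_mV=takeoffs,
        amplitudes_mV=np.array(schedule.amplitude_sequence),
        half_width_ms=template.half_width_ms,
        max_rise=schedule.amplitude_sequence[0] / template.rise_ms,
        max_decay=-schedule.amplitude_sequence[0] / template.fall_ms,
        fahp_mV=fahps,
        trough_mV=trough,
        initial_hz=schedule.initial_hz() if n_spk >= 2 else math.nan,
        steady_hz=schedule.steady_hz() if n_spk >= 7 else None,
        adaptation_ratio=schedule.adaptation_ratio() if n_spk >= 7 else None,
        accommodation=schedule.accommodation(),
        mahp_mV=schedule.mahp_depth_mV,
        n_spikes=n_spk,
    )
    return sweep, truth


# ---------------------------------------------------------------------------
# whole-cell simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Complete ground-truth parameter set for one simulated cell."""

    rmp: float = -65.0
    rin: float = 150.0
    tau_m: float = 12.0
    sag_mV: float = 2.0
    v_threshold: float = -41.0
    ap_amplitude: float = 60.0
    half_width_ms: float = 0.20
    fahp_depth: float = 20.0
    fahp_decay_ms: float = 4.0
    threshold_current_pA: float = 33.0   # cell spikes iff step >= this
    initial_hz: float = 200.0            # at the first suprathreshold step
    fi_gain: float = 1.2                 # Hz/pA
    adaptation_ratio: float = 0.75
    accommodation: float = 0.92
    mahp_depth: float = 7.0
    mahp_decay_ms: float = 40.0
    is_fs: bool = True

    def template(self) -> APTemplate:
        # rise:fall = 2:3 keeps the rise steeper, as in recorded spikes
        return APTemplate(v_threshold=self.v_threshold,
                          amplitude_mV=self.ap_amplitude,
                          rise_ms=0.8 * self.half_width_ms,
                          fall_ms=1.2 * self.half_width_ms,
                          fahp_depth_mV=self.fahp_depth,
                          fahp_decay_ms=self.fahp_decay_ms)


RHEOBASE_STEP_PA = 5.0
SUPRA_OFFSET_PA = 115.0      # first F/I step relative to rheobase
SUPRA_STEP_PA = 50.0
N_SUPRA = 3


def simulate_cell(params: CellParams, *, cell_id: str = "cell",
                  animal_id: str = "animal", group_label: str = "group",
                  holding_mV: float = -79.0, noise_sd: float = 0.0,
                  seed: int = 0, sample_khz: float = DEFAULT_SAMPLE_KHZ,
                  onset_ms: float = DEFAULT_ONSET_MS,
                  step_ms: float = DEFAULT_STEP_MS,
                  tail_ms: float = DEFAULT_TAIL_MS,
                  ) -> tuple[StepProtocol, dict]:
    """Full current-clamp protocol for one cell, with its ground-truth row.

    The protocol contains: a zero-current sweep and small negative steps
    (−5 to −20 pA) from rest; a sag step sized to hyperpolarize the held cell
    by 20 mV; a 5 pA rheobase ladder from the holding level; and ``N_SUPRA``
    suprathreshold F/I steps (50 pA apart) carrying full spike trains.
    Initial frequency follows the programmed linear F/I relation
    ``f(I) = initial_hz + fi_gain · (I − I_supra1)`` on every spiking sweep,
    so the OLS F/I slope equals ``fi_gain`` up to grid snapping.
    """
    dt = 1.0 / sample_khz
    rng = np.random.default_rng(seed)
    offset_ms = onset_ms + step_ms
    duration = offset_ms + tail_ms
    p = params
    rheobase = RHEOBASE_STEP_PA * math.ceil(
        p.threshold_current_pA / RHEOBASE_STEP_PA)
    supra = [rheobase + SUPRA_OFFSET_PA + SUPRA_STEP_PA * k
             for k in range(N_SUPRA)]
    template = p.template().snapped(dt)
    passive = PassiveGroundTruth(rmp=p.rmp, rin=p.rin, tau_m=p.tau_m,
                                 sag_mV=p.sag_mV, noise_sd=noise_sd, seed=seed)

    def rc(amp: float, *, baseline: float, holding: float,
           sag: float = 0.0) -> Sweep:
        sw = _rc_sweep(baseline_mV=baseline, rin=p.rin, tau_m=p.tau_m,
                       step_pA=amp, onset_ms=onset_ms, offset_ms=offset_ms,
                       duration_ms=duration, dt_ms=dt, sample_khz=sample_khz,
                       holding_pA=holding, sag_mV=sag)
        if noise_sd:
            sw = replace(sw, v=sw.v + band_limited_noise(
                rng, sw.n_samples, noise_sd, dt))
        return sw

    def spiking(amp: float, init_hz: float) -> tuple[Sweep, SpikingTruth]:
        sched = make_train_schedule(
            initial_hz=init_hz, adaptation_ratio=p.adaptation_ratio,
            window_ms=step_ms, amplitude_mV=p.ap_amplitude,
            accommodation=p.accommodation, mahp_depth_mV=p.mahp_depth,
            mahp_decay_ms=p.mahp_decay_ms)
        return make_spiking_sweep(template, sched, passive, amp,
                                  holding_mV=holding_mV, onset_ms=onset_ms,
                                  step_ms=step_ms, tail_ms=tail_ms,
                                  sample_khz=sample_khz, rng=rng)

    hold_pA = (holding_mV - p.rmp) / p.rin * 1000.0
    sag_amp = -20.0 * 1000.0 / p.rin
    f_of = lambda amp: p.initial_hz + p.fi_gain * (amp - supra[0])
    # near rheobase the F/I relation flattens; clamp to a 20 Hz floor (the
    # emitted F/I-slope truth is computed from the actual programmed points)
    f_rheo = max(f_of(rheobase), 20.0)

    sweeps = [rc(0.0, baseline=p.rmp, holding=0.0),
              rc(-5.0, baseline=p.rmp, holding=0.0),
              rc(-10.0, baseline=p.rmp, holding=0.0),
              rc(-15.0, baseline=p.rmp, holding=0.0),
              rc(-20.0, baseline=p.rmp, holding=0.0),
              rc(sag_amp, baseline=holding_mV, holding=hold_pA,
                 sag=p.sag_mV)]
    # rheobase ladder: subthreshold RC deflections, then the first spiking step
    amp = RHEOBASE_STEP_PA
    while amp < rheobase:
        sweeps.append(rc(amp, baseline=holding_mV, holding=hold_pA))
        amp += RHEOBASE_STEP_PA
    rheo_sweep, rheo_truth = spiking(rheobase, f_rheo)
    sweeps.append(rheo_sweep)
    supra_truths: list[SpikingTruth] = []
    for s_amp in supra:
        sw, tr = spiking(s_amp, f_of(s_amp))
        sweeps.append(sw)
        supra_truths.append(tr)

    protocol = StepProtocol(cell_id=cell_id, animal_id=animal_id,
                            group_label=group_label, sweeps=sweeps,
                            holding_potential_mV=holding_mV)

    # analysis-sweep rule on the programmed train features (closed form)
    qualifying = [k for k, tr in enumerate(supra_truths)
                  if tr.initial_hz > 150.0 and tr.n_spikes >= 100]
    if qualifying:
        k_sel, qualifies = qualifying[0], True
    else:
        k_sel = int(np.argmax([tr.n_spikes for tr in supra_truths]))
        qualifies = False
    sel = supra_truths[k_sel]

    fi_points = [(rheobase, rheo_truth.initial_hz)] + [
        (a, tr.initial_hz) for a, tr in zip(supra, supra_truths)]
    fi_slope = float(np.polyfit(*zip(*fi_points), 1)[0])

    truth = {
        "cell_id": cell_id, "animal_id": animal_id, "group_label": group_label,
        "is_fs": p.is_fs,
        "rmp": p.rmp, "rin": p.rin, "tau_m": p.tau_m,
        "cin": 1000.0 * p.tau_m / p.rin, "sag": p.sag_mV,
        "rheobase_pA": rheobase,
        "v_threshold": rheo_truth.takeoff_mV[0],
        "ap_amplitude": rheo_truth.amplitudes_mV[0],
        "half_width": template.half_width_ms,
        "max_rise": rheo_truth.max_rise, "max_decay": rheo_truth.max_decay,
        "fahp": rheo_truth.fahp_mV[0],
        "initial_hz": sel.initial_hz, "steady_hz": sel.steady_hz,
        "adaptation_ratio": sel.adaptation_ratio,
        "accommodation": sel.accommodation,
        "mahp": sel.mahp_mV, "fi_slope": fi_slope,
        "n_aps_analysis": sel.n_spikes, "qualifies": qualifies,
        "analysis_step_pA": supra[k_sel],
    }
    return protocol, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal parameter distribution (clipped at ±2.5 SD)."""

    mean: float
    sd: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        x = rng.normal(self.mean, self.sd)
        return float(np.clip(x, self.mean - 2.5 * self.sd,
                             self.mean + 2.5 * self.sd))


#: Distribution field names drawn per cell (all other CellParams fixed).
_CELL_FIELDS = ("rmp", "rin", "tau_m", "sag_mV", "v_threshold", "ap_amplitude",
                "half_width_ms", "fahp_depth", "threshold_current_pA",
                "initial_hz", "fi_gain", "adaptation_ratio", "accommodation",
                "mahp_depth")


@dataclass(frozen=True)
class CellDistributions:
    """Per-class distributions over CellParams fields."""

    dists: dict[str, ParamDist]
    is_fs: bool = True

    def sample(self, rng: np.random.Generator) -> CellParams:
        kw = {name: d.sample(rng) for name, d in self.dists.items()}
        return CellParams(is_fs=self.is_fs, **kw)

    def mean_cell(self) -> CellParams:
        return CellParams(is_fs=self.is_fs,
                          **{n: d.mean for n, d in self.dists.items()})

    def with_offsets(self, offsets: dict[str, float],
                     sd_overrides: dict[str, float] | None = None,
                     ) -> "CellDistributions":
        dists = dict(self.dists)
        for name, delta in offsets.items():
            d = dists[name]
            dists[name] = ParamDist(d.mean + delta, d.sd)
        for name, sd in (sd_overrides or {}).items():
            dists[name] = ParamDist(dists[name].mean, sd)
        return CellDistributions(dists=dists, is_fs=self.is_fs)


def make_fs_and_nonfs_presets() -> tuple[CellDistributions, CellDistributions]:
    """Cell-parameter presets straddling the fast-spiking classifier rule.

    The FS preset means (APHW 0.20 ms, fAHP 20 mV, AR 0.75) satisfy all
    three classifier conditions; the non-FS means (0.50 ms, 10 mV, 0.35)
    satisfy none.  SDs are margin/4.5, so each condition is cleared or
    violated with probability > 0.999 per cell.
    """
    fs = CellDistributions(is_fs=True, dists={
        "rmp": ParamDist(-66.0, 3.0),
        "rin": ParamDist(150.0, 25.0),
        "tau_m": ParamDist(10.0, 1.5),
        "sag_mV": ParamDist(2.0, 0.6),
        "v_threshold": ParamDist(-41.0, 1.5),
        "ap_amplitude": ParamDist(62.0, 4.0),
        "half_width_ms": ParamDist(0.20, 0.06 / 4.5),
        "fahp_depth": ParamDist(20.0, 3.5 / 4.5),
        "threshold_current_pA": ParamDist(33.0, 8.0),
        "initial_hz": ParamDist(200.0, 12.0),
        "fi_gain": ParamDist(1.2, 0.15),
        "adaptation_ratio": ParamDist(0.75, 0.19 / 4.5),
        "accommodation": ParamDist(0.92, 0.03),
        "mahp_depth": ParamDist(7.0, 1.2),
    })
    nonfs = CellDistributions(is_fs=False, dists={
        "rmp": ParamDist(-63.0, 3.0),
        "rin": ParamDist(250.0, 40.0),
        "tau_m": ParamDist(20.0, 3.0),
        "sag_mV": ParamDist(3.5, 1.0),
        "v_threshold": ParamDist(-42.0, 1.5),
        "ap_amplitude": ParamDist(70.0, 5.0),
        "half_width_ms": ParamDist(0.50, 0.24 / 4.5),
        "fahp_depth": ParamDist(10.0, 6.5 / 4.5),
        "threshold_current_pA": ParamDist(25.0, 7.0),
        "initial_hz": ParamDist(110.0, 10.0),
        "fi_gain": ParamDist(0.6, 0.1),
        "adaptation_ratio": ParamDist(0.35, 0.21 / 4.5),
        "accommodation": ParamDist(0.80, 0.04),
        "mahp_depth": ParamDist(4.0, 0.8),
    })
    return fs, nonfs


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of a simulated cohort."""

    n_animals: int
    cells_per_animal: int
    fraction_fs: float
    fs: CellDistributions
    nonfs: CellDistributions

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_fs <= 1.0:
            raise GeneratorError("fraction_fs must lie in [0, 1]")
        if self.n_animals < 1 or self.cells_per_animal < 1:
            raise GeneratorError("need at least one animal and one cell")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group (or more) cohort specification with seeded randomness."""

    groups: dict[str, GroupSpec]
    seed: int = 0
    noise_sd: float = 0.1
    sample_khz: float = DEFAULT_SAMPLE_KHZ
    holding_mV: float = -79.0


def paper_matched_cohort(seed: int = 0, *, noise_sd: float = 0.1,
                         cells_per_animal: int = 4,
                         n_animals: int | None = None,
                         sample_khz: float = DEFAULT_SAMPLE_KHZ) -> CohortSpec:
    """Cohort emulating the WT-hTSC1 vs S403L fast-spiking comparison.

    FS fAHP and mAHP means/SDs follow the published summaries
    (fAHP 23.7 vs 20.1 mV with SDs back-computed from SEM·√n ≈ 3.0/2.1;
    mAHP 7.2 vs 5.2 mV, SDs ≈ 1.5/1.0); adaptation-ratio means 0.61 vs 0.75;
    classified-FS fractions target 45% vs 56%.
    """
    fs, nonfs = make_fs_and_nonfs_presets()
    wt_fs = fs.with_offsets(
        {"fahp_depth": 23.7 - 20.0, "mahp_depth": 7.2 - 7.0,
         "adaptation_ratio": 0.61 - 0.75},
        sd_overrides={"fahp_depth": 3.0, "mahp_depth": 1.5,
                      "adaptation_ratio": 0.05})
    s403l_fs = fs.with_offsets(
        {"fahp_depth": 20.1 - 20.0, "mahp_depth": 5.2 - 7.0},
        sd_overrides={"fahp_depth": 0.8 * math.sqrt(7),
                      "mahp_depth": 0.4 * math.sqrt(6),
                      "adaptation_ratio": 0.05})
    groups = {
        "WT_hTSC1": GroupSpec(n_animals=n_animals or 5,
                              cells_per_animal=cells_per_animal,
                              fraction_fs=0.45, fs=wt_fs, nonfs=nonfs),
        "S403L": GroupSpec(n_animals=n_animals or 4,
                           cells_per_animal=cells_per_animal,
                           fraction_fs=0.5625, fs=s403l_fs, nonfs=nonfs),
    }
    return CohortSpec(groups=groups, seed=seed, noise_sd=noise_sd,
                      sample_khz=sample_khz)


def simulate_cohort(spec: CohortSpec,
                    ) -> tuple[list[StepProtocol], pd.DataFrame]:
    """Hierarchical cohort simulation: group → animal → cell → sweeps.

    Returns full protocols for every cell plus the ground-truth table.
    Reproducible bit-for-bit for a fixed spec (seeds are spawned from
    ``spec.seed`` per cell).
    """
    root = np.random.SeedSequence(spec.seed)
    protocols: list[StepProtocol] = []
    rows: list[dict] = []
    for g_idx, (label, group) in enumerate(sorted(spec.groups.items())):
        for a in range(group.n_animals):
            animal_id = f"{label}_m{a + 1}"
            for c in range(group.cells_per_animal):
                ss = np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(g_idx, a, c))
                rng = np.random.default_rng(ss)
                is_fs = rng.random() < group.fraction_fs
                dists = group.fs if is_fs else group.nonfs
                params = dists.sample(rng)
                cell_seed = int(ss.generate_state(1)[0] % (2 ** 31))
                protocol, truth = simulate_cell(
                    params, cell_id=f"{animal_id}_c{c + 1}",
                    animal_id=animal_id, group_label=label,
                    holding_mV=spec.holding_mV, noise_sd=spec.noise_sd,
                    seed=cell_seed, sample_khz=spec.sample_khz)
                protocols.append(protocol)
                rows.append(truth)
    return protocols, pd.DataFrame(rows)
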