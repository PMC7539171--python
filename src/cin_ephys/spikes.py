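"""Action-potential detection and per-AP features.

Detection uses the derivative criterion: a spike threshold is the first
sample at which dV/dt (central differences) exceeds 10 mV/ms on an upward
crossing.  Two acceptance guards reject noise transients: the voltage must
rise at least 20 mV above the crossing value before dV/dt returns below
zero, and accepted events within 1 ms of each other are merged.  Both
guards are configuration keys; the bare derivative criterion alone would
fire on noise.

Per-AP features: amplitude is peak minus threshold; the half-width is the
time between the rising and falling crossings of the half-height
(threshold + amplitude/2), each located by linear interpolation between
adjacent samples; max rise/decay are the extrema of dV/dt between threshold
and the end of the falling phase; the fAHP is threshold minus the trough
immediately after the spike (within 10 ms, bounded by the next AP and the
step offset), flagged absent when no trough falls below threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._signal import fitted_value_at, refined_min, smoothed
from .traces import Sweep


class SpikeDetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    """Spike-detection and measurement settings (times in ms, rates mV/ms)."""

    dvdt_threshold: float = 10.0
    rise_guard_mV: float = 20.0
    refractory_ms: float = 1.0
    derivative_smooth_n: int = 1       # optional 3-point smoothing: set 3
    peak_window_ms: float = 5.0
    fahp_window_ms: float = 10.0
    threshold_fit_ms: float = 8.0      # pre-threshold line-fit span on the
                                       # flat approach before a first spike
    train_threshold_fit_ms: float = 1.0  # span for later spikes, where the
                                         # interspike recovery is curved
    trough_smooth_ms: float = 0.3      # fAHP trough argmin smoothing
    trough_fit_ms: float = 0.5         # fAHP trough quadratic half-span


DEFAULT_DETECTION = DetectionConfig()


@dataclass
class APFeatures:
    """Measurements for one action potential."""

    index: int                  # ordinal within the sweep
    i_threshold: int            # sample index of the detected threshold
    t_threshold: float
    v_threshold: float
    t_peak: float = math.nan
    v_peak: float = math.nan
    amplitude: float = math.nan
    half_width: float = math.nan
    max_rise: float = math.nan
    max_decay: float = math.nan
    fahp: float | None = None
    t_fahp: float = math.nan


@dataclass
class RheobaseResult:
    rheobase_pA: float
    sweep_index: int
    first_ap: APFeatures
    n_aps: int


def _dvdt(sweep: Sweep, smooth_n: int) -> np.ndarray:
    d = np.gradient(sweep.v, sweep.dt_ms)
    return smoothed(d, smooth_n)


def detect_aps(sweep: Sweep, config: DetectionConfig = DEFAULT_DETECTION,
               ) -> list[APFeatures]:
    """Detect spike events (threshold times) in one sweep.

    Returns minimally populated :class:`APFeatures` (threshold sample and
    voltage only), ordered by time; use :func:`measure_ap` /
    :func:`measure_fahp` or :func:`extract_ap_features` to fill the rest.
    """
    if sweep.sample_khz < 5.0:
        raise SpikeDetectionError(
            f"sample rate {sweep.sample_khz} kHz too low for derivative "
            f"threshold detection")
    v = sweep.v
    d = _dvdt(sweep, config.derivative_smooth_n)
    thr = config.dvdt_threshold
    above = d > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    neg_idx = np.flatnonzero(d < 0.0)
    refractory_n = round(config.refractory_ms / sweep.dt_ms)

    events: list[APFeatures] = []
    last_accepted = -10 ** 9
    for i in crossings:
        if i - last_accepted < refractory_n:
            continue
        k = np.searchsorted(neg_idx, i)
        j_end = int(neg_idx[k]) if k < neg_idx.size else v.size - 1
        if np.max(v[i:j_end + 1]) - v[i] < config.rise_guard_mV:
            continue
        events.append(APFeatures(index=len(events), i_threshold=int(i),
                                 t_threshold=float(sweep.t[i]),
                                 v_threshold=float(v[i])))
        last_accepted = i
    return events


def measure_ap(sweep: Sweep, event: APFeatures,
               next_threshold_i: int | None = None,
               config: DetectionConfig = DEFAULT_DETECTION,
               prev_bound_i: int | None = None) -> APFeatures:
    """Fill waveform measurements for one detected event (in place).

    ``prev_bound_i`` (end of the previous AP's afterhyperpolarization)
    limits the pre-threshold line fit so it never reaches into the
    preceding spike.
    """
    v, t, dt = sweep.v, sweep.t, sweep.dt_ms
    i = event.i_threshold
    stop = min(next_threshold_i if next_threshold_i is not None else v.size,
               i + round(config.peak_window_ms / dt) + 1, v.size)
    if stop <= i + 1:
        raise SpikeDetectionError("no room to locate the AP peak before the "
                                  "next event")
    if prev_bound_i is None:
        n_back = round(config.threshold_fit_ms / dt)
    else:
        n_back = min(round(config.train_threshold_fit_ms / dt),
                     i - prev_bound_i)
    event.v_threshold = fitted_value_at(v, i, n_back)
    i_peak = i + int(np.argmax(v[i:stop]))
    event.t_peak = float(t[i_peak])
    event.v_peak = float(v[i_peak])
    event.amplitude = event.v_peak - event.v_threshold
    if event.amplitude <= 0:
        raise SpikeDetectionError("peak not found above threshold")
    half = event.v_threshold + 0.5 * event.amplitude

    def interp(j0: int, j1: int) -> float:
        # crossing of `half` between samples j0 and j1 (linear)
        f = (half - v[j0]) / (v[j1] - v[j0])
        return float(t[j0] + f * (t[j1] - t[j0]))

    up = i + int(np.argmax(v[i:i_peak + 1] >= half))
    t_up = interp(up - 1, up) if up > i else float(t[i])
    after = v[i_peak:stop]
    below = np.flatnonzero(after <= half)
    if below.size:
        dn = i_peak + int(below[0])
        t_dn = interp(dn - 1, dn)
    else:
        dn = stop - 1
        t_dn = float(t[dn])
    event.half_width = t_dn - t_up

    # falling phase ends where V returns to threshold (or the window ends)
    back = np.flatnonzero(after <= event.v_threshold)
    i_fall_end = i_peak + int(back[0]) if back.size else stop - 1
    d = np.gradient(v[max(i - 1, 0):i_fall_end + 2], dt)
    seg = d[1:-1] if i >= 1 else d[:-1]
    event.max_rise = float(np.max(seg))
    event.max_decay = float(np.min(seg))
    return event


def measure_fahp(sweep: Sweep, event: APFeatures,
                 next_threshold_i: int | None = None,
                 config: DetectionConfig = DEFAULT_DETECTION) -> APFeatures:
    """fAHP (mV, positive) for a measured AP; ``None`` when absent.

    The trough is searched from the AP peak to the earliest of the next AP
    threshold, ``fahp_window_ms`` after the peak, and the step offset; the
    value is refined with a local quadratic fit.
    """
    dt = sweep.dt_ms
    i_peak = round(event.t_peak / dt)
    i_stop = min(
        next_threshold_i if next_threshold_i is not None else sweep.n_samples,
        i_peak + round(config.fahp_window_ms / dt) + 1,
        sweep.index_at(sweep.step.offset_ms))
    if i_stop <= i_peak + 1:
        raise SpikeDetectionError("empty fAHP search window")
    v_trough, i_trough = refined_min(
        sweep.v, i_peak + 1, i_stop,
        smooth_n=max(1, round(config.trough_smooth_ms / dt)),
        fit_half_n=round(config.trough_fit_ms / dt))
    event.t_fahp = float(sweep.t[i_trough])
    depth = event.v_threshold - v_trough
    event.fahp = depth if depth > 0 else None
    return event


def extract_ap_features(sweep: Sweep,
                        config: DetectionConfig = DEFAULT_DETECTION,
                        ) -> list[APFeatures]:
    """Detect and fully measure every AP in a sweep."""
    events = detect_aps(sweep, config)
    dt = sweep.dt_ms
    prev_bound = None
    for k, ev in enumerate(events):
        nxt = events[k + 1].i_threshold if k + 1 < len(events) else None
        measure_ap(sweep, ev, nxt, config, prev_bound)
        measure_fahp(sweep, ev, nxt, config)
        if not math.isnan(ev.t_fahp):
            prev_bound = round(ev.t_fahp / dt) + round(0.8 / dt)
    return events


def aps_in_step(sweep: Sweep, events: list[APFeatures]) -> list[APFeatures]:
    """Events whose threshold time falls inside the current-step window."""
    return [e for e in events
            if sweep.step.onset_ms <= e.t_threshold < sweep.step.offset_ms]


def find_rheobase(protocol, config: DetectionConfig = DEFAULT_DETECTION,
                  ) -> RheobaseResult | None:
    """Smallest positive step evoking at least one AP, with its first AP.

    Single-AP properties for a cell are taken from the first spike of the
    rheobase sweep.  Returns ``None`` when no sweep evokes an AP (the cell
    is then excluded downstream).
    """
    for k, sweep in enumerate(protocol.sweeps):
        if sweep.step.amplitude_pA <= 0:
            continue
        events = aps_in_step(sweep, detect_aps(sweep, config))
        if events:
            first = events[0]
            nxt = events[1].i_threshold if len(events) > 1 else None
            measure_ap(sweep, first, nxt, config)
            measure_fahp(sweep, first, nxt, config)
            return RheobaseResult(rheobase_pA=sweep.step.amplitude_pA,
                                  sweep_index=k, first_ap=first,
                                  n_aps=len(events))
    return None
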