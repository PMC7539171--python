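"""Firing-train features: analysis-sweep selection, F/I slope, adaptation
ratio, spike-height accommodation and the post-train mAHP.

Conventions: instantaneous frequency is the reciprocal of an interspike
interval (Hz = 1000/ISI ms); the initial frequency of a sweep is the
reciprocal of its first ISI; the steady-state frequency is the mean
instantaneous frequency over the four ISIs spanned by the last five APs.
The analysis sweep is the first suprathreshold step whose initial frequency
exceeds 150 Hz (strict) with at least 100 APs evoked inside the step;
when no sweep qualifies the sweep with the most APs is used and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spikes import APFeatures, DetectionConfig, DEFAULT_DETECTION, aps_in_step, extract_ap_features
from .traces import StepProtocol, Sweep


class TrainFeatureError(ValueError):
    pass


@dataclass
class TrainFeatures:
    fi_slope: float = math.nan          # Hz/pA
    initial_freq: float = math.nan      # Hz
    steady_freq: float = math.nan       # Hz
    adaptation_ratio: float | None = None
    accommodation: float | None = None
    mahp: float | None = None           # mV, positive; None when absent
    analysis_sweep_index: int = -1
    qualifies: bool = False
    n_aps: int = 0


@dataclass(frozen=True)
class TrainConfig:
    min_initial_hz: float = 150.0
    min_ap_count: int = 100
    mahp_baseline_ms: float = 500.0
    mahp_search_ms: float = 500.0
    mahp_smooth_ms: float = 10.0
    mahp_fit_ms: float = 15.0
    block_drop_fraction: float = 0.5    # F/I depolarization-block exclusion


DEFAULT_TRAIN = TrainConfig()


def initial_frequency_hz(events: list[APFeatures]) -> float:
    """Reciprocal of the first interspike interval; NaN with < 2 APs."""
    if len(events) < 2:
        return math.nan
    return 1000.0 / (events[1].t_threshold - events[0].t_threshold)


def select_analysis_sweep(protocol: StepProtocol,
                          events_per_sweep: dict[int, list[APFeatures]],
                          config: TrainConfig = DEFAULT_TRAIN,
                          ) -> tuple[int, bool]:
    """Index of the analysis sweep and whether it met the selection rule."""
    candidates = [(k, ev) for k, ev in sorted(events_per_sweep.items())
                  if protocol.sweeps[k].step.amplitude_pA > 0 and ev]
    if not candidates:
        raise TrainFeatureError(
            f"protocol {protocol.cell_id!r}: no suprathreshold sweep with APs")
    for k, ev in candidates:
        f0 = initial_frequency_hz(ev)
        if f0 > config.min_initial_hz and len(ev) >= config.min_ap_count:
            return k, True
    best = max(candidates, key=lambda ke: (len(ke[1]), -ke[0]))
    return best[0], False


def compute_fi_slope(protocol: StepProtocol,
                     events_per_sweep: dict[int, list[APFeatures]],
                     config: TrainConfig = DEFAULT_TRAIN) -> float:
    """OLS slope (Hz/pA) of initial frequency against step amplitude.

    Uses every suprathreshold sweep with ≥ 2 APs.  Sweeps whose AP count
    drops by more than ``block_drop_fraction`` relative to the previous
    step (depolarization block) are excluded.
    """
    pts = []
    prev_count = None
    for k in sorted(events_per_sweep):
        sweep = protocol.sweeps[k]
        ev = events_per_sweep[k]
        if sweep.step.amplitude_pA <= 0 or len(ev) < 2:
            continue
        if prev_count is not None and len(ev) < (1 - config.block_drop_fraction
                                                 ) * prev_count:
            continue
        pts.append((sweep.step.amplitude_pA, initial_frequency_hz(ev)))
        prev_count = len(ev)
    if len(pts) < 2:
        raise TrainFeatureError(
            f"protocol {protocol.cell_id!r}: fewer than 2 usable F/I points")
    x, y = np.array(pts).T
    return float(np.polyfit(x, y, 1)[0])


def compute_adaptation_ratio(events: list[APFeatures],
                             ) -> tuple[float | None, float, float]:
    """(AR, initial Hz, steady Hz); AR None with fewer than 7 APs.

    Steady-state frequency is the mean instantaneous frequency over the four
    ISIs among the last five APs; the initial frequency is 1000 over the
    first ISI; their ratio is the adaptation ratio.
    """
    f0 = initial_frequency_hz(events)
    if len(events) < 7:
        return None, f0, math.nan
    t = np.array([e.t_threshold for e in events[-5:]])
    steady = float(np.mean(1000.0 / np.diff(t)))
    return steady / f0, f0, steady


def compute_accommodation(events: list[APFeatures]) -> float | None:
    """Amplitude of the last AP divided by the first; None with < 2 APs."""
    if len(events) < 2:
        return None
    a0, a1 = events[0].amplitude, events[-1].amplitude
    if not (a0 > 0) or math.isnan(a1):
        return None
    return a1 / a0


def measure_mahp(sweep: Sweep, config: TrainConfig = DEFAULT_TRAIN,
                 ) -> float | None:
    """Post-train medium AHP (mV, positive); None when absent.

    Baseline is the mean voltage over the 500 ms immediately before step
    onset; the trough is the minimum over a 500 ms window after step offset,
    located on a heavily smoothed copy and refined with a wide quadratic
    fit (the mAHP is a slow, flat trough).
    """
    from ._signal import refined_min

    on = sweep.step.onset_ms
    if on < config.mahp_baseline_ms - 1e-9:
        raise TrainFeatureError(
            f"pre-step baseline shorter than {config.mahp_baseline_ms} ms")
    baseline = float(np.mean(
        sweep.v[sweep.window(on - config.mahp_baseline_ms, on)]))
    dt = sweep.dt_ms
    i0 = sweep.index_at(sweep.step.offset_ms)
    i1 = min(sweep.index_at(sweep.step.offset_ms + config.mahp_search_ms) + 1,
             sweep.n_samples)
    v_min, _ = refined_min(sweep.v, i0, i1,
                           smooth_n=max(1, round(config.mahp_smooth_ms / dt)),
                           fit_half_n=round(config.mahp_fit_ms / dt))
    depth = baseline - v_min
    return depth if depth > 0 else None


def compute_train_features(protocol: StepProtocol,
                           detection: DetectionConfig = DEFAULT_DETECTION,
                           config: TrainConfig = DEFAULT_TRAIN,
                           events_per_sweep: dict[int, list[APFeatures]] | None = None,
                           ) -> TrainFeatures:
    """All train features for one protocol.

    ``events_per_sweep`` (sweep index → fully measured in-step APs) may be
    passed to reuse detections; otherwise every positive sweep is analysed.
    """
    if events_per_sweep is None:
        events_per_sweep = {}
        for k, sweep in enumerate(protocol.sweeps):
            if sweep.step.amplitude_pA > 0:
                events_per_sweep[k] = aps_in_step(
                    sweep, extract_ap_features(sweep, detection))
    out = TrainFeatures()
    k_sel, out.qualifies = select_analysis_sweep(protocol, events_per_sweep,
                                                 config)
    out.analysis_sweep_index = k_sel
    ev = events_per_sweep[k_sel]
    out.n_aps = len(ev)
    ar, f0, steady = compute_adaptation_ratio(ev)
    out.adaptation_ratio = ar
    out.initial_freq = f0
    out.steady_freq = steady
    out.accommodation = compute_accommodation(ev)
    try:
        out.mahp = measure_mahp(protocol.sweeps[k_sel], config)
    except TrainFeatureError:
        out.mahp = None
    try:
        out.fi_slope = compute_fi_slope(protocol, events_per_sweep, config)
    except TrainFeatureError:
        out.fi_slope = math.nan
    return out
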