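"""Passive membrane features: RMP, Rin, τm, Cin and sag.

Definitions (canonical units mV/pA/ms/MΩ/pF):

* RMP — mean voltage of the zero-current sweep over the pre-step baseline.
* Rin — Ohm's law on the steady-state deflection of small negative steps
  (−20 to −5 pA by default), averaged across qualifying sweeps.
* τm — single exponential ``V(t) = V_ss + A·exp(−t/τ)`` fitted to the
  averaged small-step response, starting 1 ms after step onset over a
  100–300 ms window (default 200 ms).
* Cin — 1000·τm/Rin.
* sag — steady-state voltage at the end of the designated hyperpolarizing
  step minus the peak negative potential during the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._signal import refined_min
from .traces import StepProtocol, Sweep, capacitance_pf, input_resistance_mohm


class PassiveFeatureError(ValueError):
    """Protocol lacks the sweeps a passive feature requires."""


@dataclass
class PassiveFeatures:
    rmp: float = math.nan
    rin: float = math.nan
    tau_m: float = math.nan
    cin: float = math.nan
    sag: float = math.nan
    fit_diagnostics: dict = field(default_factory=dict)


def _qualifying_sweeps(protocol: StepProtocol, lo_pA: float, hi_pA: float,
                       ) -> list[Sweep]:
    return [s for s in protocol.sweeps
            if lo_pA - 1e-9 <= s.step.amplitude_pA <= hi_pA + 1e-9]


def measure_rmp(protocol: StepProtocol, *,
                baseline_window_ms: float | None = None) -> float:
    """Resting potential from the zero-current sweep's pre-step baseline."""
    sweep = protocol.zero_sweep()
    if sweep is None:
        raise PassiveFeatureError(
            f"protocol {protocol.cell_id!r} has no zero-current sweep for RMP")
    if baseline_window_ms is None:
        sl = sweep.baseline_slice()
    else:
        sl = sweep.window(max(sweep.step.onset_ms - baseline_window_ms, 0.0),
                          sweep.step.onset_ms)
    return float(np.mean(sweep.v[sl]))


def _steady_state(sweep: Sweep, fraction: float) -> float:
    on, off = sweep.step.onset_ms, sweep.step.offset_ms
    sl = sweep.window(off - fraction * (off - on), off)
    return float(np.mean(sweep.v[sl]))


def measure_input_resistance(protocol: StepProtocol, *, lo_pA: float = -20.0,
                             hi_pA: float = -5.0,
                             steady_fraction: float = 0.2) -> float:
    """Rin (MΩ) by Ohm's law on small negative steps, averaged over sweeps.

    ΔV is the mean steady-state voltage over the last ``steady_fraction`` of
    the step window minus the sweep's own pre-step baseline.
    """
    sweeps = _qualifying_sweeps(protocol, lo_pA, hi_pA)
    if not sweeps:
        raise PassiveFeatureError(
            f"protocol {protocol.cell_id!r}: no sweep with step in "
            f"[{lo_pA}, {hi_pA}] pA for Rin")
    values = []
    for s in sweeps:
        if s.step.amplitude_pA == 0:
            raise PassiveFeatureError("ΔI = 0 in qualifying sweep")
        baseline = float(np.mean(s.v[s.baseline_slice()]))
        dv = _steady_state(s, steady_fraction) - baseline
        values.append(abs(input_resistance_mohm(dv, s.step.amplitude_pA)))
    return float(np.mean(values))


def fit_time_constant(protocol: StepProtocol, *, lo_pA: float = -20.0,
                      hi_pA: float = -5.0, fit_window_ms: float = 200.0,
                      skip_ms: float = 1.0,
                      ) -> tuple[float, dict]:
    """τm (ms) from a single-exponential fit to the averaged step response.

    The qualifying small-step sweeps are averaged pointwise; the fit window
    starts ``skip_ms`` after step onset and extends ``fit_window_ms``
    (the conventional choice is within 100–300 ms).  Returns τ and a
    diagnostics dict (window, residual RMS, flag for implausible τ).
    """
    if fit_window_ms < 1.0:
        raise PassiveFeatureError("fit window must be at least 1 ms")
    sweeps = _qualifying_sweeps(protocol, lo_pA, hi_pA)
    if not sweeps:
        raise PassiveFeatureError(
            f"protocol {protocol.cell_id!r}: no qualifying sweep for τm")
    ref = sweeps[0]
    v_mean = np.mean([s.v for s in sweeps], axis=0)
    on = ref.step.onset_ms
    sl = ref.window(on + skip_ms, min(on + skip_ms + fit_window_ms,
                                      ref.step.offset_ms))
    t = ref.t[sl] - on
    y = v_mean[sl]

    # log-linear initialization on the decaying part of the deflection
    v_ss0 = float(np.mean(v_mean[ref.window(ref.step.offset_ms - 0.2 *
                                            (ref.step.offset_ms - on),
                                            ref.step.offset_ms)]))
    resid0 = y - v_ss0
    sign = -1.0 if resid0[0] < 0 else 1.0
    usable = sign * resid0 > max(1e-6, 0.05 * abs(resid0[0]))
    if usable.sum() >= 5:
        coef = np.polyfit(t[usable], np.log(sign * resid0[usable]), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else fit_window_ms / 5.0
        a0 = sign * math.exp(coef[1])
    else:
        tau0, a0 = fit_window_ms / 5.0, resid0[0]

    def model(tt, v_ss, a, tau):
        return v_ss + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(v_ss0, a0, max(tau0, 0.1)),
                            bounds=([-200.0, -100.0, 1e-3],
                                    [50.0, 100.0, 1e3]),
                            xtol=1e-8, ftol=1e-8, maxfev=2000)
    except RuntimeError as exc:
        raise PassiveFeatureError(
            f"τm fit failed to converge for {protocol.cell_id!r}: {exc}"
        ) from exc
    tau = float(popt[2])
    rms = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    diagnostics = {
        "fit_window_ms": (float(on + skip_ms),
                          float(on + skip_ms + fit_window_ms)),
        "residual_rms_mV": rms,
        "n_sweeps_averaged": len(sweeps),
        "flagged": not (0.5 < tau < 100.0),
    }
    return tau, diagnostics


def compute_capacitance(tau_m_ms: float, rin_mohm: float) -> float:
    """Cin (pF) = 1000 · τm / Rin."""
    return capacitance_pf(tau_m_ms, rin_mohm)


def measure_sag(protocol: StepProtocol, *, steady_window_ms: float = 100.0,
                trough_smooth_ms: float = 2.0,
                trough_mean_ms: float = 1.0) -> float:
    """Sag (mV): steady-state at step end minus peak negative potential.

    Measured on the most hyperpolarizing sweep (the designated sag step).
    The trough is located on a heavily smoothed copy and read as a short
    local mean, since sag troughs are tens of milliseconds wide.
    """
    sweep = protocol.sweeps[0]
    if sweep.step.amplitude_pA >= 0:
        raise PassiveFeatureError(
            f"protocol {protocol.cell_id!r} has no hyperpolarizing sweep")
    sl = sweep.step_slice()
    dt = sweep.dt_ms
    v_min, _ = refined_min(sweep.v, sl.start, sl.stop,
                           smooth_n=max(1, round(trough_smooth_ms / dt)),
                           local_mean_n=round(trough_mean_ms / dt))
    v_ss = float(np.mean(
        sweep.v[sweep.window(sweep.step.offset_ms - steady_window_ms,
                             sweep.step.offset_ms)]))
    return max(v_ss - v_min, 0.0)


def compute_passive_features(protocol: StepProtocol, *, lo_pA: float = -20.0,
                             hi_pA: float = -5.0,
                             fit_window_ms: float = 200.0,
                             steady_fraction: float = 0.2,
                             sag_steady_window_ms: float = 100.0,
                             ) -> PassiveFeatures:
    """All passive features for one protocol (missing pieces become NaN)."""
    out = PassiveFeatures()
    try:
        out.rmp = measure_rmp(protocol)
    except PassiveFeatureError:
        pass
    try:
        out.rin = measure_input_resistance(protocol, lo_pA=lo_pA, hi_pA=hi_pA,
                                           steady_fraction=steady_fraction)
        out.tau_m, out.fit_diagnostics = fit_time_constant(
            protocol, lo_pA=lo_pA, hi_pA=hi_pA, fit_window_ms=fit_window_ms)
        out.cin = compute_capacitance(out.tau_m, out.rin)
    except PassiveFeatureError:
        pass
    try:
        out.sag = measure_sag(protocol, steady_window_ms=sag_steady_window_ms)
    except PassiveFeatureError:
        pass
    return out
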