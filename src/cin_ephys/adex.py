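"""Adaptive exponential integrate-and-fire (AdEx) current-step simulator.

A secondary realism layer: unlike the template generator, AdEx dynamics
have no closed-form ground truth, so these traces are used for qualitative
and convergence checks only.  The two-variable model

    C dV/dt = −gL (V − EL) + gL ΔT exp((V − VT)/ΔT) + I − w
    τw dw/dt = a (V − EL) − w

is integrated with explicit Euler at the sweep sample rate; when V crosses
the numerical spike ceiling, V resets to Vr, w jumps by b, and the spike is
painted with an :class:`~cin_ephys.synth.APTemplate` waveform so the trace
looks like a recording rather than a sawtooth.  Deterministic for a fixed
seed (noise optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synth import APTemplate, GeneratorError, band_limited_noise
from .traces import CurrentStep, StepProtocol, Sweep


@dataclass(frozen=True)
class AdExParams:
    """AdEx parameters in canonical units (pF, nS, mV, ms, pA)."""

    c_pF: float = 100.0
    g_leak_nS: float = 8.0
    e_leak_mV: float = -79.0
    v_thresh_mV: float = -48.0      # exponential takeoff VT
    delta_t_mV: float = 2.0         # slope factor
    a_nS: float = 0.0               # subthreshold adaptation coupling
    tau_w_ms: float = 100.0
    b_pA: float = 0.0               # spike-triggered adaptation increment
    v_reset_mV: float = -60.0
    v_ceiling_mV: float = 0.0       # numerical spike cut

    @property
    def tau_m_ms(self) -> float:
        return self.c_pF / self.g_leak_nS

    @property
    def rin_mohm(self) -> float:
        return 1000.0 / self.g_leak_nS


def adex_spike_times(params: AdExParams, step_pA: float, *,
                     onset_ms: float, offset_ms: float, duration_ms: float,
                     dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Euler integration; returns (voltage trace, spike times in ms).

    Raises on an unstable integration step (dt ≥ τm/10 or dt ≥ τw/10).
    """
    p = params
    if dt_ms >= 0.1 * min(p.tau_m_ms, p.tau_w_ms):
        raise GeneratorError(
            f"integration step {dt_ms} ms too coarse for τm={p.tau_m_ms}, "
            f"τw={p.tau_w_ms}")
    n = round(duration_ms / dt_ms) + 1
    v = np.empty(n)
    v[0] = p.e_leak_mV
    w = 0.0
    spikes = []
    i_on = round(onset_ms / dt_ms)
    i_off = round(offset_ms / dt_ms)
    vk = p.e_leak_mV
    for k in range(1, n):
        i_inj = step_pA if i_on <= k - 1 < i_off else 0.0
        exp_arg = min((vk - p.v_thresh_mV) / p.delta_t_mV, 30.0)
        dv = (-p.g_leak_nS * (vk - p.e_leak_mV)
              + p.g_leak_nS * p.delta_t_mV * math.exp(exp_arg)
              + i_inj - w) / p.c_pF
        dw = (p.a_nS * (vk - p.e_leak_mV) - w) / p.tau_w_ms
        vk = vk + dt_ms * dv
        w = w + dt_ms * dw
        if vk >= p.v_ceiling_mV:
            spikes.append(k * dt_ms)
            vk = p.v_reset_mV
            w += p.b_pA
        v[k] = vk
    return v, np.asarray(spikes)


def simulate_adex_cell(params: AdExParams, steps_pA, *,
                       template: APTemplate | None = None,
                       cell_id: str = "adex", animal_id: str = "adex",
                       group_label: str = "adex",
                       onset_ms: float = 600.0, step_ms: float = 1000.0,
                       tail_ms: float = 400.0, sample_khz: float = 50.0,
                       noise_sd: float = 0.0, seed: int = 0) -> StepProtocol:
    """AdEx responses to a family of current steps, spikes painted with a
    template waveform at each reset.  Approximate by construction (no
    closed-form ground truth); deterministic for a fixed seed.
    """
    dt = 1.0 / sample_khz
    offset_ms = onset_ms + step_ms
    duration = offset_ms + tail_ms
    rng = np.random.default_rng(seed)
    if template is None:
        template = APTemplate(v_threshold=params.v_thresh_mV)
    template = template.snapped(dt)
    r_n = round(template.rise_ms / dt)
    f_n = round(template.fall_ms / dt)
    sweeps = []
    for amp in sorted(steps_pA):
        v, spikes = adex_spike_times(params, amp, onset_ms=onset_ms,
                                     offset_ms=offset_ms,
                                     duration_ms=duration, dt_ms=dt)
        for ts in spikes:
            i0 = round(ts / dt)
            v_to = v[max(i0 - 1, 0)]
            peak = v_to + template.amplitude_mV
            hi = min(i0 + r_n + f_n, v.size - 1)
            wave = np.concatenate([np.linspace(v_to, peak, r_n + 1),
                                   np.linspace(peak, v_to, f_n + 1)[1:]])
            v[i0:hi + 1] = wave[:hi + 1 - i0]
        if noise_sd:
            v = v + band_limited_noise(rng, v.size, noise_sd, dt)
        t = np.arange(v.size) * dt
        sweeps.append(Sweep(t=t, v=v,
                            step=CurrentStep(amp, onset_ms, offset_ms),
                            holding_pA=0.0, sample_khz=sample_khz))
    return StepProtocol(cell_id=cell_id, animal_id=animal_id,
                        group_label=group_label, sweeps=sweeps,
                        holding_potential_mV=params.e_leak_mV)
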