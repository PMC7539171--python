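"""Independent oracles used by the test suite.

These deliberately use plain loops / enumeration / closed forms and share no
code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_detect(v: np.ndarray, dt_ms: float, *,
                       dvdt_threshold: float = 10.0,
                       rise_guard_mV: float = 20.0,
                       refractory_ms: float = 1.0) -> list[int]:
    """Exhaustive spike scan: upward dV/dt crossings with rise/refractory
    guards, evaluated sample by sample with explicit loops."""
    n = v.size
    d = np.empty(n)
    d[0] = (v[1] - v[0]) / dt_ms
    d[-1] = (v[-1] - v[-2]) / dt_ms
    for i in range(1, n - 1):
        d[i] = (v[i + 1] - v[i - 1]) / (2.0 * dt_ms)
    refr = round(refractory_ms / dt_ms)
    out: list[int] = []
    last = -10 ** 9
    for i in range(1, n):
        if not (d[i] > dvdt_threshold and d[i - 1] <= dvdt_threshold):
            continue
        if i - last < refr:
            continue
        j = i
        vmax = v[i]
        while j < n and d[j] >= 0.0:
            if v[j] > vmax:
                vmax = v[j]
            j += 1
        if j < n and v[j] > vmax:
            vmax = v[j]
        if vmax - v[i] >= rise_guard_mV:
            out.append(i)
            last = i
    return out


def mann_whitney_p_enumeration(x, y) -> float:
    """Exact two-sided Mann–Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(x_idx: tuple[int, ...]) -> float:
        xs = [pooled[i] for i in x_idx]
        ys = [pooled[i] for i in idx if i not in x_idx]
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in combinations(idx, n1)]
    n = len(us)
    mean_u = len(x) * len(y) / 2.0
    dev = abs(u_obs - mean_u)
    p = sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / n
    return min(p, 1.0)


def loglinear_tau(t_ms: np.ndarray, v: np.ndarray, v_ss: float) -> float:
    """τ from log-linear regression on a noiseless exponential decay."""
    resid = v - v_ss
    sign = -1.0 if resid[0] < 0 else 1.0
    keep = sign * resid > 1e-9
    slope = np.polyfit(t_ms[keep], np.log(sign * resid[keep]), 1)[0]
    return -1.0 / slope
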