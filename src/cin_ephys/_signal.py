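"""Noise-robust local estimators shared by the feature modules.

Single-sample reads of extrema are biased under noise (the minimum of n
noisy samples sits ~sd·√(2 ln n) below the true trace), so troughs and
threshold voltages are refined with small local least-squares fits:
unbiased on noiseless traces and nearly unbiased under band-limited noise.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d


def smoothed(v: np.ndarray, n: int) -> np.ndarray:
    """Moving-average smoothing (no-op for n <= 1)."""
    if n <= 1:
        return v
    return uniform_filter1d(v, size=int(n), mode="nearest")


def refined_min(v: np.ndarray, i0: int, i1: int, *, smooth_n: int = 1,
                fit_half_n: int = 0, local_mean_n: int = 0,
                ) -> tuple[float, int]:
    """Trough value and index within the half-open window [i0, i1).

    The argmin is located on a smoothed copy; the value is then refined on
    the raw trace either by a local quadratic fit evaluated at its vertex
    (``fit_half_n`` > 0; suited to sharp, locally parabolic troughs) or by a
    local mean (``local_mean_n`` > 0; suited to slow, flat troughs), falling
    back to the raw sample.
    """
    i0 = max(i0, 0)
    i1 = min(i1, v.size)
    if i1 <= i0:
        raise ValueError("empty trough search window")
    seg = smoothed(v[i0:i1], smooth_n)
    im = i0 + int(np.argmin(seg))
    if fit_half_n > 0:
        center = im
        result = None
        for _ in range(2):  # one recentering pass keeps the fit on the vertex
            lo = max(center - fit_half_n, i0)
            hi = min(center + fit_half_n + 1, i1)
            if hi - lo < 5:
                break
            x = np.arange(lo, hi) - center
            c = np.polyfit(x, v[lo:hi], 2)
            if c[0] <= 0:
                break
            xv = float(np.clip(-c[1] / (2.0 * c[0]), lo - center,
                               hi - 1 - center))
            result = float(np.polyval(c, xv))
            new_center = int(np.clip(center + round(xv), i0, i1 - 1))
            if new_center == center:
                break
            center = new_center
        if result is not None:
            return result, center
        return float(v[im]), im
    if local_mean_n > 0:
        lo = max(im - local_mean_n, i0)
        hi = min(im + local_mean_n + 1, i1)
        return float(np.mean(v[lo:hi])), im
    return float(v[im]), im


def fitted_value_at(v: np.ndarray, i: int, n_back: int) -> float:
    """Least-squares line over [i − n_back, i], evaluated at sample i.

    Used for the threshold voltage: on a locally linear approach this is
    exact, and under noise its variance is ~4/n of a raw sample read.
    """
    lo = max(i - n_back, 0)
    if i - lo < 4:
        return float(v[i])
    x = np.arange(lo, i + 1) - i
    c = np.polyfit(x, v[lo:i + 1], 1)
    return float(c[1])
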