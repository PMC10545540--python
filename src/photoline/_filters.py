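"""Shared low-level trace primitives.

The running percentile and moving average used throughout the pipeline are
*centred* windows truncated at the trace edges (edge bins use whatever part of
the window lies inside the trace).  Library filters (scipy.ndimage) pad edges
instead, which changes the first/last window-length of every trace, so these
two primitives are implemented directly and oracle-tested against brute force.
"""

from __future__ import annotations

import numpy as np

__all__ = ["moving_average", "running_percentile", "diff_of_exp_kernel"]


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive-exclusive [lo, hi) bounds of a centred window of ``window``
    bins at each index, truncated to [0, n).  Even windows extend one bin
    further to the right of centre."""
    idx = np.arange(n)
    left = (window - 1) // 2
    right = window // 2
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return lo, hi


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average over ``window`` bins, truncated at edges."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    n = x.size
    lo, hi = _window_bounds(n, window)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def running_percentile(x: np.ndarray, window: int, q: float,
                       chunk: int = 4096) -> np.ndarray:
    """Centred running ``q``-th percentile over ``window`` bins.

    Uses numpy's linear-interpolation percentile definition.  Interior bins
    (full window) are computed vectorised in chunks via a sliding-window view;
    edge bins with truncated windows are computed individually.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window <= 1 or n == 0:
        return x.copy()
    if window >= n:
        # every window truncates; brute force is fine at this size
        lo, hi = _window_bounds(n, window)
        return np.array([np.percentile(x[l:h], q) for l, h in zip(lo, hi)])
    out = np.empty(n)
    left = (window - 1) // 2
    right = window // 2
    # interior: indices where [i-left, i+right] fully inside.  A sorted window
    # is maintained in place (one remove + one insert = one memmove per step),
    # which is far cheaper than partitioning every window independently.
    start, stop = left, n - right - 1  # inclusive range of full-window centres
    pos = q / 100.0 * (window - 1)
    k0 = int(pos)
    k1 = min(k0 + 1, window - 1)
    frac = pos - k0
    win = np.sort(x[:window])
    out[start] = win[k0] * (1.0 - frac) + win[k1] * frac
    for i in range(start + 1, stop + 1):
        old = x[i - left - 1]
        new = x[i + right]
        if old != new:
            i_out = np.searchsorted(win, old)
            i_in = np.searchsorted(win, new)
            if i_in > i_out:
                i_in -= 1  # account for the removed element
                win[i_out:i_in] = win[i_out + 1: i_in + 1]
            else:
                win[i_in + 1: i_out + 1] = win[i_in:i_out]
            win[i_in] = new
        out[i] = win[k0] * (1.0 - frac) + win[k1] * frac
    # edges: truncated windows grow/shrink by one element per bin, so keep a
    # sorted window and insert incrementally instead of re-sorting each time
    srt = np.sort(x[: right + 1])
    out[0] = _sorted_percentile(srt, q)
    for i in range(1, start):
        srt = np.insert(srt, np.searchsorted(srt, x[i + right]), x[i + right])
        out[i] = _sorted_percentile(srt, q)
    srt = np.sort(x[n - 1 - left:])
    out[n - 1] = _sorted_percentile(srt, q)
    for i in range(n - 2, stop, -1):
        srt = np.insert(srt, np.searchsorted(srt, x[i - left]), x[i - left])
        out[i] = _sorted_percentile(srt, q)
    return out


def _sorted_percentile(sorted_arr: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of an already-sorted array."""
    m = sorted_arr.size
    pos = q / 100.0 * (m - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, m - 1)
    frac = pos - lo
    return float(sorted_arr[lo] * (1.0 - frac) + sorted_arr[hi] * frac)


def diff_of_exp_kernel(tau_rise: float, tau_decay: float, rate: float = 100.0,
                       n_bins: int | None = None) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient kernel sampled at
    ``rate`` Hz: k(t) = exp(-t/tau_decay) - exp(-t/tau_rise), scaled to peak 1.

    Returns the kernel from t = 0 out to ~8 decay constants (or ``n_bins``).
    """
    if not tau_rise < tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    if n_bins is None:
        n_bins = int(np.ceil(8.0 * tau_decay * rate))
    t = np.arange(n_bins) / rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum (closed form for difference of exponentials)."""
    return (np.log(tau_decay / tau_rise) * tau_rise * tau_decay
            / (tau_decay - tau_rise))
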