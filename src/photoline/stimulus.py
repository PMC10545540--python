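"""Reward / air-puff event selection and response quantification.

Response units are "normalized dF/F * s": the Riemann sum (bin value times
0.01 s) of the comparison-scaled dF/F trace over a 0.5-s window after the
stimulus ((+0.05, +0.55] s) minus the 0.5-s window before it ((-0.5, 0) s,
the delivery bin itself excluded from both windows).  Both windows hold 50
bins, so a constant trace yields exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .locomotion import InsufficientDataError, TriggeredAverage, triggered_average

LICK_WINDOW_S = 1.0          # reward must be consumed within this window
REST_ACCEL_WIDE = 2.5        # m/s^2 within +-0.75 s
REST_ACCEL_WIDE_WIN_S = 0.75
REST_ACCEL_NARROW = 1.5      # m/s^2 within +0.4 s
REST_ACCEL_NARROW_WIN_S = 0.4
POST_WINDOW_BINS = (6, 55)   # (+0.05, +0.55] s at 100 Hz, inclusive bin span
PRE_WINDOW_BINS = (-50, -1)  # (-0.5, 0) s, event bin excluded
DECEL_INTEGRAL_WIN_S = 0.75


@dataclass
class StimulusSelection:
    included_rewards: np.ndarray
    included_airpuffs: np.ndarray
    rest_rewards: np.ndarray
    included_reward_sizes: np.ndarray
    exclusion_reasons: dict[float, str] = field(default_factory=dict)


@dataclass
class StimResponse:
    response: float                # mean over events, normalized dF/F * s
    per_event_values: np.ndarray
    n_events: int
    variant: str = "raw"


def select_stimulus_events(rec, acceleration: np.ndarray,
                           rate: float = 100.0) -> StimulusSelection:
    """Apply the behavioral inclusion criteria to a recording's stimuli.

    Rewards count only if a lick occurs within (delivery, delivery + 1 s].
    ``rest_rewards`` additionally require no acceleration beyond +-2.5 m/s^2
    within 0.75 s either side of delivery and none beyond +-1.5 m/s^2 within
    0.4 s after it.  Air puffs carry no lick requirement.  ``rec`` is any
    object with ``lick``, ``reward_times``, ``reward_sizes``, ``airpuff_times``
    and ``bin_rate`` attributes (a DffRecording or BinnedSession).
    """
    lick = np.asarray(rec.lick, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    n = lick.size
    reasons: dict[float, str] = {}
    rewards, sizes, rest = [], [], []
    reward_sizes = np.asarray(rec.reward_sizes)
    for i, t in enumerate(np.asarray(rec.reward_times, dtype=float)):
        b = int(np.floor(t * rate + 1e-9))
        hi = min(n, b + int(LICK_WINDOW_S * rate) + 1)
        if b + 1 >= n or not np.any(lick[b + 1: hi] > 0):
            reasons[float(t)] = "no consumption"
            continue
        rewards.append(t)
        sizes.append(reward_sizes[i] if i < reward_sizes.size else "")
        wide = int(REST_ACCEL_WIDE_WIN_S * rate)
        narrow = int(REST_ACCEL_NARROW_WIN_S * rate)
        seg_wide = a[max(0, b - wide): min(n, b + wide + 1)]
        seg_narrow = a[b: min(n, b + narrow + 1)]
        if (np.all(np.abs(seg_wide) <= REST_ACCEL_WIDE)
                and np.all(np.abs(seg_narrow) <= REST_ACCEL_NARROW)):
            rest.append(t)
    return StimulusSelection(
        included_rewards=np.asarray(rewards, dtype=float),
        included_airpuffs=np.asarray(rec.airpuff_times, dtype=float).copy(),
        rest_rewards=np.asarray(rest, dtype=float),
        included_reward_sizes=np.asarray(sizes),
        exclusion_reasons=reasons,
    )


def _event_windows(n: int, t: float, rate: float) -> tuple[slice, slice] | None:
    b = int(np.floor(t * rate + 1e-9))
    pre = slice(b + PRE_WINDOW_BINS[0], b + PRE_WINDOW_BINS[1] + 1)
    post = slice(b + POST_WINDOW_BINS[0], b + POST_WINDOW_BINS[1] + 1)
    if pre.start < 0 or post.stop > n:
        return None
    return pre, post


def response_integral(dff: np.ndarray, event_times: np.ndarray,
                      variant: str = "raw", rate: float = 100.0) -> StimResponse:
    """Per-recording stimulus response (mean of per-event window integrals).

    ``variant="minmax_scaled"`` rescales each event's +-1 s triggered trace to
    [0, 1] (subtract its minimum, divide by the resulting maximum) before
    integrating, which discards amplitude and compares timecourses only.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    dt = 1.0 / rate
    values = []
    for t in np.asarray(event_times, dtype=float):
        win = _event_windows(n, t, rate)
        if win is None:
            continue
        pre, post = win
        if variant == "raw":
            values.append(dff[post].sum() * dt - dff[pre].sum() * dt)
        elif variant == "minmax_scaled":
            b = int(np.floor(t * rate + 1e-9))
            w = int(round(rate))
            if b - w < 0 or b + w + 1 > n:
                continue
            seg = dff[b - w: b + w + 1] - np.min(dff[b - w: b + w + 1])
            peak = np.max(seg)
            if peak <= 0:
                continue
            seg = seg / peak
            rel_pre = slice(w + PRE_WINDOW_BINS[0], w + PRE_WINDOW_BINS[1] + 1)
            rel_post = slice(w + POST_WINDOW_BINS[0], w + POST_WINDOW_BINS[1] + 1)
            values.append(seg[rel_post].sum() * dt - seg[rel_pre].sum() * dt)
        else:
            raise ValueError(f"unknown variant {variant!r}")
    if not values:
        raise InsufficientDataError("no stimulus events with full windows")
    values = np.asarray(values)
    return StimResponse(response=float(values.mean()),
                        per_event_values=values, n_events=values.size,
                        variant=variant)


@dataclass
class SizeContrast:
    difference: float            # large - small, normalized dF/F * s
    small: float
    large: float
    n_small: int
    n_large: int


def reward_size_contrast(dff: np.ndarray, small_times: np.ndarray,
                         large_times: np.ndarray,
                         rate: float = 100.0) -> SizeContrast:
    """Per-recording large-minus-small reward response difference."""
    small = response_integral(dff, small_times, rate=rate)
    large = response_integral(dff, large_times, rate=rate)
    return SizeContrast(difference=large.response - small.response,
                        small=small.response, large=large.response,
                        n_small=small.n_events, n_large=large.n_events)


def size_contrast_test(differences, bonferroni: int = 1) -> tuple[float, float]:
    """Group-level paired signed-rank test on per-recording differences.

    Returns (mean difference, Bonferroni-corrected two-sided p capped at 1).
    Recordings missing one size class should already be dropped by the caller.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2 or np.allclose(d, 0):
        return float(d.mean()) if d.size else np.nan, 1.0
    p = stats.wilcoxon(d, alternative="two-sided").pvalue
    return float(d.mean()), float(min(1.0, p * bonferroni))


@dataclass
class DecelSplit:
    small_average: TriggeredAverage
    large_average: TriggeredAverage
    small_response: float
    large_response: float
    small_times: np.ndarray
    large_times: np.ndarray


def deceleration_split(dff: np.ndarray, acceleration: np.ndarray,
                       event_times: np.ndarray,
                       rate: float = 100.0) -> DecelSplit:
    """Split stimuli by the size of the following deceleration.

    Deceleration size per event is the integral of the acceleration trace in
    the 0.75-s window after delivery (more negative = larger deceleration).
    Events are ranked and split in half; odd counts put the extra event in
    the smaller-deceleration half.  Returns triggered averages and mean
    response integrals per half.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size < 2:
        raise InsufficientDataError("need at least 2 events to split")
    a = np.asarray(acceleration, dtype=float)
    w = int(round(DECEL_INTEGRAL_WIN_S * rate))
    integrals = []
    for t in times:
        b = int(np.floor(t * rate + 1e-9))
        integrals.append(a[b + 1: min(a.size, b + w + 1)].sum() / rate)
    integrals = np.asarray(integrals)
    # ascending integral = most negative (largest deceleration) first
    order = np.lexsort((times, integrals))
    n_large = times.size // 2            # extra event goes to the small half
    large_idx, small_idx = order[:n_large], order[n_large:]
    small_t, large_t = times[small_idx], times[large_idx]
    return DecelSplit(
        small_average=triggered_average(dff, small_t, rate=rate),
        large_average=triggered_average(dff, large_t, rate=rate),
        small_response=response_integral(dff, small_t, rate=rate).response,
        large_response=response_integral(dff, large_t, rate=rate).response,
        small_times=small_t, large_times=large_t,
    )
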