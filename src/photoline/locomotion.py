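"""Locomotion segmentation, movement events and event-locked statistics.

All operations run on 100 Hz traces and honour a per-bin inclusion mask so
that artifact-excluded bins (and bins within 5 s after a stimulus) never
contribute to any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import moving_average

VEL_SEED_THRESH = 0.024     # m/s, movement seed threshold
VEL_EXTEND_THRESH = 0.010   # m/s, hysteresis extension threshold
BOUT_MIN_DURATION_S = 0.5
BOUT_MIN_MEAN_VEL = 0.2     # m/s
MIN_TOTAL_LOCOMOTION_S = 100.0
POST_STIMULUS_EXCLUSION_S = 5.0
ACCEL_EVENT_PEAK = 2.0      # m/s^2
ACCEL_EVENT_MIN_DURATION_S = 0.05
ACCEL_EVENT_ISOLATION_S = 0.25
ONSET_TARGET_VEL = 0.4      # m/s
ONSET_WINDOW_S = 0.75
ONSET_ACCEL_PEAK = 1.0      # m/s^2
ONSET_BACKWARD_LIMIT = -0.05  # m/s


class InsufficientDataError(ValueError):
    """Not enough usable bins or events for the requested statistic."""


@dataclass
class BoutMask:
    locomotion_mask: np.ndarray        # analysis bins (stimulus windows removed)
    bout_intervals: list[tuple[float, float]]  # [start, end) s, retained bouts
    total_locomotion: float            # s of analysis bins
    pass_total: bool                   # >= 100 s


@dataclass
class XCorr:
    lags: np.ndarray      # s
    values: np.ndarray    # Pearson r per lag
    n_bins_used: int      # included pairs at zero lag

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    @property
    def abs_peak(self) -> float:
        return float(np.max(np.abs(self.values)))


@dataclass
class EventSet:
    kind: str                 # acceleration/deceleration/onset/offset/transient_peak
    times: np.ndarray         # event (trigger) times, s
    peak_values: np.ndarray   # signed peak acceleration (or dF/F)
    peak_times: np.ndarray    # time of the extremum within the event

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TriggeredAverage:
    lags: np.ndarray
    mean_trace: np.ndarray
    per_event_matrix: np.ndarray   # n_events x n_lags, NaN on masked bins
    n_events: int


def compute_acceleration(velocity: np.ndarray, rate: float = 100.0) -> np.ndarray:
    """First difference of the 0.06-s-smoothed velocity, in m/s^2.

    The final bin is padded by repetition so the trace keeps its length.
    """
    v = moving_average(np.asarray(velocity, dtype=float), 6)
    a = np.empty_like(v)
    a[:-1] = np.diff(v) * rate
    a[-1] = a[-2] if v.size > 1 else 0.0
    return a


def segment_locomotion(velocity: np.ndarray,
                       stimulus_times: np.ndarray | None = None,
                       rate: float = 100.0) -> BoutMask:
    """Hysteresis segmentation of running bouts.

    Movement seeds where |v| exceeds 0.024 m/s and extends contiguously while
    |v| exceeds 0.010 m/s.  Isolated one-bin movements (no movement within two
    bins either side) are dropped, rests shorter than 0.5 s are merged into
    the surrounding movement, and a bout is retained only if it lasts more
    than 0.5 s with mean velocity above 0.2 m/s.  All bins within 5 s after
    any stimulus are removed from the analysis mask.
    """
    v = np.asarray(velocity, dtype=float)
    n = v.size
    absv = np.abs(v)
    moving = absv > VEL_EXTEND_THRESH
    # keep only extension runs containing at least one seed bin
    movement = np.zeros(n, dtype=bool)
    for start, stop in _runs(moving):
        if np.any(absv[start:stop] > VEL_SEED_THRESH):
            movement[start:stop] = True
    # drop isolated one-bin movements (no other movement within two bins)
    for start, stop in _runs(movement):
        if stop - start == 1:
            lo, hi = max(0, start - 2), min(n, stop + 2)
            if not (movement[lo:start].any() or movement[stop:hi].any()):
                movement[start] = False
    # merge rests shorter than 0.5 s between movement runs
    min_rest = int(round(BOUT_MIN_DURATION_S * rate))
    for start, stop in _runs(~movement):
        if start > 0 and stop < n and stop - start < min_rest:
            movement[start:stop] = True
    # bout criteria
    min_bout = int(round(BOUT_MIN_DURATION_S * rate))
    intervals: list[tuple[float, float]] = []
    retained = np.zeros(n, dtype=bool)
    for start, stop in _runs(movement):
        if stop - start > min_bout and np.mean(v[start:stop]) > BOUT_MIN_MEAN_VEL:
            intervals.append((start / rate, stop / rate))
            retained[start:stop] = True
    mask = retained & ~stimulus_exclusion_mask(stimulus_times, n, rate)
    total = float(mask.sum()) / rate
    return BoutMask(locomotion_mask=mask, bout_intervals=intervals,
                    total_locomotion=total,
                    pass_total=bool(total >= MIN_TOTAL_LOCOMOTION_S))


def stimulus_exclusion_mask(stimulus_times, n_bins: int,
                            rate: float = 100.0) -> np.ndarray:
    """True on bins within 5 s after any stimulus delivery."""
    mask = np.zeros(n_bins, dtype=bool)
    if stimulus_times is None:
        return mask
    span = int(round(POST_STIMULUS_EXCLUSION_S * rate))
    for t in np.asarray(stimulus_times, dtype=float):
        b = int(np.floor(t * rate))
        mask[max(0, b): min(n_bins, b + span + 1)] = True
    return mask


def xcorr_traces(x: np.ndarray, y: np.ndarray,
                 mask: np.ndarray | None = None,
                 max_lag_s: float = 1.0, rate: float = 100.0,
                 min_pairs: int = 100) -> XCorr:
    """Masked lagged Pearson correlation r(l) of {x[t], y[t+l]}.

    Positive lag means y follows x.  At each lag the correlation is computed
    over pairs where both bins are included, with means and s.d.s taken over
    those pairs, which keeps |r| <= 1 exactly under masking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("traces must have equal length")
    n = x.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    max_lag = int(round(max_lag_s * rate))
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(lags.size)
    n_used0 = 0
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
            ms = mask[: n - lag] & mask[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
            ms = mask[-lag:] & mask[: n + lag]
        npairs = int(ms.sum())
        if npairs < min_pairs:
            raise InsufficientDataError(
                f"only {npairs} usable pairs at lag {lag / rate:+.2f} s")
        xv, yv = xs[ms], ys[ms]
        xv = xv - xv.mean()
        yv = yv - yv.mean()
        denom = np.sqrt((xv @ xv) * (yv @ yv))
        values[i] = (xv @ yv) / denom if denom > 0 else 0.0
        if lag == 0:
            n_used0 = npairs
    return XCorr(lags=lags / rate, values=values, n_bins_used=n_used0)


def detect_accel_events(acceleration: np.ndarray,
                        mask: np.ndarray | None = None,
                        kind: str = "both", rate: float = 100.0) -> EventSet | tuple:
    """Isolated large accelerations/decelerations.

    Individual events are the intervals between consecutive zero-crossings of
    the acceleration trace; they qualify with duration of at least 0.05 s and
    a peak beyond +-2 m/s^2, and are rejected if any other beyond-threshold
    acceleration occurs within 0.25 s on either side of the interval.  Events
    whose interval leaves the inclusion mask are dropped.  Event times are the
    interval starts (the trigger points for triggered averages).
    """
    a = np.asarray(acceleration, dtype=float)
    n = a.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    pos = a > 0
    changes = np.flatnonzero(pos[1:] != pos[:-1]) + 1
    bounds = np.concatenate(([0], changes, [n]))
    iso = int(round(ACCEL_EVENT_ISOLATION_S * rate))
    min_dur = int(round(ACCEL_EVENT_MIN_DURATION_S * rate))
    big = np.abs(a) > ACCEL_EVENT_PEAK

    accel, decel = [], []
    for start, stop in zip(bounds[:-1], bounds[1:]):
        seg = a[start:stop]
        if stop - start < min_dur:
            continue
        peak_idx = start + int(np.argmax(np.abs(seg)))
        peak = a[peak_idx]
        if abs(peak) <= ACCEL_EVENT_PEAK:
            continue
        if not mask[start:stop].all():
            continue
        lo, hi = max(0, start - iso), min(n, stop + iso)
        if big[lo:start].any() or big[stop:hi].any():
            continue
        rec = (start / rate, peak, peak_idx / rate)
        (accel if peak > 0 else decel).append(rec)

    def _build(recs, kind_name):
        if recs:
            t, p, pt = map(np.asarray, zip(*recs))
        else:
            t = p = pt = np.empty(0)
        return EventSet(kind=kind_name, times=t, peak_values=p, peak_times=pt)

    if kind == "acceleration":
        return _build(accel, "acceleration")
    if kind == "deceleration":
        return _build(decel, "deceleration")
    return _build(accel, "acceleration"), _build(decel, "deceleration")


def detect_onsets_offsets(velocity: np.ndarray, acceleration: np.ndarray,
                          bouts: BoutMask, rate: float = 100.0
                          ) -> tuple[EventSet, EventSet]:
    """Clean movement onsets and offsets at bout boundaries.

    An onset requires reaching 0.4 m/s within 0.75 s of starting to move, an
    initial acceleration peak of at least 1 m/s^2 before that and no velocity
    below -0.05 m/s in between.  Offsets apply the time-reversed conditions.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    n = v.size
    win = int(round(ONSET_WINDOW_S * rate))
    onsets, offsets = [], []
    for t0, t1 in bouts.bout_intervals:
        b0, b1 = int(round(t0 * rate)), int(round(t1 * rate))
        # onset
        seg = v[b0: min(n, b0 + win + 1)]
        reach = np.flatnonzero(seg >= ONSET_TARGET_VEL)
        if reach.size:
            r = reach[0]
            if (np.max(a[b0: b0 + r + 1]) >= ONSET_ACCEL_PEAK
                    and np.min(seg[: r + 1]) > ONSET_BACKWARD_LIMIT):
                onsets.append((b0 / rate, float(np.max(a[b0: b0 + r + 1])),
                               (b0 + int(np.argmax(a[b0: b0 + r + 1]))) / rate))
        # offset (time-reversed): moving at >= 0.4 m/s within 0.75 s before
        # stopping, with a final deceleration of at least -1 m/s^2
        seg = v[max(0, b1 - win - 1): b1]
        reach = np.flatnonzero(seg >= ONSET_TARGET_VEL)
        if reach.size:
            r0 = max(0, b1 - win - 1) + reach[-1]
            if (np.min(a[r0: b1 + 1 if b1 < n else n]) <= -ONSET_ACCEL_PEAK
                    and np.min(v[r0: b1]) > ONSET_BACKWARD_LIMIT):
                offsets.append((b1 / rate, float(np.min(a[r0: b1])),
                                (r0 + int(np.argmin(a[r0: b1]))) / rate))

    def _build(recs, kind):
        if recs:
            t, p, pt = map(np.asarray, zip(*recs))
        else:
            t = p = pt = np.empty(0)
        return EventSet(kind=kind, times=t, peak_values=p, peak_times=pt)

    return _build(onsets, "onset"), _build(offsets, "offset")


def triggered_average(trace: np.ndarray, event_times: np.ndarray,
                      mask: np.ndarray | None = None,
                      window_s: tuple[float, float] = (-1.0, 1.0),
                      rate: float = 100.0) -> TriggeredAverage:
    """Event-locked average of a trace over a +-1 s window.

    Events without a full window inside the recording are dropped; masked
    bins propagate as missing and are ignored in the column means.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    lo = int(round(window_s[0] * rate))
    hi = int(round(window_s[1] * rate))
    lags = np.arange(lo, hi + 1)
    rows = []
    for t in np.asarray(event_times, dtype=float):
        b = int(np.floor(t * rate + 1e-9))
        if b + lo < 0 or b + hi >= n:
            continue
        row = trace[b + lo: b + hi + 1].astype(float).copy()
        row[~mask[b + lo: b + hi + 1]] = np.nan
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no events with a full window")
    per_event = np.vstack(rows)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # a fully-masked column legitimately yields NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_event, axis=0)
    return TriggeredAverage(lags=lags / rate, mean_trace=mean,
                            per_event_matrix=per_event, n_events=len(rows))


# ---------------------------------------------------------------------------
# quintile / tuning / follow-fraction analyses
# ---------------------------------------------------------------------------

@dataclass
class QuintileResult:
    averages: list[TriggeredAverage]
    amplitudes: np.ndarray        # per-quintile transient amplitude
    group_sizes: np.ndarray
    percent_change: float         # Q5/Q1 amplitude ratio, in percent

    @property
    def ratio(self) -> float:
        return self.percent_change / 100.0


def quintile_split(order_values: np.ndarray, times: np.ndarray,
                   n_groups: int = 5) -> list[np.ndarray]:
    """Rank events by value (ties broken by time) and split into equal-count
    groups; a remainder of r gives one extra event to each of the r lowest
    groups."""
    n = order_values.size
    order = np.lexsort((times, order_values))
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    groups, at = [], 0
    for s in sizes:
        groups.append(order[at: at + s])
        at += s
    return groups


def quintile_analysis(events: EventSet, dff: np.ndarray,
                      mask: np.ndarray | None = None,
                      rate: float = 100.0) -> QuintileResult:
    """Transient amplitude as a function of movement-event size.

    Events are ranked by absolute peak acceleration into five equal-count
    groups.  Each group's amplitude is the maximum of its triggered-average
    dF/F in the (0, 1] s window after the trigger minus the value at t = 0.
    """
    if len(events) < 5:
        raise InsufficientDataError("need at least 5 events for quintiles")
    groups = quintile_split(np.abs(events.peak_values), events.times)
    averages, amps, sizes = [], [], []
    for grp in groups:
        ta = triggered_average(dff, events.times[grp], mask=mask, rate=rate)
        averages.append(ta)
        t0 = int(np.argmin(np.abs(ta.lags)))
        post = ta.mean_trace[t0 + 1:]
        amps.append(float(np.nanmax(post) - ta.mean_trace[t0]))
        sizes.append(len(grp))
    amps = np.asarray(amps)
    pct = float(amps[-1] / amps[0] * 100.0) if amps[0] != 0 else np.nan
    return QuintileResult(averages=averages, amplitudes=amps,
                          group_sizes=np.asarray(sizes), percent_change=pct)


VELOCITY_BIN_EDGES = np.concatenate([np.arange(-0.05, 0.751, 0.1), [np.inf]])


def velocity_tuning(dff: np.ndarray, velocity: np.ndarray,
                    mask: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean dF/F per 0.1 m/s velocity bin (edges -0.05:0.1:0.75, then inf).

    Returns (bin_edges, means); empty bins are NaN.
    """
    dff = np.asarray(dff, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if mask is None:
        mask = np.ones(v.size, dtype=bool)
    edges = VELOCITY_BIN_EDGES
    means = np.full(edges.size - 1, np.nan)
    which = np.digitize(v, edges) - 1
    for b in range(edges.size - 1):
        sel = mask & (which == b)
        if sel.any():
            means[b] = float(dff[sel].mean())
    return edges, means


def event_follow_fraction(dff: np.ndarray, event_times: np.ndarray,
                          mask: np.ndarray | None = None,
                          window_s: float = 0.75,
                          rate: float = 100.0) -> float:
    """Fraction of events whose 0.75-s post-event dF/F integral (after
    subtracting the value at t = 0) is positive — the event-follow metric.

    Note this raw fraction has a ~0.5 floor for events never followed by a
    transient; see ``estimate_follow_probability`` for a debiased estimate.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    w = int(round(window_s * rate))
    vals = []
    for t in np.asarray(event_times, dtype=float):
        b = int(np.floor(t * rate + 1e-9))
        if b < 0 or b + w >= n or not mask[b: b + w + 1].all():
            continue
        seg = dff[b: b + w + 1] - dff[b]
        vals.append(np.sum(seg[1:]) / rate)
    if not vals:
        raise InsufficientDataError("no usable events for follow fraction")
    return float(np.mean(np.asarray(vals) > 0))


def estimate_follow_probability(dff: np.ndarray, event_times: np.ndarray,
                                mask: np.ndarray, rng: np.random.Generator,
                                transient_peak_times: np.ndarray | None = None,
                                null_event_times: np.ndarray | None = None,
                                n_null: int = 300, clean_pre_s: float = 1.2,
                                rate: float = 100.0) -> float:
    """Debiased transient-follow probability.

    The raw follow fraction f mixes followed events (positive integral) with
    a null fraction q of positives among unfollowed events: f = p + (1 - p)q.
    Two corrections make the inversion usable: (1) events (and null triggers)
    whose preceding ``clean_pre_s`` seconds contain a detected transient peak
    are dropped, so the t = 0 reference value is not riding a decaying
    transient; (2) q should be estimated from triggers with the same temporal
    relationship to the rest of the event stream as the events themselves —
    pass the opposite-direction movement events (e.g. accelerations for a
    deceleration-locked recording) as ``null_event_times``.  Random included
    bins are used as a fallback null, but they sit closer to upcoming
    transients than real events do and therefore overestimate q.  The result
    is clipped to [0, 1].
    """
    w = int(round(0.75 * rate))

    def clean(t: float) -> bool:
        if transient_peak_times is None:
            return True
        return not np.any((transient_peak_times > t - clean_pre_s)
                          & (transient_peak_times <= t + 0.05))

    times = np.asarray([t for t in np.asarray(event_times, dtype=float)
                        if clean(t)])
    if times.size == 0:
        raise InsufficientDataError("no clean events for follow estimation")
    f = event_follow_fraction(dff, times, mask=mask, rate=rate)
    if null_event_times is not None:
        null_times = np.asarray([t for t in
                                 np.asarray(null_event_times, dtype=float)
                                 if clean(t)])
        null_mask = mask
    else:
        candidates = np.flatnonzero(mask)
        candidates = candidates[candidates + w < dff.size]
        if candidates.size == 0:
            raise InsufficientDataError("no included bins for null triggers")
        null_pool = rng.choice(candidates, size=3 * n_null, replace=True) / rate
        null_times = np.asarray([t for t in null_pool if clean(t)][:n_null])
        null_mask = None
    if null_times.size == 0:
        raise InsufficientDataError("no clean null triggers")
    q = event_follow_fraction(dff, null_times, mask=null_mask, rate=rate)
    if q >= 1.0:
        return 1.0
    return float(np.clip((f - q) / (1.0 - q), 0.0, 1.0))


def _runs(cond: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(cond.astype(np.int8)))
    starts = list(edges[~cond[edges]] + 1)
    stops = list(edges[cond[edges]] + 1)
    if cond.size and cond[0]:
        starts.insert(0, 0)
    if cond.size and cond[-1]:
        stops.append(cond.size)
    return list(zip(starts, stops))
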