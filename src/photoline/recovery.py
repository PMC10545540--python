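"""Parameter-recovery measurements on analyzed recordings.

These helpers quantify, from pipeline outputs alone, the generative
quantities the synthetic cohorts program: movement-to-transient timing lags,
event-size amplitude scaling, transient-follow probability, and stimulus
response integrals.  They are what the validation suite and the acceptance
script run; on real recordings they produce the corresponding descriptive
statistics.
"""

from __future__ import annotations

import numpy as np

from ._filters import moving_average
from .locomotion import (estimate_follow_probability, quintile_analysis,
                         triggered_average)
from .pipeline import CohortAnalysis, SessionAnalysis
from .population import circular_mean_deg, timing_lag


def locked_events(analysis: SessionAnalysis, event_lock: str):
    """(locked, opposite) movement event sets for a recording."""
    if event_lock == "deceleration":
        return analysis.decel_events, analysis.accel_events
    return analysis.accel_events, analysis.decel_events


def recover_timing_lag(analysis: SessionAnalysis, event_lock: str) -> float:
    """Movement-to-transient lag from the acceleration average triggered on
    detected transient peaks (extremum location in [-1, 0] s, 0.05-s
    smoothed), reported as a positive magnitude in seconds."""
    rec = analysis.rec
    peaks = rec.transients.peak_times
    idx = np.round(peaks * rec.bin_rate).astype(int)
    idx = idx[idx < analysis.mask.size]
    peaks = idx[analysis.mask[idx]] / rec.bin_rate
    ta = triggered_average(analysis.acceleration, peaks, rate=rec.bin_rate)
    mode = "accel_min" if event_lock == "deceleration" else "accel_max"
    return timing_lag(moving_average(ta.mean_trace, 5), ta.lags, mode).lag


def recover_quintile_gain(analysis: SessionAnalysis, event_lock: str):
    """Per-recording event-size quintile result on the locked events."""
    events, _ = locked_events(analysis, event_lock)
    return quintile_analysis(events, analysis.rec.dff470,
                             mask=analysis.rec.included_mask,
                             rate=analysis.rec.bin_rate)


def recover_follow_probability(analysis: SessionAnalysis, event_lock: str,
                               seed: int = 1) -> float:
    """Debiased transient-follow probability using the opposite-direction
    events as the paired null."""
    events, opposite = locked_events(analysis, event_lock)
    return estimate_follow_probability(
        analysis.rec.dff470, events.times, analysis.mask,
        np.random.default_rng(seed), null_event_times=opposite.times,
        rate=analysis.rec.bin_rate)


def cohort_recovery(ca: CohortAnalysis, profiles) -> dict[str, dict]:
    """Per-profile cohort means of all recovered quantities."""
    out: dict[str, dict] = {}
    for profile in profiles:
        lags, gains, follows = [], [], []
        for a in ca.analyses:
            if a.rec.meta.subtype_label != profile.name:
                continue
            lags.append(recover_timing_lag(a, profile.event_lock))
            gains.append(recover_quintile_gain(a, profile.event_lock).ratio)
            follows.append(recover_follow_probability(a, profile.event_lock))
        sub = ca.features[ca.features.subtype_label == profile.name]
        out[profile.name] = {
            "timing_lag_s": float(np.mean(lags)),
            "quintile_gain": float(np.mean(gains)),
            "quintile_percent": float(np.mean(gains) * 100.0),
            "follow_probability": float(np.mean(follows)),
            "reward_response": float(sub.reward_response.mean()),
            "airpuff_response": float(sub.airpuff_response.mean()),
            "mean_angle_deg": circular_mean_deg(sub.angle_deg.to_numpy()),
            "n_recordings": int(len(sub)),
        }
    return out
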