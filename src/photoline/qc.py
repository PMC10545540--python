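"""dF/F normalization, transient detection and recording-inclusion QC.

The 470-nm channel reports calcium-dependent GCaMP fluorescence; the 405-nm
(isosbestic) channel reports calcium-independent fluorescence and is used only
to find movement artifacts, never for regression-based subtraction.

Normalization proceeds per channel:

1. background correction: ``F_bg = F - 0.85 * P8(F, 20 s)`` where ``P8`` is the
   centred running 8th percentile (85% of baseline fluorescence is background
   light measured from unlabeled tissue);
2. baseline division: ``F_bg / P8(F_bg, 20 s)``, expressed in percent, which
   together with step 1 removes photobleaching and slow drift;
3. zeroing: the 470 trace is offset so the median of its non-transient bins is
   0; the 405 trace by the median of all its bins;
4. comparison scale: both traces are multiplied by ``100 / (largest detected
   470 transient peak)`` so the largest transient peaks at 100 ("normalized
   dF/F" units everywhere downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filters import moving_average, running_percentile
from .session import BinnedSession, SessionMeta

BACKGROUND_FRACTION = 0.85        # background share of baseline fluorescence
BASELINE_WINDOW_S = 20.0
BASELINE_PERCENTILE = 8.0
RISE_SLOPE_MIN = 30.0             # dF/F %/s, isolated-transient rise criterion
DECAY_SLOPE_MAX = -5.0            # dF/F %/s, subsequent decay criterion
SNR_MIN = 10.0                    # strict: snr must exceed this
TRANSIENT_RATE_MIN = 0.2          # transients per second
ARTIFACT_FRACTION_MAX = 0.05
NOISE_FLOOR = 1e-12


class TraceLengthError(ValueError):
    """Trace too short for the requested windowed operation."""


@dataclass
class TransientSet:
    """Isolated dF/F transients (fast rise immediately followed by a decay)."""

    peak_times: np.ndarray
    peak_amps: np.ndarray
    rise_start_times: np.ndarray
    decay_end_times: np.ndarray

    def __len__(self) -> int:
        return self.peak_times.size

    def scaled(self, factor: float) -> "TransientSet":
        return TransientSet(self.peak_times.copy(),
                            self.peak_amps * factor,
                            self.rise_start_times.copy(),
                            self.decay_end_times.copy())

    def non_transient_mask(self, n_bins: int, rate: float = 100.0) -> np.ndarray:
        """Boolean mask of bins outside every [rise_start, decay_end] span."""
        mask = np.ones(n_bins, dtype=bool)
        for t0, t1 in zip(self.rise_start_times, self.decay_end_times):
            mask[int(t0 * rate): int(np.ceil(t1 * rate)) + 1] = False
        return mask


@dataclass
class DffRecording:
    """Normalized dual-channel dF/F recording with QC masks."""

    dff470: np.ndarray
    dff405: np.ndarray
    norm_factor: float            # 470 transient peak mapped to 100
    excluded_mask: np.ndarray     # True on artifact bins (applies to all traces)
    transients: TransientSet
    velocity: np.ndarray
    lick: np.ndarray
    bin_rate: float = 100.0
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_sizes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    airpuff_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: SessionMeta = field(default_factory=SessionMeta)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.dff470.size

    @property
    def duration(self) -> float:
        return self.n_bins / self.bin_rate

    @property
    def included_mask(self) -> np.ndarray:
        return ~self.excluded_mask

    @property
    def stimulus_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.reward_times, self.airpuff_times]))


@dataclass
class SNRResult:
    snr: float
    transient_rate: float
    pass_snr: bool
    pass_rate: bool
    signal: float
    noise: float
    noise_floored: bool = False


@dataclass
class QCReport:
    snr: float
    transient_rate: float
    artifact_fraction: float
    pass_snr: bool
    pass_rate: bool
    pass_artifact: bool

    @property
    def overall_pass(self) -> bool:
        return self.pass_snr and self.pass_rate and self.pass_artifact

    def to_dict(self) -> dict:
        return {
            "snr": self.snr, "transient_rate": self.transient_rate,
            "artifact_fraction": self.artifact_fraction,
            "pass_snr": self.pass_snr, "pass_rate": self.pass_rate,
            "pass_artifact": self.pass_artifact,
            "overall_pass": self.overall_pass,
        }


# ---------------------------------------------------------------------------
# transient detection
# ---------------------------------------------------------------------------

def detect_transients(dff: np.ndarray, rate: float = 100.0,
                      detrend_window: int = 250,
                      smooth_window: int = 20) -> TransientSet:
    """Locate isolated transients on a dF/F trace.

    Slow fluctuations are removed by subtracting the running 8th percentile
    over ``detrend_window`` bins (2-3 transient widths); the result and its
    derivative are smoothed over 0.2 s, and transients are segmented at the
    derivative's zero-crossings.  A transient qualifies if its rise exceeds
    ``RISE_SLOPE_MIN`` and the immediately following decay reaches
    ``DECAY_SLOPE_MAX`` or below.  Peak amplitudes are read from the input
    trace, so they are on whatever scale the caller's trace is on.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    if n < smooth_window + 2:
        return _empty_transients()
    detrended = dff - running_percentile(dff, detrend_window, BASELINE_PERCENTILE)
    sm = moving_average(detrended, smooth_window)
    deriv = np.empty(n)
    deriv[:-1] = np.diff(sm) * rate
    deriv[-1] = deriv[-2]
    deriv = moving_average(deriv, smooth_window)

    pos = deriv > 0
    changes = np.flatnonzero(pos[1:] != pos[:-1]) + 1
    ups = changes[pos[changes]]       # rise onsets (deriv turns positive)
    downs = changes[~pos[changes]]    # peaks (deriv turns negative)

    peaks, amps, starts, ends = [], [], [], []
    for d in downs:
        prior_ups = ups[ups < d]
        rise_start = int(prior_ups[-1]) if prior_ups.size else 0
        later_ups = ups[ups > d]
        decay_end = int(later_ups[0]) if later_ups.size else n - 1
        if np.max(deriv[rise_start:d]) <= RISE_SLOPE_MIN:
            continue
        if np.min(deriv[d:decay_end + 1]) > DECAY_SLOPE_MAX:
            continue
        # locate the peak on the smoothed trace (robust to noise), then refine
        # on the unsmoothed trace within +-0.05 s so a clean transient's exact
        # sample peak is reported
        peak_s = rise_start + int(np.argmax(sm[rise_start:decay_end + 1]))
        lo_r = max(rise_start, peak_s - 5)
        hi_r = min(decay_end + 1, peak_s + 6)
        peak = lo_r + int(np.argmax(detrended[lo_r:hi_r]))
        peaks.append(peak)
        amps.append(dff[peak])
        starts.append(rise_start)
        ends.append(decay_end)
    if not peaks:
        return _empty_transients()
    order = np.argsort(peaks)
    peaks = np.asarray(peaks)[order]
    return TransientSet(
        peak_times=peaks / rate,
        peak_amps=np.asarray(amps)[order],
        rise_start_times=np.asarray(starts)[order] / rate,
        decay_end_times=np.asarray(ends)[order] / rate,
    )


def _empty_transients() -> TransientSet:
    z = np.empty(0)
    return TransientSet(z, z.copy(), z.copy(), z.copy())


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------

def _baseline_normalize(f: np.ndarray, window_bins: int) -> np.ndarray:
    """Steps 1-2: background subtraction and running-baseline division,
    returned in percent units (baseline sits near 100 before zeroing)."""
    f = np.asarray(f, dtype=float)
    f_bg = f - BACKGROUND_FRACTION * running_percentile(
        f, window_bins, BASELINE_PERCENTILE)
    denom = running_percentile(f_bg, window_bins, BASELINE_PERCENTILE)
    # guard: a non-positive running baseline has no physical meaning (dark or
    # constant-zero input); fall back to a flat epsilon to stay finite
    denom = np.where(np.abs(denom) < NOISE_FLOOR, NOISE_FLOOR, denom)
    return 100.0 * f_bg / denom


def compute_dff(binned: BinnedSession, mask_artifacts: bool = True) -> DffRecording:
    """Convert a binned session to a normalized dual-channel DffRecording."""
    rate = binned.bin_rate
    window_bins = int(round(BASELINE_WINDOW_S * rate))
    if binned.n_bins < 2 * window_bins:
        raise TraceLengthError(
            f"need at least {2 * BASELINE_WINDOW_S:.0f} s of data "
            f"({2 * window_bins} bins), got {binned.n_bins}")
    warnings: list[str] = []

    raw470 = _baseline_normalize(binned.f470, window_bins)
    raw405 = _baseline_normalize(binned.f405, window_bins)

    # preliminary zeroing so transient amplitudes are measured from baseline 0
    pre470 = raw470 - np.median(raw470)
    transients = detect_transients(pre470, rate=rate)
    nt_mask = transients.non_transient_mask(pre470.size, rate=rate)
    dff470 = raw470 - np.median(raw470[nt_mask]) if nt_mask.any() else pre470
    dff405 = raw405 - np.median(raw405)

    # re-read peak amplitudes on the finally-zeroed trace
    if len(transients):
        peak_idx = np.round(transients.peak_times * rate).astype(int)
        transients.peak_amps = dff470[peak_idx]
        norm_factor = float(np.max(transients.peak_amps))
        if norm_factor <= 0:
            warnings.append("largest transient peak non-positive; "
                            "falling back to trace maximum")
            norm_factor = float(np.max(dff470))
    else:
        warnings.append("no detectable transient; normalization falls back "
                        "to the trace maximum")
        norm_factor = float(np.max(dff470))
    if norm_factor <= NOISE_FLOOR:
        warnings.append("trace maximum non-positive; scale left at unity")
        norm_factor = 100.0
    scale = 100.0 / norm_factor

    if mask_artifacts:
        excluded, _, _ = artifact_mask(dff405, rate=rate)
    else:
        excluded = np.zeros(dff470.size, dtype=bool)
    return DffRecording(
        dff470=dff470 * scale,
        dff405=dff405 * scale,
        norm_factor=norm_factor,
        excluded_mask=excluded,
        transients=transients.scaled(scale),
        velocity=np.asarray(binned.velocity, dtype=float).copy(),
        lick=np.asarray(binned.lick, dtype=float).copy(),
        bin_rate=rate,
        reward_times=np.asarray(binned.reward_times, dtype=float).copy(),
        reward_sizes=np.asarray(binned.reward_sizes).copy(),
        airpuff_times=np.asarray(binned.airpuff_times, dtype=float).copy(),
        light_times=np.asarray(binned.light_times, dtype=float).copy(),
        meta=binned.meta,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# SNR and artifact exclusion
# ---------------------------------------------------------------------------

def compute_snr(dff470: np.ndarray, transients: TransientSet,
                rate: float = 100.0) -> SNRResult:
    """Signal-to-noise of a 470 dF/F trace.

    Signal is the 80th percentile of isolated transient peak amplitudes; noise
    is the s.d. of the trace minus its 0.1-s moving average.  A recording
    passes with snr strictly greater than 10 and at least 0.2 transients/s.
    """
    dff470 = np.asarray(dff470, dtype=float)
    if dff470.size <= 10:
        raise TraceLengthError("trace too short for noise estimation")
    noise = float(np.std(dff470 - moving_average(dff470, 10)))
    floored = noise < NOISE_FLOOR
    if floored:
        noise = NOISE_FLOOR
    duration = dff470.size / rate
    n = len(transients)
    transient_rate = n / duration
    signal = float(np.percentile(transients.peak_amps, 80)) if n else 0.0
    snr = signal / noise
    return SNRResult(snr=snr, transient_rate=transient_rate,
                     pass_snr=bool(snr > SNR_MIN),
                     pass_rate=bool(transient_rate >= TRANSIENT_RATE_MIN),
                     signal=signal, noise=noise, noise_floored=floored)


def _runs(cond: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) spans of True runs."""
    edges = np.flatnonzero(np.diff(cond.astype(np.int8)))
    starts = list(edges[~cond[edges]] + 1)
    stops = list(edges[cond[edges]] + 1)
    if cond.size and cond[0]:
        starts.insert(0, 0)
    if cond.size and cond[-1]:
        stops.append(cond.size)
    return list(zip(starts, stops))


def artifact_mask(dff405: np.ndarray, rate: float = 100.0
                  ) -> tuple[np.ndarray, float, bool]:
    """Movement-artifact exclusion mask from the isosbestic trace.

    ``maxnoise`` is the maximum absolute value of the 405 trace minus its
    0.1-s moving average.  Bins beyond +-3*maxnoise are excluded, as are runs
    staying beyond +-maxnoise for more than 0.2 s (padded by 0.1 s on both
    sides).  The returned mask must be applied to the 470, 405 and velocity
    traces alike; a recording with more than 5% excluded bins fails QC.
    """
    dff405 = np.asarray(dff405, dtype=float)
    n = dff405.size
    resid = dff405 - moving_average(dff405, 10)
    maxnoise = float(np.max(np.abs(resid))) if n else 0.0
    if maxnoise < NOISE_FLOOR:
        mask = np.zeros(n, dtype=bool)
        return mask, 0.0, True
    mask = np.abs(dff405) > 3.0 * maxnoise
    run_limit = int(round(0.2 * rate))
    pad = int(round(0.1 * rate))
    for cond in (dff405 > maxnoise, dff405 < -maxnoise):
        for start, stop in _runs(cond):
            if stop - start > run_limit:
                mask[max(0, start - pad): min(n, stop + pad)] = True
    fraction = float(mask.mean()) if n else 0.0
    return mask, fraction, bool(fraction <= ARTIFACT_FRACTION_MAX)


def qc_report(rec: DffRecording) -> QCReport:
    """Full inclusion report for a normalized recording.

    SNR/transient criteria are evaluated on the non-normalized scale the
    criteria were written for, i.e. the 470 trace divided back by the
    comparison scale factor.
    """
    unscale = rec.norm_factor / 100.0
    snr = compute_snr(rec.dff470 * unscale, rec.transients.scaled(unscale),
                      rate=rec.bin_rate)
    _, fraction, pass_artifact = artifact_mask(rec.dff405 * unscale,
                                               rate=rec.bin_rate)
    return QCReport(snr=snr.snr, transient_rate=snr.transient_rate,
                    artifact_fraction=fraction, pass_snr=snr.pass_snr,
                    pass_rate=snr.pass_rate, pass_artifact=pass_artifact)
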