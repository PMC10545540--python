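"""Synthetic photometry session generator.

Emulates head-fixed treadmill sessions with the statistical structure the
analysis assumes: alternating rest/run bouts with discrete speed-change
events, subtype-specific movement-locked calcium transients (deceleration-
locked for Vglut2/Calb1-like profiles, acceleration-locked for Anxa1-like),
reward/air-puff responses with programmed response integrals, double-
exponential photobleaching, Gaussian sensor noise, movement artifacts shared
across both wavelength channels, and reward-evoked lick bursts.  Every placed
transient and programmed parameter is recorded in a GroundTruth sidecar so
parameter recovery can be asserted downstream.

The 405 channel carries bleach, artifacts and noise but no calcium latent.
The fluorescence model puts the calcium latent on 15% of the baseline (the
other 85% being background light that co-bleaches), which is the background
share the preprocessing subtracts, so the pipeline's dF/F recovers the
programmed latent in percent units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._filters import diff_of_exp_kernel, kernel_peak_time, moving_average
from .session import BinnedSession, RawSession, SessionMeta, SAMPLES_PER_EPOCH


class GenConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SubtypeProfile:
    """Programmed functional signature of one dopamine-neuron subtype."""

    name: str
    event_lock: str              # "deceleration" or "acceleration"
    follow_prob: float           # P(qualifying movement event elicits a transient)
    lag_mean: float              # s, transient peak after the event's accel extremum
    lag_sd: float
    amp_scaling: float           # expected Q5/Q1 transient-amplitude ratio
    reward_response: float       # normalized dF/F * s
    airpuff_response: float      # may be negative (signaling decrease)
    size_sensitivity: float      # large-minus-small reward integral difference
    base_amp: float = 12.0       # movement-transient base amplitude, dF/F %

    def __post_init__(self) -> None:
        if self.event_lock not in ("deceleration", "acceleration"):
            raise GenConfigError(f"unknown event_lock {self.event_lock!r}")
        if not 0.0 <= self.follow_prob <= 1.0:
            raise GenConfigError("follow_prob must be in [0, 1]")
        if self.lag_mean < 0:
            raise GenConfigError("lag_mean must be non-negative")
        if self.amp_scaling <= 0:
            raise GenConfigError("amp_scaling must be positive")


# Defaults reflect the three striatal-axon subtype signatures: deceleration-
# locked signaling with a 0.42 s (Vglut2-like) or 0.17 s (Calb1-like) lag and
# ~62% event-follow probability versus acceleration-locked (Anxa1-like, 57.5%);
# reward/air-puff response integrals 7.9/15.8, 12.4/5.3 and -0.5/-3.7
# normalized dF/F*s; largest-vs-smallest event-quintile amplitude ratios
# 2.14/2.43/2.06; reward-size sensitivity 0.9/3.9/0 dF/F*s.
VGLUT2 = SubtypeProfile("Vglut2", "deceleration", 0.624, 0.42, 0.10,
                        2.14, 7.9, 15.8, 0.9)
CALB1 = SubtypeProfile("Calb1", "deceleration", 0.623, 0.17, 0.10,
                       2.43, 12.4, 5.3, 3.9)
ANXA1 = SubtypeProfile("Anxa1", "acceleration", 0.575, 0.30, 0.10,
                       2.06, -0.5, -3.7, 0.0)
DEFAULT_PROFILES = (VGLUT2, CALB1, ANXA1)


@dataclass
class GenConfig:
    """Session-level generation parameters (defaults emulate one 15-min
    treadmill recording with pseudo-random stimuli every 10-30 s)."""

    duration: float = 900.0          # s
    bin_rate: float = 100.0          # Hz
    tau_rise: float = 0.05           # s, transient kernel rise
    tau_decay: float = 0.40          # s, transient kernel decay
    dip_tau_rise: float = 0.10       # slower kernel for signaling decreases
    dip_tau_decay: float = 0.60
    noise_sd: float = 1.0            # dF/F % per channel
    bleach_amps: tuple[float, float] = (0.3, 0.7)
    bleach_taus: tuple[float, float] = (90.0, 2500.0)  # s
    artifact_rate: float = 2.0       # events/min, shared across channels
    artifact_amp_range: tuple[float, float] = (10.0, 14.0)  # x noise_sd
    artifact_duration: float = 0.3   # s
    rest_duration_range: tuple[float, float] = (2.0, 6.0)
    run_duration_range: tuple[float, float] = (6.0, 14.0)
    speed_range: tuple[float, float] = (0.12, 0.70)   # m/s
    step_interval_range: tuple[float, float] = (0.6, 1.6)  # s between speed steps
    supra_step_prob: float = 0.6     # P(speed step exceeds the 2 m/s^2 peak)
    stim_isi_range: tuple[float, float] = (10.0, 30.0)
    stim_lag_mean: float = 0.30      # s, stimulus-response transient peak lag
    stim_lag_sd: float = 0.05
    consume_prob: float = 0.9        # P(reward is licked within 1 s)
    background_rate: float = 0.3     # spontaneous transients /s
    background_amp_median: float = 12.0
    background_amp_sigma: float = 0.4
    anchor_amp: float = 100.0        # largest transient, defines the 0-100 scale
    amp_jitter_sigma: float = 0.15   # lognormal amplitude jitter (mean 1)
    n_bouts: int | None = None       # override: exact number of run bouts
    f0_470: float = 2.0              # baseline fluorescence, arbitrary units
    f0_405: float = 1.0
    background_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise GenConfigError("duration must be positive")
        if not self.tau_rise < self.tau_decay:
            raise GenConfigError("tau_rise must be smaller than tau_decay")
        if self.noise_sd < 0:
            raise GenConfigError("noise_sd must be non-negative")


@dataclass
class TruthTransient:
    time: float       # peak time, s
    amp: float        # dF/F %, signed
    kind: str         # movement / background / anchor / reward / airpuff
    event_time: float = np.nan
    event_peak: float = np.nan


@dataclass
class GroundTruth:
    """Everything the generator placed, for parameter-recovery assertions."""

    profile: SubtypeProfile
    seed: int
    transients: list[TruthTransient]
    bout_intervals: list[tuple[float, float]]
    accel_events: list[tuple[float, float]]   # (peak time, peak m/s^2), signed
    reward_times: np.ndarray
    reward_sizes: np.ndarray
    consumed: np.ndarray                      # bool per reward
    airpuff_times: np.ndarray
    artifact_intervals: list[tuple[float, float]]
    noise_sd: float
    response_gain: float                      # unit-amp kernel response integral

    @property
    def programmed_snr(self) -> float:
        """SNR the QC stage should recover: P80 of positive transient peaks
        over the s.d. of the 0.1-s-smoothing residual of white noise."""
        amps = np.array([t.amp for t in self.transients if t.amp > 0])
        noise = self.noise_sd * np.sqrt(0.9) if self.noise_sd > 0 else 1e-12
        return float(np.percentile(amps, 80)) / noise if amps.size else 0.0

    def movement_transients(self) -> list[TruthTransient]:
        return [t for t in self.transients if t.kind == "movement"]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default)


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

_PULSE_SIGMA = 0.06  # s, width of gaussian acceleration pulses


def _add_pulse(accel: np.ndarray, t_center: float, dv: float,
               rate: float) -> float:
    """Add a gaussian acceleration pulse integrating to exactly ``dv``;
    returns the signed peak acceleration."""
    n = accel.size
    half = int(round(4 * _PULSE_SIGMA * rate))
    c = int(round(t_center * rate))
    lo, hi = max(0, c - half), min(n, c + half + 1)
    t = (np.arange(lo, hi) - c) / rate
    p = np.exp(-t ** 2 / (2 * _PULSE_SIGMA ** 2))
    full = np.exp(-(np.arange(-half, half + 1) / rate) ** 2
                  / (2 * _PULSE_SIGMA ** 2)).sum() / rate
    scale = dv / full
    accel[lo:hi] += scale * p
    return scale


def generate_velocity(config: GenConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, list, list]:
    """Treadmill velocity trace with ground-truth bouts and movement events.

    Returns (velocity, bout_intervals, accel_events) where accel_events is a
    list of (pulse peak time, signed peak acceleration in m/s^2) for every
    speed-change pulse, supra- and sub-threshold alike.
    """
    rate = config.bin_rate
    n = int(round(config.duration * rate))
    accel = np.zeros(n)
    bout_intervals: list[tuple[float, float]] = []
    events: list[tuple[float, float]] = []

    # lay out alternating rest / run bouts
    t = float(rng.uniform(*config.rest_duration_range))
    n_bouts = 0
    while t < config.duration - 6.0:
        if config.n_bouts is not None and n_bouts >= config.n_bouts:
            break
        run = float(rng.uniform(*config.run_duration_range))
        run = min(run, config.duration - t - 2.0)
        if run < 2.0:
            break
        t0, t1 = t, t + run
        bout_intervals.append((t0, t1))
        n_bouts += 1

        v_cur = 0.0
        # onset ramp
        v_base = float(rng.uniform(0.35, 0.60))
        peak = _add_pulse(accel, t0 + 0.15, v_base, rate)
        events.append((t0 + 0.15, peak))
        v_cur = v_base
        # within-bout speed steps
        tc = t0 + 0.15 + float(rng.uniform(*config.step_interval_range))
        while tc < t1 - 0.6:
            lo_v, hi_v = 0.12, config.speed_range[1]
            if rng.random() < config.supra_step_prob:
                mag = float(rng.uniform(0.32, 0.50))
            else:
                mag = float(rng.uniform(0.08, 0.28))
            if v_cur > 0.45:
                sign = -1.0
            elif v_cur < 0.30:
                sign = 1.0
            else:
                sign = rng.choice([-1.0, 1.0])
            v_new = float(np.clip(v_cur + sign * mag, lo_v, hi_v))
            dv = v_new - v_cur
            if abs(dv) > 0.02:
                peak = _add_pulse(accel, tc, dv, rate)
                events.append((tc, peak))
                v_cur = v_new
            tc += float(rng.uniform(*config.step_interval_range))
        # offset ramp back to rest
        _add_pulse(accel, t1 - 0.25, -v_cur, rate)
        t = t1 + float(rng.uniform(*config.rest_duration_range))

    velocity = np.cumsum(accel) / rate
    jitter = moving_average(rng.normal(0.0, 1.0, n), 10)
    velocity = velocity + jitter * (0.004 / max(jitter.std(), 1e-12))
    events.sort()
    return velocity, bout_intervals, events


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def _response_gain(kernel: np.ndarray, peak_time: float, lag_mean: float,
                   lag_sd: float, rate: float) -> float:
    """Expected stimulus-response integral of a unit-amplitude transient whose
    peak lands lag ~ N(lag_mean, lag_sd) after delivery, under the
    (+0.05, +0.55] minus (-0.5, 0) window definition."""
    from scipy.stats import norm
    zs = norm.ppf((np.arange(20) + 0.5) / 20)
    gains = []
    origin = 120  # event bin inside a scratch trace long enough for the kernel
    for z in zs:
        lag = max(0.0, lag_mean + lag_sd * z)
        start = origin + int(round((lag - peak_time) * rate))
        trace = np.zeros(origin + kernel.size + 200)
        trace[start: start + kernel.size] += kernel
        post_sum = trace[origin + 6: origin + 56].sum() / rate
        pre_sum = trace[origin - 50: origin].sum() / rate
        gains.append(post_sum - pre_sum)
    return float(np.mean(gains))


def _amp_jitter(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative lognormal jitter with mean exactly 1."""
    return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=size))


def generate_session(profile: SubtypeProfile, config: GenConfig | None = None,
                     seed: int = 0, meta: SessionMeta | None = None,
                     ) -> tuple[BinnedSession, GroundTruth]:
    """Generate one binned session plus its ground truth."""
    if config is None:
        config = GenConfig()
    rng = np.random.default_rng(seed)
    rate = config.bin_rate
    n = int(round(config.duration * rate))
    time = np.arange(n) / rate

    velocity, bouts, vel_events = generate_velocity(config, rng)

    # stimulus schedule: rewards and air puffs alternate at random with
    # pseudo-random 10-30 s intervals; rewards split small/large
    stim_times, stim_kinds = [], []
    t = float(rng.uniform(*config.stim_isi_range))
    while t < config.duration - 2.0:
        stim_times.append(t)
        stim_kinds.append("reward" if rng.random() < 0.5 else "airpuff")
        t += float(rng.uniform(*config.stim_isi_range))
    stim_times = np.asarray(stim_times)
    stim_kinds = np.asarray(stim_kinds)
    reward_times = stim_times[stim_kinds == "reward"]
    airpuff_times = stim_times[stim_kinds == "airpuff"]
    reward_sizes = np.where(rng.random(reward_times.size) < 0.5,
                            "small", "large").astype("U5")
    consumed = rng.random(reward_times.size) < config.consume_prob

    kernel = diff_of_exp_kernel(config.tau_rise, config.tau_decay, rate)
    k_peak_t = kernel_peak_time(config.tau_rise, config.tau_decay)
    dip_kernel = diff_of_exp_kernel(config.dip_tau_rise, config.dip_tau_decay,
                                    rate)
    dip_peak_t = kernel_peak_time(config.dip_tau_rise, config.dip_tau_decay)

    latent = np.zeros(n)
    transients: list[TruthTransient] = []

    def place(peak_time: float, amp: float, kind: str,
              event_time: float = np.nan, event_peak: float = np.nan) -> None:
        if amp == 0.0:
            return
        k, pk = (kernel, k_peak_t) if amp >= 0 else (dip_kernel, dip_peak_t)
        start = int(round((peak_time - pk) * rate))
        if start >= n:
            return
        seg = k[max(0, -start): max(0, min(k.size, n - start))]
        if seg.size == 0:
            return
        latent[max(0, start): max(0, start) + seg.size] += amp * seg
        transients.append(TruthTransient(time=peak_time, amp=amp, kind=kind,
                                         event_time=event_time,
                                         event_peak=event_peak))

    # movement-locked transients on qualifying events of the locked sign
    want_sign = -1.0 if profile.event_lock == "deceleration" else 1.0
    qualifying = [(tc, pk) for tc, pk in vel_events
                  if np.sign(pk) == want_sign and abs(pk) > 2.0]
    if qualifying:
        mags = np.array([abs(pk) for _, pk in qualifying])
        ranks = np.argsort(np.argsort(mags))
        u = (ranks + 0.5) / len(qualifying)     # magnitude quantile in (0, 1)
        g = profile.amp_scaling
        if g >= 9.0:
            raise GenConfigError("amp_scaling >= 9 has no valid linear gain")
        k_gain = (g - 1.0) / (0.9 - 0.1 * g)
        for (tc, pk), ui in zip(qualifying, u):
            if rng.random() >= profile.follow_prob:
                continue
            lag = max(0.0, rng.normal(profile.lag_mean, profile.lag_sd))
            amp = (profile.base_amp * (1.0 + k_gain * ui)
                   * float(_amp_jitter(rng, config.amp_jitter_sigma)))
            place(tc + lag, amp, "movement", event_time=tc, event_peak=pk)

    # spontaneous background transients
    n_bg = rng.poisson(config.background_rate * config.duration)
    bg_times = np.sort(rng.uniform(1.0, config.duration - 1.0, n_bg))
    bg_amps = np.minimum(
        rng.lognormal(np.log(config.background_amp_median),
                      config.background_amp_sigma, n_bg), 80.0)
    for bt, ba in zip(bg_times, bg_amps):
        place(bt, float(ba), "background")

    # normalization anchor: the session's largest transient, placed in the
    # longest rest period so it is well isolated
    rest_edges = [0.0] + [e for b in bouts for e in b] + [config.duration]
    rests = [(rest_edges[i], rest_edges[i + 1])
             for i in range(0, len(rest_edges) - 1, 2)]
    rests = [r for r in rests if r[1] - r[0] > 4.0] or [(0.0, config.duration)]
    r0, r1 = max(rests, key=lambda r: r[1] - r[0])
    place((r0 + r1) / 2.0, config.anchor_amp, "anchor")

    # stimulus responses, amplitudes calibrated so the expected response
    # integral matches the programmed target
    def stim_amp(target: float) -> float:
        if target == 0.0:
            return 0.0
        k, pk = (kernel, k_peak_t) if target >= 0 else (dip_kernel, dip_peak_t)
        gain = _response_gain(k, pk, config.stim_lag_mean, config.stim_lag_sd,
                              rate)
        return target / gain

    amp_small = stim_amp(profile.reward_response - profile.size_sensitivity / 2)
    amp_large = stim_amp(profile.reward_response + profile.size_sensitivity / 2)
    for rt, sz, cons in zip(reward_times, reward_sizes, consumed):
        if not cons:
            continue
        amp = amp_large if sz == "large" else amp_small
        if amp == 0.0:
            continue
        lag = max(0.0, rng.normal(config.stim_lag_mean, config.stim_lag_sd))
        place(rt + lag, amp * float(_amp_jitter(rng, 0.2)), "reward",
              event_time=rt)
    amp_puff = stim_amp(profile.airpuff_response)
    for at in airpuff_times:
        if amp_puff == 0.0:
            continue
        lag = max(0.0, rng.normal(config.stim_lag_mean, config.stim_lag_sd))
        place(at + lag, amp_puff * float(_amp_jitter(rng, 0.2)), "airpuff",
              event_time=at)

    # licking: burst after each consumed reward
    lick = np.zeros(n)
    for rt, cons in zip(reward_times, consumed):
        if not cons:
            continue
        first = rt + float(rng.uniform(0.15, 0.7))
        lick_t = first + np.arange(0, 1.5, 0.125)
        idx = np.round(lick_t * rate).astype(int)
        lick[idx[idx < n]] = 1.0

    # shared movement artifacts (plateau deflections in both channels)
    art470 = np.zeros(n)
    art405 = np.zeros(n)
    artifact_intervals: list[tuple[float, float]] = []
    n_art = rng.poisson(config.artifact_rate / 60.0 * config.duration)
    dur_bins = int(round(config.artifact_duration * rate))
    # raised-cosine ramps longer than the 0.1-s exclusion smoothing window so
    # the smoothed trace tracks the artifact edges (movement artifacts are
    # brain-motion deflections, slower than shot noise)
    ramp = min(8, dur_bins // 3)
    template = np.ones(dur_bins)
    edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, ramp + 1) / (ramp + 1)))
    template[:ramp] = edge
    template[-ramp:] = edge[::-1]
    for at in rng.uniform(2.0, config.duration - 2.0, n_art):
        amp = (float(rng.uniform(*config.artifact_amp_range)) * config.noise_sd
               * float(rng.choice([-1.0, 1.0])))
        b = int(round(at * rate))
        hi = min(n, b + dur_bins)
        art470[b:hi] += amp * float(rng.uniform(0.9, 1.1)) * template[: hi - b]
        art405[b:hi] += amp * float(rng.uniform(0.9, 1.1)) * template[: hi - b]
        artifact_intervals.append((b / rate, hi / rate))

    # assemble fluorescence: latent rides on the 15% non-background share of a
    # double-exponentially bleaching baseline; 405 has no calcium latent
    a1, a2 = config.bleach_amps
    t1, t2 = config.bleach_taus
    bleach = a1 * np.exp(-time / t1) + a2 * np.exp(-time / t2)
    bleach405 = a1 * np.exp(-time / (t1 * 1.15)) + a2 * np.exp(-time / (t2 * 0.9))
    sig_share = 1.0 - config.background_fraction
    lat470 = latent + art470 + rng.normal(0.0, config.noise_sd, n)
    lat405 = art405 + rng.normal(0.0, config.noise_sd, n)
    f470 = bleach * config.f0_470 * (1.0 + sig_share * lat470 / 100.0)
    f405 = bleach405 * config.f0_405 * (1.0 + sig_share * lat405 / 100.0)

    if meta is None:
        meta = SessionMeta(mouse_id=f"{profile.name}_sim",
                           subtype_label=profile.name
                           if profile.name in ("Vglut2", "Calb1", "Anxa1",
                                               "Aldh1a1", "DAT") else "unknown")
    session = BinnedSession(bin_rate=rate, f470=f470, f405=f405,
                            velocity=velocity, lick=lick,
                            reward_times=reward_times,
                            reward_sizes=reward_sizes,
                            airpuff_times=airpuff_times,
                            light_times=np.empty(0), meta=meta)
    k_resp = kernel if profile.reward_response >= 0 else dip_kernel
    pk_resp = k_peak_t if profile.reward_response >= 0 else dip_peak_t
    truth = GroundTruth(profile=profile, seed=seed, transients=transients,
                        bout_intervals=bouts, accel_events=vel_events,
                        reward_times=reward_times, reward_sizes=reward_sizes,
                        consumed=consumed, airpuff_times=airpuff_times,
                        artifact_intervals=artifact_intervals,
                        noise_sd=config.noise_sd,
                        response_gain=_response_gain(
                            k_resp, pk_resp, config.stim_lag_mean,
                            config.stim_lag_sd, rate))
    return session, truth


def make_raw(binned: BinnedSession, sample_rate: float = 4000.0,
             noise_sd: float = 0.0, seed: int = 0) -> RawSession:
    """Expand a binned session into a 4 kHz interleaved raw acquisition.

    Each 10-ms bin becomes one 40-sample illumination epoch of the channel lit
    during that bin (alternating, 470 first); the multiplexed fluorescence is
    the bin's channel value plus optional per-sample noise.
    """
    rng = np.random.default_rng(seed)
    spe = SAMPLES_PER_EPOCH
    n_bins = binned.n_bins
    illum = np.zeros(n_bins * spe, dtype=np.int8)
    states = (np.arange(n_bins) % 2 == 0)  # even bins: 470 on
    illum[np.repeat(states, spe)] = 1
    values = np.where(states, binned.f470, binned.f405)
    fluor = np.repeat(values, spe)
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, fluor.size)
    return RawSession(sample_rate=sample_rate, fluor=fluor, illum_select=illum,
                      velocity=np.repeat(binned.velocity, spe),
                      lick=np.repeat(binned.lick, spe),
                      reward_times=binned.reward_times.copy(),
                      reward_sizes=binned.reward_sizes.copy(),
                      airpuff_times=binned.airpuff_times.copy(),
                      light_times=binned.light_times.copy(),
                      meta=binned.meta)


# subtype-biased striatal recording locations (AP, ML, DV from bregma, mm):
# Anxa1 axons dorsal, Calb1 medial/ventral, Vglut2 posterior striatum
_COORD_CENTERS = {
    "Vglut2": (-1.0, 3.0, 3.0),
    "Calb1": (0.5, 1.5, 3.4),
    "Anxa1": (0.6, 2.3, 2.0),
    "DAT": (0.0, 2.2, 2.8),
}
_COORD_SD = 0.30


def generate_cohort(profiles, n_per_profile: int, base_seed: int,
                    config: GenConfig | None = None,
                    ) -> list[tuple[BinnedSession, GroundTruth]]:
    """Generate ``n_per_profile`` sessions per profile with deterministic
    per-session seeds derived from ``base_seed`` and subtype-biased
    recording coordinates."""
    profiles = list(profiles)
    if not profiles:
        raise GenConfigError("profile list must not be empty")
    if n_per_profile < 1:
        raise GenConfigError("n_per_profile must be at least 1")
    if config is None:
        config = GenConfig()
    children = np.random.SeedSequence(base_seed).spawn(
        len(profiles) * n_per_profile)
    out = []
    i = 0
    for profile in profiles:
        center = np.asarray(_COORD_CENTERS.get(profile.name, (0.0, 2.0, 3.0)))
        for j in range(n_per_profile):
            ss = children[i]
            i += 1
            seed = int(ss.generate_state(1)[0] % (2 ** 31))
            coord_rng = np.random.default_rng(seed + 1)
            coords = tuple(center + coord_rng.normal(0.0, _COORD_SD, 3))
            label = (profile.name if profile.name in
                     ("Vglut2", "Calb1", "Anxa1", "Aldh1a1", "DAT")
                     else "unknown")
            meta = SessionMeta(mouse_id=f"{profile.name}_m{j:02d}",
                               subtype_label=label, region="striatum",
                               coords=coords,
                               depth_from_surface=float(coords[2]))
            out.append(generate_session(profile, config, seed=seed, meta=meta))
    return out
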