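"""Photometry session data model and the raw -> 100 Hz demultiplex/re-bin stage.

A raw acquisition interleaves 470-nm (calcium-dependent) and 405-nm
(isosbestic) excitation at the fiber tip: the light source switches every
10 ms, so at a 4 kHz sampling rate each illumination epoch spans exactly 40
samples and lines up with one 10-ms output bin of the 100 Hz session.  The
fluorescence detector sees a single multiplexed stream; the binary
``illum_select`` waveform says which source was on for each sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

REGIONS = ("striatum", "SNc")
SUBTYPES = ("Vglut2", "Calb1", "Anxa1", "Aldh1a1", "DAT", "unknown")

SAMPLES_PER_EPOCH = 40  # 10 ms at 4 kHz; one illumination epoch = one output bin
TRANSITION_SAMPLES = 5  # dropped at each end of an epoch (LED settling)


class SessionFormatError(ValueError):
    """Malformed session container or raw acquisition layout."""


class SessionStructureError(ValueError):
    """Inconsistent array shapes / metadata within a session."""


@dataclass
class SessionMeta:
    mouse_id: str = "unknown"
    subtype_label: str = "unknown"
    region: str = "striatum"
    coords: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm from bregma
    depth_from_surface: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.subtype_label not in SUBTYPES:
            raise SessionStructureError(
                f"unknown subtype label {self.subtype_label!r}")
        if self.region not in REGIONS:
            raise SessionStructureError(f"unknown region {self.region!r}")
        coords = tuple(float(c) for c in self.coords)
        if not all(np.isfinite(coords)):
            raise SessionStructureError("coords must be finite")
        self.coords = coords


@dataclass
class RawSession:
    """4 kHz acquisition record."""

    sample_rate: float
    fluor: np.ndarray          # multiplexed fluorescence, arbitrary units
    illum_select: np.ndarray   # 1 = 470 nm on, 0 = 405 nm on
    velocity: np.ndarray       # m/s, signed (forward positive)
    lick: np.ndarray           # binary
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_sizes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    airpuff_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: SessionMeta = field(default_factory=SessionMeta)

    @property
    def duration(self) -> float:
        return self.fluor.size / self.sample_rate

    def validate(self) -> None:
        n = self.fluor.size
        for name in ("illum_select", "velocity", "lick"):
            arr = getattr(self, name)
            if arr.size != n:
                raise SessionStructureError(
                    f"trace length mismatch: fluor has {n} samples, "
                    f"{name} has {arr.size}")
        _check_epoch_layout(np.asarray(self.illum_select))
        for name in ("reward_times", "airpuff_times", "light_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise SessionStructureError(
                    f"{name} outside [0, {self.duration:.2f}] s")


@dataclass
class BinnedSession:
    """100 Hz demultiplexed dual-channel session."""

    bin_rate: float
    f470: np.ndarray
    f405: np.ndarray
    velocity: np.ndarray
    lick: np.ndarray
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_sizes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    airpuff_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: SessionMeta = field(default_factory=SessionMeta)

    @property
    def n_bins(self) -> int:
        return self.f470.size

    @property
    def duration(self) -> float:
        return self.n_bins / self.bin_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_bins) / self.bin_rate

    @property
    def stimulus_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.reward_times, self.airpuff_times]))

    def validate(self) -> None:
        n = self.n_bins
        for name in ("f405", "velocity", "lick"):
            if getattr(self, name).size != n:
                raise SessionStructureError(
                    f"binned trace length mismatch on {name}")


def _check_epoch_layout(illum: np.ndarray) -> None:
    """illum_select must alternate in runs of exactly SAMPLES_PER_EPOCH,
    starting at sample 0 (a trailing partial epoch is allowed: it is dropped)."""
    n = illum.size
    n_full = n // SAMPLES_PER_EPOCH
    if n_full == 0:
        raise SessionFormatError("raw session shorter than one epoch")
    full = illum[: n_full * SAMPLES_PER_EPOCH].reshape(n_full, SAMPLES_PER_EPOCH)
    same = full == full[:, :1]
    if not same.all():
        bad_epoch = int(np.argmin(same.all(axis=1)))
        bad_sample = bad_epoch * SAMPLES_PER_EPOCH + int(np.argmin(same[bad_epoch]))
        raise SessionFormatError(
            f"illumination runs are not {SAMPLES_PER_EPOCH} samples long: "
            f"first offending sample index {bad_sample}")
    states = full[:, 0]
    if n_full > 1 and (states[1:] == states[:-1]).any():
        bad_epoch = int(np.argmax(states[1:] == states[:-1])) + 1
        raise SessionFormatError(
            "illumination does not alternate every epoch: first offending "
            f"sample index {bad_epoch * SAMPLES_PER_EPOCH}")


def demux_rebin(raw: RawSession) -> BinnedSession:
    """Demultiplex the interleaved fluorescence stream and re-bin to 100 Hz.

    Each 40-sample illumination epoch yields one fluorescence value for the
    channel that was lit: the mean of its central 15 samples (the epoch's own
    measurement window; 5 transition samples are dropped symmetrically at each
    end of that window).  A channel's bins during the alternate-source epochs
    take the value of the nearest own-channel epoch, so both channels have
    ``floor(duration * 100)`` bins.  Velocity (and licking) are averaged over
    all 40 samples of each 10-ms window; event times are carried over.
    """
    raw.validate()
    if raw.duration < 1.0:
        raise SessionStructureError("raw session must be at least 1 s long")
    spe = SAMPLES_PER_EPOCH
    n_bins = raw.fluor.size // spe
    fluor = np.asarray(raw.fluor, dtype=float)[: n_bins * spe].reshape(n_bins, spe)
    illum = np.asarray(raw.illum_select)[: n_bins * spe].reshape(n_bins, spe)
    states = illum[:, 0].astype(bool)

    # central 15 samples of the epoch: drop (40-15)//2 at the front
    n_keep = 15
    lo = (spe - n_keep) // 2
    epoch_mean = fluor[:, lo:lo + n_keep].mean(axis=1)

    idx = np.arange(n_bins)
    out = {}
    for channel, on in (("f470", True), ("f405", False)):
        own = idx[states == on]
        if own.size == 0:
            raise SessionFormatError(f"no epochs found for channel {channel}")
        # nearest own-channel epoch for every output bin (ties -> earlier)
        pos = np.searchsorted(own, idx)
        pos_left = np.clip(pos - 1, 0, own.size - 1)
        pos_right = np.clip(pos, 0, own.size - 1)
        nearer_right = (np.abs(own[pos_right] - idx)
                        < np.abs(idx - own[pos_left]))
        nearest = np.where(nearer_right, own[pos_right], own[pos_left])
        out[channel] = epoch_mean[nearest]

    velocity = np.asarray(raw.velocity, dtype=float)[: n_bins * spe]
    lick = np.asarray(raw.lick, dtype=float)[: n_bins * spe]
    binned = BinnedSession(
        bin_rate=raw.sample_rate / spe,
        f470=out["f470"],
        f405=out["f405"],
        velocity=velocity.reshape(n_bins, spe).mean(axis=1),
        lick=lick.reshape(n_bins, spe).max(axis=1),
        reward_times=np.asarray(raw.reward_times, dtype=float).copy(),
        reward_sizes=np.asarray(raw.reward_sizes).copy(),
        airpuff_times=np.asarray(raw.airpuff_times, dtype=float).copy(),
        light_times=np.asarray(raw.light_times, dtype=float).copy(),
        meta=replace(raw.meta),
    )
    return binned


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_RAW_DATASETS = ("fluor", "illum_select", "velocity", "lick")
_BINNED_DATASETS = ("f470", "f405", "velocity", "lick")
_EVENT_DATASETS = ("reward_times", "airpuff_times", "light_times")


def _write_meta(group: h5py.Group, meta: SessionMeta) -> None:
    group.attrs["mouse_id"] = meta.mouse_id
    group.attrs["subtype_label"] = meta.subtype_label
    group.attrs["region"] = meta.region
    group.attrs["coords"] = np.asarray(meta.coords, dtype=float)
    group.attrs["depth_from_surface"] = float(meta.depth_from_surface)


def _read_meta(group: h5py.Group) -> SessionMeta:
    return SessionMeta(
        mouse_id=str(group.attrs["mouse_id"]),
        subtype_label=str(group.attrs["subtype_label"]),
        region=str(group.attrs["region"]),
        coords=tuple(np.asarray(group.attrs["coords"], dtype=float)),
        depth_from_surface=float(group.attrs["depth_from_surface"]),
    )


def _write_events(group: h5py.Group, session: RawSession | BinnedSession) -> None:
    for name in _EVENT_DATASETS:
        group.create_dataset(name, data=np.asarray(getattr(session, name),
                                                   dtype=float))
    sizes = np.asarray(session.reward_sizes, dtype="S8")
    group.create_dataset("reward_sizes", data=sizes)


def _read_events(group: h5py.Group) -> dict:
    out = {name: np.asarray(group[name], dtype=float)
           for name in _EVENT_DATASETS}
    out["reward_sizes"] = np.char.decode(
        np.asarray(group["reward_sizes"], dtype="S8"))
    return out


def save_session(session: RawSession | BinnedSession, path) -> None:
    """Write a session to an HDF5 container (group /raw or /binned)."""
    with h5py.File(path, "a") as fh:
        if isinstance(session, RawSession):
            if "raw" in fh:
                del fh["raw"]
            g = fh.create_group("raw")
            g.attrs["sample_rate"] = float(session.sample_rate)
        elif isinstance(session, BinnedSession):
            if "binned" in fh:
                del fh["binned"]
            g = fh.create_group("binned")
            g.attrs["bin_rate"] = float(session.bin_rate)
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot save object of type {type(session)}")
        names = (_RAW_DATASETS if isinstance(session, RawSession)
                 else _BINNED_DATASETS)
        for name in names:
            g.create_dataset(name, data=np.asarray(getattr(session, name),
                                                   dtype=float))
        _write_events(g, session)
        _write_meta(g, session.meta)


def load_session(path, which: str = "auto") -> RawSession | BinnedSession:
    """Load a session from an HDF5 container.

    ``which`` is "raw", "binned" or "auto" (prefer /binned if present).
    """
    with h5py.File(path, "r") as fh:
        if which == "auto":
            which = "binned" if "binned" in fh else "raw"
        if which not in fh:
            raise SessionFormatError(f"file has no /{which} group")
        g = fh[which]
        required = (_RAW_DATASETS if which == "raw" else _BINNED_DATASETS)
        missing = [n for n in required + _EVENT_DATASETS + ("reward_sizes",)
                   if n not in g]
        if missing:
            raise SessionFormatError(
                "missing required dataset(s): " + ", ".join(sorted(missing)))
        arrays = {n: np.asarray(g[n], dtype=float) for n in required}
        events = _read_events(g)
        meta = _read_meta(g)
        if which == "raw":
            return RawSession(sample_rate=float(g.attrs["sample_rate"]),
                              meta=meta, **arrays, **events)
        return BinnedSession(bin_rate=float(g.attrs["bin_rate"]),
                             meta=meta, **arrays, **events)


def export_csv(binned: BinnedSession, path) -> None:
    """CSV export of the binned traces for interoperability."""
    df = pd.DataFrame({
        "time_s": binned.time,
        "f470": binned.f470,
        "f405": binned.f405,
        "velocity": binned.velocity,
        "lick": binned.lick,
    })
    df.to_csv(path, index=False)
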