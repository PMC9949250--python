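"""Domain types, session-bundle I/O and epoch/time algebra.

A recording day is a :class:`Session`: per-unit spike trains, multichannel
LFP, a position trace and a labelled block schedule (PRE / MAZE / POST).
All timestamps are seconds (float64) with session start at 0; zeitgeber
time is stored as an offset.  Intervals are half-open ``[start, stop)``
everywhere so that partitions are exact.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import epoch_mask, interval_complement, merge_intervals

__all__ = [
    "EpochSet",
    "SpikeUnit",
    "UnitSpikeTrains",
    "LFPRecording",
    "PositionTrace",
    "Session",
    "load_session",
    "save_session",
    "restrict_spikes",
    "block_partition",
]

PN, IN, UNCLASSIFIED = "PN", "IN", "UNCLASSIFIED"


class SessionValidationError(ValueError):
    """A session bundle violates an invariant (e.g. unordered timestamps)."""


class EpochSet:
    """Ordered, labelled half-open time intervals.

    Backed by a DataFrame with columns ``start``, ``stop``, ``label`` plus
    arbitrary per-interval attribute columns.  Intervals sharing a label
    must be non-overlapping.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"start", "stop", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"EpochSet needs columns {sorted(required)}")
        df = df.sort_values(["start", "stop"], kind="stable").reset_index(drop=True)
        if len(df) and not (df["start"].to_numpy() < df["stop"].to_numpy()).all():
            raise ValueError("every interval must satisfy start < stop")
        for label, grp in df.groupby("label"):
            starts = grp["start"].to_numpy()
            stops = grp["stop"].to_numpy()
            if (starts[1:] < stops[:-1]).any():
                raise ValueError(f"intervals with label {label!r} overlap")
        self._df = df

    @classmethod
    def from_arrays(cls, starts, stops, labels, **attrs) -> "EpochSet":
        data = {"start": np.asarray(starts, float), "stop": np.asarray(stops, float), "label": list(labels)}
        data.update(attrs)
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "EpochSet":
        return cls(pd.DataFrame({"start": [], "stop": [], "label": []}))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        labs = ", ".join(f"{l}:{n}" for l, n in self._df["label"].value_counts().items())
        return f"EpochSet({len(self)} intervals; {labs})"

    @property
    def starts(self) -> np.ndarray:
        return self._df["start"].to_numpy()

    @property
    def stops(self) -> np.ndarray:
        return self._df["stop"].to_numpy()

    @property
    def labels(self) -> list:
        return list(self._df["label"])

    @property
    def intervals(self) -> np.ndarray:
        return self._df[["start", "stop"]].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self.stops - self.starts

    def total_duration(self) -> float:
        return float(merge_intervals(self.intervals)[:, 1].sum() - merge_intervals(self.intervals)[:, 0].sum()) if len(self) else 0.0

    def select(self, label) -> "EpochSet":
        labels = [label] if isinstance(label, str) else list(label)
        return EpochSet(self._df[self._df["label"].isin(labels)])

    def contains(self, times) -> np.ndarray:
        return epoch_mask(times, self.intervals)

    def complement(self, span: tuple[float, float], label: str = "complement") -> "EpochSet":
        iv = interval_complement(self.intervals, span)
        return EpochSet.from_arrays(iv[:, 0], iv[:, 1], [label] * len(iv))

    def to_tsv(self, path) -> None:
        self._df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EpochSet":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={"start_s": "start", "stop_s": "stop"})
        return cls(df)


@dataclass
class SpikeUnit:
    """One sorted unit: spike times plus classification metadata."""

    unit_id: int
    spike_times: np.ndarray            # s, sorted ascending
    shank: int = 0
    putative_type: str = UNCLASSIFIED
    stable: bool = True
    mean_waveform: np.ndarray | None = None   # (n_channels_on_shank, n_samples), uV
    wf_fs: float = 30000.0

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1 and (np.diff(self.spike_times) < 0).any():
            raise SessionValidationError(f"unit {self.unit_id}: spike times not sorted")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else 0.0


class UnitSpikeTrains:
    """Ordered collection of :class:`SpikeUnit`, keyed by unit id."""

    def __init__(self, units: list[SpikeUnit]):
        ids = [u.unit_id for u in units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids")
        self._units = {u.unit_id: u for u in sorted(units, key=lambda u: u.unit_id)}

    def __len__(self) -> int:
        return len(self._units)

    def __iter__(self):
        return iter(self._units.values())

    def __getitem__(self, unit_id: int) -> SpikeUnit:
        return self._units[unit_id]

    @property
    def unit_ids(self) -> list[int]:
        return list(self._units)

    def subset(self, unit_ids) -> "UnitSpikeTrains":
        return UnitSpikeTrains([self._units[i] for i in unit_ids])

    def select(self, putative_type: str | None = None, stable: bool | None = None) -> "UnitSpikeTrains":
        keep = []
        for u in self:
            if putative_type is not None and u.putative_type != putative_type:
                continue
            if stable is not None and u.stable != stable:
                continue
            keep.append(u)
        return UnitSpikeTrains(keep)

    def n_spikes(self) -> int:
        return sum(u.n_spikes for u in self)

    def all_spike_times(self) -> np.ndarray:
        """Pooled (multi-unit) spike times, sorted."""
        if len(self) == 0:
            return np.array([])
        return np.sort(np.concatenate([u.spike_times for u in self]))


@dataclass
class LFPRecording:
    """Multichannel LFP in uV at the analysis rate (default 1250 Hz).

    ``shank`` gives shank membership per channel; ``depth`` the order within
    its shank (0 = most superficial) and must be a permutation per shank.
    """

    samples: np.ndarray      # (n_channels, n_samples), uV
    fs: float
    shank: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        self.shank = np.asarray(self.shank, dtype=int)
        self.depth = np.asarray(self.depth, dtype=int)
        if self.fs <= 0:
            raise SessionValidationError("fs must be positive")
        if len(self.shank) != self.n_channels or len(self.depth) != self.n_channels:
            raise SessionValidationError("shank/depth must have one entry per channel")
        for sh in np.unique(self.shank):
            d = np.sort(self.depth[self.shank == sh])
            if not np.array_equal(d, np.arange(len(d))):
                raise SessionValidationError(f"depth order on shank {sh} is not a permutation")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channels_of_shank(self, sh: int) -> np.ndarray:
        idx = np.nonzero(self.shank == sh)[0]
        return idx[np.argsort(self.depth[idx])]

    def slice(self, start: float, stop: float) -> np.ndarray:
        i0 = max(0, int(np.floor(start * self.fs)))
        i1 = min(self.n_samples, int(np.ceil(stop * self.fs)))
        return self.samples[:, i0:i1]


@dataclass
class PositionTrace:
    """Animal position (cm) over time, with derived speed.

    Speed is computed on a uniform time grid at the native sampling rate by
    central differences, then Gaussian-smoothed (sigma = 0.25 s).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    linear: np.ndarray | None = None     # arc-length position on track, cm
    _speed: np.ndarray = field(default=None, repr=False)
    _grid_t: np.ndarray = field(default=None, repr=False)

    SPEED_SMOOTH_S = 0.25

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if (np.diff(self.t) < 0).any():
            raise SessionValidationError("position timestamps not sorted")
        if self.linear is not None:
            self.linear = np.asarray(self.linear, float)

    @property
    def fs(self) -> float:
        dt = np.median(np.diff(self.t)) if len(self.t) > 1 else 1.0
        return 1.0 / dt

    def _compute_speed(self) -> None:
        from scipy.ndimage import gaussian_filter1d

        dt = 1.0 / self.fs
        grid = np.arange(self.t[0], self.t[-1] + dt / 2, dt)
        gx = np.interp(grid, self.t, self.x)
        gy = np.interp(grid, self.t, self.y)
        vx = np.gradient(gx, dt)
        vy = np.gradient(gy, dt)
        sp = np.hypot(vx, vy)
        sigma = max(self.SPEED_SMOOTH_S / dt, 1e-9)
        self._speed = gaussian_filter1d(sp, sigma)
        self._grid_t = grid

    @property
    def speed(self) -> np.ndarray:
        """Speed (cm/s) on the uniform grid (see :attr:`grid_t`)."""
        if self._speed is None:
            self._compute_speed()
        return self._speed

    @property
    def grid_t(self) -> np.ndarray:
        if self._grid_t is None:
            self._compute_speed()
        return self._grid_t

    def speed_at(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, float), self.grid_t, self.speed)

    def linear_at(self, times) -> np.ndarray:
        if self.linear is None:
            raise ValueError("no linearized position available")
        return np.interp(np.asarray(times, float), self.t, self.linear)


@dataclass
class Session:
    """One recording day binding spikes, LFP, position and block schedule."""

    units: UnitSpikeTrains
    lfp: LFPRecording
    position: PositionTrace
    blocks: EpochSet
    condition: str                 # "NSD" | "SD"
    zeitgeber_zero: float = 0.0    # s, ZT0 = light onset
    track_length: float = 200.0    # cm
    duration: float | None = None

    def __post_init__(self):
        if self.condition not in ("NSD", "SD"):
            raise SessionValidationError(f"condition must be NSD or SD, got {self.condition!r}")
        if self.duration is None:
            self.duration = float(self.lfp.duration) if self.lfp is not None else float(self.blocks.stops.max())
        self.validate()

    def validate(self) -> None:
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < 0 or u.spike_times[-1] > self.duration + 1e-9):
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike at "
                    f"{u.spike_times[0] if u.spike_times[0] < 0 else u.spike_times[-1]:.3f} s "
                    f"outside session [0, {self.duration:.3f}] s"
                )
        iv = self.blocks.intervals
        if len(iv):
            if iv[:, 0].min() < -1e-9 or iv[:, 1].max() > self.duration + 1e-9:
                raise SessionValidationError("block outside session span")
            if (iv[1:, 0] < iv[:-1, 1] - 1e-9).any():
                raise SessionValidationError("blocks overlap or are unordered")

    def block(self, label: str) -> tuple[float, float]:
        sub = self.blocks.select(label)
        if len(sub) != 1:
            raise KeyError(f"expected exactly one block {label!r}, found {len(sub)}")
        return float(sub.starts[0]), float(sub.stops[0])


# ---------------------------------------------------------------------------
# native bundle I/O
# ---------------------------------------------------------------------------

_BUNDLE_FILES = ["spikes.tsv", "units.tsv", "lfp.bin", "lfp.json", "position.tsv", "epochs.tsv", "session.json"]


def save_session(session: Session, path, overwrite: bool = False) -> None:
    """Write a session to a native bundle directory.

    LFP is stored as little-endian int16 with a per-bundle uV-per-bit scale;
    everything else is TSV/JSON.  Refuses to clobber an existing bundle
    unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and any(path.iterdir()):
        if not overwrite:
            raise FileExistsError(f"bundle already exists at {path}; pass overwrite=True")
        shutil.rmtree(path)
    path.mkdir(parents=True, exist_ok=True)

    rows_id, rows_t = [], []
    for u in session.units:
        rows_id.append(np.full(u.n_spikes, u.unit_id, dtype=int))
        rows_t.append(u.spike_times)
    spikes = pd.DataFrame({
        "unit_id": np.concatenate(rows_id) if rows_id else np.array([], int),
        "time_s": np.concatenate(rows_t) if rows_t else np.array([]),
    })
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False, float_format="%.6f")

    pd.DataFrame({
        "unit_id": [u.unit_id for u in session.units],
        "shank": [u.shank for u in session.units],
        "putative_type": [u.putative_type for u in session.units],
        "stable": [int(u.stable) for u in session.units],
    }).to_csv(path / "units.tsv", sep="\t", index=False)

    wf_units = [u for u in session.units if u.mean_waveform is not None]
    if wf_units:
        shapes = {u.mean_waveform.shape for u in wf_units}
        if len(shapes) != 1:
            raise ValueError("all mean waveforms must share a shape")
        stack = np.stack([u.mean_waveform for u in wf_units]).astype(np.float32)
        stack.tofile(path / "waveforms.dat")
        (path / "waveforms.json").write_text(json.dumps({
            "shape": list(stack.shape), "dtype": "float32",
            "unit_ids": [u.unit_id for u in wf_units],
            "wf_fs": wf_units[0].wf_fs,
        }, sort_keys=True))

    lfp = session.lfp
    scale = float(np.abs(lfp.samples).max() / 32000.0) if lfp.samples.size and np.abs(lfp.samples).max() > 0 else 1.0
    ints = np.round(lfp.samples.T / scale).astype("<i2")   # channel-interleaved
    ints.tofile(path / "lfp.bin")
    (path / "lfp.json").write_text(json.dumps({
        "fs": lfp.fs, "n_channels": lfp.n_channels, "uv_per_bit": scale,
        "shank": lfp.shank.tolist(), "depth": lfp.depth.tolist(),
    }, sort_keys=True))

    pos = {"t_s": session.position.t, "x_cm": session.position.x, "y_cm": session.position.y}
    if session.position.linear is not None:
        pos["linear_cm"] = session.position.linear
    pd.DataFrame(pos).to_csv(path / "position.tsv", sep="\t", index=False, float_format="%.6f")

    df = session.blocks.df.rename(columns={"start": "start_s", "stop": "stop_s"})
    df.to_csv(path / "epochs.tsv", sep="\t", index=False, float_format="%.6f")

    (path / "session.json").write_text(json.dumps({
        "condition": session.condition,
        "zeitgeber_zero_s": session.zeitgeber_zero,
        "track_length_cm": session.track_length,
        "duration_s": session.duration,
    }, sort_keys=True))


def load_session(path) -> Session:
    """Load and validate a native bundle written by :func:`save_session`."""
    path = Path(path)
    for fname in _BUNDLE_FILES:
        if not (path / fname).exists():
            raise FileNotFoundError(f"bundle at {path} is missing {fname}")

    meta = json.loads((path / "session.json").read_text())
    lmeta = json.loads((path / "lfp.json").read_text())

    raw = np.fromfile(path / "lfp.bin", dtype="<i2")
    n_ch = int(lmeta["n_channels"])
    samples = (raw.reshape(-1, n_ch).T * lmeta["uv_per_bit"]).astype(np.float32)
    lfp = LFPRecording(samples, float(lmeta["fs"]), np.array(lmeta["shank"]), np.array(lmeta["depth"]))

    utab = pd.read_csv(path / "units.tsv", sep="\t")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    by_unit = {int(uid): grp["time_s"].to_numpy() for uid, grp in spikes.groupby("unit_id")}

    waveforms, wf_fs = {}, 30000.0
    if (path / "waveforms.json").exists():
        wmeta = json.loads((path / "waveforms.json").read_text())
        stack = np.fromfile(path / "waveforms.dat", dtype=np.float32).reshape(wmeta["shape"])
        wf_fs = float(wmeta["wf_fs"])
        waveforms = {int(uid): stack[i] for i, uid in enumerate(wmeta["unit_ids"])}

    units = UnitSpikeTrains([
        SpikeUnit(
            unit_id=int(r.unit_id),
            spike_times=by_unit.get(int(r.unit_id), np.array([])),
            shank=int(r.shank),
            putative_type=str(r.putative_type),
            stable=bool(r.stable),
            mean_waveform=waveforms.get(int(r.unit_id)),
            wf_fs=wf_fs,
        )
        for r in utab.itertuples()
    ])

    ptab = pd.read_csv(path / "position.tsv", sep="\t")
    position = PositionTrace(
        ptab["t_s"].to_numpy(), ptab["x_cm"].to_numpy(), ptab["y_cm"].to_numpy(),
        linear=ptab["linear_cm"].to_numpy() if "linear_cm" in ptab else None,
    )

    blocks = EpochSet.from_tsv(path / "epochs.tsv")

    return Session(
        units=units, lfp=lfp, position=position, blocks=blocks,
        condition=meta["condition"], zeitgeber_zero=float(meta["zeitgeber_zero_s"]),
        track_length=float(meta["track_length_cm"]), duration=float(meta["duration_s"]),
    )


# ---------------------------------------------------------------------------
# epoch algebra on spikes / blocks
# ---------------------------------------------------------------------------

def restrict_spikes(units: UnitSpikeTrains, epochs: EpochSet) -> UnitSpikeTrains:
    """Keep only spikes inside some interval of ``epochs`` (half-open)."""
    iv = epochs.intervals
    out = []
    for u in units:
        mask = epoch_mask(u.spike_times, iv)
        out.append(SpikeUnit(u.unit_id, u.spike_times[mask], u.shank, u.putative_type,
                             u.stable, u.mean_waveform, u.wf_fs))
    return UnitSpikeTrains(out)


def block_partition(session: Session, block_hours: float = 2.5,
                    sd_hours: float = 5.0) -> EpochSet:
    """Split POST into consecutive blocks of ``block_hours``.

    NSD sessions are labelled NS1, NS2, ...; SD sessions SD1, SD2 up to the
    end of the deprivation period (``sd_hours``), then RS, RS2, ....  A
    trailing partial block is retained and flagged with ``partial=True``.
    PRE and MAZE blocks are passed through unchanged.
    """
    post_start, post_stop = session.block("POST")
    width = block_hours * 3600.0
    edges = np.arange(post_start, post_stop, width)
    starts = edges
    stops = np.minimum(edges + width, post_stop)

    labels = []
    n_sd_blocks = int(round(sd_hours * 3600.0 / width))
    for i in range(len(starts)):
        if session.condition == "NSD":
            labels.append(f"NS{i + 1}")
        elif i < n_sd_blocks:
            labels.append(f"SD{i + 1}")
        else:
            k = i - n_sd_blocks
            labels.append("RS" if k == 0 else f"RS{k + 1}")
    partial = [bool(stop - start < width - 1e-6) for start, stop in zip(starts, stops)]

    pre = session.blocks.select(["PRE", "MAZE"]).df
    rows = pd.DataFrame({"start": starts, "stop": stops, "label": labels, "partial": partial})
    pre = pre.assign(partial=False)[["start", "stop", "label", "partial"]]
    return EpochSet(pd.concat([pre, rows], ignore_index=True))
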