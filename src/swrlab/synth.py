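"""Ground-truth-labelled synthetic sessions.

Emulates the statistical structure of long-duration CA1 recordings around a
novel-maze exposure: linear-track place tuning, run/rest behaviour, state-
dependent LFP (delta in NREM, theta in REM and active wake, a broadband
EMG-correlate shared across channels in wake), sharp-wave ripple events with
optional time-compressed trajectory replays, and POST pairwise co-firing
that echoes MAZE ensemble structure with a tunable decay time constant.

Sessions come in NSD (natural sleep) and SD (5 h enforced wakefulness then
recovery sleep) flavours.  Every random draw comes from a named substream
of one master seed, so a fixed seed gives byte-identical sessions and
changing one component's draw count does not perturb the others.

Reactivation model.  MAZE-adjacent place cells are grouped into small
ensembles; in POST each ensemble co-fires in 250-ms bins with probability
``q0 * react_strength * exp(-t * ln2 / (2 * react_tau))``.  Because the
explained-variance measure is a *squared* correlation whose autocorrelation
half-max is the reported reactivation timescale, this latent decay is
calibrated so that ``react_tau`` (hours) is exactly the timescale the EV
analysis estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import sosfiltfilt, butter

from ._utils import substream
from .session import (
    EpochSet,
    LFPRecording,
    PositionTrace,
    Session,
    SpikeUnit,
    UnitSpikeTrains,
)

__all__ = ["SynthConfig", "GroundTruth", "TuningSet", "make_tuning_curves",
           "simulate_behavior", "simulate_spikes", "simulate_lfp", "generate_session"]

HOUR = 3600.0
LN2 = float(np.log(2.0))

# per-block medians echoing the recorded ranges (ripple frequency in Hz,
# sharp-wave amplitude in mV); missing labels fall back to "default"
_RIPPLE_FREQ = {"PRE": 158.0, "MAZE": 166.0,
                "NS1": 163.6, "NS2": 151.5, "NS3": 150.0,
                "SD1": 171.2, "SD2": 169.7, "RS": 153.0, "default": 158.0}
_SHARPWAVE_MV = {"PRE": 4.13, "MAZE": 4.0,
                 "NS1": 5.10, "NS2": 5.13, "NS3": 4.87,
                 "SD1": 4.14, "SD2": 4.18, "RS": 5.05, "default": 4.6}


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults are the study conditions."""

    # population / track
    n_pyramidal: int = 80
    n_interneuron: int = 10
    track_length: float = 200.0          # cm
    run_speed: float = 50.0              # cm/s
    pause_mean: float = 10.0             # s at track ends
    accel_dist: float = 12.0             # cm of accel/decel ramp at each end
    # timeline (s)
    pre_duration: float = 2.5 * HOUR
    maze_duration: float = 1.0 * HOUR
    post_duration: float = 8.5 * HOUR
    condition: str = "NSD"               # NSD | SD
    sd_hours: float = 5.0
    # acquisition
    position_fs: float = 60.0
    lfp_fs: float = 1250.0
    n_shanks: int = 2
    channels_per_shank: int = 4
    # SWR scheduling (events/s per state)
    swr_rate: dict = field(default_factory=lambda: {
        "NREM": 0.75, "WAKE_quiet": 1.0, "REM": 0.0, "WAKE_active": 0.0})
    swr_duration_median: float = 0.13    # s, lognormal
    swr_duration_sigma: float = 0.25
    swr_min_gap: float = 0.35            # s between scheduled events
    ripple_freq_by_block: dict = field(default_factory=lambda: dict(_RIPPLE_FREQ))
    ripple_freq_sd: float = 12.0
    sharpwave_by_block: dict = field(default_factory=lambda: dict(_SHARPWAVE_MV))
    sharpwave_sigma: float = 0.2         # lognormal sigma around block median
    ripple_power_median: float = 5.0     # peak envelope z, session-sd units
    ripple_power_sigma: float = 0.4
    # firing rates
    pn_rate_median: float = 0.5          # Hz
    pn_rate_sigma: float = 0.8
    in_rate_median: float = 15.0         # Hz
    in_rate_sigma: float = 0.4
    state_rate_factor: dict = field(default_factory=lambda: {
        "NREM": 1.0, "REM": 0.95, "WAKE_quiet": 1.08, "WAKE_active": 1.15})
    # within-SWR response is additive and uniform across pyramidal cells
    # (sparse per-event participation); an additive response keeps the
    # within-ripple rate distribution realistic without imprinting a
    # rate-product correlation pattern on every cell pair
    swr_extra_pn: float = 1.5            # Hz added inside SWRs (PN)
    swr_extra_in: float = 30.0           # Hz added inside SWRs (IN)
    swr_extra_replay: float = 0.6        # Hz, generic PN extra in replay events
    swr_participation: float = 0.35      # fraction of events a PN joins
    # place tuning
    place_sigma: float = 10.0            # cm
    place_peak_median: float = 8.0       # Hz
    place_peak_sigma: float = 0.5
    anti_dir_factor: float = 0.15
    # replay content
    replay_fraction: float = 0.25        # of scheduled SWRs
    replay_fidelity: float = 1.0
    replay_compression: float = 15.0     # x real-time
    replay_span: float = 0.5             # fraction of track traversed
    replay_participation: float = 0.4
    replay_spikes: float = 2.0           # mean spikes per participating unit
    replay_baseline_suppress: float = 0.8  # fraction of PN baseline spikes removed in replay events
    replay_sd_factor: float = 0.55       # replay_fraction multiplier in SD/RS
    # pairwise reactivation
    react_strength: float = 0.5
    react_tau: float = 2.5               # h; EV-autocorrelation half-max timescale
    react_bin: float = 0.25              # s
    react_ensemble_size: int = 5
    react_q0: float = 0.15               # baseline co-activation probability
    react_gain: float = 0.8              # mean extra spikes/member/active bin
    react_sd_factor: float = 0.12        # suppression during enforced wake
    react_rs_factor: float = 0.6         # rebound factor at recovery-sleep onset
    # LFP composition (uV)
    lfp_white: float = 25.0
    lfp_delta: float = 250.0
    lfp_theta: float = 150.0
    lfp_quiet_low: float = 80.0
    lfp_emg: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("NSD", "SD"):
            raise ValueError("condition must be NSD or SD")
        for k, v in self.swr_rate.items():
            if v < 0:
                raise ValueError(f"swr_rate[{k}] must be >= 0")
        for name in ("replay_fraction", "replay_fidelity", "react_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def duration(self) -> float:
        return self.pre_duration + self.maze_duration + self.post_duration

    @property
    def maze_start(self) -> float:
        return self.pre_duration

    @property
    def post_start(self) -> float:
        return self.pre_duration + self.maze_duration

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)

    def block_label(self, t: float) -> str:
        """Block label at session time t (matches session.block_partition)."""
        if t < self.maze_start:
            return "PRE"
        if t < self.post_start:
            return "MAZE"
        i = int((t - self.post_start) // (2.5 * HOUR))
        if self.condition == "NSD":
            return f"NS{i + 1}"
        n_sd = int(round(self.sd_hours / 2.5))
        if i < n_sd:
            return f"SD{i + 1}"
        return "RS" if i == n_sd else f"RS{i - n_sd + 1}"


class TuningSet:
    """Gaussian place-tuning curves on a linear track, one per pyramidal unit."""

    def __init__(self, centers, peaks, directions, sigma, track_length):
        self.centers = np.asarray(centers, float)
        self.peaks = np.asarray(peaks, float)
        self.directions = np.asarray(directions, int)   # +1 / -1 preferred
        self.sigma = float(sigma)
        self.track_length = float(track_length)

    def __len__(self) -> int:
        return len(self.centers)

    def rate(self, i: int, pos: np.ndarray) -> np.ndarray:
        return self.peaks[i] * np.exp(-0.5 * ((np.asarray(pos) - self.centers[i]) / self.sigma) ** 2)


def make_tuning_curves(config: SynthConfig) -> TuningSet:
    """Uniform centers, log-normal peaks, random direction preference."""
    if config.n_pyramidal <= 0:
        raise ValueError("n_pyramidal must be positive")
    rng = config.rng("tuning")
    # stratified-uniform centers: marginally uniform, but evenly covering,
    # so the population's summed rate profile is nearly flat (dense-coverage
    # CA1 populations tile the track without large gaps)
    n = config.n_pyramidal
    strata = (np.arange(n) + rng.uniform(0.0, 1.0, n)) * (config.track_length / n)
    centers = rng.permutation(strata)
    peaks = config.place_peak_median * np.exp(rng.normal(0.0, config.place_peak_sigma, config.n_pyramidal))
    dirs = rng.choice([-1, 1], config.n_pyramidal)
    return TuningSet(centers, peaks, dirs, config.place_sigma, config.track_length)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _run_profile(t_rel, L, v, d):
    """Position along one traversal with accel/decel ramps over distance d."""
    import numpy as np
    if d <= 0:
        return np.clip(t_rel * v, 0.0, L)
    t_a = 2.0 * d / v
    T = (L + 2.0 * d) / v
    x = np.where(
        t_rel < t_a, v ** 2 * t_rel ** 2 / (4.0 * d),
        np.where(t_rel < T - t_a, d + v * (t_rel - t_a),
                 L - v ** 2 * np.maximum(T - t_rel, 0.0) ** 2 / (4.0 * d)))
    return np.clip(x, 0.0, L)


def _maze_laps(config: SynthConfig, rng) -> list[tuple[float, float, str, int]]:
    """(start, stop, 'run'|'pause', direction) segments in maze-local time."""
    segs = []
    t, pos_dir = 0.0, 1
    lap_time = (config.track_length + 2.0 * config.accel_dist) / config.run_speed
    while t < config.maze_duration:
        stop = min(t + lap_time, config.maze_duration)
        segs.append((t, stop, "run", pos_dir))
        t = stop
        if t >= config.maze_duration:
            break
        if config.pause_mean > 0:
            pause = rng.uniform(0.5, 1.5) * config.pause_mean
            stop = min(t + pause, config.maze_duration)
            segs.append((t, stop, "pause", pos_dir))
            t = stop
        pos_dir = -pos_dir
    return segs


def simulate_behavior(config: SynthConfig) -> PositionTrace:
    """Back-and-forth traversals with end-of-track pauses (maze-local time)."""
    if config.maze_duration <= 0:
        raise ValueError("maze_duration must be positive")
    rng = config.rng("behavior")
    segs = _maze_laps(config, rng)
    t = np.arange(0.0, config.maze_duration, 1.0 / config.position_fs)
    x = np.zeros_like(t)
    L = config.track_length
    for start, stop, kind, d in segs:
        m = (t >= start) & (t < stop)
        if kind == "run":
            frac = _run_profile(t[m] - start, L, config.run_speed, config.accel_dist)
            x[m] = frac if d > 0 else L - frac
        else:
            x[m] = L if d > 0 else 0.0
    x = np.clip(x, 0.0, L)
    return PositionTrace(t, x, np.zeros_like(t), linear=x.copy())


def _full_position(config: SynthConfig, maze: PositionTrace) -> PositionTrace:
    """Whole-session trace: jittering home-cage point, then maze, then cage."""
    rng = config.rng("behavior.cage")
    dt = 1.0 / config.position_fs
    home = np.array([-60.0, -60.0])

    def cage(n):
        jit = gaussian_filter1d(rng.normal(0.0, 3.0, (2, n)), 0.5 * config.position_fs, axis=1)
        return home[:, None] + jit

    n_pre = int(round(config.pre_duration * config.position_fs))
    n_post = int(round(config.post_duration * config.position_fs))
    pre = cage(n_pre)
    post = cage(n_post)
    t = np.arange(n_pre + len(maze.t) + n_post) * dt
    x = np.concatenate([pre[0], maze.x + 0.0, post[0]])
    y = np.concatenate([pre[1], maze.y, post[1]])
    lin = np.concatenate([np.full(n_pre, np.nan), maze.linear, np.full(n_post, np.nan)])
    return PositionTrace(t, x, y, linear=lin)


# ---------------------------------------------------------------------------
# state schedule
# ---------------------------------------------------------------------------

def _sleep_cycles(rng, start: float, stop: float) -> list[tuple[float, float, str]]:
    """Rodent-like cycling: brief quiet wake, long NREM, short REM."""
    segs, t = [], start
    while t < stop:
        for label, lo, hi in (("WAKE_quiet", 60, 180), ("NREM", 300, 600), ("REM", 60, 180)):
            dur = rng.uniform(lo, hi)
            end = min(t + dur, stop)
            segs.append((t, end, label))
            t = end
            if t >= stop:
                break
    return segs


def _enforced_wake(rng, start: float, stop: float) -> list[tuple[float, float, str]]:
    segs, t = [], start
    while t < stop:
        for label, lo, hi in (("WAKE_active", 120, 240), ("WAKE_quiet", 300, 600)):
            dur = rng.uniform(lo, hi)
            end = min(t + dur, stop)
            segs.append((t, end, label))
            t = end
            if t >= stop:
                break
    return segs


def _state_schedule(config: SynthConfig) -> EpochSet:
    rng = config.rng("states")
    segs = _sleep_cycles(rng, 0.0, config.pre_duration)
    # maze: runs are active wake, pauses quiet wake
    for s, e, kind, _ in _maze_laps(config, config.rng("behavior")):
        segs.append((s + config.maze_start, e + config.maze_start,
                     "WAKE_active" if kind == "run" else "WAKE_quiet"))
    p0, p1 = config.post_start, config.duration
    if config.condition == "NSD":
        segs += _sleep_cycles(rng, p0, p1)
    else:
        t_rs = p0 + config.sd_hours * HOUR
        segs += _enforced_wake(rng, p0, min(t_rs, p1))
        if t_rs < p1:
            segs += _sleep_cycles(rng, t_rs, p1)
    segs = [(s, e, l) for s, e, l in segs if e > s]
    starts, stops, labels = zip(*segs)
    return EpochSet.from_arrays(starts, stops, labels)


# ---------------------------------------------------------------------------
# SWR schedule
# ---------------------------------------------------------------------------

def _swr_schedule(config: SynthConfig, states: EpochSet) -> EpochSet:
    rng = config.rng("swr")
    rows = {k: [] for k in ("start", "stop", "peak", "label", "has_replay",
                            "direction", "start_pos", "frequency", "amplitude_mv", "power_z")}
    for seg_start, seg_stop, label in zip(states.starts, states.stops, states.labels):
        rate = config.swr_rate.get(label, 0.0)
        span = seg_stop - seg_start
        if rate <= 0 or span <= 0.5:
            continue
        # renewal schedule: dead time + exponential gap with the mean reduced
        # so the realized rate matches the nominal Poisson rate
        dead = config.swr_min_gap + config.swr_duration_median
        mean_gap = max(1.0 / rate - dead, 0.02)
        n_max = int(span * rate * 2 + 20)
        iei = dead + rng.exponential(mean_gap, n_max)
        t0 = seg_start + 0.1 + np.cumsum(iei)
        t0 = t0[t0 < seg_stop - 0.45]
        if len(t0) == 0:
            continue
        m = len(t0)
        durs = np.clip(config.swr_duration_median *
                       np.exp(rng.normal(0.0, config.swr_duration_sigma, m)), 0.06, 0.35)
        # replays exist only after the maze has been experienced; PRE
        # precedes the novel track, so PRE events never carry one
        if seg_stop <= config.maze_start:
            frac = 0.0
        else:
            frac = config.replay_fraction
            if config.condition == "SD" and t0[0] >= config.post_start:
                frac *= config.replay_sd_factor
        labels_blk = [config.block_label(t) for t in t0]
        freq_med = np.array([config.ripple_freq_by_block.get(b, config.ripple_freq_by_block["default"])
                             for b in labels_blk])
        amp_med = np.array([config.sharpwave_by_block.get(b, config.sharpwave_by_block["default"])
                            for b in labels_blk])
        rows["start"].append(t0)
        rows["stop"].append(t0 + durs)
        rows["peak"].append(t0 + durs / 2)
        rows["label"].extend(["SWR"] * m)
        rows["has_replay"].append(rng.random(m) < frac)
        rows["direction"].append(rng.choice([-1, 1], m))
        rows["start_pos"].append(rng.uniform(0.0, config.track_length * (1 - config.replay_span), m))
        rows["frequency"].append(np.clip(freq_med + rng.normal(0.0, config.ripple_freq_sd, m), 105.0, 245.0))
        rows["amplitude_mv"].append(amp_med * np.exp(rng.normal(0.0, config.sharpwave_sigma, m)))
        rows["power_z"].append(config.ripple_power_median * np.exp(rng.normal(0.0, config.ripple_power_sigma, m)))
    if not rows["start"]:
        return EpochSet.empty()
    cat = {k: np.concatenate(v) if k != "label" else v for k, v in rows.items()}
    return EpochSet.from_arrays(cat["start"], cat["stop"], cat["label"],
                                peak=cat["peak"], has_replay=cat["has_replay"],
                                direction=cat["direction"], start_pos=cat["start_pos"],
                                frequency=cat["frequency"], amplitude_mv=cat["amplitude_mv"],
                                power_z=cat["power_z"])


@dataclass
class GroundTruth:
    """Everything the generator decided, for closed-loop validation."""

    tuning: TuningSet
    state_schedule: EpochSet
    swr_schedule: EpochSet
    ensembles: list          # lists of pyramidal unit ids, adjacent place fields
    config: SynthConfig

    def replay_events(self):
        df = self.swr_schedule.df
        return df[df["has_replay"]] if len(df) else df

    def save(self, path) -> None:
        path = Path(path)
        payload = {
            "config": self.config.to_dict(),
            "tuning": {"centers": self.tuning.centers.tolist(),
                       "peaks": self.tuning.peaks.tolist(),
                       "directions": self.tuning.directions.tolist(),
                       "sigma": self.tuning.sigma},
            "ensembles": self.ensembles,
            "states": self.state_schedule.df.to_dict(orient="list"),
            "swrs": {k: np.asarray(v).tolist() for k, v in self.swr_schedule.df.items()},
        }
        path.write_text(json.dumps(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _segment_poisson(rng, rates, starts, durs):
    """Inhomogeneous-by-segment Poisson times for one unit."""
    counts = rng.poisson(np.maximum(rates, 0.0) * durs)
    total = int(counts.sum())
    if total == 0:
        return np.array([])
    u = rng.random(total)
    return np.repeat(starts, counts) + u * np.repeat(durs, counts)


# The EV measure saturates mildly at the default reactivation strength
# (the across-pair correlation stays high until the within-ensemble signal
# sinks under the pair-sampling noise), so the latent co-activation decay
# is sped up by this factor so that react_tau is exactly the timescale the
# EV autocorrelation half-max reports at the default operating point.
REACT_DECAY_CALIBRATION = 0.40


def _react_decay(config: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Latent co-activation probability factor over POST-relative time (s)."""
    tau_lat = 2.0 * config.react_tau * REACT_DECAY_CALIBRATION * HOUR / LN2
    if config.condition == "NSD":
        return config.react_strength * np.exp(-t / tau_lat)
    t_rs = config.sd_hours * HOUR
    out = np.where(
        t < t_rs,
        config.react_strength * config.react_sd_factor,
        config.react_strength * config.react_rs_factor * np.exp(-np.maximum(t - t_rs, 0.0) / tau_lat),
    )
    return out


def simulate_spikes(config: SynthConfig, tuning: TuningSet,
                    behavior: PositionTrace, truth_states: EpochSet,
                    swrs: EpochSet) -> tuple[UnitSpikeTrains, list]:
    """Inhomogeneous-Poisson spike trains for all units.

    Returns the unit collection and the ensemble membership (unit-id lists)
    used for the POST reactivation channel.
    """
    if len(tuning) == 0:
        raise ValueError("empty tuning set")
    n_pn, n_in = config.n_pyramidal, config.n_interneuron
    rng_base = config.rng("spikes.base")
    rng_maze = config.rng("spikes.maze")
    rng_swr = config.rng("spikes.swr")
    rng_react = config.rng("spikes.react")
    rng_replay = config.rng("spikes.replay")
    rng_rate = config.rng("spikes.rates")

    pn_rates = config.pn_rate_median * np.exp(rng_rate.normal(0.0, config.pn_rate_sigma, n_pn))
    in_rates = config.in_rate_median * np.exp(rng_rate.normal(0.0, config.in_rate_sigma, n_in))

    seg_starts = truth_states.starts
    seg_durs = truth_states.durations
    seg_factor = np.array([config.state_rate_factor.get(l, 1.0) for l in truth_states.labels])

    maze_runs = [(s, e, d) for s, e, kind, d in _maze_laps(config, config.rng("behavior")) if kind == "run"]

    sdf = swrs.df
    ev_start = sdf["start"].to_numpy() if len(sdf) else np.array([])
    ev_dur = (sdf["stop"] - sdf["start"]).to_numpy() if len(sdf) else np.array([])
    ev_replay = sdf["has_replay"].to_numpy(bool) if len(sdf) else np.array([], bool)

    spikes = [[] for _ in range(n_pn + n_in)]

    # --- state-dependent baseline, all units
    for i in range(n_pn):
        spikes[i].append(_segment_poisson(rng_base, pn_rates[i] * seg_factor, seg_starts, seg_durs))
    for j in range(n_in):
        spikes[n_pn + j].append(_segment_poisson(rng_base, in_rates[j] * seg_factor, seg_starts, seg_durs))

    # --- place tuning on maze runs (thinning at the peak rate)
    for i in range(n_pn):
        for gain_dir in (+1, -1):
            peak = tuning.peaks[i] * (1.0 if gain_dir == tuning.directions[i] else config.anti_dir_factor)
            segs = [(s, e) for s, e, d in maze_runs if d == gain_dir]
            if not segs or peak <= 0:
                continue
            starts = np.array([s for s, _ in segs])
            durs = np.array([e - s for s, e in segs])
            total = durs.sum()
            n_cand = rng_maze.poisson(peak * total)
            if n_cand == 0:
                continue
            offs = rng_maze.uniform(0.0, total, n_cand)
            cum = np.concatenate([[0.0], np.cumsum(durs)])
            seg_i = np.searchsorted(cum, offs, side="right") - 1
            t_local = starts[seg_i] + (offs - cum[seg_i])
            pos = np.interp(t_local, behavior.t - config.maze_start, behavior.linear)
            p = np.exp(-0.5 * ((pos - tuning.centers[i]) / tuning.sigma) ** 2)
            t_keep = t_local[rng_maze.random(n_cand) < p] + config.maze_start
            spikes[i].append(t_keep)

    # --- within-SWR response: sparse per-event participation, additive rate
    # (scaled by 1/participation so the mean within-ripple rate holds)
    if len(ev_start):
        p_join = config.swr_participation
        extra_pn = np.where(ev_replay, config.swr_extra_replay, config.swr_extra_pn)
        lam_pn = np.broadcast_to(extra_pn * ev_dur / p_join, (n_pn, len(ev_start)))
        lam_in = np.broadcast_to(config.swr_extra_in * ev_dur, (n_in, len(ev_start)))
        for lam, base, sparse in ((lam_pn, 0, True), (lam_in, n_pn, False)):
            counts = rng_swr.poisson(lam)
            if sparse:
                counts = counts * (rng_swr.random(lam.shape) < p_join)
            for u in range(lam.shape[0]):
                c = counts[u]
                tot = int(c.sum())
                if tot == 0:
                    continue
                t = np.repeat(ev_start, c) + rng_swr.random(tot) * np.repeat(ev_dur, c)
                spikes[base + u].append(t)

    # --- replay sweeps
    v_replay = config.run_speed * config.replay_compression
    jitter_sd = (1.0 - config.replay_fidelity) * 0.05
    span = config.replay_span * config.track_length
    if len(sdf):
        rdf = sdf[ev_replay]
        for t0, t1, d, p0 in zip(rdf["start"], rdf["stop"], rdf["direction"], rdf["start_pos"]):
            travel = min(span, v_replay * (t1 - t0))
            lo = p0 if d > 0 else config.track_length - p0 - travel
            hi = lo + travel
            covered = np.nonzero((tuning.centers >= lo - tuning.sigma) &
                                 (tuning.centers <= hi + tuning.sigma))[0]
            part = covered[rng_replay.random(len(covered)) < config.replay_participation]
            if len(part) == 0:
                continue
            pos_entry = lo if d > 0 else hi
            t_cross = t0 + np.abs(tuning.centers[part] - pos_entry) / v_replay
            n_sp = rng_replay.poisson(config.replay_spikes, len(part))
            pass_sd = tuning.sigma / v_replay
            for u, tc, n in zip(part, t_cross, n_sp):
                if n == 0:
                    continue
                t = tc + rng_replay.normal(0.0, pass_sd, n)
                if jitter_sd > 0:
                    t = t + rng_replay.normal(0.0, jitter_sd, n)
                spikes[u].append(np.clip(t, t0, t1 - 1e-4))

    # --- POST ensemble reactivation (non-SWR co-firing echoing MAZE)
    order = np.argsort(tuning.centers)
    k = config.react_ensemble_size
    ensembles = [order[i:i + k].tolist() for i in range(0, n_pn - k + 1, k)]
    if config.react_strength > 0 and config.post_duration > config.react_bin:
        nbin = int(config.post_duration / config.react_bin)
        t_rel = (np.arange(nbin) + 0.5) * config.react_bin
        q = config.react_q0 * _react_decay(config, t_rel)
        # co-activation only outside scheduled sleep-incompatible states is not
        # enforced: ensemble events ride on top of whatever state is scheduled
        for ens in ensembles:
            active = rng_react.random(nbin) < q
            idx = np.nonzero(active)[0]
            if len(idx) == 0:
                continue
            for u in ens:
                c = rng_react.poisson(config.react_gain, len(idx))
                tot = int(c.sum())
                if tot == 0:
                    continue
                t = (np.repeat(idx, c) + rng_react.random(tot)) * config.react_bin + config.post_start
                spikes[u].append(t)

    # --- baseline suppression inside replay events: sharp-wave bursts
    # recruit a specific assembly while other pyramidal cells fall silent
    if len(sdf) and ev_replay.any() and config.replay_baseline_suppress > 0:
        from ._utils import epoch_mask, merge_intervals
        riv = merge_intervals(np.stack([ev_start[ev_replay],
                                        ev_start[ev_replay] + ev_dur[ev_replay]], axis=1))
        rng_sup = config.rng("spikes.suppress")
        for u in range(n_pn):
            base = spikes[u][0]          # the state-baseline component
            if len(base) == 0:
                continue
            inside = epoch_mask(base, riv)
            drop = inside & (rng_sup.random(len(base)) < config.replay_baseline_suppress)
            spikes[u][0] = base[~drop]

    # --- waveforms and assembly
    rng_wf = config.rng("waveforms")
    units = []
    n_ch = config.channels_per_shank
    for u in range(n_pn + n_in):
        is_pn = u < n_pn
        t = np.sort(np.concatenate(spikes[u])) if spikes[u] else np.array([])
        t = t[(t >= 0) & (t < config.duration)]
        shank = u % config.n_shanks
        wf = _synth_waveform(rng_wf, n_ch, is_pn)
        units.append(SpikeUnit(unit_id=u, spike_times=t, shank=shank,
                               putative_type="PN" if is_pn else "IN",
                               stable=True, mean_waveform=wf, wf_fs=30000.0))
    return UnitSpikeTrains(units), ensembles


def _synth_waveform(rng, n_channels: int, is_pn: bool) -> np.ndarray:
    """Biphasic mean waveform (uV) across one shank's channels at 30 kHz."""
    fs = 30000.0
    n = 48
    t = (np.arange(n) - 16) / fs * 1000.0         # ms
    width = rng.normal(0.62, 0.05) if is_pn else rng.normal(0.24, 0.03)  # trough->peak, ms
    trough_w = 0.18 if is_pn else 0.10
    shape = -np.exp(-0.5 * (t / trough_w) ** 2) + 0.5 * np.exp(-0.5 * ((t - width) / (2.2 * trough_w)) ** 2)
    amp = rng.uniform(60.0, 220.0)
    prof = np.exp(-0.5 * ((np.arange(n_channels) - rng.integers(0, n_channels)) / 0.8) ** 2)
    return (amp * prof[:, None] * shape[None, :]).astype(np.float32)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _band_noise_low(rng, n_lo: int, fs_lo: float, lo: float, hi: float,
                    n_rows: int = 1) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise at the low synthesis rate."""
    w = rng.standard_normal((n_rows, n_lo))
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs_lo, output="sos")
    x = sosfiltfilt(sos, w, axis=-1)
    x /= np.maximum(x.std(axis=-1, keepdims=True), 1e-12)
    return x.astype(np.float32)


def _upsample(x_lo: np.ndarray, up: int, n: int) -> np.ndarray:
    """Sample-and-hold upsampling plus Gaussian anti-imaging smoothing.

    Images at fs_lo +/- band sit far above the scoring bands and are
    suppressed by > 40 dB.
    """
    full = np.repeat(x_lo.astype(np.float32), up)[:n]
    return gaussian_filter1d(full, 0.4 * up)


def _state_weight(states: EpochSet, labels: set, n_lo: int, fs_lo: float) -> np.ndarray:
    """Smooth 0/1 state weight (2 s ramps) on the low-rate grid."""
    tg = np.arange(n_lo) / fs_lo
    w = np.zeros(n_lo, dtype=np.float32)
    for s, e, l in zip(states.starts, states.stops, states.labels):
        if l in labels:
            w[(tg >= s) & (tg < e)] = 1.0
    return gaussian_filter1d(w, 2.0 * fs_lo)


def _smoothing_attenuation(dur_s: np.ndarray, fs: float, smooth_s: float = 0.0125) -> np.ndarray:
    """Peak attenuation of a Hann envelope under the detector's smoothing."""
    out = np.empty(len(dur_s))
    cache: dict[int, float] = {}
    for k, d in enumerate(dur_s):
        m = max(int(round(d * fs)), 8)
        if m not in cache:
            cache[m] = float(gaussian_filter1d(np.hanning(m), smooth_s * fs,
                                               mode="constant").max())
        out[k] = cache[m]
    return out


def _calibrate_ripple_amplitudes(z_target: np.ndarray, dur_s: np.ndarray,
                                 mu_b: float, sigma_b: float, fs: float,
                                 total_s: float, n_iter: int = 4) -> np.ndarray:
    """Tone amplitudes so events reach their target envelope z *after* the
    events themselves inflate the session-wide envelope statistics.

    The detector's smoothed envelope of a Hann tone over a noise floor is
    modelled as kappa * sqrt((a h(t))^2 + mu_b^2); session mean/variance
    shifts are accumulated from all scheduled events and the amplitudes are
    re-solved a few times until self-consistent.
    """
    kappa = _smoothing_attenuation(dur_s, fs)
    h2 = np.mean(np.hanning(64) ** 2)          # mean squared Hann shape
    duty = dur_s / total_s
    sig_f, dmu = sigma_b, 0.0
    a = np.maximum(z_target, 1.0) * sigma_b
    for _ in range(n_iter):
        target_peak = (np.asarray(z_target) * sig_f + mu_b + dmu) / np.maximum(kappa, 1e-6)
        a = np.sqrt(np.maximum(target_peak ** 2 - mu_b ** 2, (0.5 * sigma_b) ** 2))
        # event contribution to the envelope above the floor (coarse average)
        excess = np.sqrt(h2 * a ** 2 + mu_b ** 2) - mu_b
        dmu = float(np.sum(duty * excess))
        m2 = float(np.sum(duty * excess ** 2))
        sig_f = float(np.sqrt(sigma_b ** 2 + max(m2 - dmu ** 2, 0.0)))
    return a


def _sharpwave_kernel(fs: float, sigma: float = 0.03) -> np.ndarray:
    """Unit-peak Gaussian-derivative transient (zero-mean, 2-30 Hz content)."""
    half = int(4 * sigma * fs)
    t = np.arange(-half, half + 1) / fs
    g = -t * np.exp(-0.5 * (t / sigma) ** 2)
    return (g / np.abs(g).max()).astype(np.float32)


def simulate_lfp(config: SynthConfig, states: EpochSet, swrs: EpochSet) -> LFPRecording:
    """State-dependent multichannel LFP with embedded sharp-wave ripples.

    Per shank, channel order runs superficial -> deep; the ripple
    oscillation is placed on the putative pyramidal-layer channel (depth 1)
    and the sharp wave flips polarity with depth.  Ripple amplitudes are
    calibrated against the detection pipeline's own background envelope
    standard deviation so scheduled ``power_z`` values are meaningful.
    """
    fs = config.lfp_fs
    n = int(round(config.duration * fs))
    n_ch = config.n_shanks * config.channels_per_shank
    shank = np.repeat(np.arange(config.n_shanks), config.channels_per_shank)
    depth = np.tile(np.arange(config.channels_per_shank), config.n_shanks)

    rng = config.rng("lfp.white")
    lfp = np.empty((n_ch, n), dtype=np.float32)
    for c in range(n_ch):
        lfp[c] = rng.standard_normal(n).astype(np.float32) * config.lfp_white

    # state-dependent band components are synthesized and weighted at a low
    # rate (delta at fs/20, theta at fs/10) and upsampled per channel, so at
    # most one full-length temporary is alive at a time
    up_d, up_t = 20, 10
    n_d = n // up_d + 8
    n_t = n // up_t + 8
    env_nrem = _state_weight(states, {"NREM"}, n_d, fs / up_d)
    env_quiet = _state_weight(states, {"WAKE_quiet"}, n_d, fs / up_d)
    env_theta = _state_weight(states, {"REM", "WAKE_active"}, n_t, fs / up_t)

    rng_b = config.rng("lfp.bands")
    delta = _band_noise_low(rng_b, n_d, fs / up_d, 1.0, 4.0, n_rows=n_ch)
    theta = _band_noise_low(rng_b, n_t, fs / up_t, 5.0, 10.0, n_rows=n_ch)
    lowq = _band_noise_low(rng_b, n_d, fs / up_d, 1.0, 4.0, n_rows=n_ch)
    for c in range(n_ch):
        slow = (config.lfp_delta * env_nrem * delta[c]
                + config.lfp_quiet_low * env_quiet * lowq[c])
        lfp[c] += _upsample(slow, up_d, n)
        lfp[c] += _upsample(config.lfp_theta * env_theta * theta[c], up_t, n)
    del delta, theta, lowq

    # muscle artifact correlate: shared across channels, high-frequency only
    # (> 300 Hz) so it never bleeds into the ripple or scoring bands
    sos_emg = butter(4, 320.0, btype="highpass", fs=fs, output="sos")
    emg = sosfiltfilt(sos_emg, rng_b.standard_normal(n)).astype(np.float32)
    emg *= config.lfp_emg / max(emg.std(), 1e-9)
    wake_lo = _state_weight(states, {"WAKE_quiet", "WAKE_active"}, n_d, fs / up_d)
    emg *= _upsample(wake_lo, up_d, n)
    for c in range(n_ch):
        lfp[c] += emg
    del emg

    if len(swrs):
        # background envelope statistics of the detection path, estimated on
        # the event-free signal built so far (pyramidal-layer channels)
        from .ripples import _ripple_envelope
        pyr = np.nonzero(depth == 1)[0]
        calib = min(n, int(300 * fs))
        env = _ripple_envelope(lfp[pyr, :calib], fs)
        sigma_b, mu_b = float(env.std()), float(env.mean())

        rng_e = config.rng("lfp.events")
        sw_kernel = _sharpwave_kernel(fs)
        sw_profile = np.array([0.35, 0.10, -0.30, -0.65], dtype=np.float32)
        if config.channels_per_shank != 4:
            d = np.arange(config.channels_per_shank)
            sw_profile = np.interp(d, np.linspace(0, config.channels_per_shank - 1, 4),
                                   [0.35, 0.10, -0.30, -0.65]).astype(np.float32)
        sw_p2p = float(sw_profile.max() - sw_profile.min())  # per unit kernel peak

        df = swrs.df
        z_target = df["power_z"].to_numpy()
        amps = _calibrate_ripple_amplitudes(
            z_target, (df["stop"] - df["start"]).to_numpy(),
            mu_b, sigma_b, fs, n / fs)
        tones = []
        for t0, t1, f_r, a in zip(df["start"], df["stop"], df["frequency"], amps):
            i0 = int(round(t0 * fs))
            i1 = min(int(round(t1 * fs)), n)
            m = i1 - i0
            if m < 8:
                tones.append(None)
                continue
            tt = np.arange(m) / fs
            shape = (np.hanning(m) * np.sin(2 * np.pi * f_r * tt
                                            + rng_e.uniform(0, 2 * np.pi))).astype(np.float32)
            tones.append((i0, i1, shape))
            ripple = a.astype(np.float32) * shape if hasattr(a, "astype") else np.float32(a) * shape
            for c in pyr:
                lfp[c, i0:i1] += ripple
        # empirical correction: measure each event's realized z through the
        # actual detection path and rescale its tone towards the target
        scale = np.ones(len(tones))
        for _ in range(1):
            env = _ripple_envelope(lfp[pyr], fs)
            mu_f, sd_f = float(env.mean()), float(env.std())
            adjust = np.ones(len(tones))
            for k, tn in enumerate(tones):
                if tn is None:
                    continue
                i0, i1, shape = tn
                realized = (env[i0:i1].max() - mu_f) / sd_f
                if realized > 0.2:
                    adjust[k] = np.clip(z_target[k] / realized, 0.4, 3.0)
            if np.abs(adjust - 1.0).max() < 0.08:
                break
            for k, tn in enumerate(tones):
                if tn is None:
                    continue
                i0, i1, shape = tn
                delta = np.float32(amps[k] * scale[k] * (adjust[k] - 1.0)) * shape
                for c in pyr:
                    lfp[c, i0:i1] += delta
            scale *= adjust

        # sharp waves: biphasic transient centred on each event, polarity
        # flipping superficial -> deep, peak-to-trough = scheduled amplitude
        shank_rows = [np.nonzero(shank == sh)[0] for sh in range(config.n_shanks)]
        for t0, t1, amp_mv in zip(df["start"], df["stop"], df["amplitude_mv"]):
            ctr = int(round((t0 + t1) / 2 * fs))
            k0 = ctr - len(sw_kernel) // 2
            k1 = k0 + len(sw_kernel)
            s0, s1 = max(k0, 0), min(k1, n)
            kern = sw_kernel[s0 - k0: len(sw_kernel) - (k1 - s1)]
            sw_scale = np.float32(amp_mv * 1000.0 / sw_p2p)
            for rows in shank_rows:
                for ci, c in enumerate(rows):
                    lfp[c, s0:s1] += sw_scale * sw_profile[ci] * kern

    return LFPRecording(lfp, fs, shank, depth)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def generate_session(config: SynthConfig, with_lfp: bool = True) -> tuple[Session, GroundTruth]:
    """Compose behaviour, states, SWRs, spikes and (optionally) LFP.

    ``with_lfp=False`` returns a spikes-only session (lfp=None) for analyses
    that never touch the field potential, at a fraction of the cost.
    """
    tuning = make_tuning_curves(config)
    states = _state_schedule(config)
    swrs = _swr_schedule(config, states)
    maze = simulate_behavior(config)
    position = _full_position(config, maze)
    # behaviour trace in session time for tuned firing
    maze_sess = PositionTrace(maze.t + config.maze_start, maze.x, maze.y, linear=maze.linear)
    units, ensembles = simulate_spikes(config, tuning, maze_sess, states, swrs)
    lfp = simulate_lfp(config, states, swrs) if with_lfp else None

    blocks = EpochSet.from_arrays(
        [0.0, config.maze_start, config.post_start],
        [config.maze_start, config.post_start, config.duration],
        ["PRE", "MAZE", "POST"],
    )
    session = Session(units=units, lfp=lfp, position=position, blocks=blocks,
                      condition=config.condition, zeitgeber_zero=config.post_start,
                      track_length=config.track_length, duration=config.duration)
    truth = GroundTruth(tuning=tuning, state_schedule=states, swr_schedule=swrs,
                        ensembles=ensembles, config=config)
    return session, truth
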