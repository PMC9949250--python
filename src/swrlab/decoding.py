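"""Place-field rate maps, Bayesian event decoding and trajectory-replay calls.

Rate maps: per running direction, Gaussian-smoothed (sigma = 4 cm) spike
counts divided by equally smoothed occupancy in 2 cm bins, using only
samples with speed > 8 cm/s; units whose peak (over both directions) is
below 0.5 Hz are excluded from decoding.

Decoding: per 20 ms bin with counts n_i the posterior over position states

    P(x | n) = K * prod_i lambda_i[x]^{n_i} * exp(-tau * sum_i lambda_i[x])

computed in log space and normalized per time bin.  The two directional
maps are concatenated as 2*n_bins states; the decoded location is the
arc-length of the winning state, and jump distances between adjacent bins
are measured on arc-length regardless of direction state.

Replay rule: a candidate event (>= 5 active units, movement speed
< 8 cm/s, concurrent peak ripple power > 1 s.d.) is a trajectory replay
iff its decoded path holds a run of >= 4 consecutive spike-occupied time
bins (three consecutive jumps, spanning > 60 ms) whose adjacent jumps are
all < 40 cm and whose net traversal covers at least 35 cm.  The distance
clause implements "a continuous trajectory across space": a decoded point
parked in one location is not a trajectory, and without it the chance
rate of the jump rule on events of this length approaches one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session import EpochSet, PositionTrace, UnitSpikeTrains

__all__ = ["linearize_position", "RateMapSet", "compute_rate_maps",
           "select_candidates", "decode_posteriors", "PosteriorMatrix",
           "classify_trajectory_replay", "classify_path", "ReplayCall",
           "decode_events", "replay_proportions"]

LOG_RATE_FLOOR = 0.01   # Hz, keeps log-likelihoods finite off-field


def linearize_position(position: PositionTrace, skeleton: np.ndarray | None = None) -> PositionTrace:
    """Arc-length coordinate from nearest-point projection onto a polyline.

    Already-linearized traces pass through unchanged.  Ties between
    segments resolve to the lower arc length (the first minimal segment).
    """
    if position.linear is not None:
        return position
    if skeleton is None:
        raise ValueError("2-D positions need a track skeleton polyline")
    pts = np.stack([position.x, position.y], axis=1)
    seg = np.asarray(skeleton, float)
    a, b = seg[:-1], seg[1:]
    d = b - a
    seg_len = np.linalg.norm(d, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # (n_points, n_segments) projections
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psd,sd->ps", ap, d) / np.maximum(seg_len ** 2, 1e-12), 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    dist = np.linalg.norm(pts[:, None, :] - proj, axis=2)
    best = np.argmin(dist, axis=1)
    arc = cum[best] + t[np.arange(len(pts)), best] * seg_len[best]
    return PositionTrace(position.t, position.x, position.y, linear=arc)


@dataclass
class RateMapSet:
    """Directional firing-rate maps on a linear track."""

    rates: np.ndarray        # (n_units, 2, n_bins) Hz; dir 0 = increasing arc
    occupancy: np.ndarray    # (2, n_bins) s
    bin_edges: np.ndarray    # cm
    unit_ids: list
    included: list           # unit ids with peak >= min_peak

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def included_rates(self) -> np.ndarray:
        idx = [self.unit_ids.index(u) for u in self.included]
        return self.rates[idx]


def compute_rate_maps(units: UnitSpikeTrains, position: PositionTrace,
                      maze_interval: tuple[float, float], track_length: float,
                      bin_cm: float = 2.0, sigma_cm: float = 4.0,
                      speed_min: float = 8.0, min_peak_hz: float = 0.5,
                      min_occ_s: float = 0.1) -> RateMapSet:
    """Directional rate maps: smoothed counts over smoothed occupancy.

    Bins whose raw occupancy is under ``min_occ_s`` are zeroed: near the
    reward wells the animal is below the speed threshold, and the
    count/occupancy ratio in those barely-sampled bins is unstable.
    """
    t0, t1 = maze_interval
    gt = position.grid_t
    in_maze = (gt >= t0) & (gt < t1)
    speed = position.speed
    lin = np.interp(gt, position.t, np.nan_to_num(position.linear, nan=-1e6))
    vlin = np.gradient(lin, gt, edge_order=1)
    vlin = gaussian_filter1d(vlin, max(1.0, 0.25 * position.fs))
    moving = in_maze & (speed > speed_min) & (lin >= 0)
    if not moving.any():
        raise ValueError("no movement samples above the speed threshold")
    dt = 1.0 / position.fs
    edges = np.arange(0.0, track_length + bin_cm / 2, bin_cm)
    sig_bins = sigma_cm / bin_cm

    occ = np.zeros((2, len(edges) - 1))
    for d, sel in enumerate((vlin > 0, vlin <= 0)):
        occ[d], _ = np.histogram(lin[moving & sel], bins=edges)
    occ *= dt
    occ_s = gaussian_filter1d(occ, sig_bins, axis=1, mode="constant")

    rates = np.zeros((len(units), 2, len(edges) - 1))
    for r, u in enumerate(units):
        st = u.spike_times
        st = st[(st >= t0) & (st < t1)]
        if len(st) == 0:
            continue
        sp_speed = position.speed_at(st)
        sp_lin = np.interp(st, gt, lin)
        sp_v = np.interp(st, gt, vlin)
        ok = sp_speed > speed_min
        for d, sel in enumerate((sp_v > 0, sp_v <= 0)):
            cnt, _ = np.histogram(sp_lin[ok & sel], bins=edges)
            cnt_s = gaussian_filter1d(cnt.astype(float), sig_bins, mode="constant")
            with np.errstate(divide="ignore", invalid="ignore"):
                rates[r, d] = np.where(occ_s[d] > 1e-4, cnt_s / np.maximum(occ_s[d], 1e-12), 0.0)
    rates[:, occ < min_occ_s] = 0.0
    peaks = rates.max(axis=(1, 2))
    ids = units.unit_ids
    included = [ids[i] for i in range(len(ids)) if peaks[i] >= min_peak_hz]
    return RateMapSet(rates=rates, occupancy=occ, bin_edges=edges,
                      unit_ids=ids, included=included)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def select_candidates(bursts: EpochSet, units: UnitSpikeTrains,
                      position: PositionTrace, ripple_env: np.ndarray,
                      env_fs: float, included: list | None = None,
                      min_units: int = 5, speed_max: float = 8.0,
                      power_min_z: float = 1.0) -> pd.DataFrame:
    """Candidate filter for decoding: active units, immobility, ripple power.

    ``active`` counts included units with >= 1 spike inside the event;
    speed is the mean interpolated speed over the event; ripple power is
    the peak envelope z (whole-recording baseline) within the event.
    Returns a frame with is_candidate and the first failing criterion.
    """
    ids = included if included is not None else units.unit_ids
    sub = units.subset(ids)
    mu, sd = float(ripple_env.mean()), float(ripple_env.std())
    rows = []
    starts, stops = bursts.starts, bursts.stops
    peaks = bursts.df["peak"].to_numpy() if "peak" in bursts.df else (starts + stops) / 2
    spike_list = [u.spike_times for u in sub]
    for k, (t0, t1) in enumerate(zip(starts, stops)):
        n_active = sum(1 for st in spike_list
                       if np.searchsorted(st, t1, "left") > np.searchsorted(st, t0, "left"))
        n_sp = max(2, int((t1 - t0) * 100))
        speed = float(position.speed_at(np.linspace(t0, t1, n_sp)).mean())
        i0, i1 = int(t0 * env_fs), max(int(t0 * env_fs) + 1, int(t1 * env_fs))
        power_z = float((ripple_env[i0:i1].max() - mu) / sd) if sd > 0 else 0.0
        reason = ""
        if n_active < min_units:
            reason = "active_units"
        elif speed >= speed_max:
            reason = "speed"
        elif power_z <= power_min_z:
            reason = "ripple_power"
        rows.append({"event_id": k, "start": t0, "stop": t1, "peak": peaks[k],
                     "n_active": n_active, "speed": speed, "power_z": power_z,
                     "is_candidate": reason == "", "fail_reason": reason})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian decoding
# ---------------------------------------------------------------------------

@dataclass
class PosteriorMatrix:
    """Position-by-time posterior for one event."""

    posterior: np.ndarray     # (2*n_bins, n_t), columns sum to 1
    decoded: np.ndarray       # arc-length (cm) per time bin
    jumps: np.ndarray         # |delta decoded| per adjacent pair
    occupied: np.ndarray      # bool per time bin: any spike
    tau: float
    centers: np.ndarray

    @property
    def n_t(self) -> int:
        return self.posterior.shape[1]


def _log_likelihood(counts: np.ndarray, lam: np.ndarray, tau: float) -> np.ndarray:
    """(n_t, n_states) log posterior (unnormalized)."""
    loglam = np.log(np.maximum(lam, LOG_RATE_FLOOR))
    return counts.T @ loglam - tau * lam.sum(axis=0)


def decode_posteriors(counts: np.ndarray, rate_maps: RateMapSet,
                      tau: float = 0.02) -> PosteriorMatrix:
    """Posterior matrix from a per-event count matrix (n_included, n_t).

    Rows must follow ``rate_maps.included`` order.  Columns are normalized
    to sum to 1; the decoded location is the arc-length of the argmax state
    (ties go to the lowest state index).
    """
    lam3 = rate_maps.included_rates()
    if lam3.size == 0 or lam3.max() <= 0:
        raise ValueError("all-zero rate maps")
    n_bins = rate_maps.n_bins
    lam = np.concatenate([lam3[:, 0, :], lam3[:, 1, :]], axis=1)   # (n_u, 2*n_bins)
    ll = _log_likelihood(np.asarray(counts, float), lam, tau)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    states = np.argmax(post, axis=1)
    arc = rate_maps.centers[states % n_bins]
    return PosteriorMatrix(posterior=post.T, decoded=arc,
                           jumps=np.abs(np.diff(arc)),
                           occupied=np.asarray(counts).sum(axis=0) > 0,
                           tau=tau, centers=rate_maps.centers)


def event_counts(units: UnitSpikeTrains, included: list,
                 t0: float, t1: float, tau: float) -> np.ndarray:
    """(n_included, n_t) spike counts in tau-wide bins spanning [t0, t1)."""
    n_t = max(1, int(np.floor((t1 - t0) / tau + 1e-9)))
    edges = t0 + np.arange(n_t + 1) * tau
    out = np.zeros((len(included), n_t), dtype=np.int32)
    for r, uid in enumerate(included):
        st = units[uid].spike_times
        idx = np.searchsorted(st, edges, "left")
        out[r] = np.diff(idx)
    return out


@dataclass
class ReplayCall:
    event_id: int
    is_candidate: bool
    is_replay: bool
    run_bins: int
    distance_cm: float
    mean_jump_cm: float
    fail_reason: str = ""


def classify_path(decoded: np.ndarray, occupied: np.ndarray,
                  jump_max: float = 40.0, min_bins: int = 4,
                  min_distance: float = 35.0) -> tuple[bool, int, float, float]:
    """Longest qualifying run on a decoded path.

    A qualifying run is >= min_bins consecutive occupied time bins whose
    adjacent jumps are all < jump_max and whose net traversal
    |last - first| is at least min_distance (a trajectory moves *across*
    space; a decoded point parked in one place does not qualify).  Among
    candidate runs the longest is reported; ties go to the larger
    traversal.  Returns (is_replay, run bins, traversed cm, mean jump cm).
    """
    n = len(decoded)
    if n < 2:
        return False, min(n, 1), 0.0, 0.0
    jumps = np.abs(np.diff(decoded))
    ok = (jumps < jump_max) & occupied[:-1] & occupied[1:]
    best = (0, 0.0, 0.0)        # (run_bins, distance, mean_jump)
    is_rep = False
    i = 0
    while i < n - 1:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and ok[j]:
            j += 1
        # maximal block i..j; scan sub-runs for the qualifying criterion
        seg = decoded[i:j + 1]
        run_bins = j - i + 1
        dist = float(abs(seg[-1] - seg[0]))
        mj = float(np.abs(np.diff(seg)).mean())
        if (run_bins, dist) > (best[0], best[1]):
            best = (run_bins, dist, mj)
        if run_bins >= min_bins and not is_rep:
            # any sub-window of >= min_bins bins with enough net traversal
            for a in range(run_bins - min_bins + 1):
                if is_rep:
                    break
                for b in range(a + min_bins - 1, run_bins):
                    if abs(seg[b] - seg[a]) >= min_distance:
                        is_rep = True
                        break
        i = j
    if best[0] == 0:
        return False, 1, 0.0, 0.0
    return is_rep, best[0], best[1], best[2]


def classify_trajectory_replay(post: PosteriorMatrix, jump_max: float = 40.0,
                               min_bins: int = 4, min_distance: float = 35.0,
                               event_id: int = 0,
                               is_candidate: bool = True) -> ReplayCall:
    """Jump-distance trajectory-replay rule on a decoded posterior."""
    is_rep, run, dist, mj = classify_path(post.decoded, post.occupied, jump_max,
                                          min_bins, min_distance)
    return ReplayCall(event_id=event_id, is_candidate=is_candidate,
                      is_replay=bool(is_rep and is_candidate),
                      run_bins=run, distance_cm=dist, mean_jump_cm=mj)


def decode_events(units: UnitSpikeTrains, rate_maps: RateMapSet,
                  events: pd.DataFrame, tau: float = 0.02,
                  jump_max: float = 40.0, min_bins: int = 4,
                  min_distance: float = 35.0) -> pd.DataFrame:
    """Decode and classify many events (batch, log-space argmax only).

    ``events`` needs columns event_id / start / stop / is_candidate;
    non-candidates are carried through unclassified.
    """
    lam3 = rate_maps.included_rates()
    if lam3.size == 0 or lam3.max() <= 0:
        raise ValueError("all-zero rate maps")
    n_bins = rate_maps.n_bins
    lam = np.concatenate([lam3[:, 0, :], lam3[:, 1, :]], axis=1)
    loglam = np.log(np.maximum(lam, LOG_RATE_FLOOR))
    penalty = tau * lam.sum(axis=0)
    spike_list = [units[uid].spike_times for uid in rate_maps.included]

    cand = events[events["is_candidate"]] if "is_candidate" in events else events
    n_t = np.maximum(1, np.floor((cand["stop"].to_numpy() - cand["start"].to_numpy()) / tau + 1e-9).astype(int))
    offsets = np.concatenate([[0], np.cumsum(n_t)])
    total = int(offsets[-1])
    # concatenated bin edges across events
    edges = np.concatenate([
        s + np.arange(m + 1) * tau for s, m in zip(cand["start"].to_numpy(), n_t)
    ]) if total else np.array([])
    counts = np.zeros((total, len(spike_list)), dtype=np.int16)
    if total:
        # drop the one seam bin between consecutive events' edge runs
        keep = np.ones(len(edges) - 1, dtype=bool)
        if len(n_t) > 1:
            keep[offsets[1:-1] + np.arange(len(n_t) - 1)] = False
        for r, st in enumerate(spike_list):
            idx = np.searchsorted(st, edges, "left")
            counts[:, r] = np.diff(idx)[keep]
        ll = counts @ loglam - penalty
        states = np.argmax(ll, axis=1)
        arcs = rate_maps.centers[states % n_bins]
        occ = counts.sum(axis=1) > 0

    rows = []
    ev_ids = cand["event_id"].to_numpy() if len(cand) else np.array([], int)
    for k in range(len(cand)):
        a = arcs[offsets[k]:offsets[k + 1]]
        o = occ[offsets[k]:offsets[k + 1]]
        is_rep, run, dist, mj = classify_path(a, o, jump_max, min_bins, min_distance)
        rows.append({"event_id": int(ev_ids[k]), "is_candidate": True,
                     "is_replay": bool(is_rep), "run_bins": run,
                     "distance_cm": dist, "mean_jump_cm": mj,
                     "fail_reason": ""})
    out = pd.DataFrame(rows)
    if "is_candidate" in events:
        rej = events[~events["is_candidate"]]
        if len(rej):
            out = pd.concat([out, pd.DataFrame({
                "event_id": rej["event_id"].astype(int), "is_candidate": False,
                "is_replay": False, "run_bins": 0, "distance_cm": 0.0,
                "mean_jump_cm": np.nan, "fail_reason": rej["fail_reason"],
            })], ignore_index=True)
    cols = ["peak"] if "peak" in events else []
    if cols:
        out = out.merge(events[["event_id"] + cols], on="event_id", how="left")
    return out.sort_values("event_id").reset_index(drop=True)


def replay_proportions(calls: pd.DataFrame, blocks: EpochSet) -> pd.DataFrame:
    """Replays / candidates per block (events assigned by peak time).

    Blocks without candidates get a missing proportion, not zero.
    """
    peaks = calls["peak"] if "peak" in calls else (calls.get("start", 0))
    rows = []
    for start, stop, label in zip(blocks.starts, blocks.stops, blocks.labels):
        m = (peaks >= start) & (peaks < stop)
        n_cand = int((calls["is_candidate"] & m).sum())
        n_rep = int((calls["is_replay"] & m).sum())
        rows.append({"block": label, "n_candidates": n_cand, "n_replays": n_rep,
                     "proportion": n_rep / n_cand if n_cand else np.nan})
    return pd.DataFrame(rows)
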