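"""Explained-variance (EV) reactivation and its time-reversed control (REV).

Spike counts in 250 ms bins give, per 15-min sliding window (5-min step),
a vector P of Pearson correlations over admissible cell pairs.  With
R[A,B] the correlation between two such vectors, the reactivation of the
MAZE pattern in a POST window WIN, controlling for a PRE window k, is the
squared partial correlation

    EV(WIN, k) = ((R[MAZE,WIN] - R[MAZE,PRE_k] R[PRE_k,WIN]) /
                  sqrt((1 - R[MAZE,PRE_k]^2)(1 - R[PRE_k,WIN]^2)))^2

and REV swaps the roles of PRE_k and WIN (how well MAZE explains *PRE*
controlling for the POST window), an estimate of chance.  Both are
averaged over all PRE windows.  Pairs from the same shank with waveform
similarity >= 0.8 are excluded; pair correlations undefined in a window
(zero count variance) are dropped pairwise-complete per evaluation.

The reactivation timescale of a session is the half-maximum lag of the
EV series' autocorrelation, computed without mean subtraction (the EV
trace is a non-negative decaying signal; subtracting the mean destroys
the very decay being measured) and normalized by lag 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import EpochSet, Session, UnitSpikeTrains

__all__ = ["bin_spike_counts", "waveform_similarity", "admissible_pairs",
           "window_pair_correlations", "explained_variance", "ev_timecourse",
           "ev_time_constant", "ev_block_summary", "EVTimeSeries", "TimeConstant"]


def bin_spike_counts(units: UnitSpikeTrains, interval: tuple[float, float],
                     bin_s: float = 0.25) -> np.ndarray:
    """Integer count matrix (n_units, n_bins) over [start, stop).

    Bins are anchored at the interval start; a trailing partial bin is
    dropped.
    """
    start, stop = float(interval[0]), float(interval[1])
    n_bins = int(np.floor((stop - start) / bin_s))
    counts = np.zeros((len(units), n_bins), dtype=np.int32)
    edges = start + np.arange(n_bins + 1) * bin_s
    for r, u in enumerate(units):
        counts[r], _ = np.histogram(u.spike_times, bins=edges)
    return counts


def waveform_similarity(units: UnitSpikeTrains) -> np.ndarray:
    """Pairwise similarity in [0, 1]: max normalized cross-correlation of
    mean waveforms, summed over shared channels; 0 across shanks."""
    ulist = list(units)
    n = len(ulist)
    sim = np.zeros((n, n))
    np.fill_diagonal(sim, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ulist[i], ulist[j]
            if a.shank != b.shank or a.mean_waveform is None or b.mean_waveform is None:
                continue
            wa, wb = a.mean_waveform, b.mean_waveform
            xc = sum(np.correlate(wa[c], wb[c], mode="full")
                     for c in range(min(len(wa), len(wb))))
            norm = np.sqrt((wa ** 2).sum() * (wb ** 2).sum())
            if norm > 0:
                sim[i, j] = sim[j, i] = float(np.abs(xc).max() / norm)
    return sim


def admissible_pairs(units: UnitSpikeTrains, similarity: np.ndarray | None = None,
                     cutoff: float = 0.8) -> np.ndarray:
    """Index pairs (into the unit order) with waveform similarity < cutoff.

    Cross-shank pairs are always admissible (their similarity is defined 0:
    cross-contamination between shanks is impossible).
    """
    if similarity is None:
        similarity = waveform_similarity(units)
    n = len(units)
    ii, jj = np.triu_indices(n, k=1)
    keep = similarity[ii, jj] < cutoff
    return np.stack([ii[keep], jj[keep]], axis=1)


def _pair_corr(block: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Pearson correlation per pair of rows; NaN where a row has no variance."""
    X = block.astype(np.float64)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    cov = (X @ X.T) / X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    vals = corr[pairs[:, 0], pairs[:, 1]]
    bad = (sd[pairs[:, 0]] == 0) | (sd[pairs[:, 1]] == 0)
    vals = np.where(bad, np.nan, vals)
    return vals


def window_pair_correlations(counts: np.ndarray, pairs: np.ndarray,
                             bin_s: float = 0.25, window_s: float = 900.0,
                             step_s: float = 300.0,
                             bin_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """P vectors for sliding windows over a count matrix.

    Returns (window centers in s relative to the count origin, matrix
    (n_windows, n_pairs)).  ``bin_mask`` optionally restricts which bins
    participate (e.g. NREM-only); a window with < 8 usable bins is all-NaN.
    """
    w = int(round(window_s / bin_s))
    s = int(round(step_s / bin_s))
    n_bins = counts.shape[1]
    if n_bins < w:
        return np.array([]), np.zeros((0, len(pairs)))
    starts = np.arange(0, n_bins - w + 1, s)
    out = np.full((len(starts), len(pairs)), np.nan)
    for k, b0 in enumerate(starts):
        block = counts[:, b0:b0 + w]
        if bin_mask is not None:
            sel = bin_mask[b0:b0 + w]
            if sel.sum() < 8:
                continue
            block = block[:, sel]
        out[k] = _pair_corr(block, pairs)
    centers = (starts + w / 2.0) * bin_s
    return centers, out


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def explained_variance(p_maze: np.ndarray, p_pre: np.ndarray, p_win: np.ndarray,
                       min_pairs: int = 10) -> tuple[float, float]:
    """(EV, REV) for one POST window, averaged over PRE windows.

    ``p_pre`` is (n_pre_windows, n_pairs).  Entries missing in any of the
    three vectors are dropped per evaluation (pairwise-complete).  PRE
    windows with a degenerate correlation (|R| = 1) are skipped; if all
    are skipped, raises ValueError.
    """
    p_pre = np.atleast_2d(p_pre)
    evs, revs = [], []
    for k in range(p_pre.shape[0]):
        mask = np.isfinite(p_maze) & np.isfinite(p_pre[k]) & np.isfinite(p_win)
        if mask.sum() < min_pairs:
            continue
        m, p, w = p_maze[mask], p_pre[k][mask], p_win[mask]
        r_mw, r_mp, r_pw = _corr(m, w), _corr(m, p), _corr(p, w)
        if any(np.isnan(r) for r in (r_mw, r_mp, r_pw)):
            continue
        if abs(r_mp) >= 1 - 1e-12 or abs(r_pw) >= 1 - 1e-12:
            continue
        denom = np.sqrt((1 - r_mp ** 2) * (1 - r_pw ** 2))
        evs.append(((r_mw - r_mp * r_pw) / denom) ** 2)
        # reversed: how well MAZE explains PRE controlling for the POST window
        if abs(r_mw) >= 1 - 1e-12:
            continue
        denom_r = np.sqrt((1 - r_mw ** 2) * (1 - r_pw ** 2))
        revs.append(((r_mp - r_mw * r_pw) / denom_r) ** 2)
    if not evs:
        raise ValueError("no usable PRE window (all degenerate or too few pairs)")
    return float(np.mean(evs)), float(np.mean(revs)) if revs else 0.0


@dataclass
class EVTimeSeries:
    """EV / REV per sliding POST window (absolute window centers, s)."""

    t: np.ndarray
    ev: np.ndarray
    rev: np.ndarray
    n_pairs: int
    pre_windows_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_center_s": self.t, "ev": self.ev, "rev": self.rev})


def ev_timecourse(session: Session, bin_s: float = 0.25, window_s: float = 900.0,
                  step_s: float = 300.0, similarity_cutoff: float = 0.8,
                  putative_type: str | None = "PN", stable_only: bool = True,
                  hypnogram=None, states: tuple | None = None,
                  min_pairs: int = 10) -> EVTimeSeries:
    """EV / REV across POST for one session.

    Uses stable putative pyramidal cells by default.  If ``states`` (e.g.
    ``("NREM", "REM")``) and a hypnogram are given, only bins whose centre
    falls in those states enter the POST pair correlations.
    """
    units = session.units.select(putative_type=putative_type if putative_type else None,
                                 stable=True if stable_only else None)
    if len(units) < 5:
        raise ValueError("too few units for pair correlations")
    pairs = admissible_pairs(units, cutoff=similarity_cutoff)

    pre = session.block("PRE")
    maze = session.block("MAZE")
    post = session.block("POST")

    maze_counts = bin_spike_counts(units, maze, bin_s)
    pre_counts = bin_spike_counts(units, pre, bin_s)
    post_counts = bin_spike_counts(units, post, bin_s)

    p_maze = _pair_corr(maze_counts, pairs)
    _, p_pre = window_pair_correlations(pre_counts, pairs, bin_s, window_s, step_s)

    mask = None
    if states is not None and hypnogram is not None:
        n_bins = post_counts.shape[1]
        centers = post[0] + (np.arange(n_bins) + 0.5) * bin_s
        mask = np.isin(hypnogram.label_at(centers), list(states))
    centers, p_win = window_pair_correlations(post_counts, pairs, bin_s,
                                              window_s, step_s, bin_mask=mask)

    ev = np.full(len(centers), np.nan)
    rev = np.full(len(centers), np.nan)
    for k in range(len(centers)):
        if not np.isfinite(p_win[k]).any():
            continue
        try:
            ev[k], rev[k] = explained_variance(p_maze, p_pre, p_win[k], min_pairs)
        except ValueError:
            continue
    return EVTimeSeries(t=post[0] + centers, ev=ev, rev=rev,
                        n_pairs=len(pairs), pre_windows_used=p_pre.shape[0])


@dataclass
class TimeConstant:
    tau_h: float
    censored: bool


def ev_time_constant(ev: np.ndarray, step_s: float = 300.0) -> TimeConstant:
    """Reactivation timescale: half-maximum of the EV autocorrelation.

    Raw (non-demeaned) autocorrelation normalized at lag 0; the constant is
    the first lag, linearly interpolated, where it falls below 0.5.  A
    constant or empty series never decays and is returned censored at the
    series span.
    """
    x = np.asarray(ev, float)
    x = x[np.isfinite(x)]
    span_h = len(x) * step_s / 3600.0
    if len(x) < 3 or x.std() < 1e-12 or np.abs(x).max() == 0:
        return TimeConstant(span_h, True)
    n = len(x)
    d = float(np.dot(x, x))
    prev = 1.0
    for L in range(1, n):
        r = float(np.dot(x[:n - L], x[L:]) / d)
        if r < 0.5:
            frac = (prev - 0.5) / (prev - r)
            return TimeConstant(((L - 1) + frac) * step_s / 3600.0, False)
        prev = r
    return TimeConstant(span_h, True)


def ev_block_summary(series: EVTimeSeries, blocks: EpochSet) -> pd.DataFrame:
    """Mean EV - REV over windows whose centres fall in each block."""
    rows = []
    for start, stop, label in zip(blocks.starts, blocks.stops, blocks.labels):
        m = (series.t >= start) & (series.t < stop) & np.isfinite(series.ev)
        diff = series.ev[m] - series.rev[m]
        rows.append({"block": label, "n_windows": int(m.sum()),
                     "ev_minus_rev": float(diff.mean()) if m.any() else np.nan})
    return pd.DataFrame(rows)
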