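"""Unit stability screening, putative cell-type classification and
block-wise / within-event firing-rate summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import EpochSet, Session, UnitSpikeTrains, PN, IN, UNCLASSIFIED

__all__ = ["stability_filter", "classify_units", "block_firing_rates",
           "within_event_rates", "waveform_width_ms"]


def stability_filter(units: UnitSpikeTrains, duration: float,
                     n_bins: int = 5, frac: float = 0.25) -> list[int]:
    """Unit ids whose firing never drops below ``frac`` of their mean.

    The session is split into ``n_bins`` equal-duration bins; a unit is
    kept iff its rate in *every* bin is at least ``frac`` times its
    whole-session mean rate.  Zero-spike units fail (a 0 >= 0 comparison
    would retain them vacuously).
    """
    if duration <= 0:
        raise ValueError("session duration must be positive")
    edges = np.linspace(0.0, duration, n_bins + 1)
    keep = []
    for u in units:
        if u.n_spikes == 0:
            continue
        counts, _ = np.histogram(u.spike_times, bins=edges)
        rates = counts / (duration / n_bins)
        mean_rate = u.n_spikes / duration
        if (rates >= frac * mean_rate - 1e-12).all():
            keep.append(u.unit_id)
    return keep


def waveform_width_ms(waveform: np.ndarray, wf_fs: float) -> float:
    """Trough-to-peak width (ms) on the largest-amplitude channel."""
    wf = np.atleast_2d(waveform)
    ch = int(np.argmax(np.abs(wf).max(axis=1)))
    w = wf[ch]
    trough = int(np.argmin(w))
    if trough + 1 >= len(w):
        return 0.0
    peak = trough + 1 + int(np.argmax(w[trough + 1:]))
    return (peak - trough) / wf_fs * 1000.0


def classify_units(units: UnitSpikeTrains, duration: float,
                   width_thresh_ms: float = 0.4, pn_rate_max: float = 5.0,
                   in_rate_min: float = 10.0, burst_isi_s: float = 0.01,
                   burst_frac_pn: float = 0.15) -> dict[int, str]:
    """Putative PN / IN labels from waveform width, rate and ISI bursting.

    Broad waveform (>= 0.4 ms trough-to-peak) and rate < 5 Hz -> PN; narrow
    and rate > 10 Hz -> IN.  In the gap, a high fraction of inter-spike
    intervals below 10 ms (bursting) breaks the tie towards PN for broad
    waveforms; everything else stays UNCLASSIFIED.  Units without a stored
    waveform are classified on rate and ISI alone.
    """
    out = {}
    for u in units:
        rate = u.mean_rate(duration)
        isi = np.diff(u.spike_times)
        burst = float((isi < burst_isi_s).mean()) if len(isi) else 0.0
        if u.mean_waveform is not None:
            width = waveform_width_ms(u.mean_waveform, u.wf_fs)
            if width >= width_thresh_ms and rate < pn_rate_max:
                out[u.unit_id] = PN
            elif width < width_thresh_ms and rate > in_rate_min:
                out[u.unit_id] = IN
            elif width >= width_thresh_ms and burst >= burst_frac_pn and rate < in_rate_min:
                out[u.unit_id] = PN
            else:
                out[u.unit_id] = UNCLASSIFIED
        else:
            if rate < pn_rate_max and burst >= burst_frac_pn:
                out[u.unit_id] = PN
            elif rate > in_rate_min:
                out[u.unit_id] = IN
            else:
                out[u.unit_id] = UNCLASSIFIED
    return out


def block_firing_rates(units: UnitSpikeTrains, blocks: EpochSet) -> pd.DataFrame:
    """Per unit per block firing rate (Hz), silent units included as 0.

    Returns a tidy frame (unit_id, putative_type, block, rate_hz); medians
    and IQRs per block and type are a groupby away and are emitted by the
    pipeline report.
    """
    if (blocks.durations <= 0).any():
        raise ValueError("zero-duration block")
    rows = []
    for u in units:
        idx_lo = np.searchsorted(u.spike_times, blocks.starts, "left")
        idx_hi = np.searchsorted(u.spike_times, blocks.stops, "left")
        for k, label in enumerate(blocks.labels):
            rows.append({
                "unit_id": u.unit_id, "putative_type": u.putative_type,
                "block": label,
                "rate_hz": (idx_hi[k] - idx_lo[k]) / (blocks.stops[k] - blocks.starts[k]),
            })
    return pd.DataFrame(rows)


def rate_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of rates per (block, putative_type)."""
    def iqr(x):
        q = np.percentile(x, [25, 75])
        return q[1] - q[0]
    g = rates.groupby(["block", "putative_type"])["rate_hz"]
    out = g.agg(median="median", iqr=iqr, n="size").reset_index()
    return out


def within_event_rates(units: UnitSpikeTrains, events: EpochSet) -> pd.DataFrame:
    """Per-unit rate (Hz) restricted to inside events: total in-event spikes
    over total event duration."""
    if len(events) == 0:
        raise ValueError("no events")
    total = float(events.durations.sum())
    if total <= 0:
        raise ValueError("total event duration is zero")
    starts, stops = events.starts, events.stops
    rows = []
    for u in units:
        lo = np.searchsorted(u.spike_times, starts, "left")
        hi = np.searchsorted(u.spike_times, stops, "left")
        rows.append({"unit_id": u.unit_id, "putative_type": u.putative_type,
                     "rate_hz": float((hi - lo).sum()) / total})
    return pd.DataFrame(rows)
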