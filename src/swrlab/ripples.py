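"""Sharp-wave ripple and population-burst detection.

Ripples are detected on the z-scored, Gaussian-smoothed (sigma = 12.5 ms)
magnitude of the analytic signal in the 125-250 Hz band, averaged across
one channel per shank (the channel with the highest mean ripple-band
power).  Events exceed 2.5 s.d. at the peak, extend to the 0.5 s.d.
crossings, and must last 50-450 ms.  The z-scoring baseline is the whole
recording.

Population bursts are detected on all-unit spike counts in 1 ms bins
smoothed with a 20 ms Gaussian: peak above 3 s.d., boundaries at the mean
crossing, events closer than 10 ms merged, duration 80-500 ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from .session import EpochSet, LFPRecording, UnitSpikeTrains

__all__ = [
    "select_ripple_channels",
    "ripple_envelope",
    "detect_ripples",
    "ripple_power_z",
    "sharp_wave_amplitude",
    "sharpwave_amplitudes",
    "peak_ripple_frequency",
    "peak_ripple_frequencies",
    "detect_population_bursts",
    "event_rate_by_block",
]

RIPPLE_BAND = (125.0, 250.0)
SHARPWAVE_BAND = (2.0, 30.0)


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _chunked_envelope(x: np.ndarray, chunk: int = 1 << 21, overlap: int = 4096) -> np.ndarray:
    """|analytic signal| computed in overlapping chunks (FFT-friendly sizes)."""
    n = len(x)
    if n <= chunk:
        return np.abs(hilbert(x))
    out = np.empty(n, dtype=np.float32)
    start = 0
    while start < n:
        lo = max(0, start - overlap)
        hi = min(n, start + chunk + overlap)
        env = np.abs(hilbert(x[lo:hi]))
        out[start:min(n, start + chunk)] = env[start - lo: start - lo + min(n, start + chunk) - start]
        start += chunk
    return out


def select_ripple_channels(lfp: LFPRecording, band: tuple = RIPPLE_BAND) -> list[int]:
    """One channel per shank: highest mean power in the ripple band.

    Band power is estimated from the variance of the band-passed signal;
    ties resolve to the lowest channel index.
    """
    sos = _bandpass_sos(*band, lfp.fs)
    chosen = []
    for sh in np.unique(lfp.shank):
        chans = np.nonzero(lfp.shank == sh)[0]
        if len(chans) == 0:
            continue
        power = []
        for c in chans:
            x = sosfiltfilt(sos, lfp.samples[c].astype(np.float64))
            power.append(float(np.mean(x ** 2)))
        chosen.append(int(chans[int(np.argmax(power))]))
    return chosen


def _ripple_envelope(samples: np.ndarray, fs: float, band: tuple = RIPPLE_BAND,
                     smooth_s: float = 0.0125) -> np.ndarray:
    """Smoothed across-channel mean of per-channel analytic-signal magnitude."""
    sos = _bandpass_sos(*band, fs)
    acc = None
    for row in np.atleast_2d(samples):
        x = sosfiltfilt(sos, row.astype(np.float64)).astype(np.float32)
        env = _chunked_envelope(x)
        acc = env if acc is None else acc + env
    acc /= len(np.atleast_2d(samples))
    return gaussian_filter1d(acc, smooth_s * fs)


def ripple_envelope(lfp: LFPRecording, channels=None, band: tuple = RIPPLE_BAND,
                    smooth_s: float = 0.0125) -> np.ndarray:
    if channels is None:
        channels = select_ripple_channels(lfp, band)
    return _ripple_envelope(lfp.samples[list(channels)], lfp.fs, band, smooth_s)


def _threshold_events(z: np.ndarray, fs: float, peak_z: float, boundary_z: float,
                      merge_gap: float, dur_min: float, dur_max: float):
    """Regions above ``boundary_z`` containing a peak above ``peak_z``.

    Nearby regions are merged before the duration filter is applied.
    Returns (start_idx, stop_idx, peak_idx, peak_val) arrays.
    """
    above = z > boundary_z
    if not above.any():
        return (np.array([], int),) * 3 + (np.array([]),)
    d = np.diff(above.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [len(z)]])
    # merge close regions
    gap = int(round(merge_gap * fs))
    keep_s, keep_e = [starts[0]], [stops[0]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - keep_e[-1] < gap:
            keep_e[-1] = e
        else:
            keep_s.append(s)
            keep_e.append(e)
    starts, stops = np.array(keep_s), np.array(keep_e)
    out_s, out_e, out_p, out_v = [], [], [], []
    lo, hi = int(round(dur_min * fs)), int(round(dur_max * fs))
    for s, e in zip(starts, stops):
        seg = z[s:e]
        p = int(np.argmax(seg))
        if seg[p] <= peak_z:
            continue
        if not (lo <= e - s <= hi):
            continue
        out_s.append(s)
        out_e.append(e)
        out_p.append(s + p)
        out_v.append(float(seg[p]))
    return (np.array(out_s, int), np.array(out_e, int),
            np.array(out_p, int), np.array(out_v))


def detect_ripples(lfp: LFPRecording, channels=None, peak_z: float = 2.5,
                   boundary_z: float = 0.5, band: tuple = RIPPLE_BAND,
                   smooth_s: float = 0.0125, duration: tuple = (0.05, 0.45),
                   merge_gap: float = 0.03, env: np.ndarray | None = None) -> EpochSet:
    """Detect sharp-wave ripples; returns an EpochSet with per-event
    ``peak`` time and ``peak_power_z`` attributes."""
    if env is None:
        env = ripple_envelope(lfp, channels, band, smooth_s)
    mu, sd = float(env.mean()), float(env.std())
    if sd == 0:
        raise ValueError("degenerate signal: ripple-band envelope has zero variance")
    z = (env - mu) / sd
    s, e, p, v = _threshold_events(z, lfp.fs, peak_z, boundary_z,
                                   merge_gap, duration[0], duration[1])
    return EpochSet.from_arrays(s / lfp.fs, e / lfp.fs, ["ripple"] * len(s),
                                peak=p / lfp.fs, peak_power_z=v) if len(s) else EpochSet.empty()


def ripple_power_z(env: np.ndarray, fs: float, start: float, stop: float) -> float:
    """Peak smoothed ripple-band envelope in [start, stop), z-scored against
    the whole-series mean and s.d. of ``env``."""
    mu, sd = float(env.mean()), float(env.std())
    if sd == 0:
        raise ValueError("degenerate signal: envelope has zero variance")
    i0, i1 = int(start * fs), max(int(start * fs) + 1, int(stop * fs))
    return float((env[i0:i1].max() - mu) / sd)


# ---------------------------------------------------------------------------
# per-event sharp-wave amplitude and peak frequency
# ---------------------------------------------------------------------------

def _event_bounds(event) -> tuple[float, float]:
    if hasattr(event, "start"):
        return float(event.start), float(event.stop)
    if isinstance(event, dict):
        return float(event["start"]), float(event["stop"])
    start, stop = event[:2]
    return float(start), float(stop)


def sharpwave_amplitudes(lfp: LFPRecording, events: EpochSet | np.ndarray,
                         decimate: int = 10) -> np.ndarray:
    """Peak-to-trough of 2-30 Hz filtered LFP across *all* channels, in mV.

    The band-passed signal is computed once on a ``decimate``-fold
    downsampled copy (content is far below the reduced Nyquist), then
    sliced per event.
    """
    iv = events.intervals if isinstance(events, EpochSet) else np.asarray(events, float).reshape(-1, 2)
    fs_lo = lfp.fs / decimate
    sos = butter(2, list(SHARPWAVE_BAND), btype="bandpass", fs=fs_lo, output="sos")
    n_lo = int(np.ceil(lfp.n_samples / decimate))
    filt = np.empty((lfp.n_channels, n_lo))
    for c in range(lfp.n_channels):
        low = resample_poly(lfp.samples[c].astype(np.float64), 1, decimate)
        filt[c] = sosfiltfilt(sos, low)[:n_lo]
    out = np.empty(len(iv))
    n = filt.shape[1]
    for k, (t0, t1) in enumerate(iv):
        i0 = max(0, int(np.floor(t0 * fs_lo)))
        i1 = min(n, max(i0 + 1, int(np.ceil(t1 * fs_lo))))
        seg = filt[:, i0:i1]
        out[k] = (seg.max() - seg.min()) / 1000.0
    return out


def sharp_wave_amplitude(lfp: LFPRecording, event) -> float:
    """Sharp-wave amplitude (mV) of one event: max minus min of the 2-30 Hz
    filtered LFP over all channels and samples within [start, stop)."""
    t0, t1 = _event_bounds(event)
    return float(sharpwave_amplitudes(lfp, np.array([[t0, t1]]))[0])


def _morlet_bank(freqs: np.ndarray, fs: float, n_cycles: float, nfft: int) -> np.ndarray:
    """FFTs of complex Morlet wavelets, one row per frequency."""
    bank = np.zeros((len(freqs), nfft), dtype=np.complex128)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
        kern = np.zeros(nfft, dtype=np.complex128)
        kern[:len(w)] = w
        kern = np.roll(kern, -half)          # zero-phase placement
        W = np.fft.fft(kern)
        # unit response at the centre frequency: a pure tone then peaks at
        # its own wavelet regardless of the f-dependent bandwidth
        bank[i] = W / np.abs(W).max()
    return bank


def peak_ripple_frequencies(lfp: LFPRecording, events: EpochSet | np.ndarray,
                            channels=None, f_lo: float = 100.0, f_hi: float = 250.0,
                            df: float = 2.0, n_cycles: float = 7.0,
                            chunk: int = 4096) -> np.ndarray:
    """Per-event frequency (on a linear grid) with maximum total wavelet power.

    The signal (mean of the selected ripple channels, high-pass > 100 Hz)
    is convolved with complex Morlet wavelets; power |w(t)|^2 is summed over
    samples inside the event.
    """
    if channels is None:
        channels = select_ripple_channels(lfp)
    iv = events.intervals if isinstance(events, EpochSet) else np.asarray(events, float).reshape(-1, 2)
    fs = lfp.fs
    sos = butter(4, f_lo, btype="highpass", fs=fs, output="sos")
    sig = sosfiltfilt(sos, lfp.samples[list(channels)].mean(axis=0).astype(np.float64))

    freqs = np.arange(f_lo, f_hi + df / 2, df)
    pad = int(np.ceil(4 * n_cycles / (2 * np.pi * f_lo) * fs))
    max_len = int(np.ceil(iv[:, 1].max() * fs) - np.floor(iv[:, 0].min() * 0)) if len(iv) else 0
    ev_len = np.maximum((np.ceil(iv[:, 1] * fs) - np.floor(iv[:, 0] * fs)).astype(int), 1)
    nfft = 1 << int(np.ceil(np.log2(ev_len.max() + 2 * pad + 1)))
    bank = _morlet_bank(freqs, fs, n_cycles, nfft)

    n_ev = len(iv)
    out = np.empty(n_ev)
    for c0 in range(0, n_ev, chunk):
        idx = slice(c0, min(n_ev, c0 + chunk))
        sub = iv[idx]
        m = len(sub)
        snip = np.zeros((m, nfft))
        mask = np.zeros((m, nfft), dtype=bool)
        for k, (t0, t1) in enumerate(sub):
            i0 = int(np.floor(t0 * fs))
            i1 = int(np.ceil(t1 * fs))
            a0, a1 = max(0, i0 - pad), min(len(sig), i1 + pad)
            seg = sig[a0:a1]
            snip[k, :len(seg)] = seg
            mask[k, (i0 - a0):(i0 - a0) + (min(i1, len(sig)) - i0)] = True
        X = np.fft.fft(snip, axis=1)
        power = np.zeros((m, len(freqs)))
        for fi in range(len(freqs)):
            y = np.fft.ifft(X * bank[fi][None, :], axis=1)
            power[:, fi] = np.sum((np.abs(y) ** 2) * mask, axis=1)
        out[idx] = freqs[np.argmax(power, axis=1)]
    return out


def peak_ripple_frequency(lfp: LFPRecording, event, channels=None, **kw) -> float:
    t0, t1 = _event_bounds(event)
    return float(peak_ripple_frequencies(lfp, np.array([[t0, t1]]), channels, **kw)[0])


# ---------------------------------------------------------------------------
# population bursts
# ---------------------------------------------------------------------------

def detect_population_bursts(units: UnitSpikeTrains, duration: float | None = None,
                             bin_s: float = 0.001, sigma_s: float = 0.02,
                             peak_z: float = 3.0, merge_gap: float = 0.01,
                             dur: tuple = (0.08, 0.5)) -> EpochSet:
    """Multi-unit population bursts from all-unit counts.

    Counts in 1 ms bins, 20 ms Gaussian smoothing, z against the whole
    recording; peak above ``peak_z``, boundaries extended to the mean
    crossing, events within 10 ms merged, duration within ``dur``.
    Returns EpochSet with ``peak``, ``peak_mua_z`` and ``n_active_units``.
    """
    t = units.all_spike_times()
    if len(t) == 0:
        return EpochSet.empty()
    if duration is None:
        duration = float(t[-1]) + 1.0
    nbins = int(np.ceil(duration / bin_s))
    counts = np.bincount(np.minimum((t / bin_s).astype(int), nbins - 1), minlength=nbins)
    mua = gaussian_filter1d(counts.astype(np.float32), sigma_s / bin_s)
    mu, sd = float(mua.mean()), float(mua.std())
    if sd == 0:
        return EpochSet.empty()
    z = (mua - mu) / sd
    fs = 1.0 / bin_s
    s, e, p, v = _threshold_events(z, fs, peak_z, 0.0, merge_gap, dur[0], dur[1])
    if len(s) == 0:
        return EpochSet.empty()
    starts, stops = s * bin_s, e * bin_s
    n_active = np.empty(len(s), dtype=int)
    per_unit = [u.spike_times for u in units]
    for k, (t0, t1) in enumerate(zip(starts, stops)):
        n_active[k] = sum(
            1 for st in per_unit
            if np.searchsorted(st, t1, "left") > np.searchsorted(st, t0, "left")
        )
    return EpochSet.from_arrays(starts, stops, ["burst"] * len(s),
                                peak=p * bin_s, peak_mua_z=v, n_active_units=n_active)


def event_rate_by_block(events: EpochSet, blocks: EpochSet) -> pd.DataFrame:
    """Events-per-second per block; events assigned by peak time (midpoint
    if no peak attribute is present)."""
    if (blocks.durations <= 0).any():
        raise ValueError("zero-duration block")
    peaks = events.df["peak"].to_numpy() if "peak" in events.df else (events.starts + events.stops) / 2
    rows = []
    for start, stop, label in zip(blocks.starts, blocks.stops, blocks.labels):
        n = int(((peaks >= start) & (peaks < stop)).sum())
        rows.append({"block": label, "start": start, "stop": stop,
                     "n_events": n, "rate_hz": n / (stop - start)})
    return pd.DataFrame(rows)
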