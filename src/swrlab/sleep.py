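"""Sleep-state scoring from LFP alone.

WAKE vs sleep comes from a "correlation EMG": the sum of pairwise Pearson
correlations of high-pass (> 300 Hz) filtered channels in 10 s windows
(1 s step) — muscle artifact is broadband and shared across the array, so
wake windows are strongly correlated.  Within sleep, REM vs NREM (and
within wake, active vs quiet) comes from the theta / (delta + beta) power
ratio, theta 5-10 Hz over (1-4) + (10-14) Hz, smoothed by a 2-state
hidden-state model (Gaussian emissions, sticky transitions, Viterbi path).
No manual inspection stage: a 10 s minimum state duration replaces it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, resample_poly, sosfiltfilt, welch, get_window
from sklearn.mixture import GaussianMixture

from .session import EpochSet, LFPRecording

__all__ = ["correlation_emg", "theta_channel", "theta_ratio",
           "classify_states", "spectrogram_psd", "Hypnogram"]

WINDOW_S = 10.0
STEP_S = 1.0
MIN_STATE_S = 10.0
EMG_HIGHPASS_HZ = 300.0

THETA_BAND = (5.0, 10.0)
DELTA_BAND = (1.0, 4.0)
BETA_BAND = (10.0, 14.0)


@dataclass
class Hypnogram:
    """Scored sleep states tiling the scored period."""

    epochs: EpochSet
    window: float = WINDOW_S
    step: float = STEP_S

    def label_at(self, times) -> np.ndarray:
        times = np.asarray(times, float)
        out = np.array(["UNSCORED"] * len(times), dtype=object)
        for s, e, l in zip(self.epochs.starts, self.epochs.stops, self.epochs.labels):
            out[(times >= s) & (times < e)] = l
        return out

    def select(self, labels) -> EpochSet:
        return self.epochs.select(labels)


def correlation_emg(lfp: LFPRecording, window_s: float = WINDOW_S,
                    step_s: float = STEP_S,
                    highpass_hz: float = EMG_HIGHPASS_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Summed pairwise channel correlations of high-passed LFP per window.

    Windows are aligned to whole seconds (the step); per-second first and
    second moments are accumulated once, so the cost is one pass over the
    data.  Returns (window centers, values).
    """
    if lfp.n_channels < 2:
        raise ValueError("correlation EMG needs at least 2 channels")
    fs = lfp.fs
    sos = butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    sec = int(round(fs * step_s))
    n_sec = lfp.n_samples // sec
    if n_sec * step_s < window_s:
        raise ValueError("recording shorter than one scoring window")
    C = lfp.n_channels
    hp = np.empty((C, n_sec * sec), dtype=np.float32)
    for c in range(C):
        hp[c] = sosfiltfilt(sos, lfp.samples[c].astype(np.float64))[:n_sec * sec]
    blocks = hp.reshape(C, n_sec, sec)
    s1 = blocks.sum(axis=2, dtype=np.float64)                    # (C, n_sec)
    s2 = (blocks.astype(np.float64) ** 2).sum(axis=2)
    pairs = [(i, j) for i in range(C) for j in range(i + 1, C)]
    sxy = np.empty((len(pairs), n_sec))
    for k, (i, j) in enumerate(pairs):
        sxy[k] = (blocks[i].astype(np.float64) * blocks[j]).sum(axis=1)

    w = int(round(window_s / step_s))
    def wsum(a):
        c = np.cumsum(a, axis=-1)
        c = np.concatenate([np.zeros((*a.shape[:-1], 1)), c], axis=-1)
        return c[..., w:] - c[..., :-w]

    n = w * sec
    S1, S2, SXY = wsum(s1), wsum(s2), wsum(sxy)
    total = np.zeros(S1.shape[-1])
    for k, (i, j) in enumerate(pairs):
        cov = SXY[k] - S1[i] * S1[j] / n
        var = (S2[i] - S1[i] ** 2 / n) * (S2[j] - S1[j] ** 2 / n)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var)
        total += np.nan_to_num(r)
    centers = (np.arange(S1.shape[-1]) + w / 2.0) * step_s
    return centers, total


def _decimated(lfp: LFPRecording, channel: int, target_fs: float = 125.0) -> tuple[np.ndarray, float]:
    q = max(1, int(round(lfp.fs / target_fs)))
    x = resample_poly(lfp.samples[channel].astype(np.float64), 1, q)
    return x, lfp.fs / q


def theta_channel(lfp: LFPRecording) -> int:
    """Channel with the highest mean 5-10 Hz power over the full recording."""
    best, best_p = 0, -np.inf
    for c in range(lfp.n_channels):
        x, fs = _decimated(lfp, c)
        f, p = welch(x, fs=fs, nperseg=min(len(x), int(10 * fs)))
        m = (f >= THETA_BAND[0]) & (f < THETA_BAND[1])
        power = float(p[m].sum())
        if power > best_p:
            best, best_p = c, power
    return best


def theta_ratio(lfp: LFPRecording, channel: int, window_s: float = WINDOW_S,
                step_s: float = STEP_S) -> tuple[np.ndarray, np.ndarray]:
    """Theta / (delta + beta) PSD power ratio per window.

    Per 10 s window (1 s step), the periodogram power in 5-10 Hz is divided
    by the power in (1-4) + (10-14) Hz.  A zero denominator yields the
    largest finite ratio in the series, with a warning.
    """
    x, fs = _decimated(lfp, channel)
    sec = int(round(fs * step_s))
    w = int(round(window_s / step_s))
    n_sec = len(x) // sec
    if n_sec < w:
        raise ValueError("recording shorter than one scoring window")
    n_win = n_sec - w + 1
    nper = w * sec
    taper = get_window("hann", nper).astype(np.float64)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    th = (freqs >= THETA_BAND[0]) & (freqs < THETA_BAND[1])
    dn = ((freqs >= DELTA_BAND[0]) & (freqs < DELTA_BAND[1])) | \
         ((freqs >= BETA_BAND[0]) & (freqs < BETA_BAND[1]))
    num = np.empty(n_win)
    den = np.empty(n_win)
    chunk = 2048
    for c0 in range(0, n_win, chunk):
        c1 = min(n_win, c0 + chunk)
        idx = np.arange(c0, c1)
        frames = np.stack([x[i * sec: i * sec + nper] for i in idx])
        spec = np.abs(np.fft.rfft(frames * taper, axis=1)) ** 2
        num[c0:c1] = spec[:, th].sum(axis=1)
        den[c0:c1] = spec[:, dn].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    bad = ~np.isfinite(ratio)
    if bad.any():
        warnings.warn("zero denominator in theta ratio; substituting max finite value")
        ratio[bad] = ratio[~bad].max() if (~bad).any() else 1.0
    centers = (np.arange(n_win) + w / 2.0) * step_s
    return centers, ratio


def _two_state_threshold(values: np.ndarray) -> tuple[GaussianMixture, int]:
    """Deterministic 2-component 1-D Gaussian mixture (quantile init)."""
    v = values.reshape(-1, 1)
    q = np.quantile(values, [0.2, 0.8]).reshape(-1, 1)
    gm = GaussianMixture(2, means_init=q, n_init=1, random_state=0,
                         reg_covar=1e-6, max_iter=200)
    gm.fit(v)
    hi = int(np.argmax(gm.means_.ravel()))
    return gm, hi


def _sticky_viterbi(values: np.ndarray, p_stay: float = 0.99) -> np.ndarray:
    """Viterbi path of a 2-state Gaussian-emission chain on 1-D values.

    Emission parameters come from a quantile-initialized mixture fit, so
    the whole procedure is deterministic.  Returns 0 (low mean) / 1 (high).
    """
    from hmmlearn.hmm import GaussianHMM

    gm, hi = _two_state_threshold(values)
    order = np.argsort(gm.means_.ravel())
    model = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]])
    model.means_ = gm.means_[order]
    model.covars_ = np.maximum(gm.covariances_.reshape(-1, 1)[order], 1e-8)
    _, path = model.decode(values.reshape(-1, 1), algorithm="viterbi")
    return path


def _merge_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb runs shorter than min_len into the preceding (or following) run."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        lengths = [e - s for s, e in runs]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_len:
            break
        s, e = runs[k]
        labels[s:e] = labels[s - 1] if k > 0 else labels[e]
        changed = True
    return labels


def classify_states(emg: tuple[np.ndarray, np.ndarray],
                    ratio: tuple[np.ndarray, np.ndarray],
                    min_state_s: float = MIN_STATE_S,
                    step_s: float = STEP_S) -> Hypnogram:
    """Two-step scoring: EMG-correlate mixture threshold for wake vs sleep,
    then sticky 2-state smoothing of the log theta ratio within each."""
    t_e, v_e = emg
    t_r, v_r = ratio
    n = min(len(t_e), len(t_r))
    if n < 1:
        raise ValueError("series shorter than one window")
    t, v_e, v_r = t_e[:n], v_e[:n], v_r[:n]
    log_ratio = np.log(np.maximum(v_r, 1e-12))

    gm, hi = _two_state_threshold(v_e)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    if abs(mu[1] - mu[0]) < 2.5 * sd.mean():
        # unimodal EMG: the session is all wake or all sleep; the summed
        # pairwise correlation has an absolute scale (~0 in sleep), so a
        # small fixed floor separates the two cases
        wake = np.full(n, bool(np.median(v_e) > 0.5))
    else:
        wake = gm.predict(v_e.reshape(-1, 1)) == hi
    labels = np.array(["WAKE_quiet"] * n, dtype=object)

    for mask, (lo_lab, hi_lab) in ((~wake, ("NREM", "REM")),
                                   (wake, ("WAKE_quiet", "WAKE_active"))):
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        vals = log_ratio[idx]
        if len(idx) < 20 or vals.std() < 1e-6:
            labels[idx] = lo_lab
            continue
        path = _sticky_viterbi(vals)
        labels[idx] = np.where(path == 1, hi_lab, lo_lab)

    min_len = max(1, int(round(min_state_s / step_s)))
    labels = _merge_short_runs(labels, min_len)

    starts, stops, labs = [], [], []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[run_start]:
            starts.append(t[run_start] - step_s / 2)
            stops.append(t[i - 1] + step_s / 2)
            labs.append(labels[run_start])
            run_start = i
    return Hypnogram(EpochSet.from_arrays(starts, stops, labs), step=step_s)


def spectrogram_psd(lfp: LFPRecording, channel: int, epochs: EpochSet,
                    nperseg_s: float = 10.0) -> pd.DataFrame:
    """Welch PSD per labelled epoch (on the 125 Hz decimated channel).

    Returns a tidy frame (label, start, f_hz, psd) suitable for
    block-averaged reporting curves.
    """
    x, fs = _decimated(lfp, channel)
    rows = []
    nper = int(nperseg_s * fs)
    for s, e, l in zip(epochs.starts, epochs.stops, epochs.labels):
        i0, i1 = int(s * fs), int(e * fs)
        seg = x[i0:i1]
        if len(seg) < nper:
            continue
        f, p = welch(seg, fs=fs, nperseg=nper)
        rows.append(pd.DataFrame({"label": l, "start": s, "f_hz": f, "psd": p}))
    if not rows:
        return pd.DataFrame(columns=["label", "start", "f_hz", "psd"])
    return pd.concat(rows, ignore_index=True)
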