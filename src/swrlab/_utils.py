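"""Shared helpers: named random substreams and interval arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "epoch_mask", "merge_intervals", "interval_complement"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random substream derived from one master seed.

    Streams are keyed by (seed, crc32(name)), so adding draws to one
    component never perturbs another component's stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of half-open [start, stop) intervals, returned sorted/disjoint."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def epoch_mask(times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of times falling inside any half-open [start, stop)."""
    times = np.asarray(times, dtype=float)
    iv = merge_intervals(intervals)
    if len(iv) == 0:
        return np.zeros(times.shape, dtype=bool)
    idx = np.searchsorted(iv[:, 0], times, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(times.shape, dtype=bool)
    mask[ok] = times[ok] < iv[idx[ok], 1]
    return mask


def interval_complement(intervals: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    """Complement of an interval union within [span[0], span[1])."""
    lo, hi = float(span[0]), float(span[1])
    iv = merge_intervals(intervals)
    out = []
    cur = lo
    for s, e in iv:
        s, e = max(s, lo), min(e, hi)
        if s >= e:
            continue
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return np.asarray(out, dtype=float).reshape(-1, 2)
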