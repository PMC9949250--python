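"""One-command orchestration: score -> detect -> summarize -> report.

Every stage parameter defaults to the values used throughout the package
(ripple band 125-250 Hz with 2.5 / 0.5 s.d. thresholds and 50-450 ms
durations; MUA sigma 20 ms, 3 s.d., 10 ms merge, 80-500 ms; EV bins of
250 ms in 15-min windows stepped 5 min with waveform-similarity cutoff
0.8; maps binned at 2 cm, smoothed 4 cm, speed threshold 8 cm/s, peak
floor 0.5 Hz; decoding bins of 20 ms, 40 cm jump limit, 4-bin runs covering 35 cm;
2.5 h blocks).  ``run_pipeline`` writes per-stage TSVs plus a
machine-readable ``report.json`` of block summaries and echoes the
effective configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, firing, reactivation, ripples, sleep
from .session import EpochSet, Session, block_partition

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("swrlab")

REPORT_SCHEMA = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every stage's tunables, defaulting to the package's standard values."""

    ripple_band: tuple = (125.0, 250.0)
    ripple_peak_z: float = 2.5
    ripple_boundary_z: float = 0.5
    ripple_smooth_s: float = 0.0125
    ripple_duration: tuple = (0.05, 0.45)
    ripple_merge_gap: float = 0.03
    mua_sigma_s: float = 0.02
    mua_peak_z: float = 3.0
    mua_merge_gap: float = 0.01
    mua_duration: tuple = (0.08, 0.5)
    ev_bin_s: float = 0.25
    ev_window_s: float = 900.0
    ev_step_s: float = 300.0
    similarity_cutoff: float = 0.8
    map_bin_cm: float = 2.0
    map_sigma_cm: float = 4.0
    speed_thresh: float = 8.0
    map_min_peak_hz: float = 0.5
    decode_tau_s: float = 0.02
    jump_max_cm: float = 40.0
    replay_min_bins: int = 4
    replay_min_distance_cm: float = 35.0
    candidate_min_units: int = 5
    candidate_power_z: float = 1.0
    block_hours: float = 2.5
    stability_bins: int = 5
    stability_frac: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


_POSITIVE = {"ripple_peak_z", "ripple_boundary_z", "ripple_smooth_s", "ripple_merge_gap",
             "mua_sigma_s", "mua_peak_z", "mua_merge_gap", "ev_bin_s", "ev_window_s",
             "ev_step_s", "map_bin_cm", "map_sigma_cm", "speed_thresh", "decode_tau_s",
             "jump_max_cm", "block_hours", "stability_bins", "stability_frac",
             "candidate_min_units", "replay_min_bins"}


def validate_config(config: dict | PipelineConfig | None = None) -> PipelineConfig:
    """Normalize a mapping (or None) to a PipelineConfig, rejecting unknown
    keys and non-positive values for durations/rates/thresholds."""
    if config is None:
        return PipelineConfig()
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in config.items()}
        cfg = PipelineConfig(**coerced)
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            raise ValueError(f"config value {name} must be positive")
    for name in ("ripple_duration", "mua_duration", "ripple_band"):
        lo, hi = getattr(cfg, name)
        if not (0 <= lo < hi):
            raise ValueError(f"config value {name} must be an increasing pair")
    return cfg


def _write(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6f")


def run_pipeline(session: Session, config: PipelineConfig | dict | None = None,
                 out_dir=None) -> dict:
    """Full analysis of one session; returns (and optionally writes) the report.

    Stages: block partition, stability screen, sleep scoring, ripple and
    burst detection with per-event properties, firing summaries, the EV /
    REV timecourse with its time constant, and Bayesian replay calls.  Any
    stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are retained.
    """
    cfg = validate_config(config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"schema": REPORT_SCHEMA, "condition": session.condition,
                    "config": cfg.to_dict()}

    stage = "blocks"
    try:
        blocks = block_partition(session, cfg.block_hours)
        post_blocks = blocks.select([l for l in blocks.labels if l not in ("PRE", "MAZE")])
        report["blocks"] = blocks.df.to_dict(orient="list")
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "stability"
    try:
        stable_ids = firing.stability_filter(session.units, session.duration,
                                             cfg.stability_bins, cfg.stability_frac)
        stable = session.units.subset(stable_ids)
        log.info("stability: %d/%d units retained", len(stable_ids), len(session.units))
        report["n_units"] = {"total": len(session.units), "stable": len(stable_ids)}
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "sleep_scoring"
    try:
        emg = sleep.correlation_emg(session.lfp)
        th_ch = sleep.theta_channel(session.lfp)
        ratio = sleep.theta_ratio(session.lfp, th_ch)
        hyp = sleep.classify_states(emg, ratio)
        _write(hyp.epochs.df.rename(columns={"start": "start_s", "stop": "stop_s"}),
               out_dir, "hypnogram.tsv")
        frac = {l: float(hyp.epochs.select(l).durations.sum()) for l in set(hyp.epochs.labels)}
        report["state_seconds"] = frac
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "ripples"
    try:
        channels = ripples.select_ripple_channels(session.lfp, cfg.ripple_band)
        env = ripples.ripple_envelope(session.lfp, channels, cfg.ripple_band,
                                      cfg.ripple_smooth_s)
        swr = ripples.detect_ripples(session.lfp, channels, cfg.ripple_peak_z,
                                     cfg.ripple_boundary_z, cfg.ripple_band,
                                     cfg.ripple_smooth_s, cfg.ripple_duration,
                                     cfg.ripple_merge_gap, env=env)
        log.info("ripples: %d events", len(swr))
        swr_df = swr.df.copy()
        if len(swr):
            swr_df["sharpwave_mv"] = ripples.sharpwave_amplitudes(session.lfp, swr)
            swr_df["peak_freq_hz"] = ripples.peak_ripple_frequencies(session.lfp, swr, channels)
        _write(swr_df.rename(columns={"start": "start_s", "stop": "stop_s"}),
               out_dir, "ripples.tsv")
        rate_tab = ripples.event_rate_by_block(swr, post_blocks)
        report["ripple_rate_hz"] = dict(zip(rate_tab["block"], rate_tab["rate_hz"]))
        prop = {}
        for col, key in (("peak_power_z", "ripple_power_z"),
                         ("sharpwave_mv", "sharpwave_mv"),
                         ("peak_freq_hz", "ripple_freq_hz")):
            if col in swr_df and len(swr_df):
                med = {}
                for _, b in post_blocks.df.iterrows():
                    m = (swr_df["peak"] >= b["start"]) & (swr_df["peak"] < b["stop"])
                    med[b["label"]] = float(swr_df.loc[m, col].median()) if m.any() else None
                prop[key] = med
        report["ripple_properties_median"] = prop
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "bursts"
    try:
        bursts = ripples.detect_population_bursts(stable, session.duration,
                                                  sigma_s=cfg.mua_sigma_s,
                                                  peak_z=cfg.mua_peak_z,
                                                  merge_gap=cfg.mua_merge_gap,
                                                  dur=cfg.mua_duration)
        log.info("bursts: %d events", len(bursts))
        _write(bursts.df.rename(columns={"start": "start_s", "stop": "stop_s"}),
               out_dir, "bursts.tsv")
        report["n_bursts"] = len(bursts)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "firing"
    try:
        rates = firing.block_firing_rates(stable, blocks)
        summary = firing.rate_summary(rates)
        _write(rates, out_dir, "firing_rates.tsv")
        _write(summary, out_dir, "firing_summary.tsv")
        med = {}
        for _, row in summary.iterrows():
            med.setdefault(row["putative_type"], {})[row["block"]] = {
                "median_hz": float(row["median"]), "iqr_hz": float(row["iqr"])}
        report["firing_rate"] = med
        if len(swr):
            inrip = firing.within_event_rates(stable, swr)
            report["within_ripple_rate"] = {
                t: float(g["rate_hz"].median())
                for t, g in inrip.groupby("putative_type")}
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "reactivation"
    try:
        series = reactivation.ev_timecourse(stable_session(session, stable),
                                            cfg.ev_bin_s, cfg.ev_window_s, cfg.ev_step_s,
                                            cfg.similarity_cutoff)
        _write(series.to_frame(), out_dir, "ev.tsv")
        tc = reactivation.ev_time_constant(series.ev, cfg.ev_step_s)
        evb = reactivation.ev_block_summary(series, post_blocks)
        report["ev"] = {
            "n_pairs": series.n_pairs,
            "time_constant_h": tc.tau_h, "censored": tc.censored,
            "ev_minus_rev": dict(zip(evb["block"], evb["ev_minus_rev"])),
        }
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "decoding"
    try:
        maps = decoding.compute_rate_maps(stable, session.position, session.block("MAZE"),
                                          session.track_length, cfg.map_bin_cm,
                                          cfg.map_sigma_cm, cfg.speed_thresh,
                                          cfg.map_min_peak_hz)
        cands = decoding.select_candidates(bursts, stable, session.position, env,
                                           session.lfp.fs, maps.included,
                                           cfg.candidate_min_units, cfg.speed_thresh,
                                           cfg.candidate_power_z)
        calls = decoding.decode_events(stable, maps, cands, cfg.decode_tau_s,
                                       cfg.jump_max_cm, cfg.replay_min_bins,
                                       cfg.replay_min_distance_cm)
        _write(calls, out_dir, "replays.tsv")
        props = decoding.replay_proportions(calls, post_blocks)
        report["replay"] = {
            "n_candidates": int(cands["is_candidate"].sum()),
            "proportion": {r["block"]: (None if np.isnan(r["proportion"]) else float(r["proportion"]))
                           for _, r in props.iterrows()},
        }
        log.info("decoding: %d candidates, %d replays",
                 int(cands["is_candidate"].sum()), int(calls["is_replay"].sum()))
    except Exception as e:
        raise PipelineError(stage, e) from e

    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1,
                                                        default=_json_default))
    return report


def stable_session(session: Session, stable_units) -> Session:
    """Copy of the session restricted to the stability-screened units."""
    return Session(units=stable_units, lfp=session.lfp, position=session.position,
                   blocks=session.blocks, condition=session.condition,
                   zeitgeber_zero=session.zeitgeber_zero,
                   track_length=session.track_length, duration=session.duration)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
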