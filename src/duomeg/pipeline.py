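"""End-to-end orchestration: simulate, behavioral pipeline, coherence
pipeline, stream synchronization — each a thin driver over the library
modules, emitting reproducible TSV/JSON reports.

Every report echoes the configuration it was produced with plus a stable
config hash, so regenerating from the same inputs and configuration yields
identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import behavior as bh
from . import coherence as ch
from . import io as dio
from . import streamsync as ss
from . import synthgen as sg
from .utils import config_hash

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PairReport",
    "run_behavior",
    "run_coherence",
    "run_simulate",
    "run_sync",
]

SIGN_CONVENTION = "signed lag = second site (HUCH role) minus first site (Aalto role), ms"


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis, with recorded defaults."""

    # behavioral
    notch_freq_hz: float = 50.0
    notch_bandwidth_hz: float = 1.0
    lp_cutoff_hz: float = 3.0
    lp_order: int = 6
    lp_stop_atten_db: float = 30.0
    block_s: float = 240.0
    block_step_s: float = 0.1
    pca_center: bool = True
    # coherence
    band_hz: tuple[float, float] = (0.5, 2.0)
    window_len: int = 8096
    overlap: float = 0.5
    taper: str = "hann"
    # synthesis / provenance
    seed: int = 0
    out_dir: str | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.as_dict())


@dataclass
class PairReport:
    """Per-pair results: lag/cycle statistics, block, counts, provenance."""

    site_a: str
    site_b: str
    block_window_s: tuple[float, float]
    n_events: int
    lag_stats: bh.LagStats
    cycle_stats_a: bh.CycleStats
    cycle_stats_b: bh.CycleStats
    sign_convention: str = SIGN_CONVENTION
    coherence_summary: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    config_hash: str = ""

    def to_dict(self) -> dict:
        def _clean(obj):
            if dataclasses.is_dataclass(obj):
                return _clean(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return _clean(dataclasses.asdict(self))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_behavior(
    rec_a: bh.AccelRecording,
    rec_b: bh.AccelRecording,
    cfg: PipelineConfig | None = None,
) -> tuple[PairReport, dict]:
    """Full behavioral pipeline on one pair of accelerometer recordings.

    Stages: 50-Hz notch -> PCA -> polarity alignment -> 3-Hz low-pass ->
    event detection -> block selection -> cross-site matching -> lag and
    cycle statistics.  Returns the report plus a dict of intermediate
    objects (summaries, event series, matches) for plotting and testing.
    """
    cfg = cfg or PipelineConfig()
    try:
        t0 = _stage("notch + PCA + low-pass")
        summaries = []
        for rec in (rec_a, rec_b):
            filtered = bh.notch_filter(rec.samples, rec.fs_hz,
                                       cfg.notch_freq_hz, cfg.notch_bandwidth_hz)
            clean = dataclasses.replace(rec, samples=filtered)
            s = bh.pca_reduce(clean, center=cfg.pca_center)
            summaries.append(s)
        sum_a, sum_b = summaries
        sum_b = bh.align_sign(sum_b, sum_a.lp_trace)
        logger.info("preprocessing took %.2f s", time.perf_counter() - t0)

        _stage("event detection + block selection + matching")
        ev_a = bh.detect_events(sum_a.lp_trace, rec_a.fs_hz, rec_a.start_time_s,
                                rec_a.site)
        ev_b = bh.detect_events(sum_b.lp_trace, rec_b.fs_hz, rec_b.start_time_s,
                                rec_b.site)
        t_lo = max(rec_a.start_time_s, rec_b.start_time_s)
        t_hi = min(rec_a.start_time_s + rec_a.duration_s,
                   rec_b.start_time_s + rec_b.duration_s)
        window, ev_a_blk, ev_b_blk = bh.select_block(
            ev_a, ev_b, t_lo, t_hi, cfg.block_s, cfg.block_step_s
        )
        matched = bh.match_events(ev_a_blk, ev_b_blk)
        stats = bh.lag_statistics(matched)
    except Exception as err:
        raise RuntimeError(
            f"behavioral pipeline failed on pair ({rec_a.site}/{rec_a.subject}, "
            f"{rec_b.site}/{rec_b.subject}): {err}"
        ) from err

    report = PairReport(
        site_a=rec_a.site,
        site_b=rec_b.site,
        block_window_s=window,
        n_events=len(ev_a_blk),
        lag_stats=stats,
        cycle_stats_a=bh.cycle_statistics(ev_a_blk),
        cycle_stats_b=bh.cycle_statistics(ev_b_blk),
        config=cfg.as_dict(),
        config_hash=cfg.hash,
    )
    inter = {
        "summary_a": sum_a, "summary_b": sum_b,
        "events_a": ev_a, "events_b": ev_b,
        "events_a_block": ev_a_blk, "events_b_block": ev_b_blk,
        "matched": matched,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "behavior_report.json")
        dio.write_events_tsv(ev_a_blk, out / f"events_{rec_a.site}.tsv")
        dio.write_events_tsv(ev_b_blk, out / f"events_{rec_b.site}.tsv")
        dio.write_pairs_tsv(matched, out / "matched_pairs.tsv")
    return report, inter


def run_coherence(
    grad_a: ch.GradiometerRecording,
    grad_b: ch.GradiometerRecording,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Inter-subject coherence pipeline on one pair of gradiometer arrays."""
    cfg = cfg or PipelineConfig()
    try:
        _stage("204x204 Welch coherence matrix")
        cm = ch.inter_subject_matrix(grad_a, grad_b, cfg.band_hz,
                                     cfg.window_len, cfg.overlap, cfg.taper)
        tv_rows, tv_cols = ch.collapse_to_sites(cm, grad_b.module_map)
    except Exception as err:
        raise RuntimeError(
            f"coherence pipeline failed on pair ({grad_a.site}, "
            f"{grad_b.site}): {err}"
        ) from err
    result = {
        "matrix": cm,
        "topo_rows": tv_rows,
        "topo_cols": tv_cols,
        "max_msc": float(cm.values.max()),
        "top_modules": {
            tv.site: int(np.argmax(tv.per_module)) for tv in (tv_rows, tv_cols)
        },
        "config_hash": cfg.hash,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_coherence_matrix(cm, out / "coherence_matrix.txt")
        for tv, rec in ((tv_rows, grad_b), (tv_cols, grad_a)):
            dio.write_topo_tsv(tv, out / f"topo_{tv.site}.tsv")
            fig, _ = ch.render_topomap(tv, rec.layout_2d,
                                       out / f"topomap_{tv.site}.png")
            import matplotlib.pyplot as plt

            plt.close(fig)
    return result


def run_simulate(
    pair_cfg: sg.PairConfig,
    out_dir: str | Path,
    planted: set[int] | None = None,
    snr: float = 1.0,
    clock_offsets_s: tuple[float, float] = (0.0, 3.2),
    clock_drifts_ppm: tuple[float, float] = (0.0, 20.0),
    with_meg: bool = False,
) -> sg.GroundTruth:
    """Write a complete synthetic dataset (accel + triggers [+ MEG] + truth).

    Re-running with the same configuration reproduces the dataset exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_a, rec_b, gt = sg.gen_movement_pair(pair_cfg)
    dio.write_accel_tsv(rec_a, out / "accel_Aalto.tsv")
    dio.write_accel_tsv(rec_b, out / "accel_HUCH.tsv")
    for site, off, drift in zip(("Aalto", "HUCH"), clock_offsets_s,
                                clock_drifts_ppm):
        tt, cm = sg.gen_trigger_channel(pair_cfg, off, drift, site=site)
        dio.write_trigger_tsv(tt, out / f"trigger_{site}.tsv")
        dio.write_clock_map_json(cm, out / f"clock_true_{site}.json")
        gt.clock_offset_s[site] = off
        gt.clock_drift_ppm[site] = drift
    if with_meg:
        planted = planted if planted is not None else set(range(60, 68))
        ga, gb = sg.gen_meg_pair(pair_cfg, rec_a, rec_b, planted, snr)
        dio.write_grad_h5(ga, out / "grad_Aalto.h5")
        dio.write_grad_h5(gb, out / "grad_HUCH.h5")
        gt.planted_channels = {"Aalto": sorted(planted), "HUCH": sorted(planted)}
    dio.write_ground_truth_json(gt, out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(
        {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in dataclasses.asdict(pair_cfg).items()}
        | {"config_hash": config_hash(str(dataclasses.asdict(pair_cfg)))},
        indent=1,
    ))
    return gt


def run_sync(
    trigger_a: ss.TriggerTrace,
    trigger_b: ss.TriggerTrace,
) -> tuple[ss.ClockMap, ss.ClockMap]:
    """Decode both sites' trigger channels and fit their clock maps."""
    maps = []
    for tt in (trigger_a, trigger_b):
        stamps = ss.decode_timestamps(tt)
        maps.append(ss.fit_clock_map(stamps, tt.fs_hz))
    return maps[0], maps[1]
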