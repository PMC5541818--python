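"""End-to-end pipeline: simulate -> preprocess -> train/score -> fuse -> evaluate.

A run is fully described by a `PipelineConfig` (serialisable to YAML); the
same config + seed reproduces every numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path


import pandas as pd
import yaml

from . import fusion, miss, preprocess, schedule as sched, synth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_session", "miss_curve"]

_PARADIGM_STREAMS = {"single": 1, "dual": 2, "triple": 3}


@dataclass
class PipelineConfig:
    """Declarative description of one simulated multi-RSVP experiment."""

    paradigm: str = "triple"  # single | dual | triple
    # schedule
    n_blocks: int = 10
    images_per_block: int = 200
    targets_per_block: int = 20
    flash_rate_hz: float = 4.0
    stream_delay_step_ms: float = 750.0
    min_target_gap_frames: int | None = None
    refixation_frames: int = 3
    randomize_reappearance: bool = False
    # synthetic EEG
    n_channels: int = 16
    sim_fs_hz: float = 2400.0
    noise_sd_uV: float = 10.0
    noise_spatial_frac: float = 0.8
    n_noise_sources: int = 6
    line_noise_uV: float = 2.0
    erp_amplitudes_uV: tuple[float, float, float] = (6.0, 5.5, 4.0)
    erp_latencies_ms: tuple[float, float, float] = (300.0, 300.0, 400.0)
    erp_width_ms: float = 200.0
    # preprocessing
    band_low_hz: float = 0.5
    band_high_hz: float = 60.0
    target_fs_hz: float = 600.0
    epoch_length_ms: float = 1000.0
    baseline_window_ms: float = 200.0
    # classification / evaluation
    method: str = "hdca"  # hdca | swlda
    hdca_window_s: float = 0.025
    swlda_points_per_channel: int = 60
    cv_folds: int = 10
    seed: int = 0

    @property
    def n_streams(self) -> int:
        try:
            return _PARADIGM_STREAMS[self.paradigm]
        except KeyError:
            raise ValueError(f"unknown paradigm {self.paradigm!r}") from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erp_amplitudes_uV"] = list(self.erp_amplitudes_uV)
        d["erp_latencies_ms"] = list(self.erp_latencies_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("erp_amplitudes_uV", "erp_latencies_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _template(config: PipelineConfig) -> synth.ErpTemplate:
    return synth.ErpTemplate(
        peak_latency_ms=config.erp_latencies_ms,
        amplitude_uV=config.erp_amplitudes_uV,
        width_ms=config.erp_width_ms,
    )


def simulate_session(config: PipelineConfig):
    """Schedule + gaze + raw recording + preprocessed epochs for one config.

    Returns ``(schedule, gaze, raw, epochs)``.  Simulating directly at the
    target rate (``sim_fs_hz == target_fs_hz``) skips the downsampling stage.
    """
    schedule = sched.generate_schedule(
        n_streams=config.n_streams,
        n_blocks=config.n_blocks,
        images_per_block=config.images_per_block,
        targets_per_block=config.targets_per_block,
        flash_rate_hz=config.flash_rate_hz,
        stream_delays_ms=tuple(
            config.stream_delay_step_ms * s for s in range(config.n_streams)
        ),
        min_target_gap_frames=config.min_target_gap_frames,
        seed=config.seed,
        randomize_reappearance=config.randomize_reappearance,
    )
    gaze = (
        sched.derive_gaze(schedule, config.refixation_frames)
        if config.n_streams > 1
        else None
    )
    log.info(
        "schedule: %d streams, %d images, %d targets",
        schedule.n_streams, schedule.n_images, len(schedule.target_frames()),
    )
    raw = synth.simulate_recording(
        schedule,
        gaze,
        _template(config),
        n_channels=config.n_channels,
        fs_hz=config.sim_fs_hz,
        noise_sd_uV=config.noise_sd_uV,
        line_noise_uV=config.line_noise_uV,
        seed=config.seed + 1,
        spatial_noise_frac=config.noise_spatial_frac,
        n_noise_sources=config.n_noise_sources,
    )
    raw = synth.apply_acquisition(raw)
    epochs = preprocess.preprocess_chain(
        raw,
        schedule,
        low_hz=config.band_low_hz,
        high_hz=config.band_high_hz,
        target_fs_hz=config.target_fs_hz,
        epoch_length_ms=config.epoch_length_ms,
        baseline_window_ms=config.baseline_window_ms,
    )
    log.info("epochs: %s @ %g Hz", epochs.data.shape, epochs.fs_hz)
    return schedule, gaze, raw, epochs


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write scores CSV, AUC JSON, config and log.

    The AUC summary contains one entry per nested stream subset (single, and
    for multi-stream paradigms dual/triple) with per-fold and mean values,
    plus paired Wilcoxon p-values between consecutive subsets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")

    stage = "simulate"
    try:
        schedule, gaze, raw, epochs = simulate_session(config)
        stage = "score"
        fit_kwargs = (
            {"window_s": config.hdca_window_s}
            if config.method == "hdca"
            else {"points_per_channel": config.swlda_points_per_channel}
        )
        scored = fusion.score_epochs_cv(
            epochs,
            method=config.method,
            k=config.cv_folds,
            seed=config.seed,
            **fit_kwargs,
        )
        stage = "evaluate"
        results = fusion.paradigm_aucs_from_scores(scored)
        table = fusion.fuse_scores(scored)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    table.to_csv(out / "scores.csv", float_format="%.10g")

    summary: dict = {"method": config.method, "paradigm": config.paradigm,
                     "seed": config.seed, "auc": {}}
    names = list(results)
    for name, res in results.items():
        summary["auc"][name] = {
            "streams": res["streams"],
            "mean": res["mean_auc"],
            "folds": [float(a) for a in res["fold_aucs"]],
        }
    summary["wilcoxon"] = {}
    for a, b in zip(names, names[1:]):
        try:
            p, w = fusion.paired_wilcoxon(
                results[b]["fold_aucs"], results[a]["fold_aucs"]
            )
            summary["wilcoxon"][f"{b}_vs_{a}"] = {"p": p, "statistic": w}
        except (fusion.EvaluationError, ValueError):
            # too few folds for the test, or all fold AUCs tied
            summary["wilcoxon"][f"{b}_vs_{a}"] = {"p": None, "statistic": None}
    if gaze is not None:
        summary["gaze"] = {
            "missed_images": len(gaze.missed_base_frames),
            "missed_target_fraction": miss.schedule_miss_rate(schedule, gaze),
        }
    (out / "auc.json").write_text(json.dumps(summary, indent=2))
    log.info("run complete: %s", out)
    return summary


def miss_curve(
    p_target_grid,
    n_ignored_list=(3, 6, 9),
    n_trials: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Analytic (and optionally Monte-Carlo) miss probability over a grid.

    One row per (p_target, n_ignored); columns ``p_miss`` (closed form) and,
    when ``n_trials > 0``, ``p_miss_mc`` and ``mc_se``.
    """
    rows = []
    for i, n in enumerate(n_ignored_list):
        for j, p in enumerate(p_target_grid):
            row = {
                "p_target": float(p),
                "n_ignored": int(n),
                "p_miss": miss.miss_probability(p, n),
            }
            if n_trials:
                est, se = miss.simulate_miss_rate(
                    p, n, n_trials, seed + 1000 * i + j
                )
                row["p_miss_mc"], row["mc_se"] = est, se
            rows.append(row)
    return pd.DataFrame(rows)
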