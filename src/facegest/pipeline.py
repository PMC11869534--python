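"""End-to-end orchestration: predictions -> features -> classification reports.

The pipeline reads prediction tables (or self-generates them from a
synthetic scenario), keeps the fully-crossed frames, aligns them, computes
normalized pairwise-distance features, prunes correlated columns, runs the
repeated classification harness, and writes summary tables, confusion
matrices, the pruning report, and a provenance manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import (
    HarnessConfig,
    aggregate,
    compare_algorithms,
    run_harness,
)
from .features import prune_correlated, split_columns, tabulate
from .geometry import align_frame, distance_vector, is_fully_crossed, normalize
from .io_dlc import ClipLabel, FrameObservation, read_clip_labels, read_predictions
from .scheme import DEFAULT_SCHEME, LandmarkScheme

log = logging.getLogger("facegest")


@dataclass
class FilterStats:
    """Per-clip accounting of the likelihood-cutoff filter."""

    frames_in: dict[str, int]
    frames_fully_crossed: dict[str, int]

    @property
    def total_in(self) -> int:
        return sum(self.frames_in.values())

    @property
    def total_fully_crossed(self) -> int:
        return sum(self.frames_fully_crossed.values())

    @property
    def frames_rejected(self) -> dict[str, int]:
        return {
            clip: self.frames_in[clip] - self.frames_fully_crossed[clip]
            for clip in self.frames_in
        }


def build_feature_table(
    frames: Sequence[FrameObservation],
    clip_labels: Mapping[str, ClipLabel] | None,
    scheme: LandmarkScheme = DEFAULT_SCHEME,
    cutoff: float = 0.6,
    align: bool = True,
) -> tuple[pd.DataFrame, FilterStats]:
    """Filter, align, and convert frames to the normalized feature table.

    Filtering happens on the raw predictions before alignment; a frame
    enters the table only if every landmark's likelihood is strictly above
    the cutoff.
    """
    frames_in: dict[str, int] = {}
    kept: dict[str, int] = {}
    vectors = []
    for obs in frames:
        frames_in[obs.clip_id] = frames_in.get(obs.clip_id, 0) + 1
        if not is_fully_crossed(obs, cutoff):
            continue
        kept[obs.clip_id] = kept.get(obs.clip_id, 0) + 1
        work = align_frame(obs, scheme) if align else obs
        vectors.append(normalize(distance_vector(work, scheme), scheme))
    stats = FilterStats(
        frames_in=frames_in,
        frames_fully_crossed={c: kept.get(c, 0) for c in frames_in},
    )
    log.info(
        "cutoff %.2f kept %d of %d frames (%d clips)",
        cutoff,
        stats.total_fully_crossed,
        stats.total_in,
        len(frames_in),
    )
    table = tabulate(vectors, scheme, clip_labels)
    return table, stats


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the study constants."""

    predictions_dir: str | None = None  # directory of per-clip prediction CSVs
    clip_labels_path: str | None = None
    output_dir: str = "facegest_output"
    cutoff: float = 0.6
    correlation_threshold: float = 0.75
    harness: HarnessConfig = field(default_factory=HarnessConfig)
    scenario: dict | None = None  # synthetic scenario kwargs, to self-generate inputs
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "harness" in raw:
            raw["harness"] = HarnessConfig(**raw["harness"])
        return cls(**raw)


def _load_inputs(
    config: PipelineConfig, scheme: LandmarkScheme
) -> tuple[list[FrameObservation], dict[str, ClipLabel]]:
    if config.scenario is not None:
        from .synthetic import (
            SyntheticScenario,
            eight_class_scenario,
            generate,
            null_scenario,
            two_class_scenario,
        )

        kwargs = dict(config.scenario)
        preset = kwargs.pop("preset", "eight_class")
        kwargs.setdefault("seed", config.seed)
        factory = {
            "two_class": two_class_scenario,
            "eight_class": eight_class_scenario,
            "null2": lambda **kw: null_scenario(2, kw.pop("clips_per_class", 100), **kw),
            "null8": lambda **kw: null_scenario(8, kw.pop("clips_per_class", 100), **kw),
        }[preset]
        dataset = generate(factory(**kwargs))
        return dataset.predictions, dataset.clip_labels
    if config.predictions_dir is None or config.clip_labels_path is None:
        raise ValueError("either a scenario or predictions_dir + clip_labels_path is required")
    frames: list[FrameObservation] = []
    for path in sorted(Path(config.predictions_dir).glob("*.csv")):
        frames.extend(read_predictions(path, scheme))
    return frames, read_clip_labels(config.clip_labels_path)


def run_pipeline(
    config: PipelineConfig, scheme: LandmarkScheme = DEFAULT_SCHEME
) -> dict:
    """Execute the full pipeline and write the report bundle to output_dir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames, clip_labels = _load_inputs(config, scheme)
    table, stats = build_feature_table(frames, clip_labels, scheme, config.cutoff)
    reduced, report = prune_correlated(table, config.correlation_threshold)

    harness = config.harness
    results = run_harness(reduced, harness)
    summary = aggregate(results)
    comparison = compare_algorithms(results)

    # ---- report bundle
    feats, _ = split_columns(table)
    table.to_csv(out / "feature_table.csv", index=False)
    reduced.to_csv(out / "feature_table_pruned.csv", index=False)
    with open(out / "pruning_report.json", "w") as fh:
        json.dump(
            {
                "threshold": report.threshold,
                "n_before": len(feats),
                "retained": report.retained,
                "dropped": [
                    {"column": c, "partner": p, "abs_r": r} for c, p, r in report.dropped
                ],
            },
            fh,
            indent=2,
        )
    summary["summary"].to_csv(out / "classification_summary.csv")
    for algo, matrix in summary["confusion"].items():
        matrix.to_csv(out / f"confusion_{algo}.csv")
    pd.DataFrame(
        [
            {
                "pair": "-".join(c.pair),
                "shapiro_w": c.shapiro_w,
                "shapiro_p": c.shapiro_p,
                "t": c.t_statistic,
                "df": c.df,
                "p": c.p_value,
                "mean_difference": c.mean_difference,
                "degenerate": c.degenerate,
            }
            for c in comparison.comparisons
        ]
    ).to_csv(out / "algorithm_comparison.csv", index=False)
    pd.DataFrame(
        {
            "clip_id": list(stats.frames_in),
            "frames_in": list(stats.frames_in.values()),
            "frames_fully_crossed": [
                stats.frames_fully_crossed[c] for c in stats.frames_in
            ],
            "frames_rejected": [stats.frames_rejected[c] for c in stats.frames_in],
        }
    ).to_csv(out / "filter_accounting.csv", index=False)

    manifest = {
        "facegest_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "cutoff": config.cutoff,
        "correlation_threshold": config.correlation_threshold,
        "harness": asdict(harness),
        "scenario": config.scenario,
        "n_frames_in": stats.total_in,
        "n_frames_fully_crossed": stats.total_fully_crossed,
        "n_features_tabulated": len(feats),
        "n_features_retained": len(report.retained),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "table": table,
        "reduced": reduced,
        "pruning": report,
        "results": results,
        "summary": summary,
        "comparison": comparison,
        "filter_stats": stats,
        "manifest": manifest,
    }
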