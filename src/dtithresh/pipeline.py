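"""End-to-end pipelines: synthetic cohort study and real-data analysis.

Synthetic mode generates a seeded phantom cohort, fits tensors from the
noisy DWI signals, runs the masking cascade and emits the cohort table,
cohort statistics and region-wise comparisons.  Real mode consumes
pre-computed, co-registered scalar maps plus a label atlas (registration
is the caller's responsibility) and enters the same analysis path.

Every run writes a manifest with the config echo, the seed and SHA-256
hashes of each artifact, so reruns can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .acquisition import AcquisitionScheme
from .errors import GridMismatchError
from .metrics import cohort_table, summarize_subject
from .phantom import (
    CohortConfig,
    PhantomCohort,
    RegionSpec,
    generate_cohort,
)
from .segmentation import ThresholdConfig, segment
from .stats import cohort_moments, compare_conditions
from .tensor import fit_tensor, scalar_maps_from_tensors

__all__ = ["StatsConfig", "PipelineConfig", "run_pipeline", "analyze_cohort"]

MEASURES = ("percent_volume", "n_voxels", "mean_fa", "mean_ad", "mean_rd")


@dataclass(frozen=True)
class StatsConfig:
    family_alpha: float = 0.05
    family_size: int = 12
    permutation_resamples: int = 10_000
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "synthetic"  # or "real"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    # real mode: per-subject scalar-map path dicts + one label atlas
    scalar_paths: tuple[dict, ...] = ()
    labels_path: str | None = None
    out_dir: str = "dtithresh-out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real" and (not self.scalar_paths or not self.labels_path):
            raise ValueError("real mode requires scalar_paths and labels_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        regions = cohort_raw.pop("region_table", None)
        if regions is not None:
            cohort_raw["region_table"] = tuple(
                RegionSpec(**r) for r in regions
            )
        if "grid_shape" in cohort_raw:
            cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
        thr_raw = raw.pop("thresholds", {})
        if "fa_cutoffs" in thr_raw:
            thr_raw["fa_cutoffs"] = tuple(thr_raw["fa_cutoffs"])
        stats_raw = raw.pop("stats", {})
        if "scalar_paths" in raw:
            raw["scalar_paths"] = tuple(raw["scalar_paths"])
        return cls(
            cohort=CohortConfig(**cohort_raw),
            thresholds=ThresholdConfig(**thr_raw),
            stats=StatsConfig(**stats_raw),
            **raw,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_cohort(
    subjects: list[tuple[str, np.ndarray, "object"]],
    regions: tuple[RegionSpec, ...],
    thresholds: ThresholdConfig,
    stats_cfg: StatsConfig,
) -> dict[str, pd.DataFrame]:
    """Masking cascade + metrics + statistics for pre-computed scalars.

    ``subjects`` holds (subject_id, label volume, ScalarMaps) triples.
    """
    summaries = []
    for sid, labels, scalars in subjects:
        if labels.shape != scalars.shape:
            raise GridMismatchError(
                f"subject {sid}: label grid {labels.shape} does not match "
                f"scalar grid {scalars.shape}"
            )
        mask_set = segment(labels, scalars, thresholds, regions)
        atlas_counts = {
            r.label_id: int((labels == r.label_id).sum()) for r in regions
        }
        summaries.append(
            summarize_subject(sid, mask_set, scalars, regions, atlas_counts)
        )
    table = cohort_table(summaries)
    moments = pd.concat(
        [cohort_moments(table, m) for m in MEASURES], ignore_index=True
    )
    rng = np.random.default_rng(stats_cfg.seed)
    comparisons = pd.concat(
        [
            compare_conditions(
                table,
                m,
                thresholds.conditions,
                family_alpha=stats_cfg.family_alpha,
                family_size=stats_cfg.family_size,
                seed=rng,
            )
            for m in ("percent_volume", "mean_fa", "mean_ad", "mean_rd")
        ],
        ignore_index=True,
    )
    return {"table": table, "moments": moments, "comparisons": comparisons}


def _fit_subjects(cohort: PhantomCohort, scheme: AcquisitionScheme):
    out = []
    for i, sub in enumerate(cohort.subjects):
        tensors = fit_tensor(sub.dwi, scheme, voxel_size=cohort.voxel_size)
        scalars = scalar_maps_from_tensors(tensors)
        out.append((f"sub-{i:03d}", sub.labels, scalars))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured pipeline and write tables, reports and manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "synthetic":
        cohort = generate_cohort(cfg.cohort)
        regions = cohort.region_table
        subjects = _fit_subjects(cohort, cohort.scheme)
    else:
        labels, lab_aff = dio.load_labels(cfg.labels_path)
        subjects = []
        for i, paths in enumerate(cfg.scalar_paths):
            scalars = dio.load_scalar_maps(paths)
            if scalars.shape != labels.shape or (
                scalars.affine is not None
                and not np.allclose(scalars.affine, lab_aff, atol=1e-4)
            ):
                raise GridMismatchError(
                    f"scalar maps {paths.get('fa')} are not co-registered "
                    f"with label atlas {cfg.labels_path}"
                )
            subjects.append((paths.get("subject", f"sub-{i:03d}"), labels, scalars))
        regions = cfg.cohort.region_table

    results = analyze_cohort(subjects, regions, cfg.thresholds, cfg.stats)

    artifacts = {}
    for name, frame in results.items():
        if name == "comparisons":
            frame = frame.assign(
                pairwise=frame["pairwise"].map(
                    lambda p: json.dumps(p) if p is not None else ""
                )
            )
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        artifacts[name] = path

    report_path = out_dir / "report.md"
    report_path.write_text(_render_report(results, cfg))
    artifacts["report"] = report_path

    manifest = {
        "mode": cfg.mode,
        "seed": cfg.cohort.seed if cfg.mode == "synthetic" else cfg.stats.seed,
        "config": _config_echo(cfg),
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    results["manifest"] = manifest
    return results


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = asdict(cfg)
    echo["cohort"]["region_table"] = [
        asdict(r) for r in cfg.cohort.region_table
    ]
    return echo


def _render_report(results: dict, cfg: PipelineConfig) -> str:
    thr = cfg.thresholds
    lines = [
        "# Threshold-sensitivity report",
        "",
        f"Conditions: {', '.join(thr.conditions)} "
        f"(trace cutoff {thr.trace_cutoff} mm²/s, min voxels {thr.min_voxels})",
        "",
        "## Cohort means (percent of trace-masked base volume)",
        "",
    ]
    mom = results["moments"]
    pv = mom[mom["measure"] == "percent_volume"]
    for cond in thr.conditions:
        sub = pv[pv["condition"] == cond]
        if len(sub):
            lines.append(
                f"- {cond}: mean {sub['mean'].mean():.1f} %, "
                f"mean CV {sub['cv'].mean():.3f}"
            )
    lines += ["", "## Region-wise comparisons", ""]
    for _, row in results["comparisons"].iterrows():
        if row.get("skipped_reason"):
            lines.append(
                f"- {row['region']} ({row['hemisphere']}, {row['measure']}): "
                f"skipped — {row['skipped_reason']}"
            )
        else:
            star = "significant" if row["significant"] else "n.s."
            lines.append(
                f"- {row['region']} ({row['hemisphere']}, {row['measure']}): "
                f"H = {row['h']:.3f}, df = {row['df']}, "
                f"p = {row['p_chi2']:.3g} ({star})"
            )
    lines.append("")
    return "\n".join(lines)
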