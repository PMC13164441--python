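"""Formats, configuration and the end-to-end pipeline.

The interchange format between all stages is one long-format CSV with a row
per ROI per scan (``METRIC_COLUMNS``); images and masks travel as NIfTI
volumes on congruent grids.  ``run_pipeline`` chains
simulate/extract → metrics → temporal → compare and writes the metrics
table, a baseline comparison table, a temporal report (peak window and
crossovers) and a structured run log.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import stats as _stats
from . import temporal as _temporal
from .histogram import METRIC_COLUMNS, HistogramSpec, MetricSet
from .roi import ImagePlane, ROIMask
from .temporal import Trajectory, TrajectoryPoint

__all__ = [
    "PipelineConfig",
    "RunLog",
    "read_image_and_mask",
    "write_phantom_nifti",
    "frame_to_trajectories",
    "baseline_lesion_frame",
    "compare_groups",
    "comparison_frame",
    "run_pipeline",
]

METRIC_NAMES = ("sd", "skewness", "kurtosis_excess", "entropy_bits")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline in one round-trippable record."""

    seed: int
    # histogram contract
    n_bins: int = 100
    hu_min: float = -40.0
    hu_max: float = 60.0
    range_mode: str = "fixed"
    clip_policy: str = "clip_to_range"
    # statistics
    t_flavor: str = "pooled"
    bonferroni_m: int = 4
    n_boot: int = 2000
    alpha: float = 0.05
    # temporal
    window_width_min: float = 12.0
    window_step_min: float = 1.0
    anchor_tolerance_min: float = 15.0
    # synthetic cohort
    n_cortical: int = 27
    n_bg: int = 18
    scans_per_subject: float = 5.2
    crossover_fraction_cortical: float = 1.0 / 3.0
    pixels_per_roi: int = 100_000
    null_mode: bool = False
    rasterize: bool = False
    out_dir: str = "results"

    def histogram_spec(self) -> HistogramSpec:
        return HistogramSpec(
            n_bins=self.n_bins,
            hu_min=self.hu_min,
            hu_max=self.hu_max,
            range_mode=self.range_mode,
            clip_policy=self.clip_policy,
        )

    def cohort_config(self) -> _cohort.CohortConfig:
        return _cohort.CohortConfig(
            seed=self.seed,
            n_cortical=self.n_cortical,
            n_bg=self.n_bg,
            scans_per_subject=self.scans_per_subject,
            crossover_fraction_cortical=self.crossover_fraction_cortical,
            pixels_per_roi=self.pixels_per_roi,
            null_mode=self.null_mode,
            rasterize=self.rasterize,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunLog:
    """Timestamped structured events; every exclusion or clip is recorded."""

    events: list = field(default_factory=list)

    def add(self, stage: str, event: str, **details) -> None:
        self.events.append(
            {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage,
             "event": event, **details}
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.events, indent=1))


def read_image_and_mask(
    image_path, mask_path, slice_index: int | None = None
) -> tuple[ImagePlane, ROIMask]:
    """Load an HU image and its ROI mask from NIfTI files.

    The image's scale slope/intercept are applied (``get_fdata``), spacing
    comes from the header zooms, and any nonzero mask voxel counts as true.
    3-D volumes require a ``slice_index`` (axial, 0-based).
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise ValueError(
            f"grid mismatch: image shape {img.shape} vs mask shape {msk.shape}"
        )
    hu = np.asarray(img.get_fdata(), dtype=float)
    m = np.asarray(msk.get_fdata()) != 0
    zooms = img.header.get_zooms()
    if len(zooms) < 2 or not all(z > 0 for z in zooms[:2]):
        raise ValueError("missing or invalid pixel spacing in NIfTI header")
    if hu.ndim == 3:
        if slice_index is None:
            raise ValueError("3-D volume: a slice_index is required")
        hu, m = hu[:, :, slice_index], m[:, :, slice_index]
    elif hu.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: {hu.ndim}")
    plane = ImagePlane(hu=hu, spacing_mm=(float(zooms[0]), float(zooms[1])))
    return plane, ROIMask(mask=m, label="lesion")


def write_phantom_nifti(plane: ImagePlane, mask: ROIMask, image_path, mask_path) -> None:
    """Write a plane and mask as 2-D NIfTI files on a shared grid."""
    affine = np.diag([plane.spacing_mm[0], plane.spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(plane.hu.astype(np.float32), affine), str(image_path))
    nib.save(
        nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(mask_path)
    )


# --------------------------------------------------------------------------
# frame <-> trajectory plumbing


def _metric_set_from_row(row) -> MetricSet:
    return MetricSet(
        sd=row["sd"],
        skewness=row["skewness"],
        kurtosis=row["kurtosis_excess"],
        entropy=row["entropy_bits"],
        mean_hu=row["mean_hu"],
        n_pixels=int(row["n_pixels"]),
    )


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Rebuild per-subject trajectories from the long-format metrics table."""
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metrics table is missing columns: {sorted(missing)}")
    trajs = []
    for (case_id, region), g in df.groupby(["case_id", "region"], sort=True):
        pts = []
        for t, gt in g.groupby("time_min"):
            roles = gt.set_index("role")
            if not {"lesion", "control"}.issubset(roles.index):
                raise ValueError(
                    f"{case_id} at t={t}: need one lesion and one control row"
                )
            pts.append(
                TrajectoryPoint(
                    time_min=float(t),
                    lesion=_metric_set_from_row(roles.loc["lesion"]),
                    control=_metric_set_from_row(roles.loc["control"]),
                )
            )
        trajs.append(Trajectory(case_id=str(case_id), region=str(region), points=tuple(pts)))
    return trajs


def baseline_lesion_frame(df: pd.DataFrame) -> pd.DataFrame:
    """First-scan lesion rows, one per subject (the baseline table)."""
    lesions = df[df["role"] == "lesion"]
    idx = lesions.groupby("case_id")["time_min"].idxmin()
    return lesions.loc[idx]


# --------------------------------------------------------------------------
# group comparison (baseline table)


def compare_groups(
    df: pd.DataFrame, config: PipelineConfig, log: RunLog | None = None
) -> list[_stats.ComparisonResult]:
    """Cortical vs basal-ganglia baseline comparison for all four metrics.

    Per metric: one-way ANOVA, pooled (or Welch) t-test with Bonferroni
    adjustment over the metric family, Cohen's d and a seeded percentile
    bootstrap CI of the mean difference.
    """
    base = baseline_lesion_frame(df)
    a = base[base["region"] == "cortical"]
    b = base[base["region"] == "bg"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per region at baseline")
    results = []
    raw_ps = []
    partial = []
    for i, metric in enumerate(METRIC_NAMES):
        x = a[metric].to_numpy()
        y = b[metric].to_numpy()
        sx, sy = _stats.GroupSummary.from_values(x), _stats.GroupSummary.from_values(y)
        F, _, _, p_anova = _stats.oneway_anova([x, y])
        t, dfree, p_raw = _stats.pooled_t(x, y, flavor=config.t_flavor)
        d = _stats.cohens_d(sx, sy)
        lo, hi = _stats.bootstrap_ci(
            x, y, n_boot=config.n_boot, seed=config.seed + 7919 * (i + 1)
        )
        raw_ps.append(p_raw)
        partial.append((metric, sx, sy, F, p_anova, t, dfree, p_raw, d, lo, hi))
    adj = _stats.bonferroni(raw_ps, m=max(config.bonferroni_m, len(raw_ps)))
    for (metric, sx, sy, F, p_anova, t, dfree, p_raw, d, lo, hi), p_adj in zip(
        partial, adj
    ):
        results.append(
            _stats.ComparisonResult(
                metric=metric,
                group_a=sx,
                group_b=sy,
                mean_difference=sx.mean - sy.mean,
                F=F,
                p_anova=p_anova,
                t=t,
                df=dfree,
                p_raw=p_raw,
                p_adjusted=p_adj,
                cohens_d=d,
                ci_low=lo,
                ci_high=hi,
            )
        )
    if log is not None:
        log.add("compare", "baseline_comparison", n_cortical=len(a), n_bg=len(b))
    return results


def comparison_frame(results: list[_stats.ComparisonResult], alpha: float = 0.05) -> pd.DataFrame:
    """Comparison results as a baseline-table-style DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric,
                "cortical_n": r.group_a.n,
                "cortical_mean": r.group_a.mean,
                "cortical_sd": r.group_a.sd,
                "bg_n": r.group_b.n,
                "bg_mean": r.group_b.mean,
                "bg_sd": r.group_b.sd,
                "mean_difference": r.mean_difference,
                "F": r.F,
                "p_anova": r.p_anova,
                "t": r.t,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "cohens_d": r.cohens_d,
                "ci95_low": r.ci_low,
                "ci95_high": r.ci_high,
                "significant": r.p_adjusted < alpha,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    config: PipelineConfig, metrics_csv=None, out_dir=None
) -> dict:
    """Chain the stages end to end and write the report bundle.

    If ``metrics_csv`` is given it is the input cohort table; otherwise a
    synthetic cohort is generated under the config.  Outputs (under
    ``out_dir``): ``metrics.csv``, ``comparison.csv``, ``temporal.json``,
    ``windows.csv``, ``crossovers.csv``, ``run_log.json``.  Returns the
    in-memory bundle with full-precision values.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()

    if metrics_csv is not None:
        df = pd.read_csv(metrics_csv)
        log.add("input", "loaded_metrics_csv", path=str(metrics_csv), rows=len(df))
    else:
        coh = _cohort.make_cohort(config.cohort_config(), config.histogram_spec())
        df = _cohort.cohort_metrics_frame(coh)
        (out / "manifest.json").write_text(coh.manifest_json())
        log.add(
            "simulate",
            "generated_cohort",
            n_cases=len(coh.cases),
            n_crossover_planted=coh.manifest["n_crossover_planted"],
        )
    df.to_csv(out / "metrics.csv", index=False)

    results = compare_groups(df, config, log)
    comp = comparison_frame(results, alpha=config.alpha)
    comp.to_csv(out / "comparison.csv", index=False)

    trajs = frame_to_trajectories(df)
    crossings = []
    for tr in trajs:
        ev = _temporal.detect_crossover(tr)
        crossings.append(
            {"case_id": tr.case_id, "region": tr.region,
             "occurred": ev.occurred, "time_min": ev.time_min}
        )
    cross_df = pd.DataFrame(crossings)
    cross_df.to_csv(out / "crossovers.csv", index=False)
    cross_pct = {
        region: _temporal.crossover_fraction(trajs, region)
        for region in sorted({tr.region for tr in trajs})
    }

    windows = _temporal.window_scan(
        trajs, width_min=config.window_width_min, step_min=config.window_step_min
    )
    win_df = pd.DataFrame(
        [
            {
                "start_min": w.start_min,
                "end_min": w.end_min,
                "score": w.score,
                "n_cortical": w.n_cortical,
                "n_bg": w.n_bg,
                **{f"p_{m}": w.stats[m]["p"] for m in w.stats},
                **{f"t_{m}": w.stats[m]["t"] for m in w.stats},
            }
            for w in windows
        ]
    )
    win_df.to_csv(out / "windows.csv", index=False)
    peak = windows[0]

    temporal_report = {
        "peak_window": {
            "start_min": peak.start_min,
            "end_min": peak.end_min,
            "score": peak.score,
            "stats": peak.stats,
        },
        "crossover_percent": cross_pct,
        "n_windows": len(windows),
    }
    (out / "temporal.json").write_text(json.dumps(temporal_report, indent=1))
    log.add("temporal", "peak_window", start=peak.start_min, end=peak.end_min)
    log.write(out / "run_log.json")

    return {
        "metrics": df,
        "comparison": comp,
        "comparison_results": results,
        "trajectories": trajs,
        "windows": windows,
        "temporal": temporal_report,
        "out_dir": str(out),
    }
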