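"""Synthetic stroke cohort generator with metric-calibrated pixel models.

The study conditions this generator emulates: 45 subjects with acute
MCA-territory infarcts (27 cortical, 18 basal-ganglia), each scanned about
5.2 times between 0 and ~180 minutes post-onset, with lesion ROIs and
contralateral mirrored controls.  Real pixel data are not available, so
each ROI is drawn from a probability mass function over the 1-HU histogram
bins that is *calibrated by construction* to hit the target within-ROI SD
and histogram entropy of its region and scan time:

* region-level targets follow the baseline group table (cortical SD/entropy
  5.16 / 4.34; basal ganglia 3.94 / 3.99) and their temporal anchors up to
  180 min, peaking in the 76–87-min window;
* subject-level targets add between-subject spread (±1.17 / ±0.46 in SD,
  ±0.30 / ±0.15 in entropy), realized by stratified normal scores so the
  group mean ± SD columns are reproduced by construction;
* in one third of cortical subjects the lesion mean-HU trajectory is
  planted to cross its mirrored control near 94 min (penumbral-salvage
  pattern); basal-ganglia lesions never cross.

The pixel family is a symmetric four-component Gaussian mixture
(location pair ±δ × two component widths).  The location split δ lowers
entropy at fixed variance (toward bimodality), the width contrast raises
kurtosis at fixed variance; together they let the calibrator solve SD and
entropy exactly (nested root finds on the *discretized* pmf) while giving
each subject an independently drawn, feasibility-clipped kurtosis target —
kurtosis and skewness remain null dimensions with no group separation.
Since the Gaussian maximizes entropy at fixed variance, a joint
(SD, entropy) target is feasible only below the Gaussian bound
``0.5·log2(2πe·SD²)``; infeasible subject draws are clipped to the bound
and logged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from .histogram import (
    METRIC_COLUMNS,
    HistogramSpec,
    HUSample,
    metric_set,
    pmf_entropy_bits,
)
from .roi import ImagePlane, ROIMask
from .temporal import Trajectory, TrajectoryPoint

__all__ = [
    "RegionTemplate",
    "CohortConfig",
    "CalibratedPMF",
    "ScanRecord",
    "LesionCase",
    "Cohort",
    "CORTICAL_TEMPLATE",
    "BG_TEMPLATE",
    "ANCHOR_TIMES",
    "gaussian_max_entropy",
    "calibrate_entropy_pmf",
    "calibrate_joint_pmf",
    "calibrate_shape_pmf",
    "sample_roi",
    "make_case",
    "make_cohort",
    "cohort_to_trajectories",
    "trajectories_to_frame",
    "cohort_metrics_frame",
    "rasterize_scan",
]

logger = logging.getLogger("nccthist")

#: Scan-schedule anchor times (minutes post-onset): baseline, 60 min, the
#: 76–87-min peak window, the 94-min crossover, 120 and 180 min.
ANCHOR_TIMES = (0.0, 60.0, 81.5, 94.0, 120.0, 180.0)
_CORE_ANCHORS = (0.0, 81.5, 120.0)  # always scanned: baseline, peak, post-crossover
_JITTER = {
    0.0: (0.0, 3.0),
    60.0: (54.0, 66.0),
    81.5: (78.0, 86.0),
    94.0: (90.0, 98.0),
    120.0: (114.0, 126.0),
    180.0: (172.0, 188.0),
}


@dataclass(frozen=True)
class RegionTemplate:
    """Region-level generator targets and temporal anchors."""

    region: str
    lesion_mean_hu: float
    control_mean_hu: float
    target_sd: float
    target_entropy: float
    between_subject_sd_of_sd: float
    between_subject_sd_of_entropy: float
    #: anchors: (time_min, sd, entropy, lesion_mean_hu, control_mean_hu)
    trajectory: tuple[tuple[float, float, float, float, float], ...]
    #: within-ROI SD of the mirrored normal-tissue control (single Gaussian)
    control_texture_sd: float = 4.0

    def __post_init__(self) -> None:
        times = [a[0] for a in self.trajectory]
        if times != sorted(times):
            raise ValueError("trajectory anchors must be time-sorted")

    def _interp(self, t: float, col: int) -> float:
        times = np.array([a[0] for a in self.trajectory])
        vals = np.array([a[col] for a in self.trajectory])
        return float(np.interp(t, times, vals))

    def sd_at(self, t: float) -> float:
        return self._interp(t, 1)

    def entropy_at(self, t: float) -> float:
        return self._interp(t, 2)

    def lesion_hu_at(self, t: float) -> float:
        return self._interp(t, 3)

    def control_hu_at(self, t: float) -> float:
        return self._interp(t, 4)


CORTICAL_TEMPLATE = RegionTemplate(
    region="cortical",
    lesion_mean_hu=26.71,
    control_mean_hu=39.41,
    target_sd=5.16,
    target_entropy=4.34,
    between_subject_sd_of_sd=1.17,
    between_subject_sd_of_entropy=0.30,
    trajectory=(
        (0.0, 5.16, 4.34, 26.71, 39.41),
        (60.0, 5.29, 4.46, 26.71, 39.41),
        (81.5, 5.38, 4.52, 26.71, 39.41),
        (94.0, 5.35, 4.50, 26.71, 39.41),
        (120.0, 5.30, 4.47, 26.71, 39.41),
        (180.0, 5.25, 4.43, 26.71, 39.41),
    ),
    control_texture_sd=4.5,
)

BG_TEMPLATE = RegionTemplate(
    region="bg",
    lesion_mean_hu=25.93,
    control_mean_hu=29.05,
    target_sd=3.94,
    target_entropy=3.99,
    between_subject_sd_of_sd=0.46,
    between_subject_sd_of_entropy=0.15,
    trajectory=(
        (0.0, 3.94, 3.99, 25.93, 29.05),
        (60.0, 3.98, 4.02, 25.93, 29.05),
        (81.5, 4.03, 4.05, 25.93, 29.05),
        (94.0, 4.01, 4.03, 25.93, 29.05),
        (120.0, 3.99, 4.01, 25.93, 29.05),
        (180.0, 3.97, 3.99, 25.93, 29.05),
    ),
    control_texture_sd=3.5,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation settings.  The defaults are the study conditions."""

    seed: int
    n_cortical: int = 27
    n_bg: int = 18
    scans_per_subject: float = 5.2
    crossover_fraction_cortical: float = 1.0 / 3.0
    pixels_per_roi: int = 100_000
    subject_hu_offset_sd: float = 2.0
    kurt_target_mean: float = 0.08
    kurt_target_sd: float = 0.30
    iid_subject_effects: bool = False
    null_mode: bool = False
    baseline_only: bool = False
    rasterize: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cortical < 2 or self.n_bg < 2:
            raise ValueError("need at least 2 subjects per region")
        if not 0 <= self.crossover_fraction_cortical <= 1:
            raise ValueError("crossover fraction must be in [0, 1]")
        if self.pixels_per_roi < 1:
            raise ValueError("pixels_per_roi must be >= 1")
        if self.scans_per_subject < 3:
            raise ValueError("scans_per_subject must be >= 3")


@dataclass(frozen=True)
class CalibratedPMF:
    """A bin-probability vector hitting requested SD/entropy targets."""

    probs: np.ndarray
    spec: HistogramSpec
    mean_hu: float
    achieved_sd: float
    achieved_entropy: float
    achieved_kurtosis: float
    params: dict = field(compare=False)


@dataclass(frozen=True)
class ScanRecord:
    """One synthetic scan: paired lesion/control pixel samples plus truth."""

    time_min: float
    lesion: HUSample
    control: HUSample
    truth: dict
    plane: ImagePlane | None = None
    lesion_mask: ROIMask | None = None
    control_mask: ROIMask | None = None


@dataclass(frozen=True)
class LesionCase:
    case_id: str
    region: str
    crossover_planted: bool
    scans: tuple[ScanRecord, ...]
    truth: dict


@dataclass(frozen=True)
class Cohort:
    cases: tuple[LesionCase, ...]
    config: CohortConfig
    spec: HistogramSpec
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, sort_keys=True, indent=1)


# --------------------------------------------------------------------------
# pmf construction and calibration


def _mixture_pmf(
    mean: float, delta: float, sigmas: Sequence[float], spec: HistogramSpec
) -> np.ndarray:
    """Discretized symmetric mixture: components at mean±δ for each width.

    Tail mass beyond the HU range is folded into the edge bins, matching
    the default clip-to-range binning of real samples.
    """
    edges = spec.edges()
    cdf = np.zeros(edges.size)
    w = 1.0 / (2 * len(sigmas))
    for s in sigmas:
        s = max(s, 1e-9)
        cdf += w * (ndtr((edges - (mean - delta)) / s) + ndtr((edges - (mean + delta)) / s))
    p = np.diff(cdf)
    p[0] += cdf[0]
    p[-1] += 1.0 - cdf[-1]
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _pmf_moments(probs: np.ndarray, spec: HistogramSpec) -> tuple[float, float, float]:
    """(mean, SD, excess kurtosis) of a pmf over the bin centers."""
    c = spec.centers()
    m = float(probs @ c)
    d = c - m
    v = float(probs @ d**2)
    m4 = float(probs @ d**4)
    sd = math.sqrt(max(v, 0.0))
    # guard against underflow for near-degenerate (single-bin) pmfs
    kurt = m4 / v**2 - 3.0 if v > 1e-12 else 0.0
    return m, sd, kurt


def _shape_pmf(
    mean: float, scale: float, u: float, a: float, spec: HistogramSpec
) -> np.ndarray:
    """Four-component family: ±scale·√u location pair × width contrast a."""
    delta = scale * math.sqrt(u)
    s_hi = scale * math.sqrt(max((1 - u) * (1 + a), 0.0))
    s_lo = scale * math.sqrt(max((1 - u) * (1 - a), 0.0))
    return _mixture_pmf(mean, delta, (s_hi, s_lo), spec)


def _solve_scale(
    mean: float, u: float, a: float, target_sd: float, spec: HistogramSpec
) -> float:
    """Overall scale such that the discretized pmf SD equals the target."""

    def f(c: float) -> float:
        return _pmf_moments(_shape_pmf(mean, c, u, a, spec), spec)[1] - target_sd

    lo, hi = 0.05, 3.0 * target_sd + 1.0
    if f(lo) > 0:
        # even near-degenerate components exceed the target (bin-width floor)
        return lo
    return float(brentq(f, lo, hi, xtol=1e-8))


def gaussian_max_entropy(
    target_sd: float, mean_hu: float, spec: HistogramSpec | None = None
) -> float:
    """Entropy (bits) of the discretized Gaussian with the given pmf SD.

    This is the maximum-entropy bound for any pmf of that SD (up to
    discretization); joint (SD, entropy) targets must lie below it.  For
    σ ≫ bin width it approaches ``0.5·log2(2πe·σ²)``.
    """
    spec = spec or HistogramSpec()
    c = _solve_scale(mean_hu, 0.0, 0.0, target_sd, spec)
    return pmf_entropy_bits(_shape_pmf(mean_hu, c, 0.0, 0.0, spec))


def calibrate_entropy_pmf(
    target_entropy: float, mean_hu: float, spec: HistogramSpec | None = None
) -> CalibratedPMF:
    """Discretized Gaussian pmf whose entropy equals the target.

    Solved by a root find on σ (histogram entropy of the discretized
    Gaussian is strictly increasing in σ over the working range); the
    achieved entropy is within 1e-6 bits of the target.
    """
    spec = spec or HistogramSpec()
    h_max = math.log2(spec.n_bins)
    if not 0 < target_entropy < h_max:
        raise ValueError(
            f"entropy target must lie in (0, log2(n_bins)={h_max:.4f}); "
            f"got {target_entropy} (uniform limit unreachable)"
        )

    def f(sigma: float) -> float:
        return pmf_entropy_bits(_mixture_pmf(mean_hu, 0.0, (sigma,), spec)) - target_entropy

    lo, hi = 1e-3 * spec.bin_width, 0.6 * (spec.hu_max - spec.hu_min)
    if f(hi) < 0:
        raise ValueError("entropy target unreachable within the HU range")
    sigma = float(brentq(f, lo, hi, xtol=1e-10))
    probs = _mixture_pmf(mean_hu, 0.0, (sigma,), spec)
    m, sd, kurt = _pmf_moments(probs, spec)
    return CalibratedPMF(
        probs=probs,
        spec=spec,
        mean_hu=mean_hu,
        achieved_sd=sd,
        achieved_entropy=pmf_entropy_bits(probs),
        achieved_kurtosis=kurt,
        params={"sigma": sigma, "delta": 0.0, "width_contrast": 0.0},
    )


def calibrate_shape_pmf(
    target_sd: float,
    target_entropy: float,
    target_kurtosis: float | None,
    mean_hu: float,
    spec: HistogramSpec | None = None,
) -> CalibratedPMF:
    """Joint (SD, entropy[, kurtosis]) calibration of the mixture family.

    SD is solved exactly on the discretized pmf (inner root find on the
    overall scale); entropy exactly via the outer root find on the location
    split ``u = δ²/var`` (and, for positive kurtosis targets at small
    entropy deficit, the width contrast ``a``).  The kurtosis target is
    best-effort: it is honoured when the entropy deficit leaves room and
    clipped to the family's feasible band otherwise (``clipped_kurtosis``
    in the returned params records this).

    With ``target_kurtosis=None`` the family reduces to the pure
    two-component location mixture (kurtosis follows from SD and entropy).
    """
    spec = spec or HistogramSpec()
    h_upper = gaussian_max_entropy(target_sd, mean_hu, spec)
    if target_entropy > h_upper + 1e-9:
        raise ValueError(
            f"infeasible (SD, entropy) pair: entropy {target_entropy:.4f} exceeds "
            f"the Gaussian maximum {h_upper:.4f} bits at SD {target_sd:.3f}"
        )
    deficit_target = h_upper - target_entropy

    def deficit(u: float, a: float) -> float:
        c = _solve_scale(mean_hu, u, a, target_sd, spec)
        return h_upper - pmf_entropy_bits(_shape_pmf(mean_hu, c, u, a, spec))

    kt = target_kurtosis
    clipped = False
    if deficit_target < 1e-7:
        u_sol, a_sol = 0.0, 0.0
        clipped = kt is not None and abs(kt) > 1e-3
    elif kt is None:
        g = lambda u: deficit(u, 0.0) - deficit_target
        if g(0.97) < 0:
            raise ValueError("entropy target too low for the location-mixture family")
        u_sol, a_sol = float(brentq(g, 0.0, 0.97, xtol=1e-8)), 0.0
    else:
        # width contrast needed (continuous-moment approximation) to reach
        # the kurtosis target at a given location split u
        def a_for(u: float) -> float:
            need = kt + 2.0 * u**2
            if need <= 0:
                return 0.0
            return min(math.sqrt(need / 3.0) / (1.0 - u), 0.995)

        u_lo = 0.0 if kt >= 0 else min(math.sqrt(-kt / 2.0), 0.95)
        if deficit(u_lo, a_for(u_lo)) >= deficit_target:
            # entropy constraint binds before the kurtosis target is reached
            clipped = True
            if kt >= 0:
                a0 = a_for(0.0)
                g = lambda a: deficit(0.0, a) - deficit_target
                u_sol, a_sol = 0.0, float(brentq(g, 0.0, a0, xtol=1e-8))
            else:
                g = lambda u: deficit(u, 0.0) - deficit_target
                u_sol, a_sol = float(brentq(g, 0.0, u_lo, xtol=1e-8)), 0.0
        else:
            g = lambda u: deficit(u, a_for(u)) - deficit_target
            if g(0.97) < 0:
                raise ValueError("entropy target too low for the mixture family")
            u_sol = float(brentq(g, u_lo, 0.97, xtol=1e-8))
            a_sol = a_for(u_sol)

    c_sol = _solve_scale(mean_hu, u_sol, a_sol, target_sd, spec)
    probs = _shape_pmf(mean_hu, c_sol, u_sol, a_sol, spec)
    m, sd, kurt = _pmf_moments(probs, spec)
    h = pmf_entropy_bits(probs)
    if abs(sd - target_sd) > 1e-4 or abs(h - target_entropy) > 1e-4:
        raise RuntimeError(
            f"calibration failed to converge: achieved SD {sd:.6f} / entropy "
            f"{h:.6f} vs targets {target_sd:.6f} / {target_entropy:.6f}"
        )
    return CalibratedPMF(
        probs=probs,
        spec=spec,
        mean_hu=mean_hu,
        achieved_sd=sd,
        achieved_entropy=h,
        achieved_kurtosis=kurt,
        params={
            "scale": c_sol,
            "u": u_sol,
            "width_contrast": a_sol,
            "target_kurtosis": kt,
            "clipped_kurtosis": clipped,
        },
    )


def calibrate_joint_pmf(
    target_sd: float,
    target_entropy: float,
    mean_hu: float,
    spec: HistogramSpec | None = None,
) -> CalibratedPMF:
    """Joint (SD, entropy) calibration with the two-component mixture.

    The inner root find pins the discretized pmf SD exactly; the outer root
    find on the location split drives the entropy to the target (entropy
    decreases as the split grows at fixed SD).
    """
    return calibrate_shape_pmf(target_sd, target_entropy, None, mean_hu, spec)


def sample_roi(
    pmf: CalibratedPMF,
    n_px: int,
    seed: int | np.random.Generator,
    label: str = "lesion",
    pixel_spacing: tuple[float, float] | None = None,
) -> HUSample:
    """Draw an ROI pixel sample from a calibrated pmf.

    Bin indices are drawn i.i.d. from the pmf and mapped to a uniform
    jitter within each bin, so re-binning the sample under the same spec
    reproduces the pmf draws exactly.
    """
    if n_px < 1:
        raise ValueError("n_px must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = pmf.spec.centers()
    idx = rng.choice(centers.size, size=n_px, p=pmf.probs)
    w = pmf.spec.bin_width
    values = centers[idx] + rng.uniform(-0.5 * w, 0.5 * w, size=n_px)
    return HUSample(values=values, pixel_spacing=pixel_spacing, source_label=label)


# --------------------------------------------------------------------------
# case and cohort generation


def _crossover_hu_paths(t_c: float, template: RegionTemplate):
    """Lesion/control mean-HU paths for a planted crossover at time t_c.

    The control declines linearly to the 94-min crossover level (27.89 HU
    for the cortical template) and stays there; the lesion rises from its
    baseline to meet the control at ``t_c`` and overtakes it by 1 HU over
    the following 30 minutes, keeping the post-crossing margin.
    """
    ctrl_t = np.array([0.0, 94.0, 1e4])
    ctrl_v = np.array([template.control_mean_hu, 27.89, 27.89])

    def control(t: float) -> float:
        return float(np.interp(t, ctrl_t, ctrl_v))

    les_t = np.array([0.0, t_c, t_c + 30.0, 1e4])
    les_v = np.array(
        [
            template.lesion_mean_hu,
            control(t_c),
            control(t_c + 30.0) + 1.0,
            control(t_c + 30.0) + 1.0,
        ]
    )

    def lesion(t: float) -> float:
        return float(np.interp(t, les_t, les_v))

    return lesion, control


def _scan_times(rng: np.random.Generator, config: CohortConfig) -> list[float]:
    if config.baseline_only:
        return [float(rng.uniform(*_JITTER[0.0]))]
    p_keep = float(np.clip((config.scans_per_subject - len(_CORE_ANCHORS)) /
                           (len(ANCHOR_TIMES) - len(_CORE_ANCHORS)), 0.0, 1.0))
    times = []
    for anchor in ANCHOR_TIMES:
        t = float(rng.uniform(*_JITTER[anchor]))
        keep = anchor in _CORE_ANCHORS or rng.random() < p_keep
        if keep:
            times.append(t)
    return times


def make_case(
    template: RegionTemplate,
    config: CohortConfig,
    subject_seed,
    case_id: str = "case",
    sd_target: float | None = None,
    entropy_target: float | None = None,
    crossover: bool = False,
    spec: HistogramSpec | None = None,
    region_label: str | None = None,
) -> LesionCase:
    """Generate one subject: scan schedule plus lesion/control ROI samples.

    Subject-level SD/entropy targets default to normal draws around the
    template targets; explicit targets (as produced by ``make_cohort``'s
    stratified assignment) override the draws.  Per scan, the template's
    temporal anchors are rescaled to the subject's baseline targets
    (multiplicatively for SD, additively for entropy), clipped to the
    Gaussian feasibility bound, and a pmf is calibrated and sampled.
    """
    spec = spec or HistogramSpec()
    rng = (
        subject_seed
        if isinstance(subject_seed, np.random.Generator)
        else np.random.default_rng(subject_seed)
    )
    if sd_target is None:
        sd_target = float(
            rng.normal(template.target_sd, template.between_subject_sd_of_sd)
        )
    if entropy_target is None:
        entropy_target = float(
            rng.normal(template.target_entropy, template.between_subject_sd_of_entropy)
        )
    sd_target = max(sd_target, 1.2)
    entropy_target = max(entropy_target, 1.5)
    kurt_target = float(
        np.clip(rng.normal(config.kurt_target_mean, config.kurt_target_sd), -1.5, 2.0)
    )
    hu_offset = float(rng.normal(0.0, config.subject_hu_offset_sd))
    times = _scan_times(rng, config)
    t_c = float(rng.uniform(90.0, 98.0)) if crossover else None

    if crossover:
        lesion_hu_at, control_hu_at = _crossover_hu_paths(t_c, template)
    else:
        lesion_hu_at, control_hu_at = template.lesion_hu_at, template.control_hu_at

    sd0, ent0 = template.sd_at(0.0), template.entropy_at(0.0)
    scans = []
    clip_events = 0
    for t in times:
        sd_t = sd_target * template.sd_at(t) / sd0
        ent_t = entropy_target + (template.entropy_at(t) - ent0)
        lesion_mu = lesion_hu_at(t) + hu_offset
        h_upper = gaussian_max_entropy(sd_t, lesion_mu, spec)
        if ent_t > h_upper - 1e-3:
            ent_t = h_upper - 1e-3
            clip_events += 1
        ent_t = max(ent_t, 1.5)
        pmf = calibrate_shape_pmf(sd_t, ent_t, kurt_target, lesion_mu, spec)
        lesion = sample_roi(pmf, config.pixels_per_roi, rng, "lesion")

        ctrl_mu = control_hu_at(t) + hu_offset
        c = _solve_scale(ctrl_mu, 0.0, 0.0, template.control_texture_sd, spec)
        ctrl_probs = _shape_pmf(ctrl_mu, c, 0.0, 0.0, spec)
        _, ctrl_sd, ctrl_kurt = _pmf_moments(ctrl_probs, spec)
        ctrl_pmf = CalibratedPMF(
            probs=ctrl_probs,
            spec=spec,
            mean_hu=ctrl_mu,
            achieved_sd=ctrl_sd,
            achieved_entropy=pmf_entropy_bits(ctrl_probs),
            achieved_kurtosis=ctrl_kurt,
            params={"sigma": c},
        )
        control = sample_roi(ctrl_pmf, config.pixels_per_roi, rng, "control")

        plane = l_mask = c_mask = None
        if config.rasterize:
            plane, l_mask, c_mask = rasterize_scan(lesion, control, rng=rng)
        scans.append(
            ScanRecord(
                time_min=t,
                lesion=lesion,
                control=control,
                truth={
                    "sd_target": sd_t,
                    "entropy_target": ent_t,
                    "lesion_mean_hu": lesion_mu,
                    "control_mean_hu": ctrl_mu,
                },
                plane=plane,
                lesion_mask=l_mask,
                control_mask=c_mask,
            )
        )
    if clip_events:
        logger.info(
            "%s: entropy target clipped to the Gaussian feasibility bound at "
            "%d scan(s)",
            case_id,
            clip_events,
        )
    return LesionCase(
        case_id=case_id,
        region=region_label or template.region,
        crossover_planted=bool(crossover),
        scans=tuple(scans),
        truth={
            "sd_target": sd_target,
            "entropy_target": entropy_target,
            "kurtosis_target": kurt_target,
            "hu_offset": hu_offset,
            "crossover_time": t_c,
            "scan_times": [s.time_min for s in scans],
            "entropy_clip_events": clip_events,
        },
    )


def _stratified_effects(n: int, rng: np.random.Generator) -> np.ndarray:
    """Normal scores with exact sample mean 0 and sample SD 1, shuffled.

    Used so that group mean ± SD of the subject-level targets equal the
    template values by construction at any n.
    """
    z = np.array([float(_ppf((i + 0.5) / n)) for i in range(n)])
    z = (z - z.mean()) / z.std(ddof=1)
    return z[rng.permutation(n)]


def _ppf(q: float) -> float:
    from scipy.stats import norm

    return norm.ppf(q)


def make_cohort(config: CohortConfig, spec: HistogramSpec | None = None) -> Cohort:
    """Generate the full two-region cohort with a ground-truth manifest.

    Exactly ``round(crossover_fraction × n_cortical)`` cortical cases carry a
    planted crossover.  In ``null_mode`` both region labels are generated
    from the basal-ganglia template with no crossovers, giving a null cohort
    for type-I-error checks.  Generation is a pure function of the config
    (all randomness flows from ``config.seed`` through spawned per-subject
    streams).
    """
    spec = spec or HistogramSpec()
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_cortical + config.n_bg
    children = root.spawn(n_total + 1)
    assign_rng = np.random.default_rng(children[0])

    cases: list[LesionCase] = []
    child_idx = 1
    n_cross = (
        0 if config.null_mode else round(config.crossover_fraction_cortical * config.n_cortical)
    )
    cross_idx = set(
        assign_rng.choice(config.n_cortical, size=n_cross, replace=False).tolist()
    )
    for region, template, n in (
        ("cortical", CORTICAL_TEMPLATE, config.n_cortical),
        ("bg", BG_TEMPLATE, config.n_bg),
    ):
        gen_template = BG_TEMPLATE if config.null_mode else template
        if config.iid_subject_effects:
            sd_targets = ent_targets = [None] * n
        else:
            z = _stratified_effects(n, assign_rng)
            sd_targets = gen_template.target_sd + z * gen_template.between_subject_sd_of_sd
            ent_targets = (
                gen_template.target_entropy
                + z * gen_template.between_subject_sd_of_entropy
            )
        for i in range(n):
            cases.append(
                make_case(
                    gen_template,
                    config,
                    children[child_idx],
                    case_id=f"{region}{i + 1:02d}",
                    sd_target=None if sd_targets[i] is None else float(sd_targets[i]),
                    entropy_target=None if ent_targets[i] is None else float(ent_targets[i]),
                    crossover=(region == "cortical" and i in cross_idx),
                    spec=spec,
                    region_label=region,
                )
            )
            child_idx += 1

    manifest = {
        "config": asdict(config),
        "histogram_spec": asdict(spec),
        "n_crossover_planted": n_cross,
        "cases": {
            c.case_id: {"region": c.region, "crossover": c.crossover_planted, **c.truth}
            for c in cases
        },
    }
    return Cohort(cases=tuple(cases), config=config, spec=spec, manifest=manifest)


# --------------------------------------------------------------------------
# metric extraction


def cohort_to_trajectories(
    cohort: Cohort, bias_corrected: bool = True
) -> list[Trajectory]:
    """Run the metric pipeline on every ROI and bundle per-subject series."""
    trajs = []
    for case in cohort.cases:
        pts = tuple(
            TrajectoryPoint(
                time_min=s.time_min,
                lesion=metric_set(s.lesion, cohort.spec, bias_corrected=bias_corrected),
                control=metric_set(s.control, cohort.spec, bias_corrected=bias_corrected),
            )
            for s in case.scans
        )
        trajs.append(Trajectory(case_id=case.case_id, region=case.region, points=pts))
    return trajs


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format metrics table (one row per ROI per scan)."""
    rows = []
    for tr in trajectories:
        for p in tr.points:
            rows.append(p.lesion.to_row(tr.case_id, tr.region, "lesion", p.time_min))
            rows.append(p.control.to_row(tr.case_id, tr.region, "control", p.time_min))
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS))


def cohort_metrics_frame(cohort: Cohort) -> pd.DataFrame:
    return trajectories_to_frame(cohort_to_trajectories(cohort))


# --------------------------------------------------------------------------
# optional phantom rasterization


def rasterize_scan(
    lesion: HUSample,
    control: HUSample,
    shape: tuple[int, int] = (128, 128),
    spacing: tuple[float, float] = (0.45, 0.45),
    lesion_center: tuple[int, int] = (52, 92),
    rng: np.random.Generator | None = None,
):
    """Paint a symmetric head phantom carrying the two ROI pixel sets.

    The phantom is a bright skull annulus around homogeneous brain; the
    lesion ROI is the blob of ``len(lesion)`` pixels nearest to
    ``lesion_center`` and the control ROI is its exact mirror about the
    vertical midline ``(n_cols − 1) / 2``.  Geometry is the simplest shape
    satisfying the mirroring and minimum-area contracts, not an anatomical
    simulation.
    """
    n_rows, n_cols = shape
    if len(lesion) != len(control):
        raise ValueError("lesion and control samples must have equal pixel counts")
    n_px = len(lesion)
    mid = (n_cols - 1) / 2.0

    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    r_head = 0.44 * min(shape)
    dist_center = np.hypot(rr - (n_rows - 1) / 2.0, cc - mid)
    hu = np.full(shape, -1000.0)
    hu[dist_center <= r_head + 4] = 700.0  # skull annulus
    brain = dist_center <= r_head
    hu[brain] = 34.0
    if rng is not None:
        hu[brain] += rng.normal(0.0, 1.5, size=int(brain.sum()))

    d_lesion = np.hypot(rr - lesion_center[0], cc - lesion_center[1])
    order = np.argsort(d_lesion, axis=None, kind="stable")[:n_px]
    l_mask = np.zeros(shape, dtype=bool)
    l_mask.flat[order] = True
    if not l_mask[brain].sum() == n_px:
        raise ValueError("lesion blob does not fit inside the brain disc")
    c_mask = l_mask[:, ::-1].copy()  # exact mirror about (n_cols-1)/2
    if (l_mask & c_mask).any():
        raise ValueError("lesion and mirrored control overlap; move the blob laterally")

    hu[l_mask] = lesion.values  # boolean assignment is row-major
    hu[c_mask] = control.values
    plane = ImagePlane(hu=hu, spacing_mm=spacing, midline_col=mid)
    return (
        plane,
        ROIMask(mask=l_mask, label="lesion"),
        ROIMask(mask=c_mask, label="control"),
    )
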