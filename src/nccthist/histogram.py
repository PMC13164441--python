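"""First-order Hounsfield-unit histogram metrics for CT regions of interest.

On non-contrast CT, early ischemic edema lowers brain attenuation only
subtly, but it changes the *shape* of the HU distribution inside a lesion
well before the mean drop becomes obvious.  This module computes the four
first-order descriptors of that distribution used throughout the package:

* **SD** — within-ROI dispersion of HU values (tissue heterogeneity),
* **skewness** — asymmetry of the HU distribution,
* **excess kurtosis** — tailedness relative to a Gaussian,
* **entropy** — Shannon entropy (base 2) of the binned HU histogram,
  a measure of structural disorganization.

The binning contract is fixed by :class:`HistogramSpec`: by default 100 bins
of exactly 1 HU over the brain window −40..60 HU, with out-of-range pixels
(streak or bone contamination at the ROI edge) clipped into the edge bins.
Moment metrics (SD, skewness, kurtosis) are computed on the raw pixel
values; entropy is computed on the histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "HistogramSpec",
    "HUSample",
    "HistogramCounts",
    "MetricSet",
    "build_histogram",
    "entropy_bits",
    "pmf_entropy_bits",
    "sample_sd",
    "sample_skewness",
    "sample_kurtosis",
    "metric_set",
    "METRIC_COLUMNS",
]

#: Column order of the long-format per-ROI metrics table used across the
#: package (one row per ROI per scan).
METRIC_COLUMNS = (
    "case_id",
    "region",
    "role",
    "time_min",
    "n_pixels",
    "mean_hu",
    "sd",
    "skewness",
    "kurtosis_excess",
    "entropy_bits",
)

_RANGE_MODES = ("fixed", "dynamic")
_CLIP_POLICIES = ("clip_to_range", "drop_out_of_range")


@dataclass(frozen=True)
class HistogramSpec:
    """Binning contract for HU histograms.

    Parameters
    ----------
    n_bins:
        Number of histogram bins (default 100).
    hu_min, hu_max:
        HU range of the histogram (default −40..60, the brain window used
        for standardized analysis; the default bin width is exactly 1 HU).
    range_mode:
        ``"fixed"`` uses ``[hu_min, hu_max]`` for every sample;
        ``"dynamic"`` re-derives the range per sample from its min/max,
        padded outward to integer HU.  Dynamic mode changes the bin width
        and is off by default.
    clip_policy:
        ``"clip_to_range"`` maps out-of-range values into the edge bins;
        ``"drop_out_of_range"`` discards them.
    """

    n_bins: int = 100
    hu_min: float = -40.0
    hu_max: float = 60.0
    range_mode: str = "fixed"
    clip_policy: str = "clip_to_range"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not self.hu_max > self.hu_min:
            raise ValueError(
                f"hu_max ({self.hu_max}) must exceed hu_min ({self.hu_min})"
            )
        if self.range_mode not in _RANGE_MODES:
            raise ValueError(f"range_mode must be one of {_RANGE_MODES}")
        if self.clip_policy not in _CLIP_POLICIES:
            raise ValueError(f"clip_policy must be one of {_CLIP_POLICIES}")

    @property
    def bin_width(self) -> float:
        return (self.hu_max - self.hu_min) / self.n_bins

    def edges(self, values: np.ndarray | None = None) -> np.ndarray:
        """Bin edges (length ``n_bins + 1``) for a sample.

        In fixed mode the edges are independent of the sample.  In dynamic
        mode they span ``[floor(min), ceil(max)]`` of the sample, widened to
        at least 1 HU so the width never degenerates.
        """
        if self.range_mode == "fixed":
            lo, hi = float(self.hu_min), float(self.hu_max)
        else:
            if values is None or len(values) == 0:
                raise ValueError("dynamic range_mode needs a non-empty sample")
            lo = math.floor(float(np.min(values)))
            hi = math.ceil(float(np.max(values)))
            if hi <= lo:
                hi = lo + 1.0
        return np.linspace(lo, hi, self.n_bins + 1)

    def centers(self, values: np.ndarray | None = None) -> np.ndarray:
        e = self.edges(values)
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class HUSample:
    """A vector of HU pixel values extracted from one ROI at one scan time."""

    values: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    source_label: str = "lesion"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ValueError("empty ROI")
        if np.isnan(v).any():
            raise ValueError("HU sample contains NaN")
        object.__setattr__(self, "values", v)
        if self.pixel_spacing is not None:
            sr, sc = self.pixel_spacing
            if not (sr > 0 and sc > 0 and np.isfinite(sr) and np.isfinite(sc)):
                raise ValueError("pixel spacing must be finite and positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def area_mm2(self) -> float | None:
        """ROI area implied by the pixel count, if spacing is known."""
        if self.pixel_spacing is None:
            return None
        sr, sc = self.pixel_spacing
        return float(self.values.size * sr * sc)


@dataclass(frozen=True)
class HistogramCounts:
    """Binned histogram of one HU sample under a resolved edge vector."""

    counts: np.ndarray
    spec: HistogramSpec
    n_total: int
    edges: np.ndarray

    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_total


@dataclass(frozen=True)
class MetricSet:
    """The per-ROI metric bundle: four shape metrics plus mean HU and size.

    ``kurtosis`` is *excess* kurtosis (Gaussian → 0); ``entropy`` is in bits
    under the histogram spec the set was computed with.
    """

    sd: float
    skewness: float
    kurtosis: float
    entropy: float
    mean_hu: float
    n_pixels: int
    metadata: dict = field(default_factory=dict, compare=False)

    def value(self, name: str) -> float:
        """Look up a metric by its table-column alias or attribute name."""
        aliases = {"kurtosis_excess": "kurtosis", "entropy_bits": "entropy"}
        return float(getattr(self, aliases.get(name, name)))

    def to_row(self, case_id: str, region: str, role: str, time_min: float) -> dict:
        """One row of the long-format metrics table (``METRIC_COLUMNS``)."""
        return {
            "case_id": case_id,
            "region": region,
            "role": role,
            "time_min": float(time_min),
            "n_pixels": int(self.n_pixels),
            "mean_hu": float(self.mean_hu),
            "sd": float(self.sd),
            "skewness": float(self.skewness),
            "kurtosis_excess": float(self.kurtosis),
            "entropy_bits": float(self.entropy),
        }


def _as_values(sample: "HUSample | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(sample, HUSample):
        return sample.values
    v = np.asarray(sample, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("empty ROI")
    if np.isnan(v).any():
        raise ValueError("HU sample contains NaN")
    return v


def build_histogram(
    sample: "HUSample | Sequence[float] | np.ndarray", spec: HistogramSpec
) -> HistogramCounts:
    """Bin an HU sample into ``spec.n_bins`` half-open bins.

    Bins are ``[edge_i, edge_{i+1})`` with the final bin closed (numpy's
    convention), so integer HU values are never double counted.  Values
    outside the range are clipped into the edge bins or dropped according
    to ``spec.clip_policy``.
    """
    values = _as_values(sample)
    edges = spec.edges(values)
    if spec.clip_policy == "clip_to_range":
        values = np.clip(values, edges[0], edges[-1])
    else:
        values = values[(values >= edges[0]) & (values <= edges[-1])]
        if values.size == 0:
            raise ValueError("no pixels remain inside the HU range after drop")
    counts, _ = np.histogram(values, bins=edges)
    return HistogramCounts(
        counts=counts.astype(np.int64),
        spec=spec,
        n_total=int(counts.sum()),
        edges=edges,
    )


def entropy_bits(
    hist: "HistogramCounts | np.ndarray", miller_madow: bool = False
) -> float:
    """Plug-in Shannon entropy of a histogram, in bits.

    ``H = −Σ pᵢ log2 pᵢ`` with ``pᵢ = countsᵢ / n`` and ``0·log 0 := 0``.
    ``miller_madow=True`` adds the Miller–Madow small-sample bias correction
    ``(k_occupied − 1) / (2 n ln 2)``; the uncorrected plug-in estimator is
    the default.
    """
    counts = hist.counts if isinstance(hist, HistogramCounts) else np.asarray(hist)
    n = int(np.sum(counts))
    if n < 1:
        raise ValueError("histogram has zero total count")
    h = float(_sps.entropy(counts / n, base=2))
    if miller_madow:
        k = int(np.count_nonzero(counts))
        h += (k - 1) / (2.0 * n * math.log(2.0))
    return h


def pmf_entropy_bits(probs: np.ndarray) -> float:
    """Shannon entropy (bits) of a probability vector."""
    p = np.asarray(probs, dtype=float)
    if p.size < 1 or np.any(p < 0):
        raise ValueError("invalid probability vector")
    s = p.sum()
    if not s > 0:
        raise ValueError("probability vector sums to zero")
    return float(_sps.entropy(p / s, base=2))


def sample_sd(
    sample: "HUSample | Sequence[float] | np.ndarray", ddof: int = 1
) -> float:
    """Sample standard deviation (n−1 denominator by default)."""
    v = _as_values(sample)
    if v.size < 2:
        raise ValueError("sample SD needs at least 2 pixels")
    return float(np.std(v, ddof=ddof))


def sample_skewness(
    sample: "HUSample | Sequence[float] | np.ndarray", bias_corrected: bool = True
) -> float:
    """Adjusted Fisher–Pearson skewness G1 (bias-corrected by default)."""
    v = _as_values(sample)
    if v.size < 3:
        raise ValueError("skewness needs at least 3 pixels")
    if np.std(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    return float(_sps.skew(v, bias=not bias_corrected))


def sample_kurtosis(
    sample: "HUSample | Sequence[float] | np.ndarray", bias_corrected: bool = True
) -> float:
    """Excess kurtosis G2 (Gaussian → 0; bias-corrected by default)."""
    v = _as_values(sample)
    if v.size < 4:
        raise ValueError("kurtosis needs at least 4 pixels")
    if np.std(v) == 0:
        raise ValueError("degenerate sample: zero variance")
    return float(_sps.kurtosis(v, fisher=True, bias=not bias_corrected))


def metric_set(
    sample: "HUSample | Sequence[float] | np.ndarray",
    spec: HistogramSpec | None = None,
    bias_corrected: bool = True,
    miller_madow: bool = False,
    enforce_area: bool = False,
    min_area_mm2: float = 100.0,
) -> MetricSet:
    """Compute the full metric bundle for one ROI sample.

    Moment metrics are computed on the raw HU values; entropy on the binned
    histogram under ``spec``.  With ``enforce_area=True`` and a sample that
    carries pixel spacing, samples below ``min_area_mm2`` (the 1 cm² rule)
    are rejected.  Errors from the component estimators (too few pixels,
    zero variance) propagate.
    """
    spec = spec or HistogramSpec()
    if enforce_area and isinstance(sample, HUSample):
        area = sample.area_mm2
        if area is not None and area < min_area_mm2:
            raise ValueError(
                f"ROI area {area:.1f} mm² is below the {min_area_mm2:.0f} mm² minimum"
            )
    v = _as_values(sample)
    hist = build_histogram(v, spec)
    return MetricSet(
        sd=sample_sd(v),
        skewness=sample_skewness(v, bias_corrected=bias_corrected),
        kurtosis=sample_kurtosis(v, bias_corrected=bias_corrected),
        entropy=entropy_bits(hist, miller_madow=miller_madow),
        mean_hu=float(np.mean(v)),
        n_pixels=int(v.size),
        metadata={
            "entropy_base": 2,
            "entropy_estimator": "miller_madow" if miller_madow else "plugin",
            "moments": "bias_corrected" if bias_corrected else "population",
            "range_mode": spec.range_mode,
            "clip_policy": spec.clip_policy,
            "bin_width_hu": spec.bin_width,
        },
    )
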