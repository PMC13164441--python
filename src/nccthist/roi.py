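"""ROI mask handling on HU image planes.

Lesion ROIs are planar boolean masks drawn on axial CT slices; the
within-subject control is the same mask reflected across the sagittal
midline (contralateral mirroring).  Masks must cover at least 1 cm² so the
histogram metrics are estimated from enough pixels.  The pipeline assumes
masks are already in CT pixel space on axial-aligned arrays; registration
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import HUSample

__all__ = [
    "ImagePlane",
    "ROIMask",
    "roi_area_mm2",
    "area_ok",
    "mirror_mask",
    "estimate_midline",
    "extract_sample",
    "MIN_ROI_AREA_MM2",
]

#: Minimum ROI area (the 1 cm² rule), in mm².
MIN_ROI_AREA_MM2 = 100.0


@dataclass(frozen=True)
class ImagePlane:
    """A single axial HU slice with pixel spacing and (optional) midline."""

    hu: np.ndarray
    spacing_mm: tuple[float, float]
    midline_col: float | None = None

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 2:
            raise ValueError(f"image plane must be 2-D, got shape {hu.shape}")
        object.__setattr__(self, "hu", hu)
        sr, sc = self.spacing_mm
        if not (np.isfinite(sr) and np.isfinite(sc) and sr > 0 and sc > 0):
            raise ValueError("pixel spacing must be finite and positive")
        if self.midline_col is not None and not (
            0 <= self.midline_col <= hu.shape[1] - 1
        ):
            raise ValueError("midline_col outside image bounds")


@dataclass(frozen=True)
class ROIMask:
    """Boolean ROI mask congruent with its image plane."""

    mask: np.ndarray
    label: str = "lesion"
    region: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        if not m.any():
            raise ValueError("empty mask")
        if self.label not in ("lesion", "control"):
            raise ValueError("label must be 'lesion' or 'control'")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _check_congruent(plane_or_shape, mask: ROIMask) -> None:
    shape = (
        plane_or_shape.hu.shape
        if isinstance(plane_or_shape, ImagePlane)
        else tuple(plane_or_shape)
    )
    if mask.mask.shape != shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image shape {shape}"
        )


def roi_area_mm2(mask: ROIMask, spacing_mm: tuple[float, float]) -> float:
    """Physical ROI area: true-pixel count × pixel-edge spacing product."""
    sr, sc = spacing_mm
    if not (sr > 0 and sc > 0):
        raise ValueError("pixel spacing must be positive")
    return float(mask.n_pixels * sr * sc)


def area_ok(
    mask: ROIMask,
    spacing_mm: tuple[float, float],
    min_area_mm2: float = MIN_ROI_AREA_MM2,
) -> bool:
    """True iff the ROI meets the minimum-area rule (boundary inclusive)."""
    return roi_area_mm2(mask, spacing_mm) >= min_area_mm2


def mirror_mask(mask: ROIMask, midline_col: float, image_shape=None) -> ROIMask:
    """Reflect a mask across a vertical midline to build the control ROI.

    Each true pixel's column is mapped to ``round(2·midline_col − col)``;
    rows are unchanged.  The label flips lesion ↔ control and the pixel
    count is preserved.  Reflections landing outside the image raise.
    """
    shape = image_shape if image_shape is not None else mask.mask.shape
    rows, cols = np.nonzero(mask.mask)
    new_cols = np.rint(2.0 * midline_col - cols).astype(int)
    if new_cols.min() < 0 or new_cols.max() >= shape[1]:
        raise ValueError("mirror exceeds image")
    out = np.zeros(shape, dtype=bool)
    out[rows, new_cols] = True
    if out.sum() != mask.n_pixels:
        # Can only happen for a fractional midline collapsing two columns.
        raise ValueError("mirroring collapsed pixels; midline is inconsistent")
    flipped = "control" if mask.label == "lesion" else "lesion"
    return ROIMask(mask=out, label=flipped, region=mask.region)


def estimate_midline(plane: ImagePlane, search_fraction: float = 1 / 3) -> int:
    """Estimate the sagittal midline column by reflection symmetry.

    Scans candidate columns in the central ``search_fraction`` of the image
    and returns the one minimizing the mean squared HU difference between
    the left half and the mirrored right half.  Intended for head-like
    images with a bright (bone) outline, or synthetic phantoms.
    """
    hu = plane.hu
    if np.ptp(hu) == 0:
        raise ValueError("no symmetry axis: image is flat")
    n_cols = hu.shape[1]
    half_excluded = int(round(n_cols * (1 - search_fraction) / 2))
    candidates = range(half_excluded, n_cols - half_excluded)
    best_col, best_score = None, np.inf
    for c in candidates:
        span = min(c, n_cols - 1 - c)
        if span < 1:
            continue
        left = hu[:, c - span : c][:, ::-1]
        right = hu[:, c + 1 : c + span + 1]
        score = float(np.mean((left - right) ** 2))
        if score < best_score:
            best_col, best_score = c, score
    if best_col is None:
        raise ValueError("no symmetry axis: image too narrow")
    return int(best_col)


def extract_sample(plane: ImagePlane, mask: ROIMask) -> HUSample:
    """HU values at the mask's true pixels, in row-major order."""
    _check_congruent(plane, mask)
    return HUSample(
        values=plane.hu[mask.mask],
        pixel_spacing=plane.spacing_mm,
        source_label=mask.label,
    )
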