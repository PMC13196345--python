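"""Confirmatory-imaging quantification.

Two readouts mirror the plate screen's follow-up microscopy:

* per-cell ratiometry — cells are segmented by thresholding the summed
  red+green channels, and each cell's F590/F520 is the ratio of its mean
  red to mean green intensity (ratio of means, robust to near-zero green
  pixels); the per-image statistic is the unweighted mean over cells;
* mitochondrial shape — 8-connected objects in a binary mask are measured
  for aspect ratio AR = major/minor axis of the moment-matched ellipse
  (elongation) and form factor FF = perimeter^2 / (4*pi*area) (1 for a
  circle, larger for elongated or complex outlines, so fragmentation into
  rounder organelles lowers both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "RatioImage",
    "CellSegmentation",
    "MitoObject",
    "segment_cells",
    "per_cell_ratio",
    "label_mitochondria",
    "morphology_summary",
    "read_ratio_tiff",
    "read_mask_tiff",
]

DEFAULT_MIN_CELL_AREA = 50  # px
DEFAULT_MIN_MITO_AREA = 4  # px


@dataclass
class RatioImage:
    """Registered two-channel field: red = F590, green = F520."""

    red: np.ndarray
    green: np.ndarray
    pixel_size: float = 1.0  # um / pixel

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape or self.red.ndim != 2:
            raise ValueError(
                f"channels must be equal-shape 2-D arrays, got "
                f"{self.red.shape} vs {self.green.shape}"
            )
        if (self.red < 0).any() or (self.green < 0).any():
            raise ValueError("intensities must be >= 0")


@dataclass
class CellSegmentation:
    labels: np.ndarray
    n_cells: int
    per_cell_ratio: dict[int, float]
    image_mean: float | None


def segment_cells(
    image: RatioImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: int = DEFAULT_MIN_CELL_AREA,
) -> np.ndarray:
    """Label cell bodies by thresholding the summed-channel intensity.

    Returns an integer label image (0 = background); 8-connected
    components smaller than ``min_area`` pixels are dropped.
    """
    total = image.red + image.green
    if method == "otsu":
        if total.max() <= total.min():
            logger.warning("uniform image: no foreground found")
            return np.zeros(total.shape, dtype=int)
        thr = threshold_otsu(total)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown method {method!r}")

    mask = total > thr
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        logger.warning("no foreground above threshold %.3g", thr)
        return labels
    # drop small components, relabel compactly
    keep = np.zeros(labels.max() + 1, dtype=int)
    nxt = 1
    for p in measure.regionprops(labels):
        if p.area >= min_area:
            keep[p.label] = nxt
            nxt += 1
    return keep[labels]


def per_cell_ratio(image: RatioImage, labels: np.ndarray) -> CellSegmentation:
    """Per-cell F590/F520 (mean red / mean green) and the per-image mean.

    Cells whose mean green intensity is zero are excluded and logged.
    """
    labels = np.asarray(labels)
    if labels.shape != image.red.shape:
        raise ValueError("labels must align with the image")
    ratios: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        g = float(image.green[sel].mean())
        if g <= 0:
            logger.warning("cell %d excluded: zero mean green intensity", lab)
            continue
        ratios[int(lab)] = float(image.red[sel].mean()) / g
    image_mean = float(np.mean(list(ratios.values()))) if ratios else None
    return CellSegmentation(
        labels=labels,
        n_cells=len(ratios),
        per_cell_ratio=ratios,
        image_mean=image_mean,
    )


@dataclass
class MitoObject:
    """One segmented organelle with area/perimeter/axis and shape metrics."""

    label: int
    area: float  # px^2
    perimeter: float  # px
    major_axis: float  # px
    minor_axis: float  # px
    aspect_ratio: float
    form_factor: float
    centroid: tuple[float, float]

    def area_um2(self, pixel_size: float) -> float:
        return self.area * pixel_size**2


_PERIMETER_SMOOTH_SIGMA = 0.8  # px; suppresses staircase overestimation


def object_perimeter(obj_mask: np.ndarray) -> float:
    """Subpixel boundary length of one object's binary mask.

    The 0.5-level marching-squares contour of the lightly smoothed mask is
    a boundary polygon (unit and sqrt(2)-weighted diagonal steps refined
    to subpixel crossings); the slight Gaussian smoothing removes the
    systematic staircase overestimate on smooth outlines while preserving
    straight edges.  Accurate to a few percent for objects with minor
    width >= ~3 px; very small blocky objects are underestimated.
    """
    padded = np.pad(obj_mask.astype(float), 3)
    smoothed = gaussian_filter(padded, _PERIMETER_SMOOTH_SIGMA)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:  # object too small to survive smoothing
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            return 0.0
    return float(
        max(
            np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))
            for c in contours
        )
    )


def label_mitochondria(
    mask: np.ndarray, min_area: int = DEFAULT_MIN_MITO_AREA
) -> list[MitoObject]:
    """Measure every 8-connected object of a binary mask.

    Axis lengths are 4*sqrt(eigenvalue) of the second central moment
    matrix (the moment-matched ellipse); perimeter comes from the subpixel
    boundary polygon (see ``object_perimeter``).  Degenerate objects (zero
    minor axis, i.e. single-pixel-wide lines) are excluded and logged.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=2)
    objects: list[MitoObject] = []
    for p in measure.regionprops(labels):
        if p.area < min_area:
            continue
        if p.axis_minor_length <= 0:
            logger.warning("object %d degenerate (zero minor axis); excluded", p.label)
            continue
        perim = object_perimeter(labels[p.slice] == p.label)
        if perim <= 0:
            logger.warning("object %d has no measurable boundary; excluded", p.label)
            continue
        ar = p.axis_major_length / p.axis_minor_length
        ff = perim**2 / (4.0 * np.pi * p.area)
        objects.append(
            MitoObject(
                label=int(p.label),
                area=float(p.area),
                perimeter=perim,
                major_axis=float(p.axis_major_length),
                minor_axis=float(p.axis_minor_length),
                aspect_ratio=float(ar),
                form_factor=float(ff),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return objects


def morphology_summary(objects: Sequence[MitoObject]) -> dict:
    """Arithmetic mean AR and FF over a field's objects."""
    if not objects:
        raise ValueError("no objects to summarize")
    return {
        "n_objects": len(objects),
        "mean_aspect_ratio": float(np.mean([o.aspect_ratio for o in objects])),
        "mean_form_factor": float(np.mean([o.form_factor for o in objects])),
    }


def read_ratio_tiff(path, green_path=None, pixel_size: float = 1.0) -> RatioImage:
    """Read a two-page TIFF (page 1 = red, page 2 = green) or two files."""
    if green_path is None:
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] < 2:
            raise ValueError(f"{path}: expected a 2-page two-channel TIFF")
        red, green = pages[0], pages[1]
    else:
        red = tifffile.imread(path)
        green = tifffile.imread(green_path)
    return RatioImage(red=red, green=green, pixel_size=pixel_size)


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def cells_to_frame(seg: CellSegmentation) -> pd.DataFrame:
    areas = {p.label: p.area for p in measure.regionprops(seg.labels)}
    return pd.DataFrame(
        [
            {"label": lab, "area_px": areas.get(lab), "ratio": r}
            for lab, r in sorted(seg.per_cell_ratio.items())
        ]
    )


def mitochondria_to_frame(objects: Sequence[MitoObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": o.label,
                "area_px": o.area,
                "perimeter_px": o.perimeter,
                "major_axis_px": o.major_axis,
                "minor_axis_px": o.minor_axis,
                "aspect_ratio": o.aspect_ratio,
                "form_factor": o.form_factor,
            }
            for o in objects
        ]
    )
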