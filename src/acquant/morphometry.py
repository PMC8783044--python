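"""Long-term morphogenesis measurements.

Three assays from the extended (15-min-interval, multi-stage) recordings:

* the declining AP distance between the outer vulA junctions, a proxy for
  vulval cell migration toward the midline;
* the dorsal-lumen expansion delay ``Delta_t`` — the time from the last
  frame before AC fusion (reporter diffusing into neighboring uterine
  cells) to the first frame of adherens-junction ring expansion; both
  events are accepted as manual annotations;
* actin-ring occupancy at the AC-vulF interphase in ventrally oriented
  animals, an angular-bin proxy for the by-eye ring classes
  (complete / semicircle / disorganized / absent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgproc import binarize
from .stats import proportion_ci

log = logging.getLogger(__name__)

__all__ = [
    "EventAnnotation",
    "RingScore",
    "ClassFraction",
    "vulA_distance",
    "median_trend",
    "lumen_expansion_delay",
    "ring_occupancy",
    "classify_occupancy",
    "class_fraction",
]

RING_CLASSES = ("complete", "semicircle", "disorganized", "absent")


@dataclass(frozen=True)
class EventAnnotation:
    """Manually annotated fusion/expansion timestamps for one animal (hours).
    ``t_expansion_h = None`` flags an animal in which no expansion was
    observed."""

    animal_id: str
    t_pre_fusion_h: float
    t_expansion_h: float | None


@dataclass(frozen=True)
class RingScore:
    occupancy: float  # fraction of angular bins occupied, in [0, 1]
    ring_class: str


@dataclass(frozen=True)
class ClassFraction:
    k: int
    n: int
    percent: int  # rounded to nearest integer percent for reporting
    fraction: float
    ci_low: float
    ci_high: float


def vulA_distance(landmark_sets) -> np.ndarray:
    """Per-timepoint AP distance (µm) between the outer vulA junctions.

    ``landmark_sets`` is a sequence of :class:`~acquant.alignment.LandmarkSet`
    (or ``None`` for timepoints where the junctions could not be
    identified, which yield NaN gaps rather than failures).
    """
    out = np.full(len(landmark_sets), np.nan)
    for i, lm in enumerate(landmark_sets):
        if lm is None:
            continue
        pts = lm.points
        if "vulA1" not in pts or "vulA2" not in pts:
            log.warning("vulA_distance: missing junction at timepoint %d", i)
            continue
        out[i] = abs(pts["vulA2"][0] - pts["vulA1"][0])
    return out


def median_trend(series_per_animal) -> np.ndarray:
    """Per-timepoint median across animals, ignoring NaN gaps."""
    arr = np.stack([np.asarray(s, dtype=float) for s in series_per_animal])
    return np.nanmedian(arr, axis=0)


def lumen_expansion_delay(annotation: EventAnnotation) -> float | None:
    """Delay ``Delta_t = t_expansion - t_pre_fusion`` in hours.

    Returns ``None`` (with a log note) for animals without an observed
    expansion; a negative delay is rejected as an annotation error.
    """
    if annotation.t_expansion_h is None:
        log.info("lumen_expansion_delay: no expansion observed for %s", annotation.animal_id)
        return None
    dt = annotation.t_expansion_h - annotation.t_pre_fusion_h
    if dt < 0:
        raise ValueError(
            f"t_expansion precedes t_pre_fusion for {annotation.animal_id!r} ({dt:+.2f} h)"
        )
    return dt


def classify_occupancy(
    occupancy: float, complete_cutoff: float = 0.9, semicircle_cutoff: float = 0.5
) -> str:
    """Map an angular occupancy fraction to a ring class.

    The cut-offs (complete >= 0.9, semicircle in [0.5, 0.9), disorganized
    in (0, 0.5), absent = 0) are this package's quantitative proxy for the
    by-eye classes and are configurable.
    """
    if occupancy == 0:
        return "absent"
    if occupancy >= complete_cutoff:
        return "complete"
    if occupancy >= semicircle_cutoff:
        return "semicircle"
    return "disorganized"


def ring_occupancy(
    ventral_image: np.ndarray,
    center_px: tuple[float, float],
    r_in_um: float,
    r_out_um: float,
    pixel_size_um: float,
    n_bins: int = 36,
    mode: str = "fixed-normalized",
    level: float = 0.05,
    complete_cutoff: float = 0.9,
    semicircle_cutoff: float = 0.5,
) -> RingScore:
    """Score the actin ring in a ventral-view image.

    Thresholded signal inside the annulus ``r_in < r <= r_out`` (µm,
    centered on ``center_px`` = (row, col)) is assigned to ``n_bins``
    angular bins; the occupancy is the fraction of bins containing signal
    and the class follows :func:`classify_occupancy`.
    """
    if not (r_out_um > r_in_um > 0):
        raise ValueError("need r_out > r_in > 0")
    img = np.asarray(ventral_image, dtype=float)
    cr, cc = center_px
    r_out_px = r_out_um / pixel_size_um
    if (
        cr - r_out_px < -0.5
        or cc - r_out_px < -0.5
        or cr + r_out_px > img.shape[0] - 0.5
        or cc + r_out_px > img.shape[1] - 0.5
    ):
        raise ValueError("annulus extends outside the image")
    rr, cc_grid = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    radius = np.hypot(rr - cr, cc_grid - cc) * pixel_size_um
    annulus = (radius > r_in_um) & (radius <= r_out_um)
    mask = binarize(img, mode=mode, level=level) & annulus
    if not mask.any():
        return RingScore(occupancy=0.0, ring_class="absent")
    theta = np.arctan2(rr - cr, cc_grid - cc)[mask]
    bins = np.floor((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    occupancy = len(np.unique(bins)) / n_bins
    return RingScore(
        occupancy=occupancy,
        ring_class=classify_occupancy(occupancy, complete_cutoff, semicircle_cutoff),
    )


def class_fraction(
    table: pd.DataFrame,
    genotype: str | None = None,
    stage: str | None = None,
    positive_classes=("complete", "semicircle"),
    level: float = 0.95,
) -> ClassFraction:
    """Fraction of animals in the positive ring classes, with a 95% CI.

    ``table`` needs a ``ring_class`` column (plus ``genotype`` / ``stage``
    when filtering).  Percentages are rounded to the nearest integer for
    reporting, matching the counts-in-brackets style of the cohort
    summaries; the raw fraction and Wilson CI are retained.
    """
    sub = table
    if genotype is not None:
        sub = sub[sub["genotype"] == genotype]
    if stage is not None:
        sub = sub[sub["stage"] == stage]
    n = len(sub)
    if n == 0:
        raise ValueError("zero animals in the requested stratum")
    k = int(sub["ring_class"].isin(positive_classes).sum())
    frac, lo, hi = proportion_ci(k, n, level=level)
    return ClassFraction(
        k=k, n=n, percent=int(math.floor(100 * frac + 0.5)), fraction=frac, ci_low=lo, ci_high=hi
    )
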