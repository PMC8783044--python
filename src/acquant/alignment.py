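"""Anchor-cell positioning metrics from junction landmarks.

The alignment ratio ``R_A`` and the absolute AC-to-mid-vulF distance
``Delta`` quantify how precisely the AC sits on the vulval midline.  Both
are computed from five landmarks identified in the mid-sagittal plane of
the adherens-junction channel: the two outer vulA junctions, the two
HMR-1 punctae delineating the AC edges, and the mid-vulF point.

With the AC mid-point ``mid_AC`` defined as the AP midpoint of the two AC
edge punctae,

* ``R_A = x / y`` where ``x`` is the AP distance from ``mid_AC`` to the
  *nearer* vulA junction and ``y`` the AP distance between the vulA
  junctions — ``R_A = 0.5`` means perfect centering;
* ``Delta = |mid_AC - vulF_mid|`` along the AP axis, in µm.

Landmarks may be supplied manually (CSV) or detected automatically as the
five brightest local maxima of the junction channel with roles assigned
by AP order; manual input is authoritative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .imgproc import VoxelGrid, max_project

log = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_ROLES",
    "LandmarkSet",
    "AlignmentResult",
    "compute_alignment",
    "compute_polarity_index",
    "detect_landmarks",
    "landmarks_from_csv",
    "alignment_table",
]

#: Roles in canonical anterior-to-posterior order.
REQUIRED_ROLES = ("vulA1", "ac_edge_1", "vulF_mid", "ac_edge_2", "vulA2")


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2D points (AP µm, DV µm) in the mid-sagittal plane."""

    points: dict

    def require(self, roles=REQUIRED_ROLES) -> None:
        for role in roles:
            if role not in self.points:
                raise ValueError(f"missing landmark role {role!r}")

    def canonical(self) -> "LandmarkSet":
        """Order vulA1/vulA2 (and the AC edges) by ascending AP position."""
        pts = dict(self.points)
        for a, b in (("vulA1", "vulA2"), ("ac_edge_1", "ac_edge_2")):
            if a in pts and b in pts and pts[a][0] > pts[b][0]:
                pts[a], pts[b] = pts[b], pts[a]
        return LandmarkSet(pts)

    def translated(self, dap: float) -> "LandmarkSet":
        return LandmarkSet({k: (ap + dap, dv) for k, (ap, dv) in self.points.items()})


@dataclass(frozen=True)
class AlignmentResult:
    mid_ac_um: float
    x_um: float
    y_um: float
    r_a: float
    delta_um: float


def compute_alignment(landmarks: LandmarkSet) -> AlignmentResult:
    """Compute ``R_A`` and ``Delta`` from a full landmark set.

    All distances are measured along the AP axis only.  When the AC
    mid-point is exactly equidistant from both vulA junctions the nearer
    junction is taken to be vulA1 (documented tie-break; the value of
    ``R_A`` is unaffected).  Coincident vulA junctions are rejected.
    """
    landmarks.require()
    lm = landmarks.canonical().points
    a1, a2 = lm["vulA1"][0], lm["vulA2"][0]
    y = a2 - a1
    if y == 0:
        raise ValueError("vulA junctions coincide along the AP axis; R_A undefined")
    mid_ac = 0.5 * (lm["ac_edge_1"][0] + lm["ac_edge_2"][0])
    d1, d2 = abs(mid_ac - a1), abs(mid_ac - a2)
    x = d1 if d1 <= d2 else d2
    delta = abs(mid_ac - lm["vulF_mid"][0])
    return AlignmentResult(mid_ac_um=mid_ac, x_um=x, y_um=y, r_a=x / y, delta_um=delta)


def compute_polarity_index(projection: np.ndarray, ac_mask: np.ndarray) -> float:
    """Dorsoventral polarity index I_DV from a summed z-projection.

    The AC mask is split at its intensity-weighted DV centroid row
    (ventral = high row index) and ``I_DV`` is the ratio of the ventral-
    half to the dorsal-half intensity sum.  Rows strictly ventral of the
    centroid count as ventral, strictly dorsal as dorsal; the (rare)
    exactly-centroidal row contributes to neither half.  The cited
    published protocol for this index is not reproduced here; this
    formulation is the package's stated stand-in.
    """
    projection = np.asarray(projection, dtype=float)
    ac_mask = np.asarray(ac_mask, dtype=bool)
    if projection.shape != ac_mask.shape:
        raise ValueError("mask must fit the projection shape")
    if not ac_mask.any():
        raise ValueError("ac_mask is empty")
    w = projection * ac_mask
    total = w.sum()
    if total <= 0:
        raise ValueError("no signal inside the AC mask")
    rows = np.arange(projection.shape[0], dtype=float)
    row_sums = w.sum(axis=1)
    centroid = float((rows * row_sums).sum() / total)
    ventral = row_sums[rows > centroid].sum()
    dorsal = row_sums[rows < centroid].sum()
    if dorsal == 0:
        raise ValueError("dorsal half has zero intensity; I_DV undefined")
    return float(ventral / dorsal)


def _refine_peak(img: np.ndarray, r: int, c: int, radius: int = 2) -> tuple[float, float]:
    """Subpixel peak position by background-subtracted intensity centroid
    in a small window around a detected maximum."""
    r0, r1 = max(0, r - radius), min(img.shape[0], r + radius + 1)
    c0, c1 = max(0, c - radius), min(img.shape[1], c + radius + 1)
    w = img[r0:r1, c0:c1].astype(float)
    w = w - w.min()
    if w.sum() == 0:
        return float(r), float(c)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())


def detect_landmarks(
    junction: VoxelGrid, n_peaks: int = 5, min_distance_um: float = 0.5
) -> LandmarkSet:
    """Detect the five junction landmarks in the BM/junction channel.

    The channel is max-projected along z, the ``n_peaks`` brightest local
    maxima (separated by at least ``min_distance_um``) are located,
    refined to subpixel precision by local intensity centroid, and
    assigned roles in AP order: vulA1, ac_edge_1, vulF_mid, ac_edge_2,
    vulA2.  This automatic path assumes the standard landmark layout; a
    manually curated CSV takes precedence in analysis workflows.
    """
    img = max_project(junction.values, axis=0)
    _, dy, dx = junction.voxel_size
    md = max(1, int(round(min_distance_um / min(dy, dx))))
    peaks = peak_local_max(img, min_distance=md, num_peaks=n_peaks)
    if len(peaks) < n_peaks:
        raise ValueError(f"found only {len(peaks)} junction punctae, expected {n_peaks}")
    pts = []
    for r, c in peaks:
        rf, cf = _refine_peak(img, int(r), int(c))
        pts.append(((cf + 0.5) * dx, (rf + 0.5) * dy))  # (AP, DV) µm
    pts.sort(key=lambda p: p[0])
    return LandmarkSet(dict(zip(REQUIRED_ROLES, pts)))


def landmarks_from_csv(path) -> dict[str, LandmarkSet]:
    """Load per-animal landmark sets from a CSV with columns
    ``animal_id, role, ap_um, dv_um``."""
    df = pd.read_csv(path)
    required = {"animal_id", "role", "ap_um", "dv_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    out: dict[str, LandmarkSet] = {}
    for animal, sub in df.groupby("animal_id"):
        out[str(animal)] = LandmarkSet(
            {row.role: (float(row.ap_um), float(row.dv_um)) for row in sub.itertuples()}
        )
    return out


def alignment_table(landmark_sets: dict[str, LandmarkSet]) -> pd.DataFrame:
    """Alignment metrics for a cohort of animals, one row per animal."""
    rows = []
    for animal, lm in landmark_sets.items():
        res = compute_alignment(lm)
        rows.append(
            {
                "animal_id": animal,
                "mid_ac_um": res.mid_ac_um,
                "x_um": res.x_um,
                "y_um": res.y_um,
                "r_a": res.r_a,
                "delta_um": res.delta_um,
            }
        )
    return pd.DataFrame(rows)
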