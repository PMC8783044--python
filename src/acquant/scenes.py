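"""Ground-truthed synthetic two-channel microscopy scenes.

Emulates the imaging geometry of anchor-cell (AC) studies so that every
downstream estimator in this package can be exercised without external
data.  Two reporter channels are generated:

* channel 0 ("ac") — an ellipsoidal AC body with an optional ventral
  invasive protrusion that crosses the basement membrane (BM) only through
  a rendered gap, plus smooth stochastic shape fluctuations in time series;
* channel 1 ("bm") — a thin BM sheet with an optional gap and Gaussian
  punctae at the five junction landmark positions (vulA1/vulA2, the two AC
  edges and the mid-vulF point).

Scenes are blurred by a separable Gaussian PSF, corrupted by photon
(Poisson) and read (Gaussian) noise and quantized to 16 bits.  Every
fixture carries a :class:`GroundTruth` sidecar with the voxelized
protrusion volume per frame, the true landmarks and the alignment metrics
they imply, so that recovery tests compare like with like.

Axis convention (package-wide): arrays are ``(z, y, x)`` (or
``(t, channel, z, y, x)`` for time series); AP = x with anterior at low x;
DV = y with ventral at high y.  Voxel centers sit at ``(i + 0.5) * d``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize

from .imgproc import VoxelGrid, _blur, shift_integer

log = logging.getLogger(__name__)

__all__ = [
    "SceneSpecError",
    "Protrusion",
    "Noise",
    "SceneSpec",
    "GroundTruth",
    "TimeSeries",
    "build_scene",
    "render_stack",
    "simulate_timeseries",
    "write_fixture",
    "read_fixture",
    "Fixture",
]

LANDMARK_ROLES = ("vulA1", "ac_edge_1", "vulF_mid", "ac_edge_2", "vulA2")


class SceneSpecError(ValueError):
    """Raised when a scene specification violates its invariants."""


def _default_landmarks() -> dict[str, tuple[float, float]]:
    # (AP µm, DV µm) in the mid-sagittal plane; a perfectly centered AC:
    # mid-AC = mid-vulF = 8.0 µm, equidistant from both vulA junctions.
    # Vulval junctions (vulA, vulF apex) lie ventral of the BM sheet at
    # 6.0 µm; the HMR-1 punctae marking the AC edges lie dorsal of it.
    return {
        "vulA1": (3.0, 6.8),
        "vulA2": (13.0, 6.8),
        "ac_edge_1": (7.0, 5.0),
        "ac_edge_2": (9.0, 5.0),
        "vulF_mid": (8.0, 7.2),
    }


@dataclass(frozen=True)
class Protrusion:
    """Ventral invasive protrusion: a stalk crossing the BM gap plus a
    hemispherical cap.  ``length_um`` is the stalk extent ventral of the BM
    plane (the cap adds another ``stalk_radius_um``); ``growth_um_per_min``
    makes the stalk elongate linearly in time series."""

    present: bool = True
    stalk_radius_um: float = 1.2
    length_um: float = 1.5
    growth_um_per_min: float = 0.0


@dataclass(frozen=True)
class Noise:
    """Camera noise model: ``observed = gain * Poisson(signal / gain) + N(0, read_sd)``.

    ``photon_gain`` is the intensity increment per detected photon, so the
    variance of a uniform patch is ``photon_gain * mean + read_sd**2`` and
    quadrupling the photon flux (gain / 4) halves the relative shot noise.
    ``photon_gain = 0`` disables shot noise, ``read_sd = 0`` read noise.
    """

    photon_gain: float = 4.0
    read_sd: float = 2.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene / time series.

    Distances are micrometers, times seconds unless suffixed otherwise.
    ``ac_center`` and ``ac_radii`` are ordered (AP, DV, Z).  The defaults
    describe a mid-L4-like geometry on a compact grid: a ~4 µm AC centered
    on the vulval midline, a BM sheet 6 µm deep with a 3 µm gap, and the
    five junction landmarks laid out symmetrically so the true alignment
    ratio is exactly 0.5.
    """

    grid_shape: tuple[int, int, int] = (24, 96, 160)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1)  # (dz, dy, dx) µm
    ac_center: tuple[float, float, float] = (8.0, 4.2, 3.0)  # (AP, DV, Z) µm
    ac_radii: tuple[float, float, float] = (2.0, 1.5, 1.5)  # (AP, DV, Z) µm
    protrusion: Protrusion = field(default_factory=Protrusion)
    bm_y_um: float = 6.0
    bm_gap_center_um: float = 8.0
    bm_gap_width_um: float = 3.0
    bm_thickness_um: float = 0.3
    landmarks: dict[str, tuple[float, float]] = field(default_factory=_default_landmarks)
    deform_amplitude: float = 0.0
    deform_tau_s: float = 60.0
    ac_intensity: float = 600.0
    bm_intensity: float = 400.0
    puncta_intensity: float = 1500.0
    puncta_sigma_um: float = 0.15
    background: float = 5.0
    noise: Noise = field(default_factory=Noise)
    psf_sigma_um: tuple[float, float] = (0.15, 0.4)  # (lateral, axial) µm
    frame_interval_s: float = 30.0
    n_frames: int = 1
    jitter_vox: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry helpers ------------------------------------------------
    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical grid extent (z, y, x) in µm."""
        return tuple(n * d for n, d in zip(self.grid_shape, self.voxel_size))

    @property
    def gap_interval(self) -> tuple[float, float] | None:
        if self.bm_gap_width_um <= 0:
            return None
        half = self.bm_gap_width_um / 2
        return (self.bm_gap_center_um - half, self.bm_gap_center_um + half)

    def validate(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise SceneSpecError("grid_shape entries must be >= 1")
        if any(d <= 0 for d in self.voxel_size):
            raise SceneSpecError("voxel sizes must be strictly positive")
        if any(r <= 0 for r in self.ac_radii):
            raise SceneSpecError("AC semi-axes must be strictly positive")
        if self.bm_gap_width_um < 0:
            raise SceneSpecError("bm_gap_width_um must be >= 0")
        if self.bm_thickness_um <= 0 or self.puncta_sigma_um <= 0:
            raise SceneSpecError("sheet thickness and puncta sigma must be positive")
        if self.n_frames < 1:
            raise SceneSpecError("n_frames must be >= 1")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise SceneSpecError("PSF sigmas must be strictly positive")
        ez, ey, ex = self.extent_um
        for role, (ap, dv) in self.landmarks.items():
            if not (0 <= ap <= ex and 0 <= dv <= ey):
                raise SceneSpecError(
                    f"landmark {role!r} at (AP={ap}, DV={dv}) µm lies outside the "
                    f"grid extent ({ex} x {ey}) µm"
                )
        p = self.protrusion
        if p.present:
            if p.stalk_radius_um <= 0 or p.length_um <= 0:
                raise SceneSpecError("protrusion stalk radius and length must be positive")
            if self.bm_gap_width_um <= 0:
                raise SceneSpecError(
                    "inconsistent scene: a protrusion cannot cross an intact BM (gap width 0)"
                )
            lo, hi = self.gap_interval
            cx = self.ac_center[0]
            if cx - p.stalk_radius_um < lo or cx + p.stalk_radius_um > hi:
                raise SceneSpecError(
                    "protrusion stalk footprint must lie within the BM gap interval"
                )
            self._check_protrusion_depth(p.length_um)

    def _check_protrusion_depth(self, length_um: float) -> None:
        """The rendered stalk+cap must stay inside the grid, else the
        ground-truth volume would silently be clipped."""
        tip = self.bm_y_um + length_um + self.protrusion.stalk_radius_um
        if tip > self.extent_um[1]:
            raise SceneSpecError(
                f"protrusion tip at DV {tip:.2f} µm extends beyond the grid "
                f"({self.extent_um[1]:.2f} µm deep)"
            )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if isinstance(d.get("protrusion"), dict):
            d["protrusion"] = Protrusion(**d["protrusion"])
        if isinstance(d.get("noise"), dict):
            d["noise"] = Noise(**d["noise"])
        for key in ("grid_shape", "voxel_size", "ac_center", "ac_radii", "psf_sigma_um"):
            if key in d:
                d[key] = tuple(d[key])
        if "landmarks" in d:
            d["landmarks"] = {k: tuple(v) for k, v in d["landmarks"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Sidecar truth for one fixture.

    ``true_volume_trace`` holds ``(time_s, volume_um3)`` per frame, the
    volume being the voxel-center membership count of the rendered
    protrusion solid times the voxel volume.  ``applied_shifts`` records
    the per-frame (dy, dx) jitter in voxels when jitter is enabled.
    """

    true_volume_trace: list[tuple[float, float]]
    true_landmarks: dict[str, tuple[float, float]]
    true_r_a: float
    true_delta_um: float
    true_breached: bool
    applied_shifts: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_volume_trace=[tuple(v) for v in d["true_volume_trace"]],
            true_landmarks={k: tuple(v) for k, v in d["true_landmarks"].items()},
            true_r_a=d["true_r_a"],
            true_delta_um=d["true_delta_um"],
            true_breached=d["true_breached"],
            applied_shifts=[tuple(s) for s in d["applied_shifts"]],
        )


@dataclass
class TimeSeries:
    """Rendered observation of a time series: ``frames`` is uint16 with
    shape ``(t, channel, z, y, x)``."""

    frames: np.ndarray
    spec: SceneSpec
    truth: GroundTruth

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.spec.frame_interval_s

    def channel(self, index: int, frame: int = 0) -> VoxelGrid:
        label = "ac" if index == 0 else "bm"
        return VoxelGrid(
            self.frames[frame, index].astype(float),
            self.spec.voxel_size,
            channel=label,
            time_s=float(frame * self.spec.frame_interval_s),
        )


# ---------------------------------------------------------------------------
# geometry rendering
# ---------------------------------------------------------------------------


def _coord_grids(spec: SceneSpec):
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_size
    z = ((np.arange(nz) + 0.5) * dz)[:, None, None]
    y = ((np.arange(ny) + 0.5) * dy)[None, :, None]
    x = ((np.arange(nx) + 0.5) * dx)[None, None, :]
    return z, y, x


def _ac_masks(spec: SceneSpec, stalk_length_um: float, deform_field: np.ndarray | None):
    """Boolean masks: AC body (ellipsoid, optionally deformed), the
    above-BM neck, and the below-BM protrusion solid (stalk + cap)."""
    z, y, x = _coord_grids(spec)
    cx, cy, cz = spec.ac_center
    rx, ry, rz = spec.ac_radii
    q = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    if deform_field is not None and spec.deform_amplitude > 0:
        scale = np.clip(1.0 + spec.deform_amplitude * deform_field, 0.1, None)
        body = q <= scale**2
    else:
        body = q <= 1.0
    neck = np.zeros_like(body)
    below = np.zeros_like(body)
    p = spec.protrusion
    if p.present:
        r = p.stalk_radius_um
        radial = (x - cx) ** 2 + (z - cz) ** 2 <= r**2
        tip = spec.bm_y_um + stalk_length_um
        neck = radial & (y > cy) & (y <= spec.bm_y_um)
        stalk = radial & (y > spec.bm_y_um) & (y <= tip)
        cap = ((x - cx) ** 2 + (z - cz) ** 2 + (y - tip) ** 2 <= r**2) & (y > tip)
        below = stalk | cap
    return body, neck, below


def _bm_channel(spec: SceneSpec) -> np.ndarray:
    z, y, x = _coord_grids(spec)
    sheet = np.abs(y - spec.bm_y_um) <= spec.bm_thickness_um / 2
    gap = spec.gap_interval
    if gap is not None:
        sheet = sheet & ~((x >= gap[0]) & (x <= gap[1]))
    ch = np.full(spec.grid_shape, spec.background, dtype=float)
    ch += spec.bm_intensity * np.broadcast_to(sheet, spec.grid_shape)
    s_xy = spec.puncta_sigma_um
    s_z = 2.0 * s_xy
    cz = spec.ac_center[2]
    for ap, dv in spec.landmarks.values():
        ch += spec.puncta_intensity * np.exp(
            -0.5 * (((x - ap) / s_xy) ** 2 + ((y - dv) / s_xy) ** 2 + ((z - cz) / s_z) ** 2)
        )
    return ch


def _alignment_truth(landmarks: dict[str, tuple[float, float]]) -> tuple[float, float]:
    a1, a2 = sorted((landmarks["vulA1"][0], landmarks["vulA2"][0]))
    mid_ac = 0.5 * (landmarks["ac_edge_1"][0] + landmarks["ac_edge_2"][0])
    x = min(abs(mid_ac - a1), abs(mid_ac - a2))
    r_a = x / (a2 - a1)
    delta = abs(mid_ac - landmarks["vulF_mid"][0])
    return r_a, delta


def build_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the noise-free two-channel scene ``(2, z, y, x)`` and its truth.

    Channel 0 holds the AC ellipsoid plus protrusion; channel 1 the BM
    sheet with its gap and the landmark punctae.  The ground-truth volume
    is the voxel-center membership count of the below-BM protrusion solid
    times the voxel volume.
    """
    spec.validate()
    body, neck, below = _ac_masks(spec, spec.protrusion.length_um, None)
    ch0 = spec.background + spec.ac_intensity * (body | neck | below).astype(float)
    ch1 = _bm_channel(spec)
    scene = np.stack([ch0, ch1])
    dz, dy, dx = spec.voxel_size
    volume = float(below.sum()) * dz * dy * dx
    r_a, delta = _alignment_truth(spec.landmarks)
    truth = GroundTruth(
        true_volume_trace=[(0.0, volume)],
        true_landmarks=dict(spec.landmarks),
        true_r_a=r_a,
        true_delta_um=delta,
        true_breached=spec.bm_gap_width_um > 0,
        applied_shifts=[(0, 0)],
    )
    return scene, truth


def render_stack(
    scene: np.ndarray, spec: SceneSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Forward model: PSF blur, photon + read noise, 16-bit quantization.

    Same spec (including seed, when ``rng`` is not supplied) gives
    bit-identical output.  With zero noise scales and a vanishing PSF the
    output equals the scene up to quantization.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    scene = np.asarray(scene, dtype=float)
    dz, dy, dx = spec.voxel_size
    s_lat, s_ax = spec.psf_sigma_um
    sig = (s_ax / dz, s_lat / dy, s_lat / dx)
    out = np.empty(scene.shape, dtype=np.uint16)
    for c in range(scene.shape[0]):
        blurred = _blur(scene[c], sig)
        g = spec.noise.photon_gain
        obs = g * rng.poisson(blurred / g) if g > 0 else blurred.copy()
        if spec.noise.read_sd > 0:
            obs = obs + rng.normal(0.0, spec.noise.read_sd, size=obs.shape)
        saturated = np.count_nonzero(obs > 65535)
        if saturated:
            log.info("render_stack: %.3g%% of voxels saturated", 100 * saturated / obs.size)
        out[c] = np.clip(np.rint(obs), 0, 65535).astype(np.uint16)
    return out


def _deform_fields(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random boundary-perturbation fields, one per frame.

    Coarse Gaussian coefficients on a 4x6x8 grid evolve as an
    Ornstein–Uhlenbeck process with correlation time ``deform_tau_s`` and
    are linearly upsampled to the full grid, giving a unit-scale smooth
    field multiplied downstream by ``deform_amplitude``.
    """
    coarse_shape = (4, 6, 8)
    rho = float(np.exp(-spec.frame_interval_s / max(spec.deform_tau_s, 1e-9)))
    c = rng.standard_normal(coarse_shape)
    fields = np.empty((spec.n_frames, *spec.grid_shape))
    for t in range(spec.n_frames):
        if t > 0:
            c = rho * c + np.sqrt(1 - rho**2) * rng.standard_normal(coarse_shape)
        fields[t] = resize(c, spec.grid_shape, order=1, mode="edge", anti_aliasing=False)
    return fields


def simulate_timeseries(spec: SceneSpec) -> TimeSeries:
    """Simulate a rendered time series with shape fluctuations, optional
    protrusion growth and optional integer-voxel stage jitter.

    Randomness is derived from a single seed: one sub-stream drives the
    deformation/jitter process and one per frame drives rendering noise,
    so series are reproducible frame-by-frame.
    """
    spec.validate()
    if spec.n_frames < 2:
        raise SceneSpecError("simulate_timeseries requires n_frames >= 2")
    if spec.protrusion.present and spec.protrusion.growth_um_per_min:
        final_len = spec.protrusion.length_um + spec.protrusion.growth_um_per_min * (
            (spec.n_frames - 1) * spec.frame_interval_s / 60.0
        )
        spec._check_protrusion_depth(final_len)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_frames + 1)
    proc_rng = np.random.default_rng(children[0])
    fields = (
        _deform_fields(spec, proc_rng)
        if spec.deform_amplitude > 0
        else [None] * spec.n_frames
    )
    dz, dy, dx = spec.voxel_size
    frames = np.empty((spec.n_frames, 2, *spec.grid_shape), dtype=np.uint16)
    trace: list[tuple[float, float]] = []
    shifts: list[tuple[int, int]] = []
    ch1 = _bm_channel(spec)
    for t in range(spec.n_frames):
        t_s = t * spec.frame_interval_s
        length = spec.protrusion.length_um + spec.protrusion.growth_um_per_min * (t_s / 60.0)
        body, neck, below = _ac_masks(spec, length, fields[t])
        ch0 = spec.background + spec.ac_intensity * (body | neck | below).astype(float)
        rendered = render_stack(
            np.stack([ch0, ch1]), spec, rng=np.random.default_rng(children[t + 1])
        )
        if spec.jitter_vox > 0 and t > 0:
            jy, jx = proc_rng.integers(-spec.jitter_vox, spec.jitter_vox + 1, size=2)
        else:
            jy, jx = 0, 0
        if jy or jx:
            # circular shift: borders carry only background, so the wrap is
            # innocuous and the translation is exactly recoverable
            rendered = np.roll(rendered, (jy, jx), axis=(2, 3))
        frames[t] = rendered
        shifts.append((int(jy), int(jx)))
        trace.append((float(t_s), float(below.sum()) * dz * dy * dx))
    r_a, delta = _alignment_truth(spec.landmarks)
    truth = GroundTruth(
        true_volume_trace=trace,
        true_landmarks=dict(spec.landmarks),
        true_r_a=r_a,
        true_delta_um=delta,
        true_breached=spec.bm_gap_width_um > 0,
        applied_shifts=shifts,
    )
    return TimeSeries(frames=frames, spec=spec, truth=truth)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

_CHANNEL_FILES = ("channel0_ac.tif", "channel1_bm.tif")
_SIDECAR = "ground_truth.json"


@dataclass
class Fixture:
    """A fixture read back from disk; ``spec``/``truth`` are ``None`` when
    the ground-truth sidecar is absent (an explicit "no ground truth"
    state, not a failure)."""

    frames: np.ndarray  # (t, channel, z, y, x)
    spec: SceneSpec | None
    truth: GroundTruth | None


def write_fixture(
    frames: np.ndarray, spec: SceneSpec, truth: GroundTruth | None, path: str | Path
) -> list[Path]:
    """Write a fixture: one multi-page TIFF per channel (axes TZYX, voxel
    sizes in the ImageJ metadata) plus a JSON ground-truth sidecar.
    Round-tripping through :func:`read_fixture` reproduces the voxel
    values exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    if frames.ndim == 4:  # single time point (channel, z, y, x)
        frames = frames[None]
    if frames.ndim != 5 or frames.shape[1] != 2:
        raise ValueError("expected frames shaped (t, 2, z, y, x) or (2, z, y, x)")
    dz, dy, dx = spec.voxel_size
    written = []
    for c, name in enumerate(_CHANNEL_FILES):
        f = path / name
        data = frames[:, c]
        if data.dtype not in (np.uint8, np.uint16, np.float32):
            data = data.astype(np.float32)
        tifffile.imwrite(
            f,
            data,
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": "TZYX"},
        )
        written.append(f)
    sidecar = path / _SIDECAR
    payload = {"scene_spec": spec.to_dict()}
    if truth is not None:
        payload["ground_truth"] = truth.to_dict()
    sidecar.write_text(json.dumps(payload, indent=1))
    written.append(sidecar)
    return written


def read_fixture(path: str | Path) -> Fixture:
    """Read a fixture directory written by :func:`write_fixture`."""
    path = Path(path)
    stacks = []
    for name in _CHANNEL_FILES:
        f = path / name
        if not f.exists():
            raise FileNotFoundError(f"missing channel file {f}")
        data = tifffile.imread(f)
        if data.ndim == 3:  # single-frame file
            data = data[None]
        stacks.append(data)
    frames = np.stack(stacks, axis=1)
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        log.info("read_fixture: no ground-truth sidecar at %s", sidecar)
        return Fixture(frames=frames, spec=None, truth=None)
    payload = json.loads(sidecar.read_text())
    spec = SceneSpec.from_dict(payload["scene_spec"])
    truth = (
        GroundTruth.from_dict(payload["ground_truth"]) if "ground_truth" in payload else None
    )
    return Fixture(frames=frames, spec=spec, truth=truth)
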