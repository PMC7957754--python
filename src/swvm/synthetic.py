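"""Virtual elasticity phantom and freehand-sweep simulator.

The phantom is a piecewise-constant ground-truth SWV field: a uniform
background with non-overlapping cylindrical (or spherical) inclusions of
known stiffness, mirroring a commercial elasticity QA phantom whose four
inclusion types have certified moduli.  The scanner model emulates the
observation process only — no shear-wave physics is simulated: a virtual
probe translates along a straight path with the image plane orthogonal to
the motion, poses are reported at ~7 Hz with isotropic tracking jitter
(0.09 mm RMS by default), SWV frames at <= 2 Hz with additive Gaussian noise
and independent zero-valued dropout, and an optional ``speed_bias`` hook can
inject a transducer-speed-dependent offset (the out-of-plane motion artefact
is device physics, so it is pluggable rather than modelled).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import Calibration, Frame, Pose, RigidTransform, Sweep
from .reconstruction import MaskVolume, VoxelGrid, reconstruct, weighted_mean_swv
from .stats import modulus_to_velocity

__all__ = [
    "SyntheticError",
    "Inclusion",
    "Phantom",
    "AcquisitionModel",
    "default_phantom",
    "sample_phantom",
    "simulate_sweep",
    "simulate_speed_series",
    "inclusion_mask",
    "phantom_truth",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class Inclusion:
    """A stiff(er) target region of uniform known SWV."""

    shape: str  # "cylinder" | "sphere"
    center: np.ndarray  # mm
    radius: float  # mm
    swv: float  # m/s
    axis: np.ndarray | None = None  # cylinder axis (unit), ignored for spheres
    length: float = 0.0  # cylinder length, mm
    density: float | None = None  # kg/m^3

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.shape not in ("cylinder", "sphere"):
            raise SyntheticError(f"unknown inclusion shape {self.shape!r}")
        if self.radius <= 0 or self.swv <= 0:
            raise SyntheticError("inclusion radius and SWV must be positive")
        if self.shape == "cylinder":
            if self.axis is None or self.length <= 0:
                raise SyntheticError("cylinder needs an axis and positive length")
            a = np.asarray(self.axis, float).reshape(3)
            object.__setattr__(self, "axis", a / np.linalg.norm(a))

    def contains(self, points: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        """Closed-region membership test, optionally shrunk by ``margin_mm``."""
        p = np.atleast_2d(points) - self.center
        r = self.radius - margin_mm
        if r <= 0:
            return np.zeros(p.shape[0], dtype=bool)
        if self.shape == "sphere":
            return np.einsum("ij,ij->i", p, p) <= r * r
        ax = np.asarray(self.axis)
        along = p @ ax
        radial2 = np.einsum("ij,ij->i", p, p) - along**2
        half = self.length / 2.0 - margin_mm
        return (np.abs(along) <= half) & (radial2 <= r * r)

    def _aabb(self) -> tuple[np.ndarray, np.ndarray]:
        if self.shape == "sphere":
            ext = np.full(3, self.radius)
        else:
            a = np.asarray(self.axis)
            ext = self.radius * np.sqrt(np.clip(1 - a**2, 0, 1)) + (
                self.length / 2.0
            ) * np.abs(a)
        return self.center - ext, self.center + ext


@dataclass(frozen=True)
class Phantom:
    """Piecewise-constant SWV field: background + non-overlapping inclusions."""

    background_swv: float
    inclusions: tuple[Inclusion, ...] = ()
    background_density: float = 1000.0

    def __post_init__(self) -> None:
        if self.background_swv <= 0:
            raise SyntheticError("background SWV must be positive")
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        boxes = [inc._aabb() for inc in self.inclusions]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                lo = np.maximum(boxes[i][0], boxes[j][0])
                hi = np.minimum(boxes[i][1], boxes[j][1])
                if np.all(lo < hi):
                    raise SyntheticError(f"inclusions {i} and {j} overlap")


# Manufacturer-style reference set: four cylinder types.  The certified SWVs
# follow from the certified Young's moduli via v = sqrt(E/(3 rho)) with the
# type-specific densities 1040, 1040, 1050 and 1060 kg/m^3.
REFERENCE_SWV = (1.47, 2.24, 4.04, 5.42)
REFERENCE_DENSITIES = (1040.0, 1040.0, 1050.0, 1060.0)


def default_phantom(
    radius_mm: float = 5.0, length_mm: float = 60.0, spacing_mm: float = 25.0
) -> Phantom:
    """Four-cylinder QA phantom in a 1.0 m/s background.

    Cylinders run along z (the usual sweep direction), centred at depth
    y = 15 mm and laterally separated by ``spacing_mm``.
    """
    incs = [
        Inclusion(
            shape="cylinder",
            center=np.array([i * spacing_mm, 15.0, 0.0]),
            radius=radius_mm,
            swv=swv,
            axis=np.array([0.0, 0.0, 1.0]),
            length=length_mm,
            density=rho,
        )
        for i, (swv, rho) in enumerate(zip(REFERENCE_SWV, REFERENCE_DENSITIES))
    ]
    return Phantom(background_swv=1.0, inclusions=tuple(incs))


def sample_phantom(phantom: Phantom, points: np.ndarray) -> np.ndarray:
    """Ground-truth SWV at world points; first matching inclusion wins."""
    p = np.atleast_2d(np.asarray(points, float))
    out = np.full(p.shape[0], phantom.background_swv)
    unassigned = np.ones(p.shape[0], dtype=bool)
    for inc in phantom.inclusions:
        hit = unassigned & inc.contains(p)
        out[hit] = inc.swv
        unassigned &= ~hit
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


@dataclass(frozen=True)
class AcquisitionModel:
    """Observation-model parameters of the virtual tracked scanner."""

    sweep_speed: float = 3.0  # mm/s, freehand sweeps stay below 5 mm/s
    swe_rate: float = 2.0  # Hz, device maximum for SWE frames
    pose_rate: float = 7.0  # Hz, optical tracker / B-mode rate
    frame_shape: tuple[int, int] = (30, 30)  # rows (depth) x cols (lateral)
    spacing: tuple[float, float] = (1.0, 1.0)  # (row, col) mm
    noise_sd: float = 0.1  # m/s additive Gaussian per pixel
    dropout_prob: float = 0.05  # fraction of pixels zeroed (failed estimates)
    tracking_jitter_rms: float = 0.09  # mm, vector RMS
    seed: int = 0
    speed_bias: Callable[[float], float] | None = None
    include_bmode: bool = False

    def __post_init__(self) -> None:
        if self.swe_rate <= 0 or self.pose_rate <= 0:
            raise SyntheticError("sampling rates must be positive")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise SyntheticError("dropout_prob must be in [0, 1)")
        if self.noise_sd < 0 or self.tracking_jitter_rms < 0:
            raise SyntheticError("noise and jitter must be non-negative")
        if self.sweep_speed < 0:
            raise SyntheticError("sweep speed must be non-negative")


def _frame_basis(direction: np.ndarray) -> np.ndarray:
    """Right-handed basis [e_x e_y u] with the image plane orthogonal to u.

    For motion along +z this is the identity, so image columns map to world
    x and rows (depth) to world y.
    """
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e_x = helper - (helper @ u) * u
    e_x /= np.linalg.norm(e_x)
    e_y = np.cross(u, e_x)
    return np.column_stack([e_x, e_y, u])


def simulate_sweep(
    phantom: Phantom,
    acq: AcquisitionModel,
    start=(0.0, 0.0, -30.0),
    end=(0.0, 0.0, 30.0),
    duration_s: float | None = None,
    seed: int | None = None,
) -> Sweep:
    """Simulate one tracked sweep along a straight path.

    The probe translates from ``start`` towards ``end`` at ``acq.sweep_speed``
    with the image plane orthogonal to the motion.  Frame count follows
    floor(duration * rate) with the first frame at t = 0.  A static
    acquisition (speed 0) must state ``duration_s`` explicitly; a zero-length
    path with nonzero speed is an error.  Pixel values are sampled from the
    true (jitter-free) pixel positions; the emitted poses carry the tracking
    jitter, as a real tracker's would.
    """
    start = np.asarray(start, float).reshape(3)
    end = np.asarray(end, float).reshape(3)
    path = end - start
    path_len = float(np.linalg.norm(path))
    if acq.sweep_speed == 0.0:
        if duration_s is None or duration_s <= 0:
            raise SyntheticError("static acquisition (speed 0) needs duration_s > 0")
        duration = float(duration_s)
        u = path / path_len if path_len > 0 else np.array([0.0, 0.0, 1.0])
    else:
        if path_len == 0.0:
            raise SyntheticError("zero-length sweep path")
        duration = path_len / acq.sweep_speed if duration_s is None else float(duration_s)
        u = path / path_len
    basis = _frame_basis(u)
    rot = RigidTransform.from_matrix(basis, np.zeros(3)).rotation

    rng = np.random.default_rng(acq.seed if seed is None else seed)

    def probe_pos(t: float) -> np.ndarray:
        return start + acq.sweep_speed * t * basis[:, 2]

    # pose stream: pose_rate ticks from t=0, plus a final pose at t=duration
    # so every frame is bracketed (no extrapolation).
    n_pose = int(np.floor(duration * acq.pose_rate + 1e-9)) + 1
    pose_t = np.arange(n_pose) / acq.pose_rate
    if pose_t[-1] < duration - 1e-12:
        pose_t = np.append(pose_t, duration)
    jitter_sd = acq.tracking_jitter_rms / np.sqrt(3.0)
    jitter = (
        rng.normal(0.0, jitter_sd, size=(pose_t.size, 3))
        if jitter_sd > 0
        else np.zeros((pose_t.size, 3))
    )
    poses = [
        Pose(float(t), RigidTransform(rot, probe_pos(float(t)) + j))
        for t, j in zip(pose_t, jitter)
    ]

    rows, cols = np.indices(acq.frame_shape)
    sr, sc = acq.spacing
    img_pts = np.column_stack(
        [cols.ravel() * sc, rows.ravel() * sr, np.zeros(rows.size)]
    )
    plane_offsets = img_pts @ basis.T  # world offsets of pixel centres

    bias = acq.speed_bias(acq.sweep_speed) if acq.speed_bias is not None else 0.0

    frames: list[Frame] = []
    n_swe = int(np.floor(duration * acq.swe_rate + 1e-9))
    for i in range(n_swe):
        t = i / acq.swe_rate
        world = probe_pos(t) + plane_offsets
        vals = sample_phantom(phantom, world) + bias
        if acq.noise_sd > 0:
            vals = vals + rng.normal(0.0, acq.noise_sd, size=vals.shape)
        vals = np.maximum(vals, 0.0)
        if acq.dropout_prob > 0:
            vals[rng.random(vals.shape) < acq.dropout_prob] = 0.0
        frames.append(
            Frame(t, vals.reshape(acq.frame_shape), acq.spacing, modality="swe")
        )
    if acq.include_bmode:
        n_bm = int(np.floor(duration * acq.pose_rate + 1e-9))
        for i in range(n_bm):
            t = i / acq.pose_rate
            world = probe_pos(t) + plane_offsets
            inten = 40.0 + 30.0 * sample_phantom(phantom, world)
            frames.append(
                Frame(t, inten.reshape(acq.frame_shape), acq.spacing, modality="bmode")
            )
    frames.sort(key=lambda f: (f.t, f.modality))
    return Sweep(frames=frames, poses=poses, calibration=Calibration.identity())


def inclusion_mask(
    grid: VoxelGrid, phantom: Phantom, index: int, margin_mm: float = 1.5
) -> MaskVolume:
    """Segmentation of one inclusion on the grid lattice.

    ``margin_mm`` shrinks the region so that boundary voxels — whose samples
    straddle the interface — are excluded, as a careful manual segmentation
    would.
    """
    inc = phantom.inclusions[index]
    return MaskVolume.from_predicate(grid, lambda pts: inc.contains(pts, margin_mm))


def phantom_truth(phantom: Phantom) -> dict:
    """Ground-truth description (JSON-serialisable) for test harnesses."""
    return {
        "background_swv": phantom.background_swv,
        "inclusions": [
            {
                "shape": inc.shape,
                "center_mm": inc.center.tolist(),
                "radius_mm": inc.radius,
                "length_mm": inc.length,
                "axis": None if inc.axis is None else np.asarray(inc.axis).tolist(),
                "swv_m_s": inc.swv,
                "density_kg_m3": inc.density,
            }
            for inc in phantom.inclusions
        ],
    }


def _centered_path(
    inc: Inclusion, acq: AcquisitionModel, length_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Straight path along the inclusion axis with the FOV centred on it."""
    u = np.asarray(inc.axis if inc.axis is not None else [0.0, 0.0, 1.0])
    basis = _frame_basis(u)
    h, w = acq.frame_shape
    sr, sc = acq.spacing
    fov_offset = basis[:, 0] * (w - 1) * sc / 2.0 + basis[:, 1] * (h - 1) * sr / 2.0
    mid = inc.center - fov_offset
    return mid - u * length_mm / 2.0, mid + u * length_mm / 2.0


def simulate_speed_series(
    phantom: Phantom,
    acq: AcquisitionModel,
    speeds,
    frames_per_speed: int = 125,
    repeats: int = 3,
    inclusion: int = 0,
    voxel_spacing_mm: float = 0.5,
    margin_mm: float = 1.5,
) -> pd.DataFrame:
    """Transducer-speed experiment: reconstructed mean vs sweep speed.

    For each speed the probe crosses the chosen inclusion along its axis,
    acquiring ``frames_per_speed`` SWV frames; the inclusion mean is the
    dispersion-weighted voxel mean inside the shrunk inclusion mask.  Columns:
    speed_mm_s, mean_swv, sd_swv, n_repeats.
    """
    speeds = list(speeds)
    if not speeds:
        raise SyntheticError("speeds must be non-empty")
    inc = phantom.inclusions[inclusion]
    rows = []
    for si, speed in enumerate(speeds):
        duration = frames_per_speed / acq.swe_rate
        means = []
        for rep in range(repeats):
            seed = (acq.seed * 9973 + si * 101 + rep) % (2**31)
            acq_s = AcquisitionModel(
                **{**acq.__dict__, "sweep_speed": float(speed), "seed": seed}
            )
            if speed == 0:
                start = _centered_path(inc, acq_s, 0.0)[0]
                u = np.asarray(inc.axis if inc.axis is not None else [0, 0, 1.0])
                sweep = simulate_sweep(
                    phantom, acq_s, start, start + u, duration_s=duration
                )
            else:
                start, end = _centered_path(inc, acq_s, speed * duration)
                sweep = simulate_sweep(phantom, acq_s, start, end)
            grid = reconstruct(sweep, spacing=voxel_spacing_mm)
            mask = inclusion_mask(grid, phantom, inclusion, margin_mm=margin_mm)
            means.append(weighted_mean_swv(grid, mask))
        means = np.asarray(means)
        rows.append(
            {
                "speed_mm_s": float(speed),
                "mean_swv": float(means.mean()),
                "sd_swv": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
                "n_repeats": len(means),
            }
        )
    return pd.DataFrame(rows)
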