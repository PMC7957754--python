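"""Voxel-based volumetric reconstruction of tracked 2D sweeps.

Every valid pixel of every frame is mapped into tracker space (pose
interpolated at the frame timestamp) and binned into the 0.5 mm isotropic
voxel containing it.  A voxel accumulates the sample count ``n``, mean ``v``
and sample standard deviation ``sigma`` of everything that fell into it; the
structure-level summary is the dispersion-weighted mean

    v_bar = sum_i w_i v_i / sum_i w_i,      w_i = n_i / max(sigma_i, 0.5)

where the 0.5 m/s floor on sigma prevents singular weights in voxels whose
few samples happen to agree exactly.  The weight is used exactly in this
printed ``n/sigma`` form by default; ``weight_scheme="inverse_se"`` switches
to the literal inverse standard error ``sqrt(n)/sigma``.

The traditional 2D estimator (static probe, a handful of frames, one ROI) is
provided for comparison as :func:`mean_2d_swv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ExtrapolationError,
    Frame,
    GeometryError,
    Sweep,
    interpolate_pose,
    map_frame_to_world,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionError",
    "EmptyReconstructionError",
    "VoxelGrid",
    "MaskVolume",
    "reconstruct",
    "finalize_voxel",
    "weighted_mean_swv",
    "mean_2d_swv",
]

DEFAULT_SPACING_MM = 0.5
DEFAULT_SIGMA_FLOOR = 0.5  # m/s


class ReconstructionError(ValueError):
    pass


class EmptyReconstructionError(ReconstructionError):
    """No valid sample reached the voxel grid / the segmentation is empty."""


@dataclass
class VoxelGrid:
    """Isotropic voxel accumulator with per-voxel n, mean and spread.

    ``origin`` is the world position of the corner of voxel (0,0,0); it is
    snapped to a multiple of ``spacing`` so voxel boundaries are reproducible
    across re-runs.  Arrays are indexed ``[ix, iy, iz]``; a voxel with
    ``count == 0`` is empty and excluded from every summary.
    """

    origin: np.ndarray  # (3,), mm
    spacing: float  # mm, isotropic
    dims: tuple[int, int, int]
    count: np.ndarray  # int, samples per voxel
    mean: np.ndarray  # m/s, 0 where empty
    sigma: np.ndarray  # m/s sample sd (ddof=1), 0 where n <= 1
    sigma_floor: float = DEFAULT_SIGMA_FLOOR

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ReconstructionError("voxel spacing must be positive")

    @property
    def nonempty(self) -> np.ndarray:
        return self.count > 0

    def weights(self, scheme: str = "printed") -> np.ndarray:
        """Per-voxel weight; 0 for empty voxels."""
        denom = np.maximum(self.sigma, self.sigma_floor)
        if scheme == "printed":
            num = self.count.astype(float)
        elif scheme == "inverse_se":
            num = np.sqrt(self.count.astype(float))
        else:
            raise ReconstructionError(f"unknown weight_scheme {scheme!r}")
        return np.where(self.nonempty, num / denom, 0.0)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World-space centres (mm) of voxels given (N, 3) integer indices."""
        return self.origin + (np.asarray(indices) + 0.5) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(points) - self.origin) / self.spacing).astype(int)

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel index to the voxel centre (mm)."""
        a = np.diag([self.spacing] * 3 + [1.0])
        a[:3, 3] = self.origin + self.spacing / 2.0
        return a


@dataclass
class MaskVolume:
    """Boolean inclusion mask on the same lattice as a :class:`VoxelGrid`."""

    origin: np.ndarray
    spacing: float
    data: np.ndarray  # bool, same dims as the grid it masks

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.data = np.asarray(self.data, dtype=bool)

    @classmethod
    def full(cls, grid: VoxelGrid) -> "MaskVolume":
        return cls(grid.origin, grid.spacing, np.ones(grid.dims, dtype=bool))

    @classmethod
    def from_predicate(cls, grid: VoxelGrid, predicate) -> "MaskVolume":
        """Mask voxels whose centre satisfies ``predicate((N,3) mm) -> bool``."""
        idx = np.argwhere(np.ones(grid.dims, dtype=bool))
        centers = grid.voxel_centers(idx)
        data = np.asarray(predicate(centers), dtype=bool).reshape(grid.dims)
        return cls(grid.origin, grid.spacing, data)

    def check_matches(self, grid: VoxelGrid) -> None:
        if (
            self.data.shape != tuple(grid.dims)
            or self.spacing != grid.spacing
            or not np.allclose(self.origin, grid.origin)
        ):
            raise ReconstructionError("mask geometry does not match the voxel grid")


def finalize_voxel(
    samples, sigma_floor: float = DEFAULT_SIGMA_FLOOR
) -> tuple[float, float, int, float]:
    """Summarise one voxel's samples: (mean, sigma, n, weight).

    sigma is the n-1 sample standard deviation, defined as 0 for a single
    sample; the weight is n / max(sigma, sigma_floor).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n == 0:
        raise ReconstructionError("cannot finalize a voxel with no samples")
    v = float(np.mean(x))
    sigma = float(np.std(x, ddof=1)) if n > 1 else 0.0
    omega = n / max(sigma, sigma_floor)
    return v, sigma, n, omega


def _collect_samples(
    sweep: Sweep, modality: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map every frame of one modality to world space.

    Returns concatenated (points, values) in frame order / row-major pixel
    order, plus the number of frames skipped for lying outside the pose span.
    """
    pts_all: list[np.ndarray] = []
    val_all: list[np.ndarray] = []
    skipped = 0
    for frame in sweep.frames_of(modality):
        try:
            pose = interpolate_pose(sweep.poses, frame.t)
        except ExtrapolationError:
            skipped += 1
            continue
        pts, vals = map_frame_to_world(frame, pose, sweep.calibration)
        if pts.shape[0]:
            pts_all.append(pts)
            val_all.append(vals)
    if skipped:
        logger.warning("skipped %d frame(s) outside the pose span", skipped)
    if not pts_all:
        return np.empty((0, 3)), np.empty(0), skipped
    return np.concatenate(pts_all), np.concatenate(val_all), skipped


def reconstruct(
    sweep: Sweep,
    spacing: float = DEFAULT_SPACING_MM,
    modality: str = "swe",
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> VoxelGrid:
    """Bin a tracked sweep (or several pooled sweeps) into a voxel grid.

    The grid is the tight bounding box of all mapped samples padded by one
    voxel on every side, with the origin snapped to a multiple of ``spacing``.
    For SWV, zero pixels (failed estimates) are discarded before binning;
    B-mode keeps everything.  Statistics are computed in two passes (sums,
    then squared deviations from the voxel mean) so they agree with the
    definitional estimator to machine precision.
    """
    if spacing <= 0:
        raise ReconstructionError("voxel spacing must be positive")
    points, values, _ = _collect_samples(sweep, modality)
    if points.shape[0] == 0:
        raise EmptyReconstructionError("sweep contains no valid samples")

    idx_min = np.floor(points.min(axis=0) / spacing).astype(int) - 1
    idx_max = np.floor(points.max(axis=0) / spacing).astype(int) + 1
    dims = tuple(int(d) for d in (idx_max - idx_min + 1))
    origin = idx_min * spacing

    idx = np.floor((points - origin) / spacing).astype(int)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), dims)

    nvox = int(np.prod(dims))
    count = np.zeros(nvox, dtype=np.int64)
    total = np.zeros(nvox)
    np.add.at(count, flat, 1)
    np.add.at(total, flat, values)
    mean = np.zeros(nvox)
    occ = count > 0
    mean[occ] = total[occ] / count[occ]

    ssq = np.zeros(nvox)
    np.add.at(ssq, flat, (values - mean[flat]) ** 2)
    sigma = np.zeros(nvox)
    multi = count > 1
    sigma[multi] = np.sqrt(ssq[multi] / (count[multi] - 1))

    return VoxelGrid(
        origin=origin,
        spacing=spacing,
        dims=dims,
        count=count.reshape(dims),
        mean=mean.reshape(dims),
        sigma=sigma.reshape(dims),
        sigma_floor=sigma_floor,
    )


def weighted_mean_swv(
    grid: VoxelGrid,
    mask: MaskVolume | None = None,
    weight_scheme: str = "printed",
) -> float:
    """Dispersion-weighted mean SWV over the non-empty voxels in the mask."""
    if mask is None:
        mask = MaskVolume.full(grid)
    mask.check_matches(grid)
    sel = grid.nonempty & mask.data
    if not np.any(sel):
        raise EmptyReconstructionError("segmentation contains no non-empty voxel")
    w = grid.weights(weight_scheme)[sel]
    return float(np.sum(w * grid.mean[sel]) / np.sum(w))


def mean_2d_swv(
    frames: list[Frame],
    roi_masks: list[np.ndarray] | None = None,
    discard_zeros: bool = True,
) -> float:
    """Traditional 2D estimate: pooled pixel mean over the ROI of each frame.

    Mirrors static-probe practice where a few repeated frames share one
    manually segmented ROI.  Zero pixels are dropped by default, consistent
    with the 3D reconstruction's invalid-pixel rule.
    """
    if not frames:
        raise ReconstructionError("mean_2d_swv needs at least one frame")
    if roi_masks is None:
        roi_masks = [np.ones(f.pixels.shape, dtype=bool) for f in frames]
    if len(roi_masks) != len(frames):
        raise ReconstructionError("one ROI mask per frame required")
    pooled: list[np.ndarray] = []
    for frame, roi in zip(frames, roi_masks):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frame.pixels.shape:
            raise ReconstructionError("ROI mask shape does not match frame")
        vals = frame.pixels[roi]
        if discard_zeros:
            vals = vals[vals != 0.0]
        pooled.append(vals)
    allvals = np.concatenate(pooled)
    if allvals.size == 0:
        raise EmptyReconstructionError("ROI contains no valid pixel")
    return float(np.mean(allvals))
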