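"""Rigid-body geometry for tracked freehand ultrasound.

Maps image-plane pixels through the fixed image-to-marker calibration and the
time-interpolated probe pose into tracker (world) coordinates.  All lengths are
millimetres, all timestamps seconds.

Conventions
-----------
* Pixel centres, 0-based indices.  Image x-axis = columns (lateral),
  y-axis = rows (depth), the image plane is z = 0.
* A rigid transform acts as ``p' = R p + t``; composition ``a @ b`` applies
  ``b`` first.
* Rotations are stored as :class:`scipy.spatial.transform.Rotation`
  (internally unit quaternions); orientation interpolation is shortest-arc
  slerp, so antipodal quaternion representations cannot produce wrap-around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "ExtrapolationError",
    "RigidTransform",
    "Pose",
    "Calibration",
    "Frame",
    "Sweep",
    "compose",
    "interpolate_pose",
    "map_frame_to_world",
]


class GeometryError(ValueError):
    """Invalid geometric input (non-rigid transform, bad timestamps, ...)."""


class ExtrapolationError(GeometryError):
    """Requested time lies outside the recorded pose stream."""


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation + translation, mm)."""

    rotation: Rotation
    translation: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(t)):
            raise GeometryError("translation must be finite")
        q = self.rotation.as_quat()
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise GeometryError("rotation quaternion is not unit norm")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(Rotation.identity(), np.zeros(3))

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        """Build from a 3x3 matrix, rejecting non-rigid (improper or sheared) input."""
        m = np.asarray(rotation, dtype=float)
        if m.shape != (3, 3):
            raise GeometryError("rotation matrix must be 3x3")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-6) or np.linalg.det(m) < 0:
            raise GeometryError("matrix is not a proper rotation (orthonormal, det +1)")
        return cls(Rotation.from_matrix(m), translation)

    @classmethod
    def from_quat_trans(cls, qw, qx, qy, qz, tx, ty, tz) -> "RigidTransform":
        """Scalar-first quaternion + translation, the on-disk pose layout."""
        q = np.array([qx, qy, qz, qw], dtype=float)  # scipy is scalar-last
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise GeometryError("quaternion has zero or non-finite norm")
        return cls(Rotation.from_quat(q / n), np.array([tx, ty, tz], dtype=float))

    def quat_wxyz(self) -> np.ndarray:
        x, y, z, w = self.rotation.as_quat()
        return np.array([w, x, y, z])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return self.rotation.apply(p) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation * other.rotation,
            self.rotation.apply(other.translation) + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform(rinv, -rinv.apply(self.translation))

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation.as_matrix()
        m[:3, 3] = self.translation
        return m

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.as_matrix(), other.as_matrix(), atol=atol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b``: apply ``b`` first, then ``a``."""
    return a.compose(b)


@dataclass(frozen=True)
class Pose:
    """Timestamped rigid transform of the probe marker body in tracker space."""

    t: float
    transform: RigidTransform

    def __post_init__(self) -> None:
        if not np.isfinite(self.t):
            raise GeometryError("pose timestamp must be finite")

    @property
    def rotation(self) -> Rotation:
        return self.transform.rotation

    @property
    def translation(self) -> np.ndarray:
        return self.transform.translation


@dataclass(frozen=True)
class Calibration:
    """Fixed rigid transform from the image plane to the probe marker frame.

    The tracking hardware reports the marker body; this calibration closes the
    chain image -> marker -> tracker.  It is supplied as configuration (an
    identity default suits simulation, where the virtual probe is tracked
    directly at the image frame).
    """

    image_to_marker: RigidTransform = field(default_factory=RigidTransform.identity)

    @classmethod
    def identity(cls) -> "Calibration":
        return cls(RigidTransform.identity())


@dataclass
class Frame:
    """A single 2D ultrasound frame.

    ``modality="swe"`` frames hold shear wave velocity in m/s where a pixel
    value of exactly 0 marks a failed estimate; ``"bmode"`` frames hold
    arbitrary-unit intensity with no invalid sentinel.
    """

    t: float
    pixels: np.ndarray
    spacing: tuple[float, float]  # (row, col) pixel size, mm
    modality: str = "swe"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise GeometryError("frame pixels must be a 2D array")
        if self.modality not in ("swe", "bmode"):
            raise GeometryError(f"unknown modality {self.modality!r}")
        sr, sc = self.spacing
        if sr <= 0 or sc <= 0:
            raise GeometryError("pixel spacing must be positive")
        if self.modality == "swe" and np.any(self.pixels < 0):
            raise GeometryError("SWV pixels must be >= 0 (0 is the invalid sentinel)")


@dataclass
class Sweep:
    """One tracked acquisition: ordered frames + pose stream + calibration."""

    frames: list[Frame]
    poses: list[Pose]
    calibration: Calibration = field(default_factory=Calibration.identity)

    def __post_init__(self) -> None:
        if not self.poses:
            raise GeometryError("sweep requires at least one pose")
        pt = np.array([p.t for p in self.poses])
        if np.any(np.diff(pt) <= 0):
            raise GeometryError("pose timestamps must be strictly increasing")
        for modality in ("swe", "bmode"):
            ft = np.array([f.t for f in self.frames if f.modality == modality])
            if ft.size and np.any(np.diff(ft) <= 0):
                raise GeometryError(
                    f"{modality} frame timestamps must be strictly increasing"
                )
        n_out = sum(1 for f in self.frames if not (pt[0] <= f.t <= pt[-1]))
        if n_out:
            logger.warning(
                "%d frame(s) fall outside the pose time span [%g, %g] and will "
                "be dropped at reconstruction", n_out, pt[0], pt[-1],
            )

    @property
    def pose_times(self) -> np.ndarray:
        return np.array([p.t for p in self.poses])

    def frames_of(self, modality: str) -> list[Frame]:
        return [f for f in self.frames if f.modality == modality]


def interpolate_pose(poses: list[Pose], t: float) -> Pose:
    """Pose at time ``t``: linear translation, shortest-arc slerp rotation.

    The pose stream runs at ~7 Hz while SWE frames arrive at <= 2 Hz, so every
    frame needs an interpolated pose.  ``t`` must lie inside the recorded span;
    extrapolating beyond it would fabricate geometry and raises instead.
    """
    if not poses:
        raise GeometryError("empty pose stream")
    times = np.array([p.t for p in poses])
    if not (times[0] <= t <= times[-1]):
        raise ExtrapolationError(
            f"t={t} outside pose stream span [{times[0]}, {times[-1]}]"
        )
    i = int(np.searchsorted(times, t, side="right")) - 1
    i = max(0, min(i, len(poses) - 1))
    if times[i] == t:
        return poses[i]
    lo, hi = poses[i], poses[i + 1]
    w = (t - lo.t) / (hi.t - lo.t)
    trans = (1 - w) * lo.translation + w * hi.translation
    slerp = Slerp([lo.t, hi.t], Rotation.concatenate([lo.rotation, hi.rotation]))
    return Pose(t, RigidTransform(slerp(t), trans))


def frame_image_points(frame: Frame) -> np.ndarray:
    """In-plane coordinates (mm) of all pixel centres, row-major, z = 0."""
    rows, cols = np.indices(frame.pixels.shape)
    sr, sc = frame.spacing
    pts = np.column_stack(
        [cols.ravel() * sc, rows.ravel() * sr, np.zeros(frame.pixels.size)]
    )
    return pts


def map_frame_to_world(
    frame: Frame, pose: Pose, calib: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """Project every valid pixel of a frame into world (tracker) coordinates.

    Returns ``(points, values)`` where ``points`` is (N, 3) in mm.  For SWE
    frames, zero-valued pixels are invalid velocity estimates and are excluded
    before mapping; B-mode frames keep every pixel.
    """
    pts = frame_image_points(frame)
    values = frame.pixels.ravel()
    if frame.modality == "swe":
        keep = values != 0.0
        pts, values = pts[keep], values[keep]
    chain = pose.transform.compose(calib.image_to_marker)
    if pts.shape[0] == 0:
        return np.empty((0, 3)), np.empty(0)
    return chain.apply(pts), values.copy()
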