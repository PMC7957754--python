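"""Readers and writers for the on-disk artifacts.

* Sweep container: HDF5 with ``/swe/frames`` (N,H,W), ``/swe/t``,
  ``/bmode/frames``, ``/bmode/t``, ``/poses`` (M,8: t, qw,qx,qy,qz,
  tx,ty,tz), ``/calibration`` (qw,qx,qy,qz, tx,ty,tz) and per-modality
  ``spacing_row_mm`` / ``spacing_col_mm`` attributes.  Round trips are
  lossless.
* Reconstructed volumes: NIfTI-1, one 4D image holding the mean / sigma /
  count / weight layers with a 0.5 mm isotropic sform affine; masks are
  byte volumes with a matching affine.
* Small tables: pose logs, landmarks, ratings and profiles as CSV; stats
  and ground truth as JSON; run configuration as YAML.

All lengths are mm, timestamps seconds — the single-unit discipline that
prevents mm/m pose bugs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import Calibration, Frame, Pose, RigidTransform, Sweep
from .profile import LandmarkPair, Profile
from .reconstruction import MaskVolume, VoxelGrid
from .stats import RatingsMatrix, ReliabilityResult

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RunConfig",
    "write_sweep",
    "read_sweep",
    "read_pose_csv",
    "write_grid_nifti",
    "read_grid_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_ratings_csv",
    "write_reliability_json",
    "write_profile_csv",
]

GRID_LAYERS = ("mean", "sigma", "count", "weight")


class SchemaError(ValueError):
    """An on-disk artifact is missing fields or violates its contract."""


@dataclass
class RunConfig:
    """Resolved pipeline parameters; defaults follow the published protocol."""

    voxel_spacing_mm: float = 0.5
    sigma_floor_m_s: float = 0.5
    weight_scheme: str = "printed"
    kernel_sigma_mm: float = 5.0
    n_positions: int = 101
    alpha: float = 0.05
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def dump_alongside(self, out_path) -> None:
        p = Path(out_path)
        self.to_yaml(p.with_suffix(p.suffix + ".config.yaml"))


def _pose_rows(poses: list[Pose]) -> np.ndarray:
    rows = np.empty((len(poses), 8))
    for i, p in enumerate(poses):
        rows[i, 0] = p.t
        rows[i, 1:5] = p.transform.quat_wxyz()
        rows[i, 5:8] = p.translation
    return rows


def _poses_from_rows(rows: np.ndarray) -> list[Pose]:
    out = []
    for r in rows:
        out.append(
            Pose(float(r[0]), RigidTransform.from_quat_trans(*r[1:5], *r[5:8]))
        )
    return out


def write_sweep(sweep: Sweep, path) -> None:
    """Serialise a sweep container to HDF5 (lossless)."""
    with h5py.File(path, "w") as f:
        for modality in ("swe", "bmode"):
            frames = sweep.frames_of(modality)
            if not frames:
                continue
            g = f.create_group(modality)
            g.create_dataset(
                "frames", data=np.stack([fr.pixels for fr in frames])
            )
            g.create_dataset("t", data=np.array([fr.t for fr in frames]))
            g.attrs["spacing_row_mm"] = frames[0].spacing[0]
            g.attrs["spacing_col_mm"] = frames[0].spacing[1]
        f.create_dataset("poses", data=_pose_rows(sweep.poses))
        cal = sweep.calibration.image_to_marker
        f.create_dataset(
            "calibration",
            data=np.concatenate([cal.quat_wxyz(), cal.translation]),
        )


def read_sweep(path) -> Sweep:
    """Read a sweep container, validating the schema field by field."""
    with h5py.File(path, "r") as f:
        if "poses" not in f:
            raise SchemaError("sweep container is missing /poses")
        rows = np.asarray(f["poses"])
        if rows.ndim != 2 or rows.shape[1] != 8:
            raise SchemaError("/poses must be an (M, 8) dataset")
        if not np.all(np.isfinite(rows)):
            raise SchemaError("/poses contains non-finite values")
        if np.any(np.diff(rows[:, 0]) <= 0):
            raise SchemaError("/poses timestamps are not strictly increasing")
        if "calibration" not in f:
            raise SchemaError("sweep container is missing /calibration")
        cal_row = np.asarray(f["calibration"])
        if cal_row.shape != (7,):
            raise SchemaError("/calibration must hold 7 values (qw..qz, tx..tz)")
        frames: list[Frame] = []
        for modality in ("swe", "bmode"):
            if modality not in f:
                continue
            g = f[modality]
            for field in ("frames", "t"):
                if field not in g:
                    raise SchemaError(f"sweep container is missing /{modality}/{field}")
            for attr in ("spacing_row_mm", "spacing_col_mm"):
                if attr not in g.attrs:
                    raise SchemaError(f"/{modality} is missing attribute {attr}")
            pix = np.asarray(g["frames"])
            t = np.asarray(g["t"])
            if pix.ndim != 3 or pix.shape[0] != t.size:
                raise SchemaError(f"/{modality}/frames must be (N, H, W) matching /{modality}/t")
            if np.any(np.diff(t) <= 0):
                raise SchemaError(f"/{modality}/t is not strictly increasing")
            spacing = (float(g.attrs["spacing_row_mm"]), float(g.attrs["spacing_col_mm"]))
            frames.extend(
                Frame(float(ti), pi, spacing, modality=modality)
                for ti, pi in zip(t, pix)
            )
        frames.sort(key=lambda fr: (fr.t, fr.modality))
        poses = _poses_from_rows(rows)
        calib = Calibration(RigidTransform.from_quat_trans(*cal_row[:4], *cal_row[4:]))
    return Sweep(frames=frames, poses=poses, calibration=calib)


POSE_CSV_COLUMNS = ["t", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]


def read_pose_csv(path) -> list[Pose]:
    """Import a pose log from CSV; rows are sorted by time if shuffled."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose CSV is missing columns {missing}")
    if not np.all(np.isfinite(df[POSE_CSV_COLUMNS].to_numpy())):
        raise SchemaError("pose CSV contains non-finite values")
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        logger.warning("pose CSV timestamps out of order; sorting by t")
        df = df.sort_values("t", kind="stable")
    return _poses_from_rows(df[POSE_CSV_COLUMNS].to_numpy())


def write_grid_nifti(grid: VoxelGrid, path) -> None:
    """Export the mean/sigma/count/weight layers as one 4D NIfTI volume."""
    data = np.stack(
        [grid.mean, grid.sigma, grid.count.astype(float), grid.weights()], axis=-1
    )
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    img.header.set_sform(grid.affine, code=1)
    img.header.set_qform(grid.affine, code=1)
    img.header["pixdim"][1:4] = grid.spacing
    nib.save(img, str(path))


def read_grid_nifti(path, sigma_floor: float = 0.5) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] < 3:
        raise SchemaError("grid NIfTI must be 4D with mean/sigma/count layers")
    aff = img.affine
    spacing = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], spacing):
        raise SchemaError("grid NIfTI affine must be isotropic and axis-aligned")
    origin = aff[:3, 3] - spacing / 2.0
    return VoxelGrid(
        origin=origin,
        spacing=spacing,
        dims=data.shape[:3],
        count=np.round(data[..., 2]).astype(np.int64),
        mean=data[..., 0],
        sigma=data[..., 1],
        sigma_floor=sigma_floor,
    )


def write_mask_nifti(mask: MaskVolume, path) -> None:
    aff = np.diag([mask.spacing] * 3 + [1.0])
    aff[:3, 3] = mask.origin + mask.spacing / 2.0
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    img.header.set_sform(aff, code=1)
    nib.save(img, str(path))


def read_mask_nifti(path) -> MaskVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = float(aff[0, 0])
    origin = aff[:3, 3] - spacing / 2.0
    return MaskVolume(origin, spacing, np.asarray(img.dataobj) > 0)


def write_landmarks_csv(landmarks: LandmarkPair, path) -> None:
    pd.DataFrame(
        {
            "label": ["distal", "proximal"],
            "x_mm": [landmarks.distal[0], landmarks.proximal[0]],
            "y_mm": [landmarks.distal[1], landmarks.proximal[1]],
            "z_mm": [landmarks.distal[2], landmarks.proximal[2]],
        }
    ).to_csv(path, index=False)


def read_landmarks_csv(path) -> LandmarkPair:
    df = pd.read_csv(path)
    for col in ("label", "x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise SchemaError(f"landmark CSV is missing column {col}")
    if len(df) != 2:
        raise SchemaError("landmark CSV must have exactly two rows")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return LandmarkPair(distal=pts[0], proximal=pts[1])


def read_ratings_csv(path) -> RatingsMatrix:
    """Long-format ratings (subject, rater/session, value) -> matrix."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    subj = cols.get("subject")
    rater = cols.get("rater") or cols.get("session") or cols.get("operator")
    value = cols.get("value")
    if not (subj and rater and value):
        raise SchemaError(
            "ratings CSV needs columns subject, rater/session/operator, value"
        )
    wide = df.pivot(index=subj, columns=rater, values=value)
    if wide.isna().any().any():
        raise SchemaError("ratings CSV has missing subject x rater cells")
    return RatingsMatrix(wide.to_numpy())


def write_reliability_json(result: ReliabilityResult, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "icc": result.icc,
                "ci": [result.ci_low, result.ci_high],
                "sem": result.sem,
                "label": result.label,
                "n": result.n,
                "k": result.k,
            },
            indent=2,
        )
    )


def write_profile_csv(profile: Profile, path, compare: pd.DataFrame | None = None) -> None:
    df = profile.to_frame()
    if compare is not None:
        df = df.merge(
            compare[["position", "n_subjects", "t", "p", "significant"]],
            on="position",
            how="left",
        )
    df.to_csv(path, index=False)
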