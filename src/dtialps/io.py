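"""Reading and writing the formats the ALPS pipeline touches.

Volumes travel as NIfTI-1 (via :mod:`nibabel`): diffusion tensors as 4-D
volumes whose 4th dimension holds the six unique components of the symmetric
tensor, binary masks as unsigned 8-bit volumes.  Cohorts travel as plain CSV
with a fixed column schema.  Run configuration is YAML.

Tensor component order
----------------------
Tensors are stored lower-triangular: ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``,
the common convention of tensor-fit tooling.  Files written here carry the
order in the NIfTI ``descrip`` header field; on read, a file that declares a
*different* order is rejected rather than silently misinterpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AXIS_LABELS",
    "TENSOR_COMPONENTS",
    "MNI_2MM",
    "VolumeGeometry",
    "TensorVolume",
    "DataFormatError",
    "GeometryError",
    "CohortSchemaError",
    "read_tensor_volume",
    "write_tensor_volume",
    "read_mask",
    "write_mask",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
    "COHORT_SCHEMA_COLUMNS",
    "load_config",
    "save_config",
    "get_logger",
    "log_stage",
]

#: Anatomical meaning of the image axes after spatial normalization.
AXIS_LABELS = ("x: left-right", "y: posterior-anterior", "z: inferior-superior")

#: Storage order of the six unique symmetric-tensor components.
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

_TENSOR_DESCRIP = "tensor:" + ",".join(TENSOR_COMPONENTS)


class DataFormatError(ValueError):
    """A file's contents violate the documented format contract."""


class GeometryError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class CohortSchemaError(ValueError):
    """A cohort table violates the column schema."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid: shape in voxels and isotropic-or-not voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    axis_labels: tuple[str, str, str] = field(default=AXIS_LABELS)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(
                f"voxel_size_mm must be 3 positive reals, got {self.voxel_size_mm}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])

    def contains(self, index: tuple[int, int, int]) -> bool:
        return all(0 <= i < s for i, s in zip(index, self.shape))


#: The 2 mm MNI152 template grid the printed ROI coordinates live on.
MNI_2MM = VolumeGeometry(shape=(91, 109, 91), voxel_size_mm=(2.0, 2.0, 2.0))


@dataclass
class TensorVolume:
    """Voxel grid of symmetric diffusion tensors.

    ``data`` has shape ``(*geometry.shape, 6)`` in the
    :data:`TENSOR_COMPONENTS` order; diffusivities are in mm^2/s.
    """

    data: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (*self.geometry.shape, 6):
            raise GeometryError(
                f"tensor data shape {self.data.shape} does not match geometry "
                f"{self.geometry.shape} + (6,)"
            )

    def diagonal(self) -> np.ndarray:
        """(X, Y, Z, 3) array of the axis diffusivities (Dxx, Dyy, Dzz)."""
        return self.data[..., [0, 3, 5]]

    def as_matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) array of full symmetric tensors."""
        dxx, dxy, dxz, dyy, dyz, dzz = np.moveaxis(self.data, -1, 0)
        out = np.empty((*self.data.shape[:-1], 3, 3), dtype=np.float64)
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


def _geometry_from_header(img: nib.Nifti1Image) -> VolumeGeometry:
    zooms = img.header.get_zooms()[:3]
    return VolumeGeometry(shape=tuple(img.shape[:3]), voxel_size_mm=tuple(float(z) for z in zooms))


def read_tensor_volume(path) -> TensorVolume:
    """Read a 6-component symmetric-tensor NIfTI volume.

    Raises :class:`DataFormatError` if the 4th dimension is not exactly 6,
    if the file declares a different component order in its ``descrip``
    field, or if any values are non-finite (the error names the voxel count
    affected).
    """
    img = nib.load(str(path))
    if img.ndim != 4 or img.shape[3] != 6:
        raise DataFormatError(
            f"expected 6 tensor components in the 4th dimension, got shape {img.shape}"
        )
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode("ascii", "replace")
    if descrip.startswith("tensor:") and descrip != _TENSOR_DESCRIP:
        raise DataFormatError(
            f"file declares tensor component order {descrip!r}; this reader "
            f"expects {_TENSOR_DESCRIP!r}"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    bad = ~np.isfinite(data)
    if bad.any():
        n_vox = int(np.any(bad, axis=-1).sum())
        raise DataFormatError(f"non-finite tensor values in {n_vox} voxel(s) of {path}")
    return TensorVolume(data=data, geometry=_geometry_from_header(img))


def write_tensor_volume(volume: TensorVolume, path) -> None:
    """Write a tensor volume as 4-D NIfTI, stamping the component order."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.geometry.affine)
    img.header.set_zooms((*volume.geometry.voxel_size_mm, 1.0))
    img.header["descrip"] = _TENSOR_DESCRIP.encode("ascii")
    nib.save(img, str(path))


def read_mask(path, geometry: VolumeGeometry) -> set[tuple[int, int, int]]:
    """Read a binary mask; return the set of voxel indices with value > 0.5."""
    img = nib.load(str(path))
    if tuple(img.shape[:3]) != geometry.shape or img.ndim > 3 and any(s != 1 for s in img.shape[3:]):
        raise GeometryError(
            f"mask shape {tuple(img.shape)} does not match expected grid {geometry.shape}"
        )
    data = np.asarray(img.get_fdata()).reshape(geometry.shape)
    return {tuple(int(i) for i in idx) for idx in np.argwhere(data > 0.5)}


def write_mask(indices, geometry: VolumeGeometry, path) -> None:
    """Write a voxel-index set as an unsigned 8-bit binary NIfTI mask."""
    arr = np.zeros(geometry.shape, dtype=np.uint8)
    for idx in indices:
        if not geometry.contains(idx):
            raise GeometryError(f"mask index {idx} outside grid {geometry.shape}")
        arr[tuple(idx)] = 1
    img = nib.Nifti1Image(arr, geometry.affine)
    img.header.set_zooms(geometry.voxel_size_mm)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Cohort tables

_ORDINAL_RANGES = {
    "sex": (0, 1),
    "hypertension": (0, 1),
    "hyperlipemia": (0, 1),
    "diabetes": (0, 1),
    "smoker": (0, 1),
    "bgpvs_score": (0, 4),
    "wmpvs_score": (0, 4),
    "dmv_score": (0, 2),
}

_INT_COLUMNS = set(_ORDINAL_RANGES) | {"n_lacunes", "n_microbleeds"}

#: Required cohort columns, in canonical order.
COHORT_SCHEMA_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "hypertension",
    "hyperlipemia",
    "diabetes",
    "smoker",
    "psqi",
    "icv_ml",
    "brain_to_icv",
    "wmh_norm",
    "bgpvs_score",
    "wmpvs_score",
    "n_lacunes",
    "n_microbleeds",
    "dmv_score",
    "wmh_overlap_mm3",
    "alps_left",
    "alps_right",
    "alps_mean",
)

_ALPS_COLUMNS = ("alps_left", "alps_right", "alps_mean")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the schema; return a typed copy.

    Errors report offending row numbers (0-based positional).  ALPS columns
    may contain missing values; present values must be positive.
    """
    missing = [c for c in COHORT_SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    out = table.copy()
    if out["subject_id"].duplicated().any():
        dupes = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortSchemaError(f"duplicate subject_id values: {dupes}")
    numeric = [c for c in COHORT_SCHEMA_COLUMNS if c != "subject_id"]
    for col in numeric:
        vals = pd.to_numeric(out[col], errors="coerce")
        allow_na = col in _ALPS_COLUMNS
        bad = vals.isna() & ~(out[col].isna() if allow_na else False)
        if bad.any():
            rows = [int(r) for r in np.flatnonzero(bad.to_numpy())]
            raise CohortSchemaError(f"non-numeric values in column {col!r} at rows {rows}")
        out[col] = vals
    for col, (lo, hi) in _ORDINAL_RANGES.items():
        v = out[col].to_numpy()
        bad = (v < lo) | (v > hi) | (v != np.round(v))
        if bad.any():
            rows = [int(r) for r in np.flatnonzero(bad)]
            raise CohortSchemaError(
                f"column {col!r} must be an integer in [{lo}, {hi}]; bad rows {rows}"
            )
    for col in _INT_COLUMNS:
        out[col] = out[col].astype(np.int64)
    for col in ("n_lacunes", "n_microbleeds"):
        if (out[col] < 0).any():
            rows = [int(r) for r in np.flatnonzero((out[col] < 0).to_numpy())]
            raise CohortSchemaError(f"column {col!r} must be >= 0; bad rows {rows}")
    for col in _ALPS_COLUMNS:
        v = out[col].to_numpy(dtype=float)
        bad = np.isfinite(v) & (v <= 0)
        if bad.any():
            rows = [int(r) for r in np.flatnonzero(bad)]
            raise CohortSchemaError(f"column {col!r} must be > 0 where present; bad rows {rows}")
    return out


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.  Unknown columns are preserved."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_cohort(table)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Validate and write a cohort table as UTF-8 CSV with '.' decimals."""
    validate_cohort(table).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Config and logging

def load_config(path) -> dict:
    """Load a YAML config file into a nested dict (empty file -> {})."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise DataFormatError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def get_logger(name: str = "dtialps") -> logging.Logger:
    return logging.getLogger(name)


def log_stage(logger: logging.Logger, stage: str, seed=None, **params) -> None:
    """Log one pipeline stage's inputs, parameters and seed at INFO level."""
    items = ", ".join(f"{k}={v!r}" for k, v in sorted(params.items()))
    logger.info("stage=%s seed=%s %s", stage, seed, items)
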