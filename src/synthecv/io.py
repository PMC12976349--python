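"""File I/O: T1 maps and label rasters as NIfTI, cohort tables as CSV.

T1 maps are stored as 2D float32 NIfTI images (a singleton third dimension
is tolerated on read) with the voxel spacing in the header and the
acquisition metadata (contrast phase, field strength, subject id) in a JSON
sidecar next to the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError

COHORT_HEADER_COMMENT = "# synthecv cohort table v1"

_PHASES = ("native", "post")


@dataclass(frozen=True)
class T1Map:
    """One 2D T1 raster in milliseconds plus acquisition metadata."""

    values: np.ndarray
    spacing_mm: float
    field: float                  # tesla
    phase: str                    # "native" | "post"
    subject_id: str = ""

    def __post_init__(self):
        if self.phase not in _PHASES:
            raise FormatError(f"unknown phase {self.phase!r}")
        if self.spacing_mm <= 0:
            raise FormatError("spacing must be positive")
        if self.values.ndim != 2:
            raise FormatError("T1 map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("T1 map contains non-finite values")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _squeeze_2d(data: np.ndarray, path: Path) -> np.ndarray:
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise FormatError(f"{path}: expected a single 2D slice, got "
                              f"shape {data.shape}")
        data = data[:, :, 0]
    if data.ndim != 2:
        raise FormatError(f"{path}: expected 2D data, got shape {data.shape}")
    return data


def write_t1map(t1map: T1Map, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag([t1map.spacing_mm, t1map.spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(
        t1map.values.astype(np.float32)[:, :, np.newaxis], affine)
    img.header.set_zooms((t1map.spacing_mm, t1map.spacing_mm, 1.0))
    nib.save(img, path)
    sidecar = {"phase": t1map.phase, "field_t": t1map.field,
               "subject_id": t1map.subject_id}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_t1map(path: str | Path, phase: str | None = None,
               field: float | None = None,
               subject_id: str | None = None) -> T1Map:
    """Load a T1 map; ``phase``/``field`` override or replace the sidecar."""
    path = Path(path)
    img = nib.load(path)
    data = _squeeze_2d(np.asanyarray(img.dataobj, dtype=np.float64), path)
    zooms = img.header.get_zooms()
    if len(zooms) < 2 or zooms[0] <= 0:
        raise FormatError(f"{path}: missing voxel spacing in header")
    sidecar = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)
    phase = phase if phase is not None else sidecar.get("phase")
    field = field if field is not None else sidecar.get("field_t")
    if phase is None:
        raise FormatError(f"{path}: contrast phase not given (no sidecar "
                          "entry 'phase' and no override)")
    if field is None:
        raise FormatError(f"{path}: field strength not given (no sidecar "
                          "entry 'field_t' and no override)")
    sid = subject_id if subject_id is not None else sidecar.get("subject_id", "")
    return T1Map(values=data, spacing_mm=float(zooms[0]), field=float(field),
                 phase=phase, subject_id=sid)


def write_label_raster(raster, path: str | Path) -> None:
    from .phantom import LabelRaster  # local to avoid import cycle at load

    assert isinstance(raster, LabelRaster)
    affine = np.diag([raster.spacing_mm, raster.spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(
        raster.labels.astype(np.uint8)[:, :, np.newaxis], affine)
    img.header.set_zooms((raster.spacing_mm, raster.spacing_mm, 1.0))
    nib.save(img, Path(path))


def read_label_raster(path: str | Path):
    from .phantom import LabelRaster

    path = Path(path)
    img = nib.load(path)
    data = _squeeze_2d(np.asanyarray(img.dataobj), path).astype(np.uint8)
    zooms = img.header.get_zooms()
    raster = LabelRaster(labels=data, spacing_mm=float(zooms[0]))
    raster.validate()
    return raster


def write_mask(mask: np.ndarray, spacing_mm: float, path: str | Path) -> None:
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8)[:, :, np.newaxis], affine)
    img.header.set_zooms((spacing_mm, spacing_mm, 1.0))
    nib.save(img, Path(path))


# ---------------------------------------------------------------------------
# cohort tables


def write_cohort_table(table: pd.DataFrame, path: str | Path,
                       required: list[str] | None = None) -> None:
    from .phantom import COHORT_COLUMNS

    required = COHORT_COLUMNS if required is None else required
    validate_columns(table, required)
    with open(path, "w") as fh:
        fh.write(COHORT_HEADER_COMMENT + "\n")
        table.to_csv(fh, index=False)


def read_cohort_table(path: str | Path,
                      required: list[str] | None = None) -> pd.DataFrame:
    from .phantom import COHORT_COLUMNS

    required = COHORT_COLUMNS if required is None else required
    table = pd.read_csv(path, comment="#")
    validate_columns(table, required)
    return table


def validate_columns(table: pd.DataFrame, required: list[str]) -> None:
    for col in required:
        if col not in table.columns:
            raise FormatError(f"cohort table missing required column "
                              f"'{col}'")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
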