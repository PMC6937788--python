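"""Read/write the on-disk formats the pipeline touches.

Velocity components, magnitude and masks are stored as NIfTI volumes with the
cardiac frame as the 4th dimension (one file per velocity component); voxel
spacing is taken from the header zooms.  Cycle timing, VENC, orientation
metadata and unit scale factors travel in a JSON sidecar.  Cohort covariates
and result tables are CSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FLOW_PARAMETERS, FormatError, SegmentationCine, SubjectRecord, VelocityField4D

logger = logging.getLogger(__name__)

__all__ = [
    "read_velocity_series",
    "write_velocity_series",
    "read_mask_series",
    "write_mask_series",
    "read_subject_dir",
    "write_subject_dir",
    "write_results",
    "read_covariates",
    "write_covariates",
]

META_FILENAME = "meta.json"


def _load_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_velocity_series(
    component_paths: Sequence, metadata: Mapping
) -> VelocityField4D:
    """Read three per-component NIfTI series into a :class:`VelocityField4D`.

    ``metadata`` must provide ``rr_interval`` (s) and may provide ``venc``
    (cm/s), ``scale`` (multiplier converting stored values to cm/s, default 1)
    and ``magnitude_path``.
    """
    if len(component_paths) != 3:
        raise FormatError(f"expected 3 component paths (vx, vy, vz), got {len(component_paths)}")
    scale = float(metadata.get("scale", 1.0))
    arrays = []
    ref_shape = None
    ref_zooms = None
    ref_path = None
    for path in component_paths:
        data, zooms = _load_volume(path)
        if data.ndim == 3:  # single-frame series are promoted to one cardiac frame
            data = data[..., None]
        if ref_shape is None:
            ref_shape, ref_zooms, ref_path = data.shape, zooms, path
        else:
            if data.shape != ref_shape:
                raise FormatError(
                    f"component {path} has shape {data.shape}, expected {ref_shape} "
                    f"(as in {ref_path})"
                )
            if not np.allclose(zooms, ref_zooms):
                raise FormatError(
                    f"component {path} has spacing {zooms}, expected {ref_zooms} "
                    f"(as in {ref_path})"
                )
        arrays.append(np.asarray(data, dtype=float) * scale)
    magnitude = None
    if metadata.get("magnitude_path"):
        mag, mzooms = _load_volume(metadata["magnitude_path"])
        if mag.ndim == 3:
            mag = mag[..., None]
        if mag.shape != ref_shape or not np.allclose(mzooms, ref_zooms):
            raise FormatError(
                f"magnitude series {metadata['magnitude_path']} does not share the velocity grid"
            )
        magnitude = np.asarray(mag, dtype=float)
    return VelocityField4D(
        vx=arrays[0],
        vy=arrays[1],
        vz=arrays[2],
        spacing=ref_zooms,
        rr_interval=float(metadata["rr_interval"]),
        venc=float(metadata["venc"]) if metadata.get("venc") is not None else None,
        magnitude=magnitude,
    )


def _nifti(data: np.ndarray, spacing) -> nib.Nifti1Image:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(spacing) + (1.0,) if data.ndim == 4 else tuple(spacing))
    return img


def write_velocity_series(field: VelocityField4D, paths: Sequence) -> list[Path]:
    """Write the three components (cm/s, scale 1) as NIfTI; returns the paths."""
    if len(paths) != 3:
        raise FormatError("expected 3 output paths (vx, vy, vz)")
    written = []
    for comp, path in zip((field.vx, field.vy, field.vz), paths):
        path = Path(path)
        nib.save(_nifti(comp, field.spacing), str(path))
        written.append(path)
    return written


def read_mask_series(path, slice_axis: int = 2, apex_to_base_sign: int = 1) -> SegmentationCine:
    """Read a binary LV-cavity mask series; non-binary values are rejected."""
    data, zooms = _load_volume(path)
    if data.ndim == 3:
        data = data[..., None]
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FormatError(f"mask {path} contains non-binary values {uniq[:10]}")
    for t in range(data.shape[3]):
        if not data[..., t].any():
            raise FormatError(f"mask {path} is empty at frame {t}")
    return SegmentationCine(
        mask=data.astype(bool),
        spacing=zooms,
        slice_axis=slice_axis,
        apex_to_base_sign=apex_to_base_sign,
    )


def write_mask_series(seg: SegmentationCine, path) -> Path:
    path = Path(path)
    nib.save(_nifti(seg.mask.astype(np.uint8), seg.spacing), str(path))
    return path


# ---------------------------------------------------------------------------
# subject dataset directories


def write_subject_dir(
    out_dir,
    field: VelocityField4D,
    seg: SegmentationCine,
    record: Optional[SubjectRecord] = None,
    pathline_field: Optional[VelocityField4D] = None,
) -> Path:
    """Write one subject's dataset: vx/vy/vz/mask NIfTI files + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_velocity_series(field, [out_dir / f"v{a}.nii" for a in "xyz"])
    write_mask_series(seg, out_dir / "mask.nii")
    meta = {
        "rr_interval": field.rr_interval,
        "venc": field.venc,
        "scale": 1.0,
        "slice_axis": seg.slice_axis,
        "apex_to_base_sign": seg.apex_to_base_sign,
    }
    if pathline_field is not None:
        write_velocity_series(
            pathline_field, [out_dir / f"pathline_v{a}.nii" for a in "xyz"]
        )
        meta["pathline_rr_interval"] = pathline_field.rr_interval
    if record is not None:
        meta["subject"] = {
            "id": record.id,
            "group": record.group,
            "age": record.age,
            "sex": record.sex,
            "heart_rate": record.heart_rate,
        }
        if record.infarct_scores is not None:
            meta["subject"]["infarct_scores"] = [int(s) for s in record.infarct_scores]
    (out_dir / META_FILENAME).write_text(json.dumps(meta, indent=2))
    return out_dir


def read_subject_dir(subject_dir) -> tuple[VelocityField4D, SegmentationCine, Optional[SubjectRecord], Optional[VelocityField4D]]:
    """Load one subject's dataset written by :func:`write_subject_dir`."""
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / META_FILENAME).read_text())
    field = read_velocity_series(
        [subject_dir / f"v{a}.nii" for a in "xyz"], meta
    )
    seg = read_mask_series(
        subject_dir / "mask.nii",
        slice_axis=int(meta.get("slice_axis", 2)),
        apex_to_base_sign=int(meta.get("apex_to_base_sign", 1)),
    )
    if seg.grid_shape != field.grid_shape or not np.allclose(seg.spacing, field.spacing):
        raise FormatError(
            f"mask grid {seg.grid_shape}@{seg.spacing} does not match velocity grid "
            f"{field.grid_shape}@{field.spacing} in {subject_dir}"
        )
    record = None
    if "subject" in meta:
        s = meta["subject"]
        record = SubjectRecord(
            id=s["id"],
            group=s["group"],
            age=float(s["age"]),
            sex=s["sex"],
            heart_rate=float(s["heart_rate"]),
            infarct_scores=(
                np.asarray(s["infarct_scores"], dtype=int) if "infarct_scores" in s else None
            ),
        )
    pathline_field = None
    if (subject_dir / "pathline_vx.nii").exists():
        pathline_field = read_velocity_series(
            [subject_dir / f"pathline_v{a}.nii" for a in "xyz"],
            {
                "rr_interval": meta.get("pathline_rr_interval", meta["rr_interval"]),
                "venc": meta.get("venc"),
            },
        )
    return field, seg, record, pathline_field


# ---------------------------------------------------------------------------
# result tables


def write_results(records: Iterable[SubjectRecord], tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write the per-subject parameter table plus any analysis tables as CSV.

    ``tables`` maps a short name (e.g. ``group_effects``, ``correlations``,
    ``demographics``) to a DataFrame; each is written as ``<name>.csv``.
    Returns the mapping of table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = list(records)
    paths: dict[str, Path] = {}

    subject_path = out_dir / "subjects.csv"
    if records:
        df = pd.DataFrame([r.as_row() for r in records])
    else:
        warnings.warn("writing results for an empty cohort: header-only tables")
        df = pd.DataFrame(
            columns=["subject", "group", "age", "sex", "heart_rate", *FLOW_PARAMETERS]
        )
    df.to_csv(subject_path, index=False)
    paths["subjects"] = subject_path

    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_covariates(path) -> pd.DataFrame:
    """Read the per-subject covariate table (subject, group, age, sex, heart_rate)."""
    df = pd.read_csv(path)
    required = {"subject", "group", "age", "sex", "heart_rate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"covariate table {path} is missing columns {sorted(missing)}")
    return df


def write_covariates(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
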