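"""Core in-memory containers for time-resolved LV velocity and segmentation data.

Conventions
-----------
* Arrays are indexed ``(x, y, z, frame)``; the cardiac frame is the last axis.
* Voxel indices are 0-based; continuous positions are in mm at voxel centers,
  with world coordinate = index * spacing (co-registration is assumed upstream).
* Velocities are stored in cm/s along the grid axes.  The apex-to-base sign
  convention is applied analytically at computation time via
  :attr:`SegmentationCine.apex_to_base_sign`; stored data are never mutated.
* The cardiac cycle is periodic with duration ``rr_interval`` seconds; frame
  ``k`` samples time ``k * rr_interval / n_frames``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["VelocityField4D", "SegmentationCine", "SubjectRecord", "FormatError"]


class FormatError(ValueError):
    """Raised when on-disk data violate the expected dialect (shape, spacing, values)."""


@dataclass
class VelocityField4D:
    """Gridded 3-component velocity over space and cardiac phase.

    Parameters
    ----------
    vx, vy, vz
        4-D arrays ``(nx, ny, nz, n_frames)`` of velocity in cm/s along the
        grid axes.
    spacing
        Per-axis voxel size in mm, ``(dx, dy, dz)``.
    rr_interval
        Cardiac cycle duration in seconds.
    venc
        Velocity-encoding limit in cm/s.  Speeds beyond it are permitted
        (they would have aliased in a real acquisition) but are flagged by
        :meth:`quality_report`.
    magnitude
        Optional magnitude image on the same grid (arbitrary units).
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    spacing: tuple[float, float, float]
    rr_interval: float
    venc: Optional[float] = None
    magnitude: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.vz = np.asarray(self.vz, dtype=float)
        if not (self.vx.shape == self.vy.shape == self.vz.shape):
            raise FormatError(
                f"velocity components disagree in shape: "
                f"{self.vx.shape} / {self.vy.shape} / {self.vz.shape}"
            )
        if self.vx.ndim != 4:
            raise FormatError(f"expected 4-D (x,y,z,frame) arrays, got ndim={self.vx.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")
        if self.n_frames < 2:
            raise FormatError("at least 2 cardiac frames are required")
        if self.rr_interval <= 0:
            raise FormatError("rr_interval must be positive")
        if self.magnitude is not None and self.magnitude.shape != self.vx.shape:
            raise FormatError("magnitude image does not share the velocity grid")

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.vx.shape

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vx.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.vx.shape[3]

    @property
    def frame_interval(self) -> float:
        """Temporal spacing between cardiac frames in seconds."""
        return self.rr_interval / self.n_frames

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3  # mm^3 -> cm^3

    def frame_times(self) -> np.ndarray:
        """Sample times of the cardiac frames in seconds (frame k at k*TR)."""
        return np.arange(self.n_frames) * self.frame_interval

    # -- derived quantities -------------------------------------------------

    def speed(self) -> np.ndarray:
        """Velocity magnitude |v| in cm/s, shape (nx, ny, nz, n_frames)."""
        return np.sqrt(self.vx**2 + self.vy**2 + self.vz**2)

    def component(self, axis: int) -> np.ndarray:
        return (self.vx, self.vy, self.vz)[axis]

    def quality_report(self) -> dict:
        """Data-quality summary; speeds above VENC are flagged, never rejected."""
        speed = self.speed()
        report = {
            "n_voxels": int(speed.size),
            "max_speed_cm_s": float(speed.max()),
            "n_nonfinite": int(np.count_nonzero(~np.isfinite(speed))),
        }
        if self.venc is not None:
            report["venc_cm_s"] = float(self.venc)
            report["n_exceeding_venc"] = int(np.count_nonzero(speed > self.venc))
        return report

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            vx=self.vx.copy(),
            vy=self.vy.copy(),
            vz=self.vz.copy(),
            spacing=self.spacing,
            rr_interval=self.rr_interval,
            venc=self.venc,
            magnitude=None if self.magnitude is None else self.magnitude.copy(),
        )


@dataclass
class SegmentationCine:
    """Time-resolved binary LV-cavity mask sharing the velocity grid.

    ``slice_axis`` names the grid axis along the short-axis stack direction,
    and ``apex_to_base_sign`` is +1 when increasing index along that axis
    points from the apex toward the base (−1 otherwise).
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    apex_to_base_sign: int = 1

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 4:
            raise FormatError(f"expected 4-D (x,y,z,frame) mask, got ndim={mask.ndim}")
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask must be binary; found values {uniq[:10]}")
        self.mask = mask.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.slice_axis not in (0, 1, 2):
            raise FormatError("slice_axis must be one of the three spatial axes (0, 1, 2)")
        if self.apex_to_base_sign not in (-1, 1):
            raise FormatError("apex_to_base_sign must be +1 or -1")
        for t in range(self.n_frames):
            if not self.mask[..., t].any():
                raise FormatError(f"segmentation empty at frame {t}")

    @property
    def n_frames(self) -> int:
        return self.mask.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape[:3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3  # mm^3 -> mL

    def volume_curve_ml(self) -> np.ndarray:
        """Cavity volume (mL) per cardiac frame, by voxel counting."""
        counts = self.mask.reshape(-1, self.n_frames).sum(axis=0)
        return counts * self.voxel_volume_ml

    def slice_mask(self, slice_index: int, frame: int) -> np.ndarray:
        return np.take(self.mask[..., frame], slice_index, axis=self.slice_axis)


# the 11 LV flow parameters carried through the cohort analysis
FLOW_PARAMETERS = (
    "peak_systolic_flow_base",
    "peak_systolic_flow_mid",
    "peak_systolic_flow_apex",
    "peak_diastolic_flow_base",
    "peak_diastolic_flow_mid",
    "peak_diastolic_flow_apex",
    "kei_edv",
    "direct_flow_pct",
    "retained_inflow_pct",
    "delayed_ejection_pct",
    "residual_volume_pct",
)


@dataclass
class SubjectRecord:
    """Per-subject covariates plus the flow parameters filled in by the pipeline."""

    id: str
    group: str  # "control" or "AMI"
    age: float
    sex: str  # "F" or "M"
    heart_rate: float
    infarct_scores: Optional[np.ndarray] = None
    strain: dict = field(default_factory=dict)
    flow_parameters: dict = field(default_factory=dict)
    function: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "AMI"):
            raise ValueError(f"group must be 'control' or 'AMI', got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    def as_row(self) -> dict:
        row = {
            "subject": self.id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "heart_rate": self.heart_rate,
        }
        row.update(self.function)
        row.update(self.flow_parameters)
        return row
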