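"""Regional through-plane flow curves, peak flows, and kinetic energy.

The LV long axis (short-axis stack direction) is divided at end diastole into
three equal-length physical segments — base, mid-ventricle, apex — and each
short-axis slice is labeled by its center coordinate.  Through-plane flow per
slice is the mean signed through-plane velocity over in-mask voxels times the
in-mask cross-sectional area; regional flow is the arithmetic mean of the
member slice curves.  The sign convention is positive from the apex to the
base, so systolic ejection is positive and diastolic filling negative.

Kinetic energy is the cycle-average of the summed per-voxel KE over the LV,
KE_avg = (1/N_t) * sum_t sum_vox (1/2) rho V_vox |v|^2 with blood density
rho = 1.06 g/cm^3, reported in microjoules and indexed to EDV (KEi_EDV,
uJ/mL).  Regional KE is deliberately not computed: the squared-velocity term
is dominated by high-velocity voxels and too noise-sensitive in slow-flow
regions to subdivide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SegmentationCine, VelocityField4D

logger = logging.getLogger(__name__)

__all__ = [
    "RegionPartition",
    "FlowCurveSet",
    "FlowPeaks",
    "KEResult",
    "partition_regions",
    "throughplane_flow",
    "peak_flows",
    "kinetic_energy",
]

RHO_BLOOD = 1.06  # g/cm^3
REGIONS = ("base", "mid", "apex")
ERG_TO_UJ = 0.1


@dataclass
class RegionPartition:
    """Slice-to-region assignment along the LV long axis.

    ``labels[i]`` is the region of grid slice i ('base'/'mid'/'apex'/'outside');
    ``apex_mm``/``base_mm`` are the axial coordinates of the apical-most and
    basal-most in-mask slice centers at ED, between which the three
    equal-length thirds are laid out.
    """

    labels: np.ndarray  # (n_slices,) of str
    apex_mm: float
    base_mm: float
    slice_axis: int
    spacing_mm: float  # along the slice axis

    def slices(self, region: str) -> np.ndarray:
        return np.nonzero(self.labels == region)[0]

    def label_coordinate(self, axial_mm: float) -> str:
        """Region label for an arbitrary axial coordinate (mm).

        Coordinates beyond the basal-most slice center map to 'base' (valve
        plane side) and beyond the apical tip to 'apex'.
        """
        s = (axial_mm - self.apex_mm) / (self.base_mm - self.apex_mm)
        if s < 1.0 / 3.0:
            return "apex"
        if s < 2.0 / 3.0:
            return "mid"
        return "base"


def partition_regions(seg: SegmentationCine, ed_frame: int | None = None) -> RegionPartition:
    """Divide the ED long-axis extent into three equal-length thirds.

    The extent runs from the center of the apical-most to the center of the
    basal-most in-mask slice at end diastole.  Thirds are closed-open going
    from apex to base, with the basal interval closed at the top.
    """
    if ed_frame is None:
        ed_frame = int(np.argmax(seg.volume_curve_ml()))
    mask_ed = seg.mask[..., ed_frame]
    in_plane_axes = tuple(ax for ax in range(3) if ax != seg.slice_axis)
    slice_counts = mask_ed.sum(axis=in_plane_axes)
    in_mask = np.nonzero(slice_counts > 0)[0]
    if len(in_mask) < 3:
        raise ValueError(
            f"regional partition needs at least 3 in-mask slices, found {len(in_mask)}"
        )
    spacing = seg.spacing[seg.slice_axis]
    lo, hi = in_mask.min() * spacing, in_mask.max() * spacing
    if seg.apex_to_base_sign > 0:
        apex_mm, base_mm = lo, hi
    else:
        apex_mm, base_mm = hi, lo

    n_slices = seg.mask.shape[seg.slice_axis]
    labels = np.full(n_slices, "outside", dtype=object)
    length = base_mm - apex_mm
    in_mask_set = set(in_mask.tolist())
    for i in range(n_slices):
        if i not in in_mask_set:
            continue
        s = (i * spacing - apex_mm) / length  # 0 at apex, 1 at base
        if s < 1.0 / 3.0:
            labels[i] = "apex"
        elif s < 2.0 / 3.0:
            labels[i] = "mid"
        else:
            labels[i] = "base"
    return RegionPartition(
        labels=np.asarray(labels),
        apex_mm=float(apex_mm),
        base_mm=float(base_mm),
        slice_axis=seg.slice_axis,
        spacing_mm=float(spacing),
    )


@dataclass
class FlowCurveSet:
    """Per-slice and per-region through-plane flow (L/min) versus cardiac frame.

    ``slice_flow[i, t]`` is NaN where slice i is outside the LV or empty at
    frame t; region curves average the member slices, skipping empty ones.
    """

    slice_flow: np.ndarray  # (n_slices, n_frames)
    region_flow: dict  # region -> (n_frames,)
    frame_interval: float  # s

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.slice_flow,
            index=[f"slice_{i}" for i in range(self.slice_flow.shape[0])],
        )
        for region, curve in self.region_flow.items():
            df.loc[f"region_{region}"] = curve
        df.columns = [f"frame_{t}" for t in range(self.slice_flow.shape[1])]
        return df


def throughplane_flow(
    field: VelocityField4D, seg: SegmentationCine, partition: RegionPartition
) -> FlowCurveSet:
    """Per-slice flow = mean signed through-plane velocity x in-mask area.

    The through-plane component is the velocity along the slice-stack axis,
    signed so that apex-to-base is positive; the cross-sectional area is the
    in-mask voxel count at that frame times the in-plane voxel area (the mask
    is time-resolved, so the area follows the per-frame segmentation).
    Result in L/min (cm^3/s x 0.06).
    """
    axis = seg.slice_axis
    v = field.component(axis) * seg.apex_to_base_sign  # cm/s, positive apex->base
    in_plane_axes = tuple(ax for ax in range(3) if ax != axis)
    area_per_voxel = (
        field.spacing[in_plane_axes[0]] * field.spacing[in_plane_axes[1]] / 100.0
    )  # cm^2

    mask = seg.mask
    counts = mask.sum(axis=in_plane_axes)  # (n_slices, n_frames)
    # mean velocity per slice/frame: sum of masked v / count
    vsum = (v * mask).sum(axis=in_plane_axes)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_v = np.where(counts > 0, vsum / np.maximum(counts, 1), np.nan)
    slice_flow = mean_v * counts * area_per_voxel * 0.06  # L/min
    slice_flow = np.where(counts > 0, slice_flow, np.nan)

    # slices the partition calls 'outside' carry no flow curve
    outside = partition.labels == "outside"
    slice_flow[outside, :] = np.nan

    region_flow = {}
    for region in REGIONS:
        members = partition.slices(region)
        if len(members) == 0:
            region_flow[region] = np.full(seg.n_frames, np.nan)
            continue
        block = slice_flow[members, :]
        n_empty = int(np.isnan(block).sum())
        if n_empty:
            logger.info(
                "region %s: %d empty slice-frames skipped in the regional average",
                region,
                n_empty,
            )
        with np.errstate(invalid="ignore"):
            region_flow[region] = np.nanmean(block, axis=0)
    return FlowCurveSet(
        slice_flow=slice_flow,
        region_flow=region_flow,
        frame_interval=field.frame_interval,
    )


@dataclass
class FlowPeaks:
    """Peak systolic (max positive) and diastolic (|max negative|) regional flow."""

    peak_systolic: dict  # region -> L/min, >= 0 by sign convention at peak
    peak_diastolic: dict  # region -> L/min, magnitude of the most negative flow
    systolic_frame: dict
    diastolic_frame: dict


def peak_flows(curves: FlowCurveSet) -> FlowPeaks:
    """Extract regional flow extrema; the earliest frame wins ties."""
    peak_s, peak_d, frame_s, frame_d = {}, {}, {}, {}
    for region, curve in curves.region_flow.items():
        if np.all(np.isnan(curve)):
            raise ValueError(f"region {region} has an all-NaN flow curve")
        imax = int(np.nanargmax(curve))
        imin = int(np.nanargmin(curve))
        peak_s[region] = float(curve[imax])
        peak_d[region] = float(abs(curve[imin]))
        frame_s[region] = imax
        frame_d[region] = imin
    return FlowPeaks(
        peak_systolic=peak_s,
        peak_diastolic=peak_d,
        systolic_frame=frame_s,
        diastolic_frame=frame_d,
    )


@dataclass
class KEResult:
    ke_avg_uj: float
    kei_edv_uj_ml: float
    rho_g_cm3: float = RHO_BLOOD


def kinetic_energy(field: VelocityField4D, seg: SegmentationCine, edv_ml: float) -> KEResult:
    """Whole-LV cycle-averaged kinetic energy (uJ) and its EDV index (uJ/mL).

    KE per voxel is (1/2) rho V_vox |v|^2 in erg (g cm^2/s^2, v in cm/s,
    V_vox in cm^3); the sum runs over in-mask voxels per frame and the
    average over cardiac frames.  1 erg = 0.1 uJ.
    """
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    speed2 = field.vx**2 + field.vy**2 + field.vz**2
    ke_per_frame_erg = (
        0.5 * RHO_BLOOD * field.voxel_volume_cm3 * (speed2 * seg.mask).sum(axis=(0, 1, 2))
    )
    ke_avg = float(ke_per_frame_erg.mean()) * ERG_TO_UJ
    return KEResult(ke_avg_uj=ke_avg, kei_edv_uj_ml=ke_avg / edv_ml)
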