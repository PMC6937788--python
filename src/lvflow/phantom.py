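"""Synthetic 4D-flow phantoms and cohorts with analytic ground truth.

Two image phantoms are provided:

* a *deforming half-ellipsoid ventricle* — closed apex, open base, wall radius
  ``r_w(z,t) = R(t) * sqrt(1 - ((L-z)/L)^2)`` with ``R(t) = R0 * (1 - alpha *
  sin^2(pi t / T))``.  Axial velocity is uniform over each cross-section and
  chosen so that the slice flux exactly balances the apical volume change
  (mass conservation in closed form); radial velocity follows the wall.  The
  first half of the cycle is systolic (R decreasing), so end diastole is
  frame 0 and the flow sign convention (positive = apex-to-base) makes
  systolic flow positive.

* a *plug-flow cylinder* — static mask, spatially uniform axial velocity,
  positive (toward the base) during systole with total displacement ``d_out``
  and negative during diastole with displacement ``d_in``.  Because motion is
  a rigid axial shift, the four flow compartments reduce to 1-D slab
  overlaps along the axis and are known exactly.

Per-frame velocity samples of the plug phantom are chosen so that the
piecewise-linear interpolation used by the tracker integrates to *exactly*
``d_in``/``d_out`` (the plateau value compensates the zero-velocity samples
at the valve-switch frames); compartment truth is therefore limited only by
seed voxelization.

A parametric cohort simulator plants covariate-confounded group effects in
the 11 flow parameters for validating the adjusted statistical model, and can
materialize image data per subject by modulating the ellipsoid phantom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import FLOW_PARAMETERS, SegmentationCine, SubjectRecord, VelocityField4D
from .preprocessing import PolyCoeffs, evaluate_background

logger = logging.getLogger(__name__)

__all__ = [
    "EllipsoidPhantomConfig",
    "PlugPhantomConfig",
    "CohortSimConfig",
    "PhantomTruth",
    "make_ellipsoid_phantom",
    "make_plug_phantom",
    "plug_truth_fractions",
    "plant_background_phase",
    "add_velocity_noise",
    "simulate_cohort",
    "materialize_cohort",
    "simulate_infarct_scores",
]


class ConfigError(ValueError):
    """Raised when a phantom configuration is geometrically impossible."""


@dataclass
class PhantomTruth:
    """Closed-form reference quantities carried alongside a phantom."""

    slice_flow_l_min: np.ndarray  # (n_slices, n_frames), analytic, apex->base positive
    volume_curve_ml: np.ndarray  # (n_frames,)
    ed_frame: int
    es_frame: int
    apex_mm: float  # axial coordinate of the apex (z of the closed tip)
    base_mm: float  # axial coordinate of the open base plane
    phase_coeffs: Optional[PolyCoeffs] = None
    compartment_fractions_pct: Optional[dict] = None

    @property
    def edv_ml(self) -> float:
        return float(self.volume_curve_ml.max())

    @property
    def esv_ml(self) -> float:
        return float(self.volume_curve_ml.min())


# ---------------------------------------------------------------------------
# deforming half-ellipsoid ventricle


@dataclass
class EllipsoidPhantomConfig:
    r0_cm: float = 2.0  # end-diastolic basal radius
    length_cm: float = 8.0  # apex-to-base long-axis length
    alpha: float = 0.2  # radial contraction fraction, R_es = R0*(1-alpha)
    n_frames: int = 20
    rr_interval: float = 1.0  # s
    shape: tuple[int, int, int] = (40, 40, 72)
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)  # mm
    noise_sd: float = 0.0  # cm/s, added after truth is recorded
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ConfigError("contraction fraction alpha must lie in [0, 1)")
        if self.n_frames < 2:
            raise ConfigError("need at least 2 frames")
        # phantom must fit inside the grid with >= 2 voxels margin on all sides
        margin = 2
        r_mm = self.r0_cm * 10.0
        l_mm = self.length_cm * 10.0
        for ax in (0, 1):
            half_extent = (self.shape[ax] - 1) / 2 * self.spacing[ax]
            if r_mm > half_extent - margin * self.spacing[ax]:
                raise ConfigError(
                    f"phantom radius {r_mm} mm exceeds grid axis {ax} "
                    f"(half extent {half_extent} mm, margin {margin} voxels)"
                )
        z_extent = (self.shape[2] - 1) * self.spacing[2]
        if l_mm > z_extent - 2 * margin * self.spacing[2]:
            raise ConfigError(
                f"phantom length {l_mm} mm exceeds grid z extent {z_extent} mm with margin"
            )


def _radius_and_rate(cfg: EllipsoidPhantomConfig, t: np.ndarray):
    """R(t) in cm and dR/dt in cm/s for the contraction law."""
    T = cfg.rr_interval
    R = cfg.r0_cm * (1.0 - cfg.alpha * np.sin(np.pi * t / T) ** 2)
    dR = -cfg.r0_cm * cfg.alpha * (np.pi / T) * np.sin(2.0 * np.pi * t / T)
    return R, dR


def make_ellipsoid_phantom(
    cfg: EllipsoidPhantomConfig,
) -> tuple[VelocityField4D, SegmentationCine, PhantomTruth]:
    """Build the deforming half-ellipsoid phantom with its analytic truth.

    The apical volume up to height z (cm above the apex) is
    ``V(z,t) = pi R(t)^2 g(z)`` with ``g(z) = 2L/3 - (L-z) + (L-z)^3/(3L^2)``,
    so the flux through the plane at z is ``Q(z,t) = -dV/dt = -2 pi R R' g(z)``
    and the uniform axial velocity is ``v_z = Q / (pi r_w^2)``.  The radial
    velocity is ``v_r = (R'/R) r``, i.e. material points follow the wall.
    """
    nx, ny, nz = cfg.shape
    dx, dy, dz = cfg.spacing
    L = cfg.length_cm
    t = np.arange(cfg.n_frames) * cfg.rr_interval / cfg.n_frames
    R, dR = _radius_and_rate(cfg, t)

    # grid coordinates (mm); apex placed a small margin above the grid floor
    xc = (nx - 1) / 2 * dx
    yc = (ny - 1) / 2 * dy
    apex_mm = 2 * dz
    x = np.arange(nx) * dx - xc
    y = np.arange(ny) * dy - yc
    z = np.arange(nz) * dz
    z_cm = (z - apex_mm) / 10.0  # height above apex, cm

    # analytic per-slice profiles
    u = L - z_cm
    g = np.where(
        (z_cm >= 0) & (z_cm <= L), 2 * L / 3 - u + u**3 / (3 * L**2), 0.0
    )
    gprime = np.where((z_cm >= 0) & (z_cm <= L), 1.0 - u**2 / L**2, 0.0)

    flux_cm3_s = -2.0 * np.pi * R[None, :] * dR[None, :] * g[:, None]  # (nz, nt)
    slice_flow = flux_cm3_s * 0.06  # cm^3/s -> L/min
    volume_ml = (2.0 / 3.0) * np.pi * R**2 * L  # cm^3 == mL

    # axial velocity: v_z = Q / A = -2 R R' g / (R^2 g') ; 0 where area vanishes
    with np.errstate(divide="ignore", invalid="ignore"):
        vz_profile = np.where(
            gprime[:, None] > 0,
            -2.0 * dR[None, :] / R[None, :] * g[:, None] / gprime[:, None],
            0.0,
        )  # (nz, nt), cm/s

    r2 = (x[:, None] ** 2 + y[None, :] ** 2) / 100.0  # cm^2, in-plane radius^2
    rw2 = (R[None, :] ** 2) * gprime[:, None]  # (nz, nt) wall radius^2, cm^2
    inside = r2[:, :, None, None] <= rw2[None, None, :, :]  # (nx, ny, nz, nt)
    inside &= ((z_cm >= 0) & (z_cm <= L))[None, None, :, None]

    vz = np.where(inside, vz_profile[None, None, :, :], 0.0)
    # radial velocity v_r = (R'/R) r  ->  vx = (R'/R) x, vy = (R'/R) y (cm/s, x in cm)
    rate = (dR / R)[None, None, None, :]
    vx = np.where(inside, rate * (x[:, None, None, None] / 10.0), 0.0)
    vy = np.where(inside, rate * (y[None, :, None, None] / 10.0), 0.0)

    field = VelocityField4D(
        vx=vx, vy=vy, vz=vz, spacing=cfg.spacing, rr_interval=cfg.rr_interval, venc=150.0
    )
    seg = SegmentationCine(
        mask=inside, spacing=cfg.spacing, slice_axis=2, apex_to_base_sign=1
    )
    truth = PhantomTruth(
        slice_flow_l_min=slice_flow,
        volume_curve_ml=volume_ml,
        ed_frame=int(np.argmax(volume_ml)),
        es_frame=int(np.argmin(volume_ml)),
        apex_mm=apex_mm,
        base_mm=apex_mm + L * 10.0,
    )
    if cfg.noise_sd > 0:
        field = add_velocity_noise(field, cfg.noise_sd, cfg.seed)
    return field, seg, truth


# ---------------------------------------------------------------------------
# plug-flow cylinder


@dataclass
class PlugPhantomConfig:
    radius_cm: float = 1.5
    length_cm: float = 8.0
    d_in_cm: float = 4.0  # diastolic inflow displacement
    d_out_cm: float = 4.0  # systolic outflow displacement
    n_frames: int = 20
    rr_interval: float = 1.0
    shape: tuple[int, int, int] = (16, 16, 44)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def __post_init__(self) -> None:
        if self.n_frames < 4 or self.n_frames % 2:
            raise ConfigError("plug phantom needs an even frame count >= 4")
        if not 0 <= self.d_in_cm <= self.length_cm:
            raise ConfigError("d_in must lie in [0, length]")
        if not 0 <= self.d_out_cm <= self.length_cm:
            raise ConfigError("d_out must lie in [0, length]")
        if 2 * self.radius_cm * 10 > (min(self.shape[:2]) - 4) * min(self.spacing[:2]):
            raise ConfigError("cylinder radius does not fit the grid with margin")
        if self.length_cm * 10 > (self.shape[2] - 6) * self.spacing[2]:
            raise ConfigError("cylinder length does not fit the grid with margin")


def plug_truth_fractions(cfg: PlugPhantomConfig) -> dict:
    """Exact compartment fractions from 1-D slab overlaps along the axis.

    A particle at end-diastolic height z0 (above the closed end) entered
    during diastole iff z0 > L - d_in and leaves during systole iff
    z0 > L - d_out; the four compartments are the overlaps of those slabs.
    """
    L, din, dout = cfg.length_cm, cfg.d_in_cm, cfg.d_out_cm
    direct = min(din, dout) / L
    retained = max(0.0, din - dout) / L
    delayed = max(0.0, dout - din) / L
    residual = (L - max(din, dout)) / L
    return {
        "direct_flow_pct": 100.0 * direct,
        "retained_inflow_pct": 100.0 * retained,
        "delayed_ejection_pct": 100.0 * delayed,
        "residual_volume_pct": 100.0 * residual,
    }


def make_plug_phantom(
    cfg: PlugPhantomConfig,
) -> tuple[VelocityField4D, SegmentationCine, PhantomTruth]:
    """Static cylinder with spatially uniform, time-varying axial plug flow.

    Frames 0 and n/2 (end diastole / end systole) carry zero velocity; the
    remaining systolic (diastolic) frames carry a constant plateau whose
    trapezoidal integral over the half cycle equals d_out (−d_in) exactly.
    """
    nx, ny, nz = cfg.shape
    dx, dy, dz = cfg.spacing
    n2 = cfg.n_frames // 2
    dt = cfg.rr_interval / cfg.n_frames

    v_frame = np.zeros(cfg.n_frames)
    if n2 > 1:
        v_frame[1:n2] = cfg.d_out_cm / (dt * (n2 - 1))  # systole: toward base (+z)
        v_frame[n2 + 1 :] = -cfg.d_in_cm / (dt * (n2 - 1))  # diastole: toward apex

    xc = (nx - 1) / 2 * dx
    yc = (ny - 1) / 2 * dy
    bottom_mm = 2 * dz
    x = np.arange(nx) * dx - xc
    y = np.arange(ny) * dy - yc
    z = np.arange(nz) * dz
    in_plane = (x[:, None] ** 2 + y[None, :] ** 2) <= (cfg.radius_cm * 10.0) ** 2
    # half-open axial interval: L/dz voxel slabs tile the length exactly,
    # so voxel-center seeds align with the analytic slab boundaries
    in_axis = (z >= bottom_mm) & (z < bottom_mm + cfg.length_cm * 10.0)
    mask3 = in_plane[:, :, None] & in_axis[None, None, :]
    mask = np.repeat(mask3[..., None], cfg.n_frames, axis=3)

    vz = np.where(mask, v_frame[None, None, None, :], 0.0)
    zeros = np.zeros_like(vz)
    field = VelocityField4D(
        vx=zeros, vy=zeros.copy(), vz=vz, spacing=cfg.spacing,
        rr_interval=cfg.rr_interval, venc=150.0,
    )
    seg = SegmentationCine(mask=mask, spacing=cfg.spacing, slice_axis=2, apex_to_base_sign=1)

    volume_ml = np.full(cfg.n_frames, mask3.sum() * np.prod(cfg.spacing) * 1e-3)
    area_cm2 = np.pi * cfg.radius_cm**2
    slice_flow = np.zeros((nz, cfg.n_frames))
    slice_flow[in_axis, :] = v_frame[None, :] * area_cm2 * 0.06
    truth = PhantomTruth(
        slice_flow_l_min=slice_flow,
        volume_curve_ml=volume_ml,
        ed_frame=0,
        es_frame=n2,
        apex_mm=bottom_mm,
        base_mm=bottom_mm + cfg.length_cm * 10.0,
        compartment_fractions_pct=plug_truth_fractions(cfg),
    )
    return field, seg, truth


# ---------------------------------------------------------------------------
# corruptions


def plant_background_phase(field: VelocityField4D, coeffs: PolyCoeffs) -> VelocityField4D:
    """Add a time-constant cubic polynomial offset to every frame of each component."""
    offsets = evaluate_background(coeffs, field.grid_shape)
    out = field.copy()
    out.vx += offsets[0][..., None]
    out.vy += offsets[1][..., None]
    out.vz += offsets[2][..., None]
    return out


def add_velocity_noise(field: VelocityField4D, sd: float, seed: int) -> VelocityField4D:
    """Add i.i.d. zero-mean Gaussian noise (cm/s) per component, reproducibly."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    out = field.copy()
    if sd == 0:
        return out
    rng = np.random.default_rng(seed)
    out.vx += rng.normal(0.0, sd, size=field.shape)
    out.vy += rng.normal(0.0, sd, size=field.shape)
    out.vz += rng.normal(0.0, sd, size=field.shape)
    return out


# ---------------------------------------------------------------------------
# cohort simulation


#: adjusted AMI-minus-control effects planted by default (outcome units)
DEFAULT_GROUP_EFFECTS = {
    "peak_systolic_flow_base": -2.1,
    "peak_systolic_flow_mid": -3.9,
    "peak_systolic_flow_apex": -1.4,
    "peak_diastolic_flow_base": 1.1,
    "peak_diastolic_flow_mid": -1.6,
    "peak_diastolic_flow_apex": -2.4,
    "kei_edv": -0.9,
    "direct_flow_pct": -41.0,
    "retained_inflow_pct": 12.0,
    "delayed_ejection_pct": 8.0,
    "residual_volume_pct": 21.0,
}

#: control-group baselines for the 11 flow parameters (outcome units)
DEFAULT_BASELINES = {
    "peak_systolic_flow_base": 16.2,
    "peak_systolic_flow_mid": 8.5,
    "peak_systolic_flow_apex": 2.2,
    "peak_diastolic_flow_base": 18.6,
    "peak_diastolic_flow_mid": 12.0,
    "peak_diastolic_flow_apex": 3.1,
    "kei_edv": 11.3,
    "direct_flow_pct": 58.0,
    "retained_inflow_pct": 15.0,
    "delayed_ejection_pct": 16.0,
    "residual_volume_pct": 7.0,
}


@dataclass
class CohortSimConfig:
    """Two-group cohort with planted, covariate-confounded flow effects.

    Covariate distributions default to a typical young-volunteer control
    group (40±16 y, 60±10 bpm, 10/19 male) versus an older, faster-heart-rate
    infarct group (66±12 y, 79±15 bpm, 11/12 male), so age/sex/HR confound
    the unadjusted group contrast by construction.
    """

    n_control: int = 19
    n_ami: int = 12
    group_effects: dict = dfield(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    baselines: dict = dfield(default_factory=lambda: dict(DEFAULT_BASELINES))
    # per-parameter (b_age, b_sex, b_hr): outcome units per year / per (M vs F) / per bpm
    covariate_coeffs: dict = dfield(default_factory=dict)
    default_covariate_coeffs: tuple[float, float, float] = (-0.03, 0.5, -0.04)
    age_mean_sd: dict = dfield(
        default_factory=lambda: {"control": (40.0, 16.0), "AMI": (66.0, 12.0)}
    )
    hr_mean_sd: dict = dfield(
        default_factory=lambda: {"control": (60.0, 10.0), "AMI": (79.0, 15.0)}
    )
    male_fraction: dict = dfield(
        default_factory=lambda: {"control": 10 / 19, "AMI": 11 / 12}
    )
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_ami < 2:
            raise ConfigError("need at least 2 subjects per group")


def simulate_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """Draw covariates and flow-parameter outcomes for a two-group cohort.

    Outcome = baseline + b_age*(age-50) + b_sex*sex + b_hr*(HR-70)
    + effect*group + N(0, residual_sd); centering keeps baselines near their
    nominal values.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, n in (("control", cfg.n_control), ("AMI", cfg.n_ami)):
        age_m, age_s = cfg.age_mean_sd[group]
        hr_m, hr_s = cfg.hr_mean_sd[group]
        for i in range(n):
            age = float(np.clip(rng.normal(age_m, age_s), 18.0, 95.0))
            hr = float(np.clip(rng.normal(hr_m, hr_s), 35.0, 140.0))
            sex = "M" if rng.random() < cfg.male_fraction[group] else "F"
            row = {
                "subject": f"{group.lower()}_{i:03d}",
                "group": group,
                "age": age,
                "sex": sex,
                "heart_rate": hr,
            }
            for name in FLOW_PARAMETERS:
                b_age, b_sex, b_hr = cfg.covariate_coeffs.get(
                    name, cfg.default_covariate_coeffs
                )
                value = (
                    cfg.baselines.get(name, 0.0)
                    + b_age * (age - 50.0)
                    + b_sex * (sex == "M")
                    + b_hr * (hr - 70.0)
                    + cfg.group_effects.get(name, 0.0) * (group == "AMI")
                    + rng.normal(0.0, cfg.residual_sd)
                )
                row[name] = value
            rows.append(row)
    return pd.DataFrame(rows)


def materialize_cohort(
    cohort: pd.DataFrame,
    out_dir,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (24, 24, 40),
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5),
    n_frames: int = 20,
) -> list[Path]:
    """Write per-subject ellipsoid-phantom image datasets for a simulated cohort.

    Contractility is modulated by group (controls contract more than infarct
    subjects) and the cycle length follows each subject's heart rate, so the
    imaging pipeline recovers group differences in regional flow and EF.
    Subject directories are written through the io module; returns the paths.
    """
    from . import io as lvio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for _, row in cohort.iterrows():
        alpha_mean = 0.45 if row["group"] == "control" else 0.25
        alpha = float(np.clip(rng.normal(alpha_mean, 0.03), 0.05, 0.6))
        r0 = float(np.clip(rng.normal(1.7, 0.08), 1.5, 1.9))
        cfg = EllipsoidPhantomConfig(
            r0_cm=r0,
            length_cm=7.0,
            alpha=alpha,
            n_frames=n_frames,
            rr_interval=60.0 / float(row["heart_rate"]),
            shape=grid_shape,
            spacing=spacing,
            noise_sd=0.5,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        field, seg, _ = make_ellipsoid_phantom(cfg)
        record = SubjectRecord(
            id=str(row["subject"]),
            group=str(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            heart_rate=float(row["heart_rate"]),
        )
        path = lvio.write_subject_dir(out_dir / record.id, field, seg, record)
        paths.append(path)
    lvio.write_covariates(
        cohort[["subject", "group", "age", "sex", "heart_rate"]],
        out_dir / "covariates.csv",
    )
    return paths


def simulate_infarct_scores(
    n_subjects: int, distribution, seed: int = 0
) -> np.ndarray:
    """Draw per-subject 17-segment transmurality scores in {0..4}.

    ``distribution`` is a length-5 probability vector over scores 0..4.
    """
    p = np.asarray(distribution, dtype=float)
    if p.shape != (5,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("distribution must be 5 non-negative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    return rng.choice(5, size=(n_subjects, 17), p=p)
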