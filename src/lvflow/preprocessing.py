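"""Background phase-error correction for phase-contrast velocity data.

Uncorrected phase-contrast acquisitions carry a spatially smooth, temporally
constant velocity offset (eddy currents, gradient imperfections).  The
standard remedy, applied here, fits a 3rd-order 3-D polynomial to the
temporal-mean velocity of static tissue and subtracts the evaluated
polynomial from every cardiac frame of each component.

The 20-term basis {x^a y^b z^c : a+b+c <= 3} is evaluated in normalized
coordinates in [-1, 1] tied to the grid extent; raw mm coordinates would make
the cubic design badly conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import VelocityField4D

logger = logging.getLogger(__name__)

__all__ = [
    "PolyCoeffs",
    "polynomial_exponents",
    "polynomial_design",
    "estimate_static_mask",
    "fit_background_phase",
    "correct_background_phase",
]

MAX_ORDER = 3


def polynomial_exponents(order: int = MAX_ORDER) -> np.ndarray:
    """Exponent triples (a, b, c) with a+b+c <= order, in lexicographic order."""
    exps = [
        (a, b, c)
        for a in range(order + 1)
        for b in range(order + 1 - a)
        for c in range(order + 1 - a - b)
    ]
    return np.asarray(sorted(exps), dtype=int)


N_TERMS = len(polynomial_exponents())  # 20


@dataclass
class PolyCoeffs:
    """Fitted background-offset polynomial: one 20-vector per velocity component.

    ``grid_shape`` records the grid the normalized coordinates were tied to so
    that evaluation and fitting use the same basis.
    """

    coeffs: np.ndarray  # (3, 20)
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (3, N_TERMS):
            raise ValueError(
                f"expected coefficient array of shape (3, {N_TERMS}), got {self.coeffs.shape}"
            )

    def to_dict(self) -> dict:
        exps = polynomial_exponents()
        return {
            "grid_shape": list(self.grid_shape),
            "exponents": exps.tolist(),
            "coefficients": {c: self.coeffs[i].tolist() for i, c in enumerate("xyz")},
        }


def _normalized_coordinates(grid_shape, indices) -> np.ndarray:
    """Map voxel indices to [-1, 1] per axis (degenerate axes map to 0)."""
    out = np.empty((len(indices[0]), 3), dtype=float)
    for ax in range(3):
        n = grid_shape[ax]
        if n > 1:
            out[:, ax] = 2.0 * np.asarray(indices[ax]) / (n - 1) - 1.0
        else:
            out[:, ax] = 0.0
    return out


def polynomial_design(grid_shape, indices) -> np.ndarray:
    """Design matrix of the 20-term cubic basis at the given voxel indices."""
    xyz = _normalized_coordinates(grid_shape, indices)
    exps = polynomial_exponents()
    return (
        xyz[:, 0:1] ** exps[:, 0]
        * xyz[:, 1:2] ** exps[:, 1]
        * xyz[:, 2:3] ** exps[:, 2]
    )


def _fluctuation_sd(field: VelocityField4D) -> np.ndarray:
    """Temporal SD of the velocity vector, sqrt(sum_c Var_t v_c).

    Using component variances (rather than the SD of the speed) makes the
    statistic invariant under constant offsets, so a background error does not
    perturb the static-tissue estimate it is meant to support.
    """
    return np.sqrt(
        field.vx.var(axis=3) + field.vy.var(axis=3) + field.vz.var(axis=3)
    )


def estimate_static_mask(field: VelocityField4D, sd_percentile: float = 30.0) -> np.ndarray:
    """Boolean 3-D mask of putative static tissue.

    A voxel is static iff its temporal velocity-fluctuation SD falls below the
    given percentile of all in-body voxels.  The body is defined by a
    magnitude threshold (10% of the temporal-mean maximum) when a magnitude
    image is present, otherwise all voxels are candidates.
    """
    if field.n_frames < 2:
        raise ValueError("static-tissue estimation needs at least 2 frames")
    sd = _fluctuation_sd(field)
    if field.magnitude is not None:
        mag = field.magnitude.mean(axis=3)
        body = mag > 0.1 * mag.max()
    else:
        body = np.ones(sd.shape, dtype=bool)
    threshold = np.percentile(sd[body], sd_percentile)
    # absolute tolerance (cm/s) absorbs round-off in the variance of
    # effectively constant voxels; far below any physiological fluctuation
    static = body & (sd <= threshold + 1e-9)
    if not static.any():
        raise ValueError(
            f"static-tissue mask is empty at percentile {sd_percentile}; increase the percentile"
        )
    return static


def fit_background_phase(field: VelocityField4D, static_mask: np.ndarray) -> PolyCoeffs:
    """Least-squares fit of the static-tissue temporal-mean velocity to the cubic basis."""
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.grid_shape:
        raise ValueError("static mask does not share the velocity grid")
    idx = np.nonzero(static_mask)
    n_static = len(idx[0])
    if n_static < N_TERMS:
        raise ValueError(
            f"need at least {N_TERMS} static voxels to fit the cubic basis, got {n_static}"
        )
    design = polynomial_design(field.grid_shape, idx)
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(
            "background-phase design matrix is rank deficient "
            f"(condition number {cond:.3g}); static voxels lack spatial spread"
        )
    coeffs = np.empty((3, N_TERMS))
    for i, comp in enumerate((field.vx, field.vy, field.vz)):
        target = comp.mean(axis=3)[idx]
        coeffs[i], *_ = np.linalg.lstsq(design, target, rcond=None)
    logger.debug("background-phase fit: %d static voxels, cond %.3g", n_static, cond)
    return PolyCoeffs(coeffs=coeffs, grid_shape=field.grid_shape)


def evaluate_background(coeffs: PolyCoeffs, grid_shape=None) -> np.ndarray:
    """Evaluate the offset polynomial on the full grid; shape (3, nx, ny, nz)."""
    shape = tuple(grid_shape) if grid_shape is not None else tuple(coeffs.grid_shape)
    if shape != tuple(coeffs.grid_shape):
        raise ValueError("coefficients were fitted on a different grid")
    idx = np.indices(shape).reshape(3, -1)
    design = polynomial_design(shape, idx)
    fields = design @ coeffs.coeffs.T  # (N, 3)
    return fields.T.reshape((3,) + shape)


def correct_background_phase(field: VelocityField4D, coeffs: PolyCoeffs) -> VelocityField4D:
    """Subtract the evaluated offset polynomial from every frame of each component.

    Temporal fluctuations are untouched: v(t) - mean_t v is preserved exactly.
    """
    offsets = evaluate_background(coeffs, field.grid_shape)
    out = field.copy()
    out.vx -= offsets[0][..., None]
    out.vy -= offsets[1][..., None]
    out.vz -= offsets[2][..., None]
    return out
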