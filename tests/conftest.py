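"""Shared fixtures: small phantoms generated programmatically at test time."""

import numpy as np
import pytest

from lvflow.core import SegmentationCine, VelocityField4D
from lvflow.phantom import (
    EllipsoidPhantomConfig,
    PlugPhantomConfig,
    make_ellipsoid_phantom,
    make_plug_phantom,
)


@pytest.fixture(scope="session")
def ellipsoid_small():
    """Coarse deforming-ventricle phantom (2.5 mm grid) for fast pipeline tests."""
    cfg = EllipsoidPhantomConfig(
        r0_cm=1.8,
        length_cm=7.0,
        alpha=0.3,
        n_frames=20,
        shape=(24, 24, 40),
        spacing=(2.5, 2.5, 2.5),
    )
    return cfg, *make_ellipsoid_phantom(cfg)


@pytest.fixture(scope="session")
def plug_default():
    cfg = PlugPhantomConfig(d_in_cm=4.0, d_out_cm=4.0)
    return cfg, *make_plug_phantom(cfg)


@pytest.fixture()
def uniform_field():
    """Spatially uniform axial velocity 10 cm/s apex->base, full-grid mask."""
    shape = (6, 6, 8, 4)
    vz = np.full(shape, 10.0)
    field = VelocityField4D(
        vx=np.zeros(shape), vy=np.zeros(shape), vz=vz,
        spacing=(1.25, 1.25, 1.25), rr_interval=1.0,
    )
    seg = SegmentationCine(
        mask=np.ones(shape, dtype=bool), spacing=(1.25, 1.25, 1.25),
        slice_axis=2, apex_to_base_sign=1,
    )
    return field, seg


@pytest.fixture(scope="session")
def rotation_field():
    """Rigid rotation (omega = 2*pi rad/s) about the grid center; linear in space,
    so trilinear interpolation is exact and only the RK4 time error remains."""
    n, sp = 25, 1.25
    x = (np.arange(n) - (n - 1) / 2) * sp  # mm
    X, Y = np.meshgrid(x, x, indexing="ij")
    omega = 2 * np.pi
    vx3 = np.repeat((-omega * Y / 10.0)[:, :, None], 3, axis=2)  # cm/s
    vy3 = np.repeat((omega * X / 10.0)[:, :, None], 3, axis=2)
    vx4 = np.repeat(vx3[..., None], 10, axis=3)
    vy4 = np.repeat(vy3[..., None], 10, axis=3)
    field = VelocityField4D(
        vx=vx4, vy=vy4, vz=np.zeros_like(vx4), spacing=(sp, sp, sp), rr_interval=1.0
    )
    center = np.array([(n - 1) / 2 * sp, (n - 1) / 2 * sp, 1 * sp])
    return field, center
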