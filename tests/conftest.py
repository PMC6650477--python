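"""Shared fixtures: small synthetic phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fiborient import (
    ExtensionParams,
    FiberFieldSpec,
    FiberGeometry,
    apply_biaxial_extension,
    generate_collagen_geometry,
    rasterize_stack,
)


def make_spec(**kwargs) -> FiberFieldSpec:
    """A small, fast phantom tile spec with sensible test defaults."""
    defaults = dict(
        z_extent=24.0,
        bundle_depths=[(12.0, 20.0)],
        mode_centers=[60.0],
        mode_weights=[1.0],
        mode_dispersion=5.0,
        bundle_coherent=False,
        waviness_amplitude=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return FiberFieldSpec(**defaults)


@pytest.fixture(scope="session")
def straight_tile():
    """One straight-fiber bundle at 60°, rasterized; slab center at slice 6."""
    spec = make_spec(seed=20)
    geom = generate_collagen_geometry(spec)
    stack = rasterize_stack(geom, spec, channel="collagen")
    return spec, geom, stack


@pytest.fixture(scope="session")
def noise_stack():
    """Pure background+noise stack (no fibers)."""
    spec = make_spec(z_extent=8.0, bundle_depths=[(4.0, 4.0)], seed=21)
    stack = rasterize_stack(FiberGeometry([], spec.field_xy, spec.z_extent), spec)
    return spec, stack


@pytest.fixture(scope="session")
def crimped_geometry():
    """Wavy-fiber bundle for extension/straightening tests."""
    spec = make_spec(waviness_amplitude=5.0, waviness_wavelength=40.0, seed=22)
    return spec, generate_collagen_geometry(spec)
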