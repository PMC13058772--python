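"""Shared fixtures: the packaged reference assay and a fast scaled-down one."""

from __future__ import annotations

import dataclasses

import pytest

import vesselperm as vp
from vesselperm.permeability import FieldOfView


@pytest.fixture(scope="session")
def ref() -> vp.AssayConfig:
    """Packaged reference assay configuration (7 µm capillary, 180 min)."""
    return vp.reference_config()


@pytest.fixture(scope="session")
def ref_solution(ref: vp.AssayConfig) -> vp.synthetic.WallFluxSolution:
    """1D membrane-flux solution for the reference assay (shared: ~1 s)."""
    return vp.solve_wall_flux_1d(ref.scenario, ref.grid, dx=1.0)


@pytest.fixture(scope="session")
def small_assay(ref: vp.AssayConfig) -> vp.AssayConfig:
    """Desk-scale assay for fast unit tests: 60x50 µm FOV, 20 min movie.

    Same physics as the reference (wall-limited leak of a 7 µm capillary),
    but ~200x fewer pixels and 5 frames, so a full simulate-quantify cycle
    takes well under a second.
    """
    fov = FieldOfView(width_um=60.0, height_um=50.0, nx=120, ny=100)
    return dataclasses.replace(
        ref,
        fov=fov,
        geometry=vp.VesselGeometry2D(
            axis_point=(30.0, 25.0), axis_angle=0.0, diameter=7.0
        ),
        grid=vp.TimeGrid(frame_interval=5.0, duration=20.0),
    )


@pytest.fixture()
def small_noiseless(small_assay: vp.AssayConfig) -> vp.AssayConfig:
    """Small assay with a noise-free, unseeded sensor (deterministic)."""
    return dataclasses.replace(
        small_assay,
        render=vp.RenderParams(k=2000.0, bg_mean=100.0, bg_sd=0.0,
                               bit_depth=16, seed=0),
    )
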