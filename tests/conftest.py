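"""Shared fixtures: phantoms at several scales and one full default plan."""

from __future__ import annotations

import time

import numpy as np
import pytest

from needlepath import PhantomSpec, PlanConfig, generate_phantom, plan


def default_spec(seed: int = 1) -> PhantomSpec:
    return PhantomSpec(seed=seed)


def small_spec(seed: int = 1, **overrides) -> PhantomSpec:
    """Coarse variant of the default thorax (same anatomy, 4 mm voxels)."""
    kw = dict(
        shape=(64, 64, 64),
        spacing=(4.0, 4.0, 4.0),
        skin_thickness_mm=6.0,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def sphere_spec(spacing: float = 2.0) -> PhantomSpec:
    """Spherical body (radius 80 mm) with a concentric spherical lung.

    The tumor sits at the common center, so every candidate trajectory is
    radial: the skin entry is at radius 80 and the pleural entry angle is 90
    degrees for every cell, up to discretization.
    """
    n = int(round(174.0 / spacing)) + 1
    c = (n - 1) * spacing / 2.0
    return PhantomSpec(
        shape=(n, n, n),
        spacing=(spacing,) * 3,
        body_half_axes=(80.0, 80.0, 80.0),
        skin_thickness_mm=4.0,
        lung_half_axes=(40.0, 40.0, 40.0),
        lung_center_offset=(0.0, 0.0, 0.0),
        include_heart=False,
        include_bronchi=False,
        include_mediastinum=False,
        rib_count=0,
        vessels=(),
        tumor_center=(c, c, c),
        tumor_radius=8.0,
        jitter_mm=0.0,
    )


def rib_spec(seed: int = 1) -> PhantomSpec:
    """Default-geometry thorax whose only organ structures are the rib cage."""
    return PhantomSpec(
        seed=seed,
        vessels=(),
        include_heart=False,
        include_bronchi=False,
        include_mediastinum=False,
    )


@pytest.fixture(scope="session")
def default_scene():
    return generate_phantom(default_spec())


@pytest.fixture(scope="session")
def default_plan(default_scene):
    """Full pipeline on the default 128^3 / 2 mm phantom (timed)."""
    config = PlanConfig()
    t0 = time.perf_counter()
    result, fm = plan(default_scene, config)
    duration = time.perf_counter() - t0
    return {"result": result, "fm": fm, "config": config, "duration_s": duration}


@pytest.fixture(scope="session")
def small_scene():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_plan(small_scene):
    config = PlanConfig()
    result, fm = plan(small_scene, config)
    return {"result": result, "fm": fm, "config": config}


@pytest.fixture(scope="session")
def sphere_plan():
    scene = generate_phantom(sphere_spec(2.0))
    config = PlanConfig()
    result, fm = plan(scene, config)
    return {"scene": scene, "result": result, "fm": fm, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240215)
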