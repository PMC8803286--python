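"""Shared fixtures: a small fast phantom and normalized tangential plan.

The small phantom (48x48x32 voxels at 2.5 mm) keeps every geometric
relation of the default phantom — port inside implant inside body, PTV
margin, lung/heart ellipsoids — at roughly half scale, so unit tests of the
editing, accumulation and metrics operations run in milliseconds.
"""

import numpy as np
import pytest

from expander_sim import (PhantomConfig, PlanBuildConfig, TissueModel,
                          generate_phantom, make_tangential_plan,
                          normalize_plan_with_dose, override_port_densities)


def small_phantom_config(**overrides) -> PhantomConfig:
    params = dict(
        grid_shape=(48, 48, 32),
        voxel_size=(2.5, 2.5, 2.5),
        body_center=(0.0, -10.0, 0.0),
        body_semiaxes=(55.0, 42.0, 36.0),
        lung_center=(22.0, -18.0, 0.0),
        lung_semiaxes=(18.0, 20.0, 24.0),
        heart_center=(6.0, -16.0, -4.0),
        heart_semiaxes=(13.0, 12.0, 14.0),
        implant_center=(20.0, 12.0, 0.0),
        implant_radius=16.0,
        port_core_radius=4.0,
        port_core_length=6.0,
        port_shell_thickness=1.5,
    )
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def tissues() -> TissueModel:
    return TissueModel()


@pytest.fixture(scope="session")
def small_phantom(tissues):
    """(density grid with metal overrides applied, structures)."""
    grid, structures = generate_phantom(small_phantom_config(), tissues)
    grid = override_port_densities(grid, structures, tissues)
    return grid, structures

@pytest.fixture(scope="session")
def small_raw_phantom(tissues):
    """Phantom before any density editing (no metal overrides)."""
    return generate_phantom(small_phantom_config(), tissues)


@pytest.fixture(scope="session")
def small_tangential(small_phantom):
    """Normalized tangential plan and its (scaled) plan dose."""
    grid, structures = small_phantom
    plan = make_tangential_plan(structures, PlanBuildConfig())
    return normalize_plan_with_dose(plan, grid, structures)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
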