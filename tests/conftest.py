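import numpy as np
import pytest

from droptrap.flow import FlowField, FlowPattern, FluidProperties
from droptrap.slender_body import SlenderBody


@pytest.fixture(scope="session")
def unit_body() -> SlenderBody:
    """Rod with L = 1 and L/a = e, so the drag correction c equals 1."""
    return SlenderBody(length_L=1.0, radius_a=1.0 / np.e)


@pytest.fixture(scope="session")
def unit_fluid() -> FluidProperties:
    return FluidProperties(viscosity_mu=1.0)


@pytest.fixture(scope="session")
def pure_strain() -> FlowField:
    return FlowField(FlowPattern.PURE_STRAIN, strain_rate=1.0)


@pytest.fixture(scope="session")
def small_scene():
    """A compact rendered tracer scene shared by tracking tests.

    Coarser pixels than the defaults keep the frames small; everything else
    (droplet size, pattern, frame rate) is the standard tracer setup.
    """
    from droptrap.synth import SceneSpec, render_scene

    spec = SceneSpec(
        n_particles=20,
        duration_s=1.0,
        px_scale=40e-6,
        min_separation_m=0.8e-3,
        seed=11,
    )
    stack, truth = render_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def dense_scene():
    """Densely seeded tracer scene for velocity-field reconstruction."""
    from droptrap.synth import SceneSpec, render_scene

    spec = SceneSpec(
        n_particles=300, duration_s=1.5, px_scale=40e-6, seed=21
    )
    stack, truth = render_scene(spec)
    return spec, stack, truth
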