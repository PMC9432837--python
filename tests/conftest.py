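import numpy as np
import pytest

from podomech import (ContractionModel, StriationSpec, build_mesh,
                      solve_contraction)


@pytest.fixture
def straight_fiber_spec():
    """12-um horizontal fiber, 1.0-um spacing, noise-free."""
    def factory(spacing=1.0, noise_sd=0.0, seed=0, **kw):
        polyline = np.array([[1.0, 7.0], [13.0, 7.0]])
        return StriationSpec(spacing=spacing, fiber_polyline=polyline,
                             noise_sd=noise_sd, seed=seed, **kw)
    return factory


@pytest.fixture(scope="session")
def coarse_model():
    return ContractionModel(substrate_modulus=0.9, mesh_resolution=3)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_model):
    return build_mesh(coarse_model)


@pytest.fixture(scope="session")
def coarse_solution(coarse_model, coarse_mesh):
    return solve_contraction(coarse_model, coarse_mesh)
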