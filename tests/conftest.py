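"""Shared fixtures.

Light fixtures (models, contact parameters) are session-scoped and cheap.
The heavy fixtures run the optimal-control pipeline once per session at a
reduced mesh and are shared by the feasibility, measures and acceptance
tests.
"""

import numpy as np
import pytest

from kafogait import build_planar_model
from kafogait.contact import CrutchContactParams, FootContactParams
from kafogait.knee_trajectory import KneeTrajectoryParams
from kafogait.ocp import OCPConfig, solve_prediction
from kafogait.synthetic_reference import SyntheticGaitSpec, generate_reference

#: Mesh used by every solver-backed test: coarse enough for the suite to
#: fit a desk-scale budget, fine enough to exercise all constraint groups.
TEST_MESH = dict(n_mesh_swing=2, n_mesh_support=1)


@pytest.fixture(scope="session")
def sci_model():
    return build_planar_model({"mass": 72.0, "height": 1.72})


@pytest.fixture(scope="session")
def healthy_model():
    return build_planar_model({"mass": 54.0, "height": 1.62})


@pytest.fixture(scope="session")
def contact_params():
    return (FootContactParams(), CrutchContactParams())


@pytest.fixture(scope="session")
def gait_spec():
    return SyntheticGaitSpec(seed=42)


@pytest.fixture(scope="session")
def track_config():
    return OCPConfig(**TEST_MESH, maxiter=2500, time_limit=300)


@pytest.fixture(scope="session")
def reference_bundle(gait_spec, sci_model, contact_params, track_config):
    """Dynamically consistent synthetic reference + its tracking solution."""
    ref, sol = generate_reference(gait_spec, sci_model, contact_params,
                                  config=track_config)
    assert sol.converged, sol.constraint_report
    return ref, sol


@pytest.fixture(scope="session")
def sci_config():
    return OCPConfig(**TEST_MESH, maxiter=1200, time_limit=240, profile="sci")


@pytest.fixture(scope="session")
def sweep_solutions(reference_bundle, sci_model, contact_params, sci_config):
    """SCI-profile predictions for k_a in {0 (locked), 20, 30, 40} deg,
    warm-started along the sweep as in the study workflow."""
    ref, _ = reference_bundle
    sols = {}
    prev = None
    for k_a in (0.0, 20.0, 30.0, 40.0):
        knee = None if k_a == 0.0 else KneeTrajectoryParams(k_a=k_a)
        sols[k_a] = solve_prediction(sci_model, contact_params, ref, knee,
                                     config=sci_config, guess=prev)
        prev = sols[k_a]
    return sols


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
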