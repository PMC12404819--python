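"""Shared fixtures: simulated datasets at several scales, aligned once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shapevar as sv
from shapevar.procrustes import align_to_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_params():
    return sv.default_paper_design(seed=1)


@pytest.fixture(scope="session")
def paper_sim(paper_params):
    """Full-scale study design: 434 individuals x 2 sides x 2 replicates."""
    configs, design, truth = sv.simulate_dataset(paper_params)
    return configs, design, truth


@pytest.fixture(scope="session")
def paper_aligned(paper_sim, paper_params):
    configs, design, truth = paper_sim
    aligned = align_to_reference(sv.gpa(configs), paper_params.mean_shape)
    return aligned


@pytest.fixture(scope="session")
def paper_mats(paper_aligned, paper_sim):
    _, design, _ = paper_sim
    return sv.estimate_dgp(paper_aligned, design)


@pytest.fixture(scope="session")
def calib_params():
    """Balanced, well-conditioned design (200 individuals) for estimator checks."""
    return sv.calibration_design(n_families=40, offspring_per_family=5, seed=3)


@pytest.fixture(scope="session")
def calib_sim(calib_params):
    configs, design, truth = sv.simulate_dataset(calib_params)
    return configs, design, truth


@pytest.fixture(scope="session")
def calib_aligned(calib_sim, calib_params):
    configs, design, truth = calib_sim
    return align_to_reference(sv.gpa(configs), calib_params.mean_shape)


@pytest.fixture(scope="session")
def tiny_sim():
    """A few families only; for format round-trips and smoke tests."""
    params = sv.calibration_design(n_families=6, offspring_per_family=2, seed=7)
    configs, design, truth = sv.simulate_dataset(params)
    return configs, design, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
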