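"""Shared synthetic fixtures.

Heavy objects (meshes, a simulated cohort and its boundary map) are
session scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

import arealmap as am
from arealmap import boundaries, preprocess, synthetic


@pytest.fixture(scope="session")
def mesh2():
    return am.make_sphere_mesh(2, radius_mm=25.0)


@pytest.fixture(scope="session")
def mesh3():
    return am.make_sphere_mesh(3, radius_mm=18.0)


@pytest.fixture(scope="session")
def mesh4():
    return am.make_sphere_mesh(4, radius_mm=25.0)


@pytest.fixture(scope="session")
def truth3(mesh3):
    return am.plant_parcellation(mesh3, 24, 4, seed=1)


@pytest.fixture(scope="session")
def cohort3(mesh3, truth3):
    spec = synthetic.CohortSpec(n_subjects=8, frames=150, seed=3)
    return synthetic.simulate_cohort(mesh3, truth3, spec)


@pytest.fixture(scope="session")
def clean3(mesh3, cohort3):
    params = preprocess.PreprocessParams()
    return [preprocess.preprocess_subject(s, mesh3, params) for s in cohort3]


@pytest.fixture(scope="session")
def boundary3(mesh3, clean3):
    bmap, mean_z = boundaries.cohort_boundary_pipeline(
        [c for c in clean3 if c.usable], mesh3, n_boot=4, seed=7, cohort="test")
    return bmap, mean_z
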