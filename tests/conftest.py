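"""Shared fixtures: synthetic bones, plans and built guides.

Guide construction is the expensive step, so built guides are
session-scoped and shared across test modules.
"""
import numpy as np
import pytest

from osteoguide import fixtures, frames, planning, guides


@pytest.fixture(scope="session")
def fibula():
    return fixtures.synthetic_fibula()


@pytest.fixture(scope="session")
def mandible_with_defect():
    return fixtures.synthetic_mandible(defect=(0.0, 40.0))


@pytest.fixture(scope="session")
def norm_fibula(fibula):
    mesh, _ = frames.normalize_fibula(fibula)
    return mesh


@pytest.fixture(scope="session")
def norm_mandible(mandible_with_defect):
    mesh, _ = frames.normalize_mandible(mandible_with_defect[0])
    return mesh


@pytest.fixture(scope="session")
def plan2(norm_mandible, norm_fibula, mandible_with_defect):
    """Default two-graft case with 1 mm kerf."""
    _, planes = mandible_with_defect
    return planning.init_plan(
        norm_mandible, norm_fibula, n_grafts=2, kerf=1.0, resection_planes=planes
    )


@pytest.fixture(scope="session")
def plan1(norm_mandible, norm_fibula):
    """One-graft case with square-cut resection normals (no tilt)."""
    _, planes = fixtures.synthetic_mandible(defect=(0.0, 40.0))
    return planning.init_plan(
        norm_mandible, norm_fibula, n_grafts=1, kerf=1.0, resection_planes=planes
    )


@pytest.fixture(scope="session")
def fibula_guide(plan2):
    return guides.build_fibula_guide(plan2)


@pytest.fixture(scope="session")
def mandible_guide(plan2):
    return guides.build_mandible_guide(plan2)


@pytest.fixture(scope="session")
def fibula_guide_1(plan1):
    return guides.build_fibula_guide(plan1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
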