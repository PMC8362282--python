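import numpy as np
import pytest

from disccalib import CohortParams, Contour, MaterialSet


@pytest.fixture
def circle_disc() -> Contour:
    return Contour.circle(20.0, n_vertices=720)


@pytest.fixture
def ellipse_disc() -> Contour:
    return Contour.ellipse(25.0, 17.0, n_vertices=720)


@pytest.fixture
def rectangle() -> Contour:
    # depth 10 along x (bending axis direction), width 30 along y
    return Contour(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 30.0], [0.0, 30.0]]))


@pytest.fixture
def dented_disc() -> Contour:
    """Non-convex disc with an off-midline posterior concavity.

    On convex outlines a ratio-driven nucleus placement is always feasible
    (the mid-sagittal feasibility bound coincides with full containment);
    a concavity that the shifted nucleus cannot nest into is what makes
    large P1 requests genuinely infeasible.
    """
    from shapely.geometry import Point, Polygon

    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    ellipse = Polygon(np.c_[25 * np.cos(t), 17 * np.sin(t)])
    dented = ellipse.difference(Point(22.0, 10.0).buffer(9.0, quad_segs=64))
    return Contour(np.array(dented.exterior.coords[:-1]))


@pytest.fixture
def default_params() -> CohortParams:
    return CohortParams(seed=0)


@pytest.fixture
def symmetric_materials() -> MaterialSet:
    return MaterialSet(
        annulus_tension_modulus=4.0,
        annulus_compression_modulus=4.0,
        nucleus_modulus=1.0,
        disc_height=10.0,
    )
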