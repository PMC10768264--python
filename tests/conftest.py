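import numpy as np
import pytest

from ggnshape import (
    BiEllipseParams,
    CohortSpec,
    GroundTruth,
    make_biellipse_polygon,
    make_biellipse_volume,
    sample_cohort,
)

#: Canonical asymmetric test nodule: semi-axes 6/4 mm, shared minor 3 mm.
CANONICAL = BiEllipseParams(a1=6.0, a2=4.0, c=3.0)


@pytest.fixture(scope="session")
def canonical_truth() -> GroundTruth:
    return GroundTruth.from_params(CANONICAL)


@pytest.fixture(scope="session")
def canonical_polygon():
    contour, truth = make_biellipse_polygon(CANONICAL, n_vertices=720)
    return contour, truth


@pytest.fixture(scope="session")
def canonical_volume():
    return make_biellipse_volume(CANONICAL, spacing=0.1)


@pytest.fixture(scope="session")
def default_cohort():
    """Table-matched synthetic cohort (39 + 59 lesions), fixed seed."""
    table, contours = sample_cohort(CohortSpec(seed=42))
    return table, contours


def random_biellipse_params(rng: np.random.Generator) -> BiEllipseParams:
    c = rng.uniform(1.5, 6.0)
    a2 = c * rng.uniform(1.0, 2.0)
    a1 = a2 * rng.uniform(1.0, 2.0)
    return BiEllipseParams(
        a1=a1,
        a2=a2,
        c=c,
        rotation=rng.uniform(0.0, 180.0),
        translation=tuple(rng.uniform(-10.0, 10.0, 2)),
    )
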