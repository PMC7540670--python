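import numpy as np
import pytest

from rangescore.geometry import RangePolygon, StudyArea
from rangescore.scoring import make_grid


def square(lon0: float, lat0: float, side_deg: float) -> RangePolygon:
    return RangePolygon.from_coords(
        [
            (lon0, lat0),
            (lon0 + side_deg, lat0),
            (lon0 + side_deg, lat0 + side_deg),
            (lon0, lat0 + side_deg),
        ]
    )


@pytest.fixture
def unit_square_study_area() -> StudyArea:
    """1 deg x 1 deg study area at the equator."""
    return StudyArea(square(0.0, 0.0, 1.0))


@pytest.fixture
def small_grid(unit_square_study_area):
    """6 x 6 grid (10 arc minutes) on the equatorial unit square."""
    return make_grid(unit_square_study_area, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
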