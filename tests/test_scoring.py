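"""Grid construction, the Bernoulli scoring rule, deviance, expert score."""

import numpy as np
import pytest

from rangescore.geometry import RangePolygon, StudyArea
from rangescore.scoring import (
    BinaryMapGrid,
    GridSpec,
    expert_score,
    make_grid,
    occupancy_probability,
    rasterize_map,
    scoring_rule,
    total_deviance,
)

from conftest import square


def brute_force_deviance(y, p, areas):
    """Independent per-cell oracle: plain python loop over Eq-style terms."""
    import math

    total = 0.0
    for yi, pi, ai in zip(y, p, areas):
        total += -2.0 * (yi * math.log(pi) + (1 - yi) * math.log(1 - pi)) * ai
    return total


class TestMakeGrid:
    def test_unit_square_at_10_arcmin_has_36_cells(self, small_grid):
        assert small_grid.n_masked == 36

    def test_unit_square_at_5_arcmin_has_144_cells(self, unit_square_study_area):
        assert make_grid(unit_square_study_area, 5.0).n_masked == 144

    def test_masked_area_matches_geodesic_area(self, unit_square_study_area, small_grid):
        assert small_grid.masked_area_km2 == pytest.approx(
            unit_square_study_area.area_km2, rel=0.005
        )

    def test_origin_snapped_to_graticule(self):
        sa = StudyArea(square(0.03, 0.07, 1.0))
        g = make_grid(sa, 10.0)
        r = 10.0 / 60.0
        assert g.origin_lon == pytest.approx(0.0)
        assert g.origin_lat == pytest.approx(round(g.origin_lat / r) * r)

    def test_nonpositive_resolution_errors(self, unit_square_study_area):
        with pytest.raises(ValueError, match="positive"):
            make_grid(unit_square_study_area, 0.0)

    def test_grid_too_coarse_errors(self):
        # a sliver that dodges every 10-arcmin cell center
        sliver = StudyArea(
            RangePolygon.from_coords([(0.0, 0.0), (0.05, 0.0), (0.05, 0.05), (0.0, 0.05)])
        )
        with pytest.raises(ValueError, match="too coarse"):
            make_grid(sliver, 10.0)


class TestRasterize:
    def test_study_area_rasterizes_to_all_ones(self, unit_square_study_area, small_grid):
        b = rasterize_map(unit_square_study_area.boundary, small_grid)
        assert np.all(b.y[small_grid.mask] == 1)

    def test_empty_map_rasterizes_to_zeros(self, small_grid):
        from shapely.geometry import Polygon

        b = rasterize_map(RangePolygon(Polygon()), small_grid)
        assert not b.y.any()

    def test_west_half_covers_half_the_cells(self, small_grid):
        west = RangePolygon.from_coords([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
        b = rasterize_map(west, small_grid)
        assert b.y[small_grid.mask].sum() == 18


class TestOccupancyProbability:
    def test_log_two_mass_gives_half(self):
        s = occupancy_probability(np.array([np.log(2.0)]))
        assert s.p[0] == pytest.approx(0.5, rel=1e-12)

    def test_zero_mass_clamped_to_eps(self):
        s = occupancy_probability(np.array([0.0]), clamp_eps=1e-10)
        assert s.p[0] == 1e-10
        assert s.n_clamped == 1

    def test_huge_mass_clamped_below_one(self):
        s = occupancy_probability(np.array([50.0]), clamp_eps=1e-10)
        assert s.p[0] == 1 - 1e-10
        assert s.n_clamped == 1

    def test_negative_mass_errors(self):
        with pytest.raises(ValueError, match="negative"):
            occupancy_probability(np.array([-0.1]))


class TestScoringRule:
    def test_closed_forms(self):
        assert scoring_rule(1, 0.5) == pytest.approx(2 * np.log(2), rel=1e-12)
        assert scoring_rule(0, 0.75) == pytest.approx(-2 * np.log(0.25), rel=1e-12)
        assert scoring_rule(1, 1 - 1e-10) == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative(self, rng):
        p = rng.uniform(1e-6, 1 - 1e-6, size=100)
        y = rng.integers(0, 2, size=100)
        assert np.all(scoring_rule(y, p) >= 0)

    def test_p_outside_open_interval_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError, match="strictly"):
                scoring_rule(1, bad)


class TestTotalDeviance:
    def test_uniform_half_probability_closed_form(self, small_grid):
        p = occupancy_probability(np.full(small_grid.mask.shape, np.log(2.0)))
        y = BinaryMapGrid(np.ones(small_grid.mask.shape, dtype=np.int8), small_grid)
        expected = 2 * np.log(2) * small_grid.masked_area_km2
        assert total_deviance(y, p, small_grid) == pytest.approx(expected, rel=1e-12)

    def test_matching_extreme_surface_is_near_zero(self, small_grid):
        lam = np.where(np.arange(small_grid.n_cols) < 3, 50.0, 0.0)
        lam = np.broadcast_to(lam, small_grid.mask.shape).copy()
        p = occupancy_probability(lam)
        y = BinaryMapGrid((lam > 1).astype(np.int8), small_grid)
        assert total_deviance(y, p, small_grid) == pytest.approx(0.0, abs=1e-5)

    def test_matches_brute_force_oracle(self, small_grid, rng):
        lam = rng.uniform(0.01, 3.0, size=small_grid.mask.shape)
        surf = occupancy_probability(lam)
        y2d = rng.integers(0, 2, size=small_grid.mask.shape).astype(np.int8)
        y = BinaryMapGrid(y2d, small_grid)
        m = small_grid.mask
        oracle = brute_force_deviance(
            y2d[m].tolist(), surf.p[m].tolist(), small_grid.cell_areas_km2[m].tolist()
        )
        assert total_deviance(y, surf, small_grid) == pytest.approx(oracle, rel=1e-12)

    def test_grid_mismatch_errors(self, small_grid, unit_square_study_area):
        other = make_grid(unit_square_study_area, 5.0)
        p = occupancy_probability(np.full(other.mask.shape, 1.0))
        y = BinaryMapGrid(np.ones(other.mask.shape, dtype=np.int8), other)
        with pytest.raises(ValueError, match="does not match"):
            total_deviance(y, p, small_grid)


class TestExpertScore:
    def surface(self, grid, rng=None, lam=None):
        if lam is None:
            lam = rng.uniform(0.05, 2.5, size=grid.mask.shape)
        return occupancy_probability(np.asarray(lam, dtype=float))

    def test_null_map_scores_exactly_zero(self, unit_square_study_area, small_grid, rng):
        surf = self.surface(small_grid, rng)
        res = expert_score(
            unit_square_study_area.boundary, surf, unit_square_study_area, small_grid
        )
        assert res.expert_score == 0.0
        assert res.scaled_outside == 0.0
        assert res.deviance_expert == res.deviance_null

    def test_perfect_map_approaches_one(self, unit_square_study_area, small_grid):
        # surface saturated inside the west half, ~zero outside; map = west half
        lam = np.zeros(small_grid.mask.shape)
        lam[:, :3] = 50.0
        surf = self.surface(small_grid, lam=lam)
        west = RangePolygon.from_coords([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
        res = expert_score(west, surf, unit_square_study_area, small_grid)
        assert res.expert_score == pytest.approx(1.0, abs=1e-6)

    def test_map_on_the_wrong_half_scores_negative(self):
        # two-cell instance checked by brute force: map covers the low-p cell
        sa = StudyArea(RangePolygon.from_coords([(0, 0), (2, 0), (2, 1), (0, 1)]))
        grid = make_grid(sa, 60.0)
        assert grid.n_masked == 2
        lam = np.array([[0.01, 3.0]])
        surf = occupancy_probability(lam)
        low_half = RangePolygon.from_coords([(0, 0), (1, 0), (1, 1), (0, 1)])
        res = expert_score(low_half, surf, sa, grid)
        a = grid.cell_areas_km2[0]
        p = surf.p[0]
        d_null = (-2 * np.log(p[0])) * a[0] + (-2 * np.log(p[1])) * a[1]
        d_exp = (-2 * np.log(p[0])) * a[0] + (-2 * np.log(1 - p[1])) * a[1]
        assert res.expert_score == pytest.approx(1 - d_exp / d_null, rel=1e-12)
        assert res.expert_score < 0

    def test_decomposition_identity(self, unit_square_study_area, small_grid, rng):
        surf = self.surface(small_grid, rng)
        west = RangePolygon.from_coords([(0, 0), (0.4, 0), (0.4, 1), (0, 1)])
        res = expert_score(west, surf, unit_square_study_area, small_grid)
        assert res.expert_score == pytest.approx(
            1 - (res.scaled_inside + res.scaled_outside), abs=1e-12
        )
        assert res.deviance_expert == pytest.approx(
            res.deviance_inside + res.deviance_outside, rel=1e-12
        )

    def test_adding_high_p_cell_never_hurts(self, unit_square_study_area, small_grid):
        # map grows eastward one column at a time over a west-high surface
        lam = np.tile(np.linspace(3.0, 0.01, small_grid.n_cols), (small_grid.n_rows, 1))
        surf = occupancy_probability(lam)
        scores = []
        for ncol in range(1, small_grid.n_cols + 1):
            m = RangePolygon.from_coords(
                [(0, 0), (ncol / 6, 0), (ncol / 6, 1), (0, 1)]
            )
            res = expert_score(m, surf, unit_square_study_area, small_grid)
            scores.append(res.expert_score)
            p_col = surf.p[0, ncol - 1]
            if ncol > 1:
                if p_col > 0.5:
                    assert scores[-1] >= scores[-2] - 1e-12
                elif p_col < 0.5:
                    assert scores[-1] <= scores[-2] + 1e-12

    def test_score_invariant_to_weight_rescaling(self, unit_square_study_area, small_grid, rng):
        surf = self.surface(small_grid, rng)
        west = RangePolygon.from_coords([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
        res = expert_score(west, surf, unit_square_study_area, small_grid)
        scaled = GridSpec(
            resolution_arcmin=small_grid.resolution_arcmin,
            origin_lon=small_grid.origin_lon,
            origin_lat=small_grid.origin_lat,
            n_cols=small_grid.n_cols,
            n_rows=small_grid.n_rows,
            mask=small_grid.mask,
            cell_areas_km2=small_grid.cell_areas_km2 * 7.5,
        )
        res2 = expert_score(west, surf, unit_square_study_area, scaled)
        assert res2.expert_score == pytest.approx(res.expert_score, rel=1e-12)
        assert res2.scaled_inside == pytest.approx(res.scaled_inside, rel=1e-12)
        assert res2.scaled_outside == pytest.approx(res.scaled_outside, rel=1e-12)

    def test_map_outside_study_area_clipped_with_warning(
        self, unit_square_study_area, small_grid, rng
    ):
        surf = self.surface(small_grid, rng)
        big = RangePolygon.from_coords([(-1, -1), (2, -1), (2, 2), (-1, 2)])
        with pytest.warns(UserWarning, match="clipping"):
            res = expert_score(big, surf, unit_square_study_area, small_grid)
        assert res.expert_score == 0.0  # clipped back to the null map

    def test_degenerate_saturated_surface_errors(
        self, unit_square_study_area, small_grid
    ):
        surf = occupancy_probability(np.full(small_grid.mask.shape, 60.0))
        with pytest.raises(ValueError, match="degenerate"):
            expert_score(
                unit_square_study_area.boundary, surf, unit_square_study_area, small_grid
            )

    def test_grid_refinement_within_reported_bound(self, unit_square_study_area):
        # smooth surface, fixed polygon: 10' vs 5' differ less than the bounds
        west = RangePolygon.from_coords([(0, 0), (0.47, 0), (0.47, 1), (0, 1)])
        results = {}
        for res_arcmin in (10.0, 5.0):
            grid = make_grid(unit_square_study_area, res_arcmin)
            gx, gy = grid.center_mesh()
            lam = 2.0 * np.exp(-((gx - 0.3) ** 2 + (gy - 0.5) ** 2) / 0.08)
            surf = occupancy_probability(lam + 1e-3)
            results[res_arcmin] = expert_score(
                west, surf, unit_square_study_area, grid
            )
        diff = abs(results[10.0].expert_score - results[5.0].expert_score)
        assert diff < results[10.0].discretization_bound + results[5.0].discretization_bound
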