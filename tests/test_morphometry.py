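import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Point

from gliamorph import (
    MeasurementError,
    ParameterError,
    SamplingDesign2D,
    UndefinedMeasureError,
    coverage_distribution,
    dystrophy_metrics,
    grid_coverage,
    microglial_domain,
    microglial_loading,
    sample_cells_systematic,
    skeleton_endpoints,
    threshold_mask,
    to_gray8,
)
from gliamorph.segmentation import BinaryMask, LabeledCells, SegmentationParams, label_cells


def _mask(grid, px=1.0):
    return BinaryMask(grid=np.asarray(grid, bool), px_size_um=px)


class TestLoading:
    def test_pixel_count_arithmetic(self):
        grid = np.zeros((10, 10), bool)
        grid.ravel()[:25] = True
        res = microglial_loading(_mask(grid), np.ones((10, 10), bool))
        assert res.positive_area_um2 == 25.0
        assert res.region_area_um2 == 100.0
        assert res.loading == 0.25
        assert res.percent == 25.0

    def test_half_positive(self):
        grid = np.zeros((10, 10), bool)
        grid[:5] = True
        res = microglial_loading(_mask(grid), np.ones((10, 10), bool))
        assert res.loading == 0.5

    def test_empty_mask_zero_loading(self):
        res = microglial_loading(_mask(np.zeros((5, 5))), np.ones((5, 5), bool))
        assert res.loading == 0.0

    def test_empty_region_is_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            microglial_loading(_mask(np.ones((5, 5))), np.zeros((5, 5), bool))

    def test_only_region_pixels_count(self):
        grid = np.ones((10, 10), bool)
        region = np.zeros((10, 10), bool)
        region[:5] = True
        res = microglial_loading(_mask(grid), region)
        assert res.loading == 1.0
        assert res.region_area_um2 == 50.0


class TestGridCoverage:
    def test_all_positive_every_square_full(self):
        region = np.ones((300, 300), bool)
        res = grid_coverage(_mask(np.ones((300, 300))), region, side_um=100.0)
        assert res.n_squares == 9
        assert (res.squares["covered_fraction"] == 1.0).all()

    def test_empty_mask_zero_everywhere(self):
        region = np.ones((300, 300), bool)
        res = grid_coverage(_mask(np.zeros((300, 300))), region, side_um=100.0)
        assert (res.squares["covered_area_um2"] == 0.0).all()

    def test_nominal_square_area_354um(self):
        # 354 um at 1 um/px: each square can hold at most 354^2 = 125316 um^2
        region = np.ones((800, 800), bool)
        res = grid_coverage(_mask(np.ones((800, 800))), region, side_um=354.0)
        assert res.square_side_um == 354.0
        assert res.squares["covered_area_um2"].max() == 354.0**2 == 125316.0
        assert (res.squares["covered_area_um2"] <= res.square_side_um**2).all()

    def test_edge_squares_excluded_below_cutoff(self):
        region = np.zeros((250, 250), bool)
        region[:220, :220] = True  # second row/col of 100-px squares: 20% overlap
        res = grid_coverage(_mask(np.ones((250, 250))), region, side_um=100.0)
        assert res.n_squares == 4

    def test_region_smaller_than_square_single_result(self):
        region = np.ones((40, 40), bool)
        with pytest.warns(UserWarning):
            res = grid_coverage(_mask(np.ones((40, 40))), region, side_um=100.0)
        assert res.n_squares == 1

    def test_grid_conservation(self, ramified_field, seg_params):
        img, _ = ramified_field
        mask = threshold_mask(to_gray8(img.raster), seg_params, px_size_um=0.5)
        res = grid_coverage(mask, img.region_mask, side_um=100.0)
        positive = (mask.grid & img.region_mask).sum() * 0.25
        assert res.squares["covered_area_um2"].sum() <= positive + 1e-6


class TestCoverageDistribution:
    def test_identical_squares_single_bin(self):
        region = np.ones((300, 300), bool)
        res = grid_coverage(_mask(np.ones((300, 300))), region, side_um=100.0)
        dist = coverage_distribution(res, bin_width_um2=500.0)
        assert (dist["frequency"] > 0).sum() == 1
        assert dist["frequency"].sum() == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, ramified_field, seg_params):
        img, _ = ramified_field
        mask = threshold_mask(to_gray8(img.raster), seg_params, px_size_um=0.5)
        res = grid_coverage(mask, img.region_mask, side_um=80.0)
        dist = coverage_distribution(res, bin_width_um2=200.0)
        assert dist["frequency"].sum() == pytest.approx(1.0)


class TestSkeletonEndpoints:
    def test_straight_segment_two_endpoints(self):
        grid = np.zeros((16, 16), bool)
        grid[8, 2:14] = True
        assert len(skeleton_endpoints(grid)) == 2

    def test_cross_four_endpoints(self):
        grid = np.zeros((21, 21), bool)
        grid[10, 2:19] = True
        grid[2:19, 10] = True
        assert len(skeleton_endpoints(grid)) == 4

    def test_empty_mask_raises(self):
        with pytest.raises(MeasurementError):
            skeleton_endpoints(np.zeros((8, 8), bool))

    def test_endpoints_match_generator_tips(self, ramified_field, seg_params):
        img, _ = ramified_field
        mask = threshold_mask(to_gray8(img.raster), seg_params, px_size_um=0.5)
        cells = label_cells(mask, seg_params)
        checked = 0
        for cell in img.ground_truth[:10]:
            # find the label under the true soma
            r = int(cell.soma_xy_um[1] / 0.5)
            c = int(cell.soma_xy_um[0] / 0.5)
            lab = cells.label_grid[r, c]
            if lab == 0:
                continue
            row = cells.cells[cells.cells["label"] == lab].iloc[0]
            eps = skeleton_endpoints(cells.cell_mask(lab))
            eps_um = (eps + [row.min_col, row.min_row]) * 0.5
            for tip in cell.endpoints_um:
                d = np.sqrt(((eps_um - tip) ** 2).sum(1)).min()
                assert d <= 2.0  # within 2 um (= 4 px) of a true tip
            checked += 1
        assert checked >= 5


class TestMicroglialDomain:
    def test_rectangle_area(self):
        pts = np.array([[0, 0], [40, 0], [40, 50], [0, 50]])
        res = microglial_domain(pts, px_size_um=1.0)
        assert res.domain_um2 == pytest.approx(2000.0)

    def test_collinear_points_excluded(self):
        res = microglial_domain(np.array([[0, 0], [1, 1], [2, 2]]), 1.0)
        assert np.isnan(res.domain_um2)
        assert res.excluded_reason == "collinear endpoints"

    def test_too_few_points_excluded(self):
        res = microglial_domain(np.array([[0, 0], [5, 5]]), 1.0)
        assert res.excluded_reason == "fewer than 3 endpoints"

    def test_regular_hexagon_closed_form(self):
        # six tips at radius 25 um: area = 6 * 25^2 * sin(60 deg) / 2
        theta = np.arange(6) * np.pi / 3
        pts = 25.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        res = microglial_domain(pts, px_size_um=1.0)
        assert res.domain_um2 == pytest.approx(0.5 * 6 * 25**2 * np.sin(np.pi / 3))
        assert res.domain_um2 == pytest.approx(1623.80, abs=0.01)

    def test_hull_matches_monte_carlo(self, rng):
        # the convex-hull area agrees with a point-in-hull MC estimator
        for _ in range(5):
            pts = rng.uniform(0, 100, size=(8, 2))
            res = microglial_domain(pts, px_size_um=1.0)
            hull = MultiPoint(pts.tolist()).convex_hull
            lo = np.array(hull.bounds[:2])
            hi = np.array(hull.bounds[2:])
            samples = rng.uniform(lo, hi, size=(100_000, 2))
            from shapely import contains_xy

            frac = contains_xy(hull, samples[:, 0], samples[:, 1]).mean()
            mc = frac * np.prod(hi - lo)
            assert res.domain_um2 == pytest.approx(mc, rel=0.02)

    def test_angular_method_never_exceeds_hull(self, rng):
        pts = rng.uniform(0, 50, size=(9, 2))
        hull = microglial_domain(pts, 1.0, method="hull").domain_um2
        ang = microglial_domain(pts, 1.0, method="angular").domain_um2
        assert ang <= hull + 1e-9

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            microglial_domain(np.zeros((4, 2)), 1.0, method="banana")


def _point_cells(xs, ys, px=1.0, shape=(400, 400)):
    cells = pd.DataFrame(
        {"label": np.arange(1, len(xs) + 1), "soma_x_um": xs, "soma_y_um": ys}
    )
    return LabeledCells(
        label_grid=np.zeros(shape, np.int32), cells=cells, px_size_um=px
    )


class TestSystematicSampling:
    def test_frame_side_must_not_exceed_step(self):
        with pytest.raises(ParameterError):
            SamplingDesign2D(frame_area_um2=300**2, step_um=238.64)

    def test_soma_on_forbidden_line_not_sampled(self):
        # offset (0, 0) via a degenerate rng: place the frame analytically
        class FixedRng:
            def uniform(self, lo, hi, size=None):
                return np.zeros(size) if size else 0.0

        design = SamplingDesign2D(frame_area_um2=100.0 * 100.0, step_um=200.0)
        region = np.ones((400, 400), bool)
        # soma exactly on the left forbidden line x=200 of the frame at
        # (200, 200); and one strictly inside
        lc = _point_cells([200.0, 250.0], [250.0, 250.0])
        got = sample_cells_systematic(lc, region, design, rng=FixedRng())
        assert got == [2]

    def test_empirical_inclusion_probability(self):
        rng = np.random.default_rng(3)
        n = 300
        lc = _point_cells(
            rng.uniform(300, 1700, n), rng.uniform(300, 1700, n), shape=(2000, 2000)
        )
        region = np.ones((2000, 2000), bool)
        fracs = [
            len(sample_cells_systematic(lc, region, SamplingDesign2D(seed=s))) / n
            for s in range(120)
        ]
        expected = 7118.3 / 238.64**2
        assert np.mean(fracs) == pytest.approx(expected, rel=0.05)

    def test_n_target_truncates(self):
        lc = _point_cells(np.linspace(50, 350, 40), np.linspace(50, 350, 40))
        region = np.ones((400, 400), bool)
        design = SamplingDesign2D(frame_area_um2=150.0 * 150.0, step_um=160.0, seed=0)
        got = sample_cells_systematic(lc, region, design, n_target=3)
        assert len(got) == 3


class TestDystrophyMetrics:
    def test_single_segment_one_fragment(self):
        grid = np.zeros((16, 32), bool)
        grid[8, 2:30] = True
        d = dystrophy_metrics(grid, px_size_um=1.0)
        assert d.n_skeleton_fragments == 1
        assert d.n_endpoints == 2
        assert d.total_branch_length_um == pytest.approx(27.0, abs=1.5)

    def test_three_fragments_counted(self):
        grid = np.zeros((16, 64), bool)
        grid[8, 2:18] = True
        grid[8, 24:40] = True
        grid[8, 46:62] = True
        d = dystrophy_metrics(grid, px_size_um=1.0)
        assert d.n_skeleton_fragments == 3

    def test_empty_mask_raises(self):
        with pytest.raises(MeasurementError):
            dystrophy_metrics(np.zeros((8, 8), bool), 1.0)

    def test_dystrophic_cells_have_shorter_branches(
        self, ramified_field, dystrophic_field, seg_params
    ):
        def mean_length(img):
            mask = threshold_mask(to_gray8(img.raster), seg_params, px_size_um=0.5)
            cells = label_cells(mask, seg_params)
            lengths = [
                dystrophy_metrics(cells.cell_mask(lab), 0.5).total_branch_length_um
                for lab in cells.cells["label"][:25]
            ]
            return np.mean(lengths)

        assert mean_length(dystrophic_field[0]) < mean_length(ramified_field[0])
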