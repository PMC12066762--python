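"""Tray crossing detection, grid extrapolation and partition cropping."""

import numpy as np
import pytest

from seedtrack import growthfit, synthdata, traygrid
from seedtrack.errors import DetectionFailureError, GridFitError

LAYOUT = (5, 4)
PITCH = 70.0
ORIGIN = (10.0, 10.0)


def tray(jitter_mm=0.0, plants=None, seed=0):
    return synthdata.make_tray_image(layout=LAYOUT, pitch_mm=PITCH, mm_per_px=1.0,
                                     jitter_mm=jitter_mm, plants=plants, rng_seed=seed)


def crossing_errors(points, truth):
    return [np.linalg.norm(truth.inner_crossings - p, axis=1).min() for p in points]


class TestDetectCrossings:
    def test_zero_jitter_exact_lattice(self):
        img, truth = tray()
        pts = traygrid.detect_crossings(img, layout=LAYOUT)
        assert len(pts) == 12
        assert max(crossing_errors(pts, truth)) <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_3mm_jitter_within_2px(self, seed):
        img, truth = tray(jitter_mm=3.0, seed=seed)
        pts = traygrid.detect_crossings(img, layout=LAYOUT)
        assert len(pts) == 12
        assert max(crossing_errors(pts, truth)) <= 2.0

    def test_error_grows_at_most_linearly_with_jitter(self):
        # localization stays bounded by detector resolution across the
        # whole fabrication-inaccuracy range
        errs = []
        for jit in (0.0, 1.5, 3.0):
            worst = 0.0
            for seed in range(3):
                img, truth = tray(jitter_mm=jit, seed=seed)
                pts = traygrid.detect_crossings(img, layout=LAYOUT)
                worst = max(worst, max(crossing_errors(pts, truth)))
            errs.append(worst)
        assert all(e <= 1.0 + j for e, j in zip(errs, (0.0, 1.5, 3.0)))

    def test_featureless_image_fails(self):
        img = np.full((300, 370, 3), 120, dtype=np.uint8)
        with pytest.raises(DetectionFailureError) as exc:
            traygrid.detect_crossings(img, layout=LAYOUT)
        assert exc.value.found < 12


class TestFitAndExtrapolate:
    def lattice_points(self, shift=(0.0, 0.0)):
        xs = ORIGIN[0] + PITCH * np.arange(1, 5) + shift[0]
        ys = ORIGIN[1] + PITCH * np.arange(1, 4) + shift[1]
        return np.array([(x, y) for y in ys for x in xs])

    def test_perfect_lattice_exact_outer_points(self):
        grid = traygrid.fit_and_extrapolate(self.lattice_points(), LAYOUT)
        expect_x = ORIGIN[0] + PITCH * np.arange(6)
        expect_y = ORIGIN[1] + PITCH * np.arange(5)
        np.testing.assert_allclose(grid.lattice[:, 0, 0], expect_x, atol=1e-8)
        np.testing.assert_allclose(grid.lattice[0, :, 1], expect_y, atol=1e-8)
        assert grid.outer_crossings.shape == (6 * 5 - 4 * 3, 2)

    def test_translation_equivariance(self):
        g0 = traygrid.fit_and_extrapolate(self.lattice_points(), LAYOUT)
        g1 = traygrid.fit_and_extrapolate(self.lattice_points(shift=(13.0, -7.0)), LAYOUT)
        np.testing.assert_allclose(g1.lattice - g0.lattice,
                                   np.broadcast_to((13.0, -7.0), g0.lattice.shape),
                                   atol=1e-8)

    def test_outer_points_within_3px_on_jittered_tray(self):
        img, truth = tray(jitter_mm=1.0, seed=2)
        pts = traygrid.detect_crossings(img, layout=LAYOUT)
        grid = traygrid.fit_and_extrapolate(pts, LAYOUT)
        errs = np.linalg.norm(grid.lattice - truth.nodes, axis=-1)
        assert errs.max() <= 3.0

    def test_collinear_points_rejected(self):
        pts = np.array([(10.0 * i, 5.0) for i in range(12)])
        with pytest.raises(GridFitError):
            traygrid.fit_and_extrapolate(pts, LAYOUT)


class TestCropPots:
    def test_20_crops_and_blob_isolation(self):
        img, truth = tray(plants=[synthdata.PlantSpec(pot=(2, 3), n_pixels=100)])
        grid = traygrid.fit_and_extrapolate(traygrid.detect_crossings(img, LAYOUT), LAYOUT)
        crops = traygrid.crop_pots(img, grid, "T001")
        assert len(crops) == 20
        counts = {(c.x_index, c.y_index): growthfit.green_area(c.image)[0] for c in crops}
        assert counts[(2, 3)] == 100
        assert all(v == 0 for k, v in counts.items() if k != (2, 3))
        assert crops[0].name == "T001_0_0"

    def test_whole_image_1x1_grid_is_identity(self):
        img, _ = tray()
        grid = traygrid.regular_grid(img.shape, (1, 1))
        crops = traygrid.crop_pots(img, grid, "T")
        assert len(crops) == 1
        np.testing.assert_array_equal(crops[0].image, img)

    def test_straddling_blob_split_between_two_crops(self):
        # blob centered on an inner wall: negative clearance pushes it
        # halfway across, so its pixels land in exactly two crops
        plant = synthdata.PlantSpec(pot=(1, 1), n_pixels=120, at_wall="right",
                                    wall_clearance_mm=-np.sqrt(120 / np.pi))
        img, truth = tray(plants=[plant])
        grid = traygrid.fit_and_extrapolate(traygrid.detect_crossings(img, LAYOUT), LAYOUT)
        crops = traygrid.crop_pots(img, grid, "T")
        counts = {(c.x_index, c.y_index): growthfit.green_area(c.image)[0] for c in crops}
        nonzero = {k: v for k, v in counts.items() if v > 0}
        assert set(nonzero) == {(1, 1), (2, 1)}
        assert sum(nonzero.values()) == 120

    def test_partition_covers_tray_exactly_once(self):
        img, _ = tray(jitter_mm=3.0, seed=1)
        grid = traygrid.fit_and_extrapolate(traygrid.detect_crossings(img, LAYOUT), LAYOUT)
        col_map, row_map = traygrid.assign_cells(img.shape, grid)
        assigned = col_map >= 0
        crops = traygrid.crop_pots(img, grid, "T")
        assert sum(c.pixel_mask.sum() for c in crops) == assigned.sum()
        # interior of the tray quadrilateral is fully assigned
        lat = grid.lattice
        x0 = int(np.ceil(lat[0, :, 0].max())) + 1
        x1 = int(np.floor(lat[-1, :, 0].min())) - 1
        y0 = int(np.ceil(lat[:, 0, 1].max())) + 1
        y1 = int(np.floor(lat[:, -1, 1].min())) - 1
        assert assigned[y0:y1, x0:x1].all()


class TestAdaptiveVsFixed:
    def test_adaptive_loses_no_plant_pixels_fixed_does(self):
        # seedlings near inner pot walls on flexed trays: cropping along
        # the detected grid keeps every plant pixel while the nominal
        # fixed grid cuts some plants
        plants = [synthdata.PlantSpec(pot=(ix, iy), n_pixels=100, at_wall=wall,
                                      wall_clearance_mm=1.5)
                  for iy in (1, 2) for ix, wall in ((0, "right"), (2, "right"), (4, "left"))]
        lost = {"adaptive": 0, "fixed": 0}
        for seed in range(6):
            img, truth = tray(jitter_mm=3.0, plants=plants, seed=seed)
            grid = traygrid.fit_and_extrapolate(
                traygrid.detect_crossings(img, LAYOUT), LAYOUT)
            fixed = traygrid.nominal_grid(LAYOUT, PITCH, ORIGIN)
            for name, g in (("adaptive", grid), ("fixed", fixed)):
                crops = traygrid.crop_pots(img, g, "T")
                cmap = {(c.x_index, c.y_index): c for c in crops}
                lost[name] += sum(
                    int(m.sum()) - growthfit.green_area(cmap[p].image)[0]
                    for m, p in zip(truth.blob_masks, truth.blob_pots))
        assert lost["adaptive"] == 0
        assert lost["fixed"] > 0
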