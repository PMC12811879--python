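"""Stimulus geometry, rendering, masking, and pool-sum accounting."""

import math
from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Point, box as shapely_box

from rivalnorm.stimulus import (
    ConditionSpec,
    GeometrySpec,
    PoolAccounting,
    StimulusConfigurationError,
    channel_sums,
    circle_rect_intersection_area,
    relabel_channels,
    render_fields,
    rivalry_mask,
    swap_eyes,
)
from rivalnorm.experiments import exp1_condition, exp2_condition

DISK_AREA = math.pi * 0.75**2


def raster_geometry(res=40):
    return GeometrySpec(raster_resolution=res, analytic=False)


class TestGeometryValidation:
    def test_defaults_are_valid(self):
        GeometrySpec().validate()

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(box_side=1.0), "box_side"),
            (dict(disk_diameter=2.0), "annulus_outer_diameter"),
            (dict(raster_resolution=0), "raster_resolution"),
            (dict(disk_center_offsets=(0.5, -0.5)), "overlap"),
            (dict(disk_center_offsets=(2.0, -2.0)), "beyond the fusion box"),
        ],
    )
    def test_invalid_geometry_names_constraint(self, kwargs, fragment):
        with pytest.raises(StimulusConfigurationError, match=fragment):
            GeometrySpec(**kwargs).validate()

    def test_rivalrous_background_requires_exp2(self):
        with pytest.raises(StimulusConfigurationError, match="exp2"):
            ConditionSpec(experiment="exp1", background="rivalrous").validate()

    def test_patchwork_required(self):
        bad = dict(exp1_condition("gray").disk_assignment)
        bad[("L", "bottom")] = bad[("L", "top")]
        with pytest.raises(StimulusConfigurationError, match="patchwork"):
            replace(exp1_condition("gray"), disk_assignment=bad).validate()


class TestAnalyticAreas:
    def test_circle_inside_rect_is_full_circle(self):
        area = circle_rect_intersection_area(0.0, 0.0, 1.0, 5.0, 5.0)
        assert area == pytest.approx(math.pi, rel=1e-12)

    @pytest.mark.parametrize("cy, r", [(1.5, 0.875), (1.5, 0.75), (2.0, 0.5), (-1.5, 0.875)])
    def test_clipped_circle_matches_shapely(self, cy, r):
        """Independent geometric oracle for the circle-box intersection."""
        ours = circle_rect_intersection_area(0.0, cy, r, 2.25, 2.25)
        oracle = Point(0.0, cy).buffer(r, quad_segs=4096).intersection(
            shapely_box(-2.25, -2.25, 2.25, 2.25)
        )
        assert ours == pytest.approx(oracle.area, rel=1e-5)

    def test_default_disk_is_tangent_not_clipped(self):
        assert GeometrySpec().disk_area() == pytest.approx(DISK_AREA, rel=1e-12)


class TestMask:
    def test_analytic_mask_area_is_two_disks(self):
        assert rivalry_mask(GeometrySpec()).area() == pytest.approx(
            2 * DISK_AREA, rel=1e-12
        )

    def test_raster_mask_area_converges(self):
        """Pixel-count error oscillates between adjacent resolutions, so the
        convergence ladder samples resolutions a factor of 4 apart."""
        errs = []
        for res in (10, 40, 160):
            area = rivalry_mask(raster_geometry(res)).area()
            errs.append(abs(area - 2 * DISK_AREA))
        assert errs[0] > errs[1] > errs[2]

    def test_mask_zero_at_fixation(self):
        mask = rivalry_mask(raster_geometry(40))
        n = mask.weights.shape[0]
        assert not mask.weights[n // 2, n // 2]


class TestRendering:
    def test_gray_background_has_no_chromatic_background_field(self):
        stim = render_fields(exp1_condition("gray"))
        assert stim.background_fields == {}
        # each eye carries one red and one green disk field
        for eye in ("L", "R"):
            assert {(eye, "red"), (eye, "green")} <= set(stim.disk_fields)

    def test_green_background_field_covers_box_minus_annulus_holes(self):
        stim = render_fields(exp1_condition("green"))
        geo = stim.geometry
        expected = geo.background_area("annulus_punched")
        for eye in ("L", "R"):
            assert stim.background_fields[(eye, "green")] == pytest.approx(expected)
            assert (eye, "red") not in stim.background_fields

    def test_raster_disk_area_within_one_percent(self):
        cond = replace(exp1_condition("gray"), geometry=raster_geometry(40))
        stim = render_fields(cond)
        pa = stim.pixel_area
        for (eye, lab), ind in stim.disk_fields.items():
            assert float(np.sum(ind)) * pa == pytest.approx(DISK_AREA, rel=0.01)

    def test_channel_exclusivity_per_pixel(self):
        cond = replace(exp1_condition("green"), geometry=raster_geometry(40))
        stim = render_fields(cond)
        for eye in ("L", "R"):
            total = np.zeros(next(iter(stim.disk_fields.values())).shape, dtype=int)
            for (e, lab), ind in stim.disk_fields.items():
                if e == eye:
                    total += ind.astype(int)
            for (e, lab), ind in stim.background_fields.items():
                if e == eye:
                    total += ind.astype(int)
            assert total.max() <= 1


class TestChannelSums:
    def test_gray_background_masked_equals_total(self, gray_bg):
        sums = channel_sums(render_fields(gray_bg), rivalry_mask(gray_bg.geometry))
        for lab in ("red", "green"):
            assert sums.masked[lab] == pytest.approx(sums.total[lab])

    def test_green_background_red_channel_fully_masked(self, green_bg):
        sums = channel_sums(render_fields(green_bg), rivalry_mask(green_bg.geometry))
        assert sums.masked["red"] == pytest.approx(sums.total["red"])
        assert sums.masked["green"] < sums.total["green"]

    @pytest.mark.parametrize("factory", [lambda: exp1_condition("green"), exp2_condition])
    def test_interocular_swap_leaves_sums_unchanged(self, factory):
        cond = factory()
        mask = rivalry_mask(cond.geometry)
        a = channel_sums(render_fields(cond), mask)
        b = channel_sums(render_fields(swap_eyes(cond)), mask)
        assert a.masked == b.masked and a.total == b.total

    def test_relabel_mirrors_sums(self, green_bg):
        mask = rivalry_mask(green_bg.geometry)
        a = channel_sums(render_fields(green_bg), mask)
        b = channel_sums(render_fields(relabel_channels(green_bg)), mask)
        assert a.masked["green"] == pytest.approx(b.masked["red"])
        assert a.total["green"] == pytest.approx(b.total["red"])

    def test_raster_ratio_converges_to_analytic(self):
        analytic = channel_sums(
            render_fields(exp1_condition("green")),
            rivalry_mask(GeometrySpec()),
            PoolAccounting(background_pool_weight=1.0),
        )
        target = analytic.masked["green"] / analytic.total["green"]
        errs = []
        for res in (10, 40, 160):
            geo = raster_geometry(res)
            cond = replace(exp1_condition("green"), geometry=geo)
            sums = channel_sums(
                render_fields(cond),
                rivalry_mask(geo),
                PoolAccounting(background_pool_weight=1.0),
            )
            errs.append(abs(sums.masked["green"] / sums.total["green"] - target))
        assert errs[0] > errs[1] > errs[2]

    def test_grid_mismatch_raises(self):
        cond = replace(exp1_condition("gray"), geometry=raster_geometry(40))
        with pytest.raises(StimulusConfigurationError, match="mode"):
            channel_sums(render_fields(cond), rivalry_mask(GeometrySpec()))
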