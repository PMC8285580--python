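"""Array registration: axes, reference optode, layout, placement rules."""

import numpy as np
import pytest

from nirsdot.array_registration import (
    PlacementMeasurement,
    apply_placement_rules,
    bright_array_spec,
    channel_scalp_midpoints,
    define_scalp_axes,
    layout_array,
    register_reference_optode,
)
from nirsdot.head_model import HeadMeasurements, curve_walk, measure_head, warp_head_model


@pytest.fixture(scope="module")
def right_axes(phantom):
    return define_scalp_axes(phantom, "right")


class TestArraySpec:
    def test_bilateral_composition(self, array_spec):
        assert array_spec.n_sources == 6
        assert array_spec.n_detectors == 7
        assert len(array_spec.channels_per_hemisphere) == 17
        assert len(array_spec.channels()) == 34

    def test_channels_pair_source_with_detector(self, array_spec):
        by_id = {o.optode_id: o for o in array_spec.optodes}
        for s, d in array_spec.channels_per_hemisphere:
            assert by_id[s].role == "source"
            assert by_id[d].role == "detector"

    def test_flat_template_channels_at_nominal_spacing(self, array_spec):
        by_id = {o.optode_id: o for o in array_spec.optodes}
        for s, d in array_spec.channels_per_hemisphere:
            a, b = by_id[s], by_id[d]
            assert np.hypot(a.x - b.x, a.y - b.y) == pytest.approx(20.0, abs=1e-9)

    def test_json_round_trip(self, array_spec):
        from nirsdot.array_registration import ArraySpec

        restored = ArraySpec.from_json(array_spec.to_json())
        assert restored == array_spec


class TestPlacementRules:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (1.0, 0.5, "keep"),
            (1.6, 0.0, "shift_backward"),
            (-1.6, 0.0, "shift_forward"),
            (0.0, 1.7, "exclude"),
            (-1.6, 1.6, "shift_forward"),   # 1.6 is not > 1.6: not excluded
            (0.0, -1.7, "exclude"),         # |y| rule by default
            (1.59, 1.59, "keep"),
        ],
    )
    def test_thresholds(self, x, y, expected):
        action = apply_placement_rules(PlacementMeasurement("left", x, y))
        assert action == expected

    def test_signed_y_option(self):
        p = PlacementMeasurement("left", 0.0, -1.7)
        assert apply_placement_rules(p, abs_y=False) == "keep"


class TestScalpAxes:
    def test_x_curve_endpoints(self, phantom, right_axes):
        from nirsdot.head_model import compute_10_5_positions

        pos = compute_10_5_positions(phantom)
        assert np.linalg.norm(right_axes.x_curve.points[0] -
                              phantom.landmarks["Iz"]) < 1.0
        assert np.linalg.norm(right_axes.x_curve.points[-1] - pos["FPz"]) < 1.0

    def test_left_right_axes_mirror(self, phantom, right_axes):
        left = define_scalp_axes(phantom, "left")
        assert left.x_curve.length == pytest.approx(right_axes.x_curve.length,
                                                    rel=1e-6)

    def test_transverse_arc_on_sphere(self, sphere_phantom):
        # preauricular -> CCPz spans 50 deg of longitude plus 5% midline arc;
        # compare against the analytic great-circle arc between those points
        axes = define_scalp_axes(sphere_phantom, "right")
        start = sphere_phantom.landmarks["Ar"]
        end = axes.y_anchor
        centre = np.array([0.0, 70.0, 0.0])
        u = (start - centre) / 70.0
        v = (end - centre) / np.linalg.norm(end - centre)
        expected = 70.0 * np.arccos(np.clip(np.dot(u, v), -1, 1))
        path = curve_walk(sphere_phantom.scalp_trimesh(), start, end,
                          prefer="short")
        assert path.length == pytest.approx(expected, rel=0.02)


class TestReferenceOptode:
    def test_zero_displacement_is_axes_origin(self, phantom, right_axes):
        ref = register_reference_optode(
            phantom, "right", PlacementMeasurement("right", 0.0, 0.0), right_axes)
        origin = right_axes.x_curve.point_at(right_axes.origin_arc)
        assert np.linalg.norm(ref - origin) < 1e-9

    def test_one_cm_anterior_is_10mm_arc(self, phantom, right_axes):
        ref0 = register_reference_optode(
            phantom, "right", PlacementMeasurement("right", 0.0, 0.0), right_axes)
        ref1 = register_reference_optode(
            phantom, "right", PlacementMeasurement("right", 1.0, 0.0), right_axes)
        s0 = right_axes.x_curve.arc_position_of(ref0)
        s1 = right_axes.x_curve.arc_position_of(ref1)
        assert s1 - s0 == pytest.approx(10.0, abs=0.5)

    def test_arc_displacements_add_along_y(self, phantom, right_axes):
        up = register_reference_optode(
            phantom, "right", PlacementMeasurement("right", 0.0, 1.0), right_axes)
        down = register_reference_optode(
            phantom, "right", PlacementMeasurement("right", 0.0, -1.0), right_axes)
        path = curve_walk(phantom.scalp_trimesh(), down, up, prefer="short")
        assert path.length == pytest.approx(20.0, abs=1.0)


class TestLayout:
    def test_same_row_arc_separation_nominal(self, phantom, array_spec, right_axes):
        pos = layout_array(phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, right_axes)
        scalp = phantom.scalp_trimesh()
        for row in ("lower", "upper"):
            optodes = sorted((o for o in array_spec.optodes if o.row == row),
                             key=lambda o: o.x)
            for a, b in zip(optodes[:-1], optodes[1:]):
                arc = curve_walk(scalp, pos["R:" + a.optode_id],
                                 pos["R:" + b.optode_id], prefer="short").length
                assert arc == pytest.approx(20.0, abs=1.0)

    def test_channel_chords_bounded_by_arc(self, phantom, array_spec, right_axes):
        pos = layout_array(phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, right_axes)
        scalp = phantom.scalp_trimesh()
        for ch in array_spec.channels():
            if ch.hemisphere != "right":
                continue
            chord = np.linalg.norm(pos[ch.source] - pos[ch.detector])
            arc = curve_walk(scalp, pos[ch.source], pos[ch.detector],
                             prefer="short").length
            assert chord <= arc + 1e-6
            assert chord <= 1.2 * array_spec.nominal_spacing

    def test_array_does_not_scale_with_head(self, phantom, array_spec):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.15,
                                  ar_cz_al=m0.ar_cz_al * 1.15,
                                  nz_cz_iz=m0.nz_cz_iz * 1.15)
        big, _ = warp_head_model(phantom, target)
        axes = define_scalp_axes(big, "right")
        pos = layout_array(big, "right", PlacementMeasurement("right", 0, 0),
                           array_spec, axes)
        scalp = big.scalp_trimesh()
        lower = sorted((o for o in array_spec.optodes if o.row == "lower"),
                       key=lambda o: o.x)
        for a, b in zip(lower[:-1], lower[1:]):
            arc = curve_walk(scalp, pos["R:" + a.optode_id],
                             pos["R:" + b.optode_id], prefer="short").length
            assert arc == pytest.approx(20.0, abs=1.0)

    def test_mirrored_layouts_on_symmetric_phantom(self, phantom, array_spec):
        right = layout_array(phantom, "right",
                             PlacementMeasurement("right", 0.3, 0.2), array_spec)
        left = layout_array(phantom, "left",
                            PlacementMeasurement("left", 0.3, 0.2), array_spec)
        for o in array_spec.optodes:
            mirrored = left["L:" + o.optode_id] * np.array([-1.0, 1.0, 1.0])
            assert np.linalg.norm(right["R:" + o.optode_id] - mirrored) < 1e-6

    def test_positions_on_scalp(self, phantom, array_spec, right_axes):
        pos = layout_array(phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, right_axes)
        semi = np.array([65.0, 72.0, 58.0])
        centre = np.array([0.0, 72.0, 0.0])
        for p in pos.values():
            r = np.linalg.norm((p - centre) / semi)
            assert r == pytest.approx(1.0, abs=0.01)

    def test_excessive_displacement_errors(self, phantom, array_spec, right_axes):
        with pytest.raises(ValueError, match="curve"):
            layout_array(phantom, "right",
                         PlacementMeasurement("right", 9.0, 0.0),
                         array_spec, right_axes)


class TestChannelMidpoints:
    def test_midpoint_equidistant_from_pair(self, phantom, array_spec, right_axes):
        pos = layout_array(phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, right_axes)
        mids = channel_scalp_midpoints(phantom, pos, array_spec)
        scalp = phantom.scalp_trimesh()
        ch = [c for c in array_spec.channels() if c.hemisphere == "right"][0]
        m = mids[ch.channel_id]
        da = curve_walk(scalp, pos[ch.source], m, prefer="short").length
        db = curve_walk(scalp, m, pos[ch.detector], prefer="short").length
        assert abs(da - db) < 1.0

    def test_degenerate_pair_midpoint_is_point(self, phantom, array_spec):
        pos = {c: np.array([65.0, 72.0, 0.0]) for c in
               [ch.source for ch in array_spec.channels()] +
               [ch.detector for ch in array_spec.channels()]}
        mids = channel_scalp_midpoints(phantom, pos, array_spec)
        for m in mids.values():
            assert np.allclose(m, [65.0, 72.0, 0.0])

    def test_midpoint_on_great_circle_on_sphere(self, sphere_phantom, array_spec):
        axes = define_scalp_axes(sphere_phantom, "right")
        pos = layout_array(sphere_phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, axes)
        mids = channel_scalp_midpoints(sphere_phantom, pos, array_spec)
        centre = np.array([0.0, 70.0, 0.0])
        ch = [c for c in array_spec.channels() if c.hemisphere == "right"][0]
        a = pos[ch.source] - centre
        b = pos[ch.detector] - centre
        n = np.cross(a, b)
        n /= np.linalg.norm(n)
        m = mids[ch.channel_id] - centre
        assert abs(np.dot(m, n)) < 1.0  # within mesh tolerance of the plane
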