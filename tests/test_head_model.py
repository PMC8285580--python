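"""Head-model geometry: landmark frame, curve walks, measurement, warping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nirsdot.head_model import (
    HeadMeasurements,
    WarpTolerances,
    WarpConvergenceError,
    align_to_landmark_frame,
    compute_10_5_positions,
    curve_walk,
    measure_head,
    parcel_of_node,
    warp_head_model,
    _transform,
)
from nirsdot.synthetic_data import PhantomSpec, make_phantom


class TestLandmarkFrame:
    def test_identity_for_mesh_already_in_frame(self, phantom):
        aligned = align_to_landmark_frame(phantom)
        assert np.abs(aligned.volume_nodes - phantom.volume_nodes).max() < 1e-9

    def test_inverts_rigid_transform(self, phantom):
        moved = phantom.copy()
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        _transform(moved, lambda p: p @ rot.T + np.array([5.0, -3.0, 7.0]))
        aligned = align_to_landmark_frame(moved)
        assert np.abs(aligned.volume_nodes - phantom.volume_nodes).max() < 1e-6

    def test_preauricular_points_levelled_after_random_transform(self, phantom, rng):
        moved = phantom.copy()
        rot = Rotation.random(random_state=7).as_matrix()
        _transform(moved, lambda p: p @ rot.T + rng.normal(size=3) * 10)
        aligned = align_to_landmark_frame(moved)
        dz = aligned.landmarks["Ar"][2] - aligned.landmarks["Al"][2]
        assert abs(dz) < 1e-6
        # brute-force search over y-rotations cannot do better
        d = aligned.landmarks["Ar"] - aligned.landmarks["Al"]
        best = min(
            abs(-np.sin(th) * d[0] + np.cos(th) * d[2])
            for th in np.linspace(-np.pi, np.pi, 3601)
        )
        assert abs(dz) <= best + 1e-6
        assert np.linalg.norm(aligned.landmarks["Iz"]) < 1e-9
        nz = aligned.landmarks["Nz"]
        assert abs(nz[0]) < 1e-6 and abs(nz[2]) < 1e-6 and nz[1] > 0

    def test_missing_landmark_is_named(self, phantom):
        broken = phantom.copy()
        del broken.landmarks["Cz"]
        with pytest.raises(ValueError, match="Cz"):
            align_to_landmark_frame(broken)


class TestCurveWalk:
    def test_degenerate_start_equals_end(self, sphere_phantom):
        scalp = sphere_phantom.scalp_trimesh()
        p = sphere_phantom.landmarks["Cz"]
        path = curve_walk(scalp, p, p)
        assert path.length == 0.0

    def test_pole_to_pole_arc_matches_great_circle(self, sphere_phantom):
        scalp = sphere_phantom.scalp_trimesh()
        path = curve_walk(
            scalp, sphere_phantom.landmarks["Nz"], sphere_phantom.landmarks["Iz"],
            via=sphere_phantom.landmarks["Cz"],
        )
        assert path.length == pytest.approx(np.pi * 70.0, rel=0.02)

    def test_arc_at_least_chord(self, phantom, rng):
        scalp = phantom.scalp_trimesh()
        verts = scalp.vertices
        for _ in range(5):
            a, b = verts[rng.integers(len(verts), size=2)]
            path = curve_walk(scalp, a, b, prefer="short")
            assert path.length >= np.linalg.norm(a - b) - 1e-9

    def test_refinement_converges_to_geodesic(self):
        errs = []
        for sub in (2, 3, 4):
            ph = make_phantom(PhantomSpec(semi_axes=(70.0, 70.0, 70.0),
                                          scalp_subdivisions=sub))
            path = curve_walk(ph.scalp_trimesh(), ph.landmarks["Nz"],
                              ph.landmarks["Iz"], via=ph.landmarks["Cz"])
            errs.append(abs(path.length - np.pi * 70.0))
        assert errs[2] < errs[0]


class TestTenFivePositions:
    def test_midline_midpoint_is_cz(self, sphere_phantom):
        pos = compute_10_5_positions(sphere_phantom)
        edge = 70.0 * 0.07  # scalp mesh edge length bound at subdivision 4
        assert np.linalg.norm(pos["Cz"] - sphere_phantom.landmarks["Cz"]) < edge

    def test_left_right_mirror_symmetry(self, sphere_phantom):
        pos = compute_10_5_positions(sphere_phantom)
        # coronal chain: fraction f from Ar mirrors fraction 1-f from Ar
        a = pos["cor_0.25"]
        b = pos["cor_0.75"]
        mirrored = b * np.array([-1.0, 1.0, 1.0])
        assert np.linalg.norm(a - mirrored) < 2.0

    def test_fpz_at_ten_percent_of_midline(self, sphere_phantom):
        pos = compute_10_5_positions(sphere_phantom)
        scalp = sphere_phantom.scalp_trimesh()
        mid = curve_walk(scalp, sphere_phantom.landmarks["Nz"],
                         sphere_phantom.landmarks["Iz"],
                         via=sphere_phantom.landmarks["Cz"])
        frac = mid.arc_position_of(pos["FPz"]) / mid.length
        assert frac == pytest.approx(0.10, abs=0.005)


class TestMeasureHead:
    def test_sphere_circumference_analytic(self, sphere_phantom):
        m = measure_head(sphere_phantom)
        assert m.circumference * 10 == pytest.approx(2 * np.pi * 70, rel=0.02)

    def test_nz_cz_iz_half_circumference_on_sphere(self, sphere_phantom):
        m = measure_head(sphere_phantom)
        assert m.nz_cz_iz == pytest.approx(m.circumference / 2, rel=0.02)

    def test_scaling_doubles_all_measurements(self, phantom):
        m0 = measure_head(phantom)
        doubled = phantom.copy()
        _transform(doubled, lambda p: 2.0 * p)
        m2 = measure_head(doubled)
        for name in ("circumference", "ar_cz_al", "nz_cz_iz"):
            assert getattr(m2, name) == pytest.approx(
                2 * getattr(m0, name), rel=1e-6)


class TestWarp:
    def test_fixed_point_converges_immediately(self, phantom):
        target = measure_head(phantom)
        warped, log = warp_head_model(phantom, target)
        assert len(log) == 1
        assert abs(log[0]["factor"] - 1.0) < 1e-9
        assert np.abs(warped.volume_nodes - phantom.volume_nodes).max() < 1e-9

    def test_similarity_target_scales_nodes(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(
            circumference=2 * m0.circumference,
            ar_cz_al=2 * m0.ar_cz_al,
            nz_cz_iz=2 * m0.nz_cz_iz,
        )
        warped, _ = warp_head_model(phantom, target)
        ratio = warped.volume_nodes / np.where(
            np.abs(phantom.volume_nodes) > 1e-9, phantom.volume_nodes, np.nan)
        assert np.nanmax(np.abs(ratio - 2.0)) < 0.02

    def test_anisotropic_target_met_within_tolerance(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(
            circumference=m0.circumference * 1.05,
            ar_cz_al=m0.ar_cz_al * 0.97,
            nz_cz_iz=m0.nz_cz_iz * 1.02,
        )
        warped, _ = warp_head_model(phantom, target)
        m = measure_head(warped)  # independent re-measurement
        assert abs(m.circumference - target.circumference) * 10 < 3.0
        assert abs(m.ar_cz_al - target.ar_cz_al) * 10 < 6.0
        assert abs(m.nz_cz_iz - target.nz_cz_iz) * 10 < 6.0

    def test_absent_nz_cz_iz_warps_on_remaining_measures(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.04,
                                  ar_cz_al=m0.ar_cz_al * 1.02)
        warped, _ = warp_head_model(phantom, target)
        m = measure_head(warped)
        assert abs(m.circumference - target.circumference) * 10 < 3.0
        assert abs(m.ar_cz_al - target.ar_cz_al) * 10 < 6.0

    def test_idempotent_at_fixed_point(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.05,
                                  ar_cz_al=m0.ar_cz_al * 0.97,
                                  nz_cz_iz=m0.nz_cz_iz * 1.02)
        once, _ = warp_head_model(phantom, target)
        twice, _ = warp_head_model(once, target)
        assert np.abs(twice.volume_nodes - once.volume_nodes).max() < 1e-6

    def test_topology_and_correspondence_preserved(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.1,
                                  ar_cz_al=m0.ar_cz_al * 1.05,
                                  nz_cz_iz=m0.nz_cz_iz)
        warped, _ = warp_head_model(phantom, target)
        assert warped.tetrahedra is phantom.tetrahedra or np.array_equal(
            warped.tetrahedra, phantom.tetrahedra)
        assert np.array_equal(warped.gm_surface_faces, phantom.gm_surface_faces)
        assert len(warped.volume_nodes) == len(phantom.volume_nodes)

    def test_nonconvergence_raises_with_errors(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.5,
                                  ar_cz_al=m0.ar_cz_al * 0.6,
                                  nz_cz_iz=m0.nz_cz_iz * 1.4)
        with pytest.raises(WarpConvergenceError, match="errors"):
            warp_head_model(phantom, target, WarpTolerances(max_iterations=2))

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            HeadMeasurements(circumference=-40.0)


class TestParcels:
    def test_returns_stored_label(self, phantom):
        assert parcel_of_node(phantom, 0) == int(phantom.parcel_labels[0])

    def test_label_rides_through_warp(self, phantom):
        m0 = measure_head(phantom)
        target = HeadMeasurements(circumference=m0.circumference * 1.05,
                                  ar_cz_al=m0.ar_cz_al,
                                  nz_cz_iz=m0.nz_cz_iz)
        warped, _ = warp_head_model(phantom, target)
        for idx in (0, 100, 500):
            assert parcel_of_node(warped, idx) == parcel_of_node(phantom, idx)

    def test_out_of_range_index(self, phantom):
        with pytest.raises(IndexError):
            parcel_of_node(phantom, len(phantom.parcel_labels))

    def test_four_parcels_near_uniform_on_sphere(self):
        ph = make_phantom(PhantomSpec(semi_axes=(70.0, 70.0, 70.0), n_parcels=4))
        counts = np.bincount(ph.parcel_labels, minlength=4)
        assert counts.min() > 0.9 * counts.mean()
        assert counts.max() < 1.1 * counts.mean()
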