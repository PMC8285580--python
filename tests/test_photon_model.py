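"""Sensitivity model, grey-matter masks, Tikhonov reconstruction."""

import numpy as np
import pytest

from nirsdot.array_registration import PlacementMeasurement, define_scalp_axes, layout_array
from nirsdot.photon_model import (
    compute_sensitivity,
    group_gm_mask,
    individual_gm_mask,
    load_optical_properties,
    make_reconstructor,
    mua_to_hb,
    node_volumes,
    reconstruct,
    sensitivity_com,
    volume_to_surface,
    window_average_image,
)
from nirsdot.preprocessing import extinction_matrix


@pytest.fixture(scope="module")
def right_positions(phantom, array_spec):
    axes = define_scalp_axes(phantom, "right")
    return layout_array(phantom, "right",
                        PlacementMeasurement("right", 0.0, 0.0),
                        array_spec, axes)


@pytest.fixture(scope="module")
def right_channels(array_spec):
    return [(c.source, c.detector) for c in array_spec.channels()
            if c.hemisphere == "right"]


@pytest.fixture(scope="module")
def J(phantom, right_positions, right_channels):
    return compute_sensitivity(phantom, right_positions, right_channels)


class TestSensitivity:
    def test_reciprocity(self, phantom, right_positions, right_channels):
        s, d = right_channels[0]
        both = compute_sensitivity(phantom, right_positions, [(s, d), (d, s)])
        v = both.values[780.0]
        assert np.abs(v[0] - v[1]).max() <= 1e-9 * np.abs(v[0]).max()

    def test_nonnegative_for_absorption(self, J):
        for v in J.values.values():
            assert v.min() >= 0.0

    def test_banana_core_exceeds_lateral_nodes(self, phantom, J, right_positions,
                                               right_channels):
        s, d = right_channels[0]
        mid = 0.5 * (right_positions[s] + right_positions[d])
        nodes = phantom.volume_nodes[J.node_indices]
        vols = node_volumes(phantom)[J.node_indices]
        density = J.values[780.0][0] / vols   # per-volume sensitivity
        d_axis = np.linalg.norm(nodes - mid, axis=1)
        near = density[d_axis < 12.0].max()
        lateral = density[d_axis >= 30.0]
        assert near > lateral.max()

    def test_decay_with_distance_from_channel(self, phantom, J, right_positions,
                                              right_channels):
        s, d = right_channels[0]
        mid = 0.5 * (right_positions[s] + right_positions[d])
        nodes = phantom.volume_nodes[J.node_indices]
        vols = node_volumes(phantom)[J.node_indices]
        density = J.values[780.0][0] / vols
        d_axis = np.linalg.norm(nodes - mid, axis=1)
        shells = [(20, 35), (35, 50), (50, 80)]
        means = [density[(d_axis >= a) & (d_axis < b)].mean() for a, b in shells]
        assert means[0] > means[1] > means[2]

    def test_off_scalp_properties_rejected(self):
        with pytest.raises(ValueError):
            load_optical_properties("granite")


class TestCentreOfMass:
    def test_uniform_row_gives_centroid(self, rng):
        coords = rng.random((50, 3))
        com = sensitivity_com(np.ones(50), coords)
        assert np.allclose(com, coords.mean(axis=0))

    def test_symmetric_channel_on_midplane(self, phantom, right_positions,
                                           right_channels, J):
        # a lower-row channel spanning the reference sits symmetric about
        # the coronal plane of its own midpoint; CoM x matches midpoint x
        s, d = right_channels[0]
        mid = 0.5 * (right_positions[s] + right_positions[d])
        nodes = phantom.volume_nodes[J.node_indices]
        com = sensitivity_com(J.values[780.0][0], nodes)
        assert abs(com[2] - mid[2]) < 6.0  # stays near the channel plane

    def test_translation_invariance_infinite_medium(self, phantom, array_spec):
        channels = [(c.source, c.detector) for c in array_spec.channels()
                    if c.hemisphere == "right"][:1]
        axes = define_scalp_axes(phantom, "right")
        pos = layout_array(phantom, "right",
                           PlacementMeasurement("right", 0.0, 0.0),
                           array_spec, axes)
        J0 = compute_sensitivity(phantom, pos, channels, semi_infinite=False)
        shift = np.array([3.0, -2.0, 1.5])
        shifted = {k: v + shift for k, v in pos.items()}
        # translate the node cloud with the optodes: rows must be identical
        moved = phantom.copy()
        moved.volume_nodes = moved.volume_nodes + shift
        moved.scalp_surface_nodes = moved.scalp_surface_nodes + shift
        J1 = compute_sensitivity(moved, shifted, channels, semi_infinite=False)
        a, b = J0.values[780.0][0], J1.values[780.0][0]
        assert np.abs(a - b).max() < 1e-9 * np.abs(a).max()

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_com(np.zeros(5), np.zeros((5, 3)))


class TestMasks:
    def test_uniform_sensitivity_includes_all(self, phantom, J):
        uniform = type(J)(
            values={780.0: np.ones_like(J.values[780.0])},
            channel_ids=J.channel_ids,
            node_indices=J.node_indices,
            optode_positions=J.optode_positions,
            optical_properties=J.optical_properties,
        )
        mask = individual_gm_mask(uniform, phantom)
        assert mask.all()

    def test_one_percent_threshold_boundary(self, phantom, J):
        # construct a row with known fractional values at three gm-surface
        # shell nodes (which map to the surface at distance zero)
        nodes = phantom.volume_nodes[J.node_indices]
        gm = phantom.gm_surface_nodes
        cols = []
        for target in (gm[10], gm[200], gm[400]):
            cols.append(int(np.argmin(np.linalg.norm(nodes - target, axis=1))))
        row = np.zeros(len(nodes))
        row[cols[0]] = 1.0
        row[cols[1]] = 0.009
        row[cols[2]] = 0.011
        fake = type(J)(
            values={780.0: row[None, :]},
            channel_ids=[("s", "d")],
            node_indices=J.node_indices,
            optode_positions={},
            optical_properties=J.optical_properties,
        )
        mask = individual_gm_mask(fake, phantom)
        assert mask[10] and mask[400]
        assert not mask[200]

    def test_empty_sensitivity_empty_mask(self, phantom, J):
        empty = type(J)(
            values={780.0: np.zeros((0, len(J.node_indices)))},
            channel_ids=[],
            node_indices=J.node_indices,
            optode_positions={},
            optical_properties=J.optical_properties,
        )
        assert not individual_gm_mask(empty, phantom).any()

    def test_threshold_monotonicity(self, phantom, J):
        low = individual_gm_mask(J, phantom, threshold_fraction=0.01)
        high = individual_gm_mask(J, phantom, threshold_fraction=0.05)
        assert not (high & ~low).any()

    @pytest.mark.parametrize("present,total,kept", [
        (3, 4, True), (2, 4, False), (30, 40, True), (29, 40, False)])
    def test_group_mask_three_quarters_rule(self, present, total, kept):
        masks = [np.array([i < present]) for i in range(total)]
        assert group_gm_mask(masks)[0] == kept

    def test_identical_masks_unchanged(self, rng):
        m = rng.random(100) > 0.5
        assert np.array_equal(group_gm_mask([m] * 7), m)


class TestReconstruction:
    def test_zero_data_zero_image(self, rng):
        J = rng.random((8, 40))
        assert np.abs(reconstruct(J, np.zeros(8))).max() == 0.0

    def test_matches_svd_oracle(self, rng):
        for _ in range(5):
            J = rng.random((10, 50))
            y = rng.standard_normal(10)
            lam2 = 0.1**2 * np.max(np.diag(J @ J.T))
            U, S, Vt = np.linalg.svd(J, full_matrices=False)
            oracle = Vt.T @ (S / (S**2 + lam2) * (U.T @ y))
            x = reconstruct(J, y)
            assert np.abs(x - oracle).max() < 1e-8 * np.abs(oracle).max()

    def test_linearity(self, rng):
        J = rng.random((6, 30))
        y1, y2 = rng.standard_normal((2, 6))
        lhs = reconstruct(J, 2.0 * y1 + 3.0 * y2)
        rhs = 2.0 * reconstruct(J, y1) + 3.0 * reconstruct(J, y2)
        assert np.abs(lhs - rhs).max() < 1e-9 * max(1.0, np.abs(rhs).max())

    def test_operator_factored_once_for_all_frames(self, rng):
        J = rng.random((6, 30))
        W = make_reconstructor(J)
        frames = rng.standard_normal((6, 221))
        batch = W @ frames
        single = np.column_stack([reconstruct(J, frames[:, k])
                                  for k in range(0, 221, 55)])
        assert np.allclose(batch[:, ::55], single)

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ValueError):
            make_reconstructor(np.zeros((0, 10)))


class TestChromophoreSolve:
    def test_pure_hbo_change(self, rng):
        E = extinction_matrix() / 10.0
        hbo = rng.standard_normal(25)
        dm = {780.0: E[0, 0] * hbo, 850.0: E[1, 0] * hbo}
        out_o, out_r = mua_to_hb(dm)
        assert np.abs(out_o - hbo).max() < 1e-9
        assert np.abs(out_r).max() < 1e-9

    def test_round_trip(self, rng):
        E = extinction_matrix() / 10.0
        hbo, hbr = rng.standard_normal((2, 30))
        dm = {780.0: E[0, 0] * hbo + E[0, 1] * hbr,
              850.0: E[1, 0] * hbo + E[1, 1] * hbr}
        out_o, out_r = mua_to_hb(dm)
        assert np.abs(out_o - hbo).max() < 1e-9
        assert np.abs(out_r - hbr).max() < 1e-9

    def test_hbo_increase_raises_850_more(self):
        E = extinction_matrix() / 10.0
        assert E[1, 0] > E[0, 0]


class TestWindowAverage:
    TIME = -2.0 + np.arange(221) / 10.0

    def test_constant_timecourse(self):
        img = np.full((5, 221), 3.3)
        assert np.allclose(window_average_image(img, self.TIME), 3.3)

    def test_41_samples_in_window(self):
        sel = (self.TIME >= 12.0 - 1e-9) & (self.TIME <= 16.0 + 1e-9)
        assert sel.sum() == 41

    def test_linear_ramp_mean(self):
        img = (2.0 * self.TIME)[None, :]
        assert window_average_image(img, self.TIME)[0] == pytest.approx(28.0)

    def test_window_outside_block_rejected(self):
        with pytest.raises(ValueError):
            window_average_image(np.zeros((1, 221)), self.TIME, window=(19, 23))


class TestVolumeToSurface:
    def test_surface_shell_maps_identically(self, phantom, J):
        vals = np.arange(len(J.node_indices), dtype=float)
        mapped = volume_to_surface(vals, J.node_indices, phantom)
        nodes = phantom.volume_nodes[J.node_indices]
        # gm-surface nodes exist in the volume cloud at distance zero
        i = int(np.argmin(np.linalg.norm(nodes - phantom.gm_surface_nodes[50],
                                         axis=1)))
        assert mapped[50] == vals[i]
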