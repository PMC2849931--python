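import numpy as np
import pandas as pd
import pytest

from fluoroi.image_io import Image
from fluoroi.laminar import (
    ISO_INDICES,
    CentreOfMass,
    Contour,
    assign_positions,
    centre_of_mass,
    classify_polarity,
    contour_from_csv,
    contour_to_csv,
    isocontour_family,
    orient_contours,
    position_histogram,
    resample_contour,
    smooth_contour,
)
from fluoroi.roi_detect import ROIMask
from fluoroi.synthgen import SceneSpec, make_layered_scene


def straight_family(y0=0.0, y100=100.0, x_max=100.0, m=101):
    xs = np.linspace(0, x_max, m)
    c0 = Contour(np.column_stack([xs, np.full(m, y0)]))
    c100 = Contour(np.column_stack([xs, np.full(m, y100)]))
    return isocontour_family(c0, c100)


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        c = Contour(np.array([[0.0, 0.0], [10.0, 0.0]]))
        r = resample_contour(c, 11)
        np.testing.assert_allclose(r.points[:, 0], np.arange(11.0), atol=1e-12)
        np.testing.assert_allclose(r.points[:, 1], 0.0)

    def test_l_shape_matches_cumulative_arc_length_oracle(self):
        # L: (0,0)->(4,0)->(4,3), total length 7
        c = Contour(np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 3.0]]))
        r = resample_contour(c, 8)  # spacing 1.0
        expected = []
        for s in np.linspace(0, 7, 8):
            expected.append([s, 0.0] if s <= 4 else [4.0, s - 4.0])
        np.testing.assert_allclose(r.points, expected, atol=1e-12)

    def test_endpoints_preserved(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(6, 2)), axis=0)
        r = resample_contour(Contour(pts), 64)
        np.testing.assert_allclose(r.points[0], pts[0])
        np.testing.assert_allclose(r.points[-1], pts[-1])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_contour(Contour(np.array([[0, 0], [1, 1]])), 1)


class TestSmooth:
    def test_straight_line_unchanged(self):
        xs = np.linspace(0, 50, 80)
        c = Contour(np.column_stack([xs, 2.0 * xs + 1.0]))
        s = smooth_contour(c, span=0.2)
        np.testing.assert_allclose(s.points, c.points, atol=1e-8)

    def test_zigzag_attenuated(self):
        xs = np.arange(100.0)
        ys = np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        s = smooth_contour(Contour(np.column_stack([xs, ys])), span=0.2)
        assert np.abs(s.points[:, 1]).max() < 0.3

    def test_tiny_span_returns_input_with_warning(self):
        c = Contour(np.column_stack([np.arange(10.0), np.zeros(10)]))
        with pytest.warns(UserWarning):
            s = smooth_contour(c, span=0.05)
        np.testing.assert_array_equal(s.points, c.points)


class TestOrient:
    def test_parallel_lines_unchanged(self):
        xs = np.linspace(0, 10, 20)
        c0 = Contour(np.column_stack([xs, np.zeros(20)]))
        c100 = Contour(np.column_stack([xs, np.full(20, 5.0)]))
        _, out = orient_contours(c0, c100)
        np.testing.assert_array_equal(out.points, c100.points)

    def test_reversed_second_line_flipped(self):
        xs = np.linspace(0, 10, 20)
        c0 = Contour(np.column_stack([xs, np.zeros(20)]))
        c100 = Contour(np.column_stack([xs[::-1], np.full(20, 5.0)]))
        _, out = orient_contours(c0, c100)
        np.testing.assert_allclose(out.points[:, 0], xs)

    def test_pairing_segments_do_not_cross(self, rng):
        """Index-wise pairing chords between oriented borders never intersect."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            xs = np.linspace(0, 60, 40)
            c0 = Contour(np.column_stack([xs, 5 * np.sin(xs / 12) + r.uniform(-0.2, 0.2, 40)]))
            flip = r.random() < 0.5
            x2 = xs[::-1] if flip else xs
            c100 = Contour(
                np.column_stack([x2, 20 + 4 * np.cos(x2 / 15) + r.uniform(-0.2, 0.2, 40)])
            )
            a, b = orient_contours(c0, c100)

            def ccw(p, q, s):
                return (s[1] - p[1]) * (q[0] - p[0]) > (q[1] - p[1]) * (s[0] - p[0])

            for j in range(0, 39, 3):
                for k in range(j + 3, 40, 7):
                    p1, p2 = a.points[j], b.points[j]
                    q1, q2 = a.points[k], b.points[k]
                    crosses = (ccw(p1, q1, q2) != ccw(p2, q1, q2)) and (
                        ccw(p1, p2, q1) != ccw(p1, p2, q2)
                    )
                    assert not crosses


class TestIsocontours:
    def test_endpoint_contours_reproduced_exactly(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(30, 2)), axis=0)
        c0 = Contour(pts)
        c100 = Contour(pts + [0.0, 25.0])
        fam = isocontour_family(c0, c100)
        np.testing.assert_array_equal(fam.contour(0), c0.points)
        np.testing.assert_array_equal(fam.contour(100), c100.points)

    def test_family_has_99_intermediate_and_2_extrapolated(self):
        fam = straight_family()
        indices = sorted(fam.contours)
        assert len(indices) == 103
        assert sum(1 for i in indices if 0 < i < 100) == 99
        assert -1 in indices and 101 in indices

    def test_straight_borders_interpolate_linearly(self):
        fam = straight_family()
        for i in (-1, 0, 37, 100, 101):
            np.testing.assert_allclose(fam.contour(i)[:, 1], float(i))

    def test_mismatched_point_counts_rejected(self):
        c0 = Contour(np.array([[0.0, 0.0], [1.0, 0.0]]))
        c100 = Contour(np.array([[0.0, 5.0], [0.5, 5.0], [1.0, 5.0]]))
        with pytest.raises(ValueError):
            isocontour_family(c0, c100)


class TestCentreOfMass:
    def test_uniform_square_gives_geometric_centroid(self):
        labels = np.ones((8, 8), np.int32)
        labels[0:4, 0:4] = -1
        com = centre_of_mass(ROIMask(labels), Image(np.ones((8, 8))), 1)
        assert com.position == (1.5, 1.5)

    def test_hand_computed_weighted_example(self):
        labels = np.ones((3, 3), np.int32)
        labels[0, 0] = labels[0, 1] = -1
        weights = np.zeros((3, 3))
        weights[0, 0], weights[0, 1] = 1.0, 3.0  # x=0 mass 1, x=1 mass 3
        com = centre_of_mass(ROIMask(labels), Image(weights + 1e-12), 1)
        assert com.position[0] == pytest.approx(0.75)
        assert com.position[1] == pytest.approx(0.0)

    def test_single_pixel_roi(self):
        labels = np.ones((5, 5), np.int32)
        labels[3, 2] = -1
        com = centre_of_mass(ROIMask(labels), Image(np.full((5, 5), 2.0)), 1)
        assert com.position == (2.0, 3.0)

    def test_zero_mass_falls_back_to_centroid(self):
        labels = np.ones((4, 4), np.int32)
        labels[0:2, 0:2] = -1
        with pytest.warns(UserWarning):
            com = centre_of_mass(ROIMask(labels), Image(np.zeros((4, 4))), 1)
        assert com.position == (0.5, 0.5)

    def test_missing_roi_rejected(self):
        with pytest.raises(ValueError):
            centre_of_mass(ROIMask(np.ones((4, 4), np.int32)), Image(np.ones((4, 4))), 1)


class TestAssignPositions:
    def test_centre_on_border_gets_zero(self):
        fam = straight_family()
        t = assign_positions(fam, [CentreOfMass(1, (50.0, 0.0), 1.0)])
        assert t.depth_percent.iloc[0] == 0

    def test_analytic_fractional_depth_rounds_to_nearest(self):
        fam = straight_family()
        t = assign_positions(fam, [CentreOfMass(1, (12.0, 37.2), 1.0)])
        assert t.depth_percent.iloc[0] == 37

    def test_beyond_outer_border_binned_to_101(self):
        fam = straight_family()
        t = assign_positions(fam, [CentreOfMass(1, (50.0, 104.0), 1.0)])
        assert t.depth_percent.iloc[0] == 101

    def test_border_swap_mirrors_depths(self):
        xs = np.linspace(0, 100, 201)
        c0 = Contour(np.column_stack([xs, 3 * np.sin(xs / 20)]))
        c100 = Contour(np.column_stack([xs, 80 + 2 * np.cos(xs / 25)]))
        centres = [
            CentreOfMass(i + 1, (x, y), 1.0)
            for i, (x, y) in enumerate([(20, 10), (50, 40), (80, 70), (30, 85)])
        ]
        fwd = assign_positions(isocontour_family(c0, c100), centres)
        rev = assign_positions(isocontour_family(c100, c0), centres)
        np.testing.assert_array_equal(
            rev.depth_percent.to_numpy(), 100 - fwd.depth_percent.to_numpy()
        )

    def test_invariant_under_rigid_motion(self, rng):
        xs = np.linspace(0, 60, 121)
        b0 = np.column_stack([xs, 2 * np.sin(xs / 10)])
        b100 = np.column_stack([xs, 40 + 2 * np.cos(xs / 10)])
        pts = rng.uniform([5, 5], [55, 35], size=(6, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([13.0, -4.0])

        def table(bb0, bb100, cc):
            fam = isocontour_family(Contour(bb0), Contour(bb100))
            centres = [CentreOfMass(i + 1, tuple(p), 1.0) for i, p in enumerate(cc)]
            return assign_positions(fam, centres).depth_percent.to_numpy()

        before = table(b0, b100, pts)
        after = table(b0 @ R.T + shift, b100 @ R.T + shift, pts @ R.T + shift)
        np.testing.assert_array_equal(before, after)


class TestPolarity:
    def test_flat_trace_nonresponsive(self, rng):
        trace = rng.normal(0, 0.05, 60)
        call = classify_polarity(trace, slice(0, 20), slice(25, 40), slice(45, 60))
        assert call.polarity == "NONRESPONSIVE"

    def test_sustained_increase_is_on(self, rng):
        trace = rng.normal(0, 0.05, 60)
        trace[25:40] += 1.0
        call = classify_polarity(trace, slice(0, 20), slice(25, 40), slice(45, 60))
        assert call.polarity == "ON" and call.stim_score > 3

    def test_dip_with_rebound_is_off(self, rng):
        trace = rng.normal(0, 0.05, 60)
        trace[25:40] -= 0.6
        trace[45:55] += 0.8
        call = classify_polarity(trace, slice(0, 20), slice(25, 40), slice(45, 60))
        assert call.polarity == "OFF"

    def test_rebound_only_off(self, rng):
        trace = rng.normal(0, 0.05, 60)
        trace[45:60] += 1.0  # increase only after the stimulus
        call = classify_polarity(trace, slice(0, 20), slice(25, 40), slice(45, 60))
        assert call.polarity == "OFF"

    def test_zero_pre_sd_warns_nonresponsive(self):
        trace = np.zeros(60)
        trace[30] = 5.0
        with pytest.warns(UserWarning):
            call = classify_polarity(trace, slice(0, 20), slice(25, 40), slice(45, 60))
        assert call.polarity == "NONRESPONSIVE"

    def test_overlapping_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_polarity(rng.normal(size=60), slice(0, 30), slice(25, 40), slice(45, 60))


class TestHistogram:
    def _table(self, depths):
        return pd.DataFrame(
            {"roi_id": range(1, len(depths) + 1), "depth_percent": depths,
             "distance_px": 0.0}
        )

    def test_counts_conserved_with_all_filter(self):
        depths = [-1, 3, 37, 50, 50, 99, 101]
        h = position_histogram(self._table(depths), polarity="ALL")
        assert h["count"].sum() == len(depths)

    def test_two_layer_scene_modal_bins(self, rng):
        on_d = rng.integers(68, 73, size=30)
        off_d = rng.integers(18, 23, size=20)
        depths = np.concatenate([on_d, off_d])
        calls = [
            type("C", (), {"roi_id": i + 1, "polarity": "ON" if i < 30 else "OFF"})()
            for i in range(50)
        ]
        t = self._table(depths)
        h_on = position_histogram(t, calls, polarity="ON")
        h_off = position_histogram(t, calls, polarity="OFF")
        modal_on = h_on.loc[h_on["count"].idxmax()]
        modal_off = h_off.loc[h_off["count"].idxmax()]
        assert abs((modal_on.bin_low + modal_on.bin_high) / 2 - 70) <= 5
        assert abs((modal_off.bin_low + modal_off.bin_high) / 2 - 20) <= 5

    def test_empty_class_gives_all_zero(self):
        calls = [type("C", (), {"roi_id": 1, "polarity": "ON"})()]
        h = position_histogram(self._table([50]), calls, polarity="OFF")
        assert h["count"].sum() == 0


class TestLayeredSceneDepths:
    def test_arc_scene_recovers_planted_depths_within_two_points(self):
        spec = SceneSpec(
            shape=(128, 128), n_blobs=5, noise_sd=0.1, background="constant",
            min_separation=10, margin=8, seed=4,
        )
        img, (c0, c100), truth = make_layered_scene(
            [10, 30, 50, 70, 90], spec, geometry="arc"
        )
        m = 8 * 128
        c0r = smooth_contour(resample_contour(c0, m), 0.1)
        c100r = smooth_contour(resample_contour(c100, m), 0.1)
        c0r, c100r = orient_contours(c0r, c100r)
        fam = isocontour_family(c0r, c100r)
        centres = [
            CentreOfMass(i + 1, tuple(truth.centres[i]), 1.0) for i in range(5)
        ]
        t = assign_positions(fam, centres)
        assert np.abs(t.depth_percent.to_numpy() - truth.depths).max() <= 2

    def test_out_of_layer_terminals_bin_to_extrapolated_contours(self):
        spec = SceneSpec(
            shape=(128, 128), n_blobs=2, noise_sd=0.0, background="constant",
            min_separation=10, margin=8, seed=7,
        )
        _, (c0, c100), truth = make_layered_scene([-1, 101], spec, geometry="line")
        fam = isocontour_family(
            *orient_contours(resample_contour(c0, 512), resample_contour(c100, 512))
        )
        centres = [CentreOfMass(i + 1, tuple(truth.centres[i]), 1.0) for i in range(2)]
        depths = set(assign_positions(fam, centres).depth_percent)
        assert depths == {-1, 101}


class TestContourCsv:
    def test_round_trip(self, tmp_path, rng):
        c = Contour(rng.uniform(0, 50, size=(9, 2)))
        contour_to_csv(c, tmp_path / "c.csv")
        np.testing.assert_allclose(contour_from_csv(tmp_path / "c.csv").points, c.points)
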