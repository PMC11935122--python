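"""ER segmentation, skeleton junction analysis, and instance counting."""

import numpy as np
import pytest
from skimage.draw import disk as disk_coords

from stedqc.phantom import (AcquisitionParams, DynamicsParams, PhantomParams,
                            generate_phantom, simulate_timeseries)
from stedqc.structure import (BACKGROUND, SBT, SHEET, TUBE, ClassLabelMap,
                              class_fractions, count_instances,
                              foreground_fraction, merge_sbt,
                              rolling_ball_subtract, segment_er,
                              skeleton_junctions, summarize_timeseries)
from conftest import draw_stroke


def _flood_fill_counts(labels):
    """Independent instance counts: stack-based flood fill.

    8-connectivity for tube/sheet masks, 4-connectivity for background;
    gaps are background components not touching the border.
    """
    def components(mask, conn8):
        seen = np.zeros_like(mask, dtype=bool)
        comps = []
        nbrs = ([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
                if conn8 else [(-1, 0), (1, 0), (0, -1), (0, 1)])
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if mask[i, j] and not seen[i, j]:
                    stack, comp = [(i, j)], []
                    seen[i, j] = True
                    while stack:
                        r, c = stack.pop()
                        comp.append((r, c))
                        for dr, dc in nbrs:
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                    and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                    comps.append(comp)
        return comps

    n_tube = len(components(labels == TUBE, True))
    n_sheet = len(components(np.isin(labels, (SHEET, SBT)), True))
    h, w = labels.shape
    gaps = 0
    for comp in components(labels == BACKGROUND, False):
        if not any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp):
            gaps += 1
    return n_tube, n_sheet, gaps


class TestRollingBall:
    def test_constant_image_removed(self):
        out = rolling_ball_subtract(np.full((64, 64), 37.0), radius_px=15)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_single_bright_pixel_preserved(self):
        img = np.zeros((64, 64))
        img[30, 30] = 100.0
        out = rolling_ball_subtract(img, radius_px=15)
        assert out[30, 30] == pytest.approx(100.0, rel=0.05)

    def test_ramp_removed_disk_preserved(self):
        h = w = 96
        ramp = np.tile(np.linspace(0, 50, w), (h, 1))
        img = ramp.copy()
        rr, cc = disk_coords((48, 48), 4)
        img[rr, cc] += 80.0
        out = rolling_ball_subtract(img, radius_px=15)
        # disk contrast against its local surroundings survives
        disk_peak = out[rr, cc].mean()
        assert disk_peak >= 0.9 * 80.0 * 0.9  # within ~10% of added contrast
        ramp_residual = np.ptp(out[10, :])    # a row far from the disk
        assert ramp_residual < 0.2 * 50.0     # >80% of the ramp amplitude gone

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((32, 32)), radius_px=0)
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((32, 32)), radius_px=40)


class TestSegmentER:
    def test_tube_only_phantom_mostly_tube(self):
        ph = generate_phantom(PhantomParams(n_sheets=0, rng_seed=4))
        seg = segment_er(ph.density_map * 100, pixel_size_nm=20.0)
        _, sheet_frac = class_fractions(seg)
        assert sheet_frac <= 0.05

    def test_single_disk_mostly_sheet(self):
        img = np.zeros((128, 128))
        rr, cc = disk_coords((64, 64), 25)
        img[rr, cc] = 100.0
        seg = segment_er(img, pixel_size_nm=20.0)
        tube_frac, _ = class_fractions(seg)
        assert tube_frac <= 0.1

    def test_all_zero_frame_is_background(self):
        with pytest.warns(UserWarning):
            seg = segment_er(np.zeros((64, 64)), pixel_size_nm=20.0)
        assert (seg.labels == BACKGROUND).all()

    def test_recovery_against_truth_over_seeds(self):
        """Mean |tube_fraction - truth| over 10 phantoms stays within 0.15."""
        errors = []
        for seed in range(10):
            ph = generate_phantom(PhantomParams(
                height_px=128, width_px=128, n_seed_nodes=15, n_sheets=1,
                sheet_area_px_range=(150, 500), rng_seed=seed))
            truth_tube, _ = class_fractions(ph.label_map)
            seg = segment_er(ph.density_map * 100, pixel_size_nm=20.0)
            if not seg.foreground_mask.any():
                continue
            got_tube, _ = class_fractions(seg)
            errors.append(abs(got_tube - truth_tube))
        assert np.mean(errors) <= 0.15


class TestMergeSBT:
    def test_no_sbt_unchanged(self):
        labels = ClassLabelMap(np.array([[0, 1], [2, 1]], dtype=np.uint8), 20.0)
        np.testing.assert_array_equal(merge_sbt(labels).labels, labels.labels)

    def test_all_sbt_becomes_sheet(self):
        labels = ClassLabelMap(np.full((8, 8), SBT, dtype=np.uint8), 20.0)
        assert (merge_sbt(labels).labels == SHEET).all()

    def test_mixed_map_bookkeeping_and_idempotence(self, rng):
        arr = rng.integers(0, 4, (32, 32)).astype(np.uint8)
        labels = ClassLabelMap(arr, 20.0)
        n_sbt = int((arr == SBT).sum())
        n_sheet = int((arr == SHEET).sum())
        merged = merge_sbt(labels)
        assert int((merged.labels == SHEET).sum()) == n_sheet + n_sbt
        assert not (merged.labels == SBT).any()
        np.testing.assert_array_equal(merge_sbt(merged).labels, merged.labels)


class TestClassFractions:
    def test_all_tube(self):
        labels = ClassLabelMap(np.full((16, 16), TUBE, dtype=np.uint8), 20.0)
        assert class_fractions(labels) == (1.0, 0.0)

    def test_counting(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr.ravel()[:60] = TUBE
        arr.ravel()[60:100] = SHEET
        tube_frac, sheet_frac = class_fractions(ClassLabelMap(arr, 20.0))
        assert tube_frac == pytest.approx(0.6)
        assert sheet_frac == pytest.approx(0.4)
        assert tube_frac + sheet_frac == pytest.approx(1.0)

    def test_empty_foreground_is_nan(self):
        labels = ClassLabelMap(np.zeros((8, 8), dtype=np.uint8), 20.0)
        with pytest.warns(UserWarning):
            tube_frac, sheet_frac = class_fractions(labels)
        assert np.isnan(tube_frac) and np.isnan(sheet_frac)

    def test_unmerged_sbt_rejected(self):
        arr = np.full((8, 8), SBT, dtype=np.uint8)
        with pytest.raises(ValueError):
            class_fractions(ClassLabelMap(arr, 20.0))


class TestSkeletonJunctions:
    def _labels(self, mask):
        return ClassLabelMap(mask.astype(np.uint8) * TUBE, 20.0)

    def test_straight_line(self):
        mask = draw_stroke((64, 64), (32, 8), (32, 56), 2.0)
        g = skeleton_junctions(self._labels(mask))
        assert g.n_endpoints == 2
        assert g.junction_counts == {}

    def test_y_shape_one_order3(self):
        mask = (draw_stroke((96, 96), (48, 48), (10, 48), 2.0)
                | draw_stroke((96, 96), (48, 48), (80, 20), 2.0)
                | draw_stroke((96, 96), (48, 48), (80, 76), 2.0))
        g = skeleton_junctions(self._labels(mask))
        assert g.n_endpoints == 3
        assert g.junction_counts == {3: 1}

    def test_cross_one_order4(self):
        mask = (draw_stroke((96, 96), (48, 10), (48, 86), 2.0)
                | draw_stroke((96, 96), (10, 48), (86, 48), 2.0))
        g = skeleton_junctions(self._labels(mask))
        assert g.n_endpoints == 4
        assert g.junction_counts == {4: 1}

    def test_empty_mask_empty_graph(self):
        g = skeleton_junctions(self._labels(np.zeros((32, 32), dtype=bool)))
        assert g.nodes == [] and g.n_edges == 0

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_handshake_identity_on_phantoms(self, seed):
        """Sum of node degrees equals twice the number of edge incidences."""
        ph = generate_phantom(PhantomParams(
            height_px=128, width_px=128, n_seed_nodes=15, n_sheets=0,
            rng_seed=seed))
        g = skeleton_junctions(ph.label_map)
        assert sum(d for *_, d in g.nodes) == 2 * g.n_edges

    def test_order3_modal_on_target3_phantoms(self):
        ph = generate_phantom(PhantomParams(n_sheets=0, rng_seed=1))
        g = skeleton_junctions(ph.label_map)
        assert g.junction_counts
        assert max(g.junction_counts, key=g.junction_counts.get) == 3


class TestCountInstances:
    def test_empty_map(self):
        assert count_instances(
            ClassLabelMap(np.zeros((16, 16), dtype=np.uint8), 20.0)) == (0, 0, 0)

    def test_ring_encloses_one_gap(self):
        arr = np.zeros((32, 32), dtype=np.uint8)
        rr, cc = np.mgrid[0:32, 0:32]
        ring = (np.hypot(rr - 16, cc - 16) <= 10) & (np.hypot(rr - 16, cc - 16) >= 6)
        arr[ring] = TUBE
        assert count_instances(ClassLabelMap(arr, 20.0)) == (1, 0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(20):
            arr = r.choice([0, 0, 0, 1, 2], size=(24, 24)).astype(np.uint8)
            got = count_instances(ClassLabelMap(arr, 20.0))
            assert got == _flood_fill_counts(arr)


class TestForegroundFraction:
    def test_all_zero_is_zero(self):
        assert foreground_fraction(np.zeros((32, 32))) == 0.0

    def test_half_set_binary(self):
        img = np.zeros((32, 32))
        img[:16] = 1.0
        assert foreground_fraction(img) == pytest.approx(0.5)

    def test_fixed_threshold_counting(self, rng):
        img = np.zeros((100, 100))
        idx = rng.choice(10_000, size=137, replace=False)
        img.ravel()[idx] = 1.0
        assert foreground_fraction(img, method="fixed", threshold=0.5) \
            == pytest.approx(0.0137)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            foreground_fraction(np.ones((8, 8)), method="median")


class TestSummarizeTimeseries:
    PARAMS = PhantomParams(height_px=128, width_px=128, n_seed_nodes=12,
                           n_sheets=1, rng_seed=6)

    def test_single_frame_has_no_adjacent_ssim(self):
        movie, truths = simulate_timeseries(
            self.PARAMS, DynamicsParams(n_frames=1, rng_seed=1),
            AcquisitionParams(dose_per_unit_density=100))
        summaries = summarize_timeseries(movie, truths)
        assert len(summaries) == 1
        assert summaries[0].adjacent_ssim is None

    def test_static_movie_constant_metrics(self):
        movie, truths = simulate_timeseries(
            self.PARAMS, DynamicsParams(n_frames=3, rearrangement_rate=0.0,
                                        rng_seed=2),
            AcquisitionParams(dose_per_unit_density=100))
        static = np.stack([movie[0]] * 3)  # identical frames, identical labels
        summaries = summarize_timeseries(static, [truths[0]] * 3)
        for s in summaries[1:]:
            assert s.tube_fraction == summaries[0].tube_fraction
            assert s.n_gap_instances == summaries[0].n_gap_instances
            assert s.adjacent_ssim == pytest.approx(1.0)

    def test_rearrangement_ramp_lowers_second_half_ssim(self):
        """A movie that starts quiet and turns turbulent loses adjacent SSIM."""
        quiet, truths_q = simulate_timeseries(
            self.PARAMS, DynamicsParams(n_frames=6, rearrangement_rate=0.02,
                                        rng_seed=3),
            AcquisitionParams(dose_per_unit_density=100, rng_seed=1))
        wild, truths_w = simulate_timeseries(
            self.PARAMS, DynamicsParams(n_frames=6, rearrangement_rate=0.7,
                                        rng_seed=3),
            AcquisitionParams(dose_per_unit_density=100, rng_seed=2))
        movie = np.concatenate([quiet, wild])
        summaries = summarize_timeseries(movie, truths_q + truths_w)
        vals = [s.adjacent_ssim for s in summaries[1:]]
        assert np.mean(vals[6:]) < np.mean(vals[:5])

    def test_length_mismatch_rejected(self, rng):
        movie = rng.random((3, 32, 32))
        with pytest.raises(ValueError):
            summarize_timeseries(movie, [])
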