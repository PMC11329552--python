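import numpy as np
import pytest
from scipy import ndimage

from rimotion.errors import (
    EmptySegmentationError,
    InvalidArgumentError,
    NoCyclesError,
    TrackingGapError,
)
from rimotion.signals import DisplacementTrace
from rimotion.simulator import simulate_mask_sequence
from rimotion.ustrack import (
    BinaryMask,
    EdgeSet,
    FilterConfig,
    RoiBox,
    dice,
    evaluate_segmentation,
    extract_edge,
    hausdorff,
    postprocess_mask,
    preprocess_image,
    summarize_displacement,
    track_displacement,
)


def brute_force_hausdorff_px(a, b):
    """Independent oracle over all point pairs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def square_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess_image(np.full((20, 20), 7.0), RoiBox(0, 10, 0, 10))
        assert out.shape == (10, 10)
        assert np.all(out == 0.0)

    def test_crop_to_512(self):
        img = np.random.default_rng(0).uniform(0, 255, (600, 700))
        out = preprocess_image(img, RoiBox(10, 522, 50, 562))
        assert out.shape == (512, 512)

    def test_stretch_spans_unit_interval(self):
        img = np.linspace(10, 200, 10000).reshape(100, 100)
        out = preprocess_image(img, RoiBox(0, 100, 0, 100))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_crop_outside_image_rejected(self):
        with pytest.raises(InvalidArgumentError):
            preprocess_image(np.zeros((10, 10)), RoiBox(0, 20, 0, 5))


class TestPostprocess:
    def test_smaller_component_removed(self):
        m = np.zeros((10, 20), dtype=bool)
        m[1:3, 1:6] = True  # 10 px
        m[7:8, 15:18] = True  # 3 px
        out = postprocess_mask(m, closing_radius=0)
        assert out.n_foreground == 10
        assert not out.data[7, 15]

    def test_interior_hole_filled(self):
        m = square_mask((10, 10), 2, 7, 2, 7)
        m[4, 4] = False
        out = postprocess_mask(m, closing_radius=0)
        assert out.data[4, 4]

    def test_idempotent_on_clean_mask(self):
        m = square_mask((12, 12), 3, 9, 3, 9)
        out = postprocess_mask(m, closing_radius=0)
        assert np.array_equal(out.data, m)

    def test_empty_mask_raises_with_frame_id(self):
        with pytest.raises(EmptySegmentationError) as err:
            postprocess_mask(BinaryMask(data=np.zeros((5, 5)), frame_id=17))
        assert err.value.frame_id == 17

    def test_metadata_preserved(self):
        m = BinaryMask(data=square_mask((8, 8), 2, 6, 2, 6),
                       pixel_spacing=0.05, timestamp=1.5, frame_id=3)
        out = postprocess_mask(m, closing_radius=1)
        assert (out.pixel_spacing, out.timestamp, out.frame_id) == (0.05, 1.5, 3)


class TestExtractEdge:
    def test_three_by_three_square_has_eight_edge_pixels(self):
        edges = extract_edge(square_mask((5, 5), 1, 4, 1, 4))
        assert len(edges) == 8
        assert [2, 2] not in edges.pixels.tolist()

    def test_single_pixel_is_its_own_edge(self):
        m = np.zeros((4, 4), dtype=bool)
        m[2, 2] = True
        edges = extract_edge(m)
        assert edges.pixels.tolist() == [[2, 2]]

    def test_one_pixel_wide_line_is_all_edge(self):
        m = np.zeros((5, 8), dtype=bool)
        m[2, 1:7] = True
        assert len(extract_edge(m)) == 6

    def test_border_counts_as_background(self):
        m = np.ones((3, 3), dtype=bool)
        # border is background, so the ring is edge; only the centre is interior
        assert len(extract_edge(m)) == 8

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            extract_edge(np.zeros((3, 3)))


class TestTrackDisplacement:
    def _edges_at_cols(self, cols, shape=(20, 120)):
        out = []
        for i, c in enumerate(cols):
            m = square_mask(shape, 4, 16, 2, c + 1)  # right edge at column c
            out.append(extract_edge(m))
        return out

    def test_constant_edge_gives_zero_trace(self):
        edges = self._edges_at_cols([50, 50, 50])
        trace = track_displacement(edges, RoiBox(6, 14, 40, 120),
                                   pixel_spacing=0.027)
        assert np.allclose(trace.si_mm, 0.0)

    def test_ten_pixel_shift_is_0p27_cm(self):
        edges = self._edges_at_cols([100, 110])
        trace = track_displacement(edges, RoiBox(6, 14, 60, 120),
                                   pixel_spacing=0.027)
        assert trace.si_cm[1] == pytest.approx(0.27)
        assert trace.si_mm[1] == pytest.approx(2.7)

    def test_roundtrip_recovers_simulated_sinusoid_within_one_pixel(self):
        t = np.arange(0, 12, 1 / 15)
        si = 15.0 * (1 - np.cos(2 * np.pi * 0.25 * t))
        gen = DisplacementTrace(timestamps=t, si_mm=si)
        masks = simulate_mask_sequence(gen, image_size=(64, 220),
                                       pixel_spacing=0.027, rest_col=30)
        edges = [extract_edge(m.data) for m in masks]
        trace = track_displacement(edges, RoiBox(10, 54, 1, 220),
                                   pixel_spacing=0.027, timestamps=t)
        assert np.max(np.abs(trace.si_mm - si)) <= 10 * 0.027  # 1 px in mm

    def test_gap_raises_with_frame_id(self):
        edges = self._edges_at_cols([100, 20, 100])  # middle frame leaves ROI
        with pytest.raises(TrackingGapError) as err:
            track_displacement(edges, RoiBox(6, 14, 60, 120))
        assert err.value.frame_id == 1

    def test_gap_interpolated_when_allowed(self):
        edges = self._edges_at_cols([100, 20, 104])
        trace = track_displacement(edges, RoiBox(6, 14, 60, 120),
                                   pixel_spacing=1.0, max_gap=1)
        assert trace.si_cm[1] == pytest.approx(2.0)  # midway 100 -> 104

    def test_filtering_never_amplifies_white_noise(self, rng):
        t = np.arange(0, 30, 1 / 15)
        clean = 10 * np.sin(2 * np.pi * 0.25 * t)
        cols = np.round(60 + clean + rng.normal(0, 1.0, t.size)).astype(int)
        edges = self._edges_at_cols(cols.tolist(), shape=(20, 160))
        raw = track_displacement(edges, RoiBox(6, 14, 30, 160), 0.027,
                                 timestamps=t, filter_cfg=None)
        smooth = track_displacement(edges, RoiBox(6, 14, 30, 160), 0.027,
                                    timestamps=t, filter_cfg=FilterConfig())
        resid_raw = raw.si_mm - (clean - clean[0]) * 0.27
        resid_smooth = smooth.si_mm - (clean - clean[0]) * 0.27
        assert resid_smooth.var() <= resid_raw.var()


class TestDice:
    def test_identical_masks(self):
        m = square_mask((10, 10), 2, 6, 2, 6)
        assert dice(m, m) == pytest.approx(100.0)

    def test_two_by_two_blocks_half_overlap(self):
        a = square_mask((6, 6), 1, 3, 1, 3)
        b = square_mask((6, 6), 1, 3, 2, 4)
        assert dice(a, b) == pytest.approx(50.0)  # 2*2 / (4+4)

    def test_disjoint_masks(self):
        a = square_mask((6, 6), 0, 2, 0, 2)
        b = square_mask((6, 6), 4, 6, 4, 6)
        assert dice(a, b) == 0.0

    def test_symmetry(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        assert dice(a, b) == pytest.approx(dice(b, a))

    def test_both_empty_flagged_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(dice(np.zeros((3, 3)), np.zeros((3, 3))))


class TestHausdorff:
    def test_identical_sets_zero(self):
        e = EdgeSet(pixels=[[0, 0], [1, 2]])
        assert hausdorff(e, e) == 0.0

    def test_three_four_five_triangle(self):
        # distance 5 px * 0.027 cm/px * 10 = 1.35 mm
        assert hausdorff([[0, 0]], [[3, 4]], 0.027) == pytest.approx(1.35)
        assert hausdorff([[0, 0]], [[3, 4]], 0.027, units="px") == pytest.approx(5.0)

    def test_shifted_square_edge_matches_brute_force(self):
        a = extract_edge(square_mask((12, 12), 3, 8, 3, 8)).pixels
        b = extract_edge(square_mask((12, 12), 3, 8, 4, 9)).pixels
        expected = brute_force_hausdorff_px(a, b)
        assert hausdorff(a, b, 0.027, units="px") == pytest.approx(expected)
        assert expected == pytest.approx(1.0)
        assert hausdorff(a, b, 0.027) == pytest.approx(0.27)

    def test_symmetry_and_triangle_inequality_on_toys(self, rng):
        sets = [rng.integers(0, 20, size=(6, 2)) for _ in range(3)]
        d = lambda i, j: hausdorff(sets[i], sets[j], 1.0, units="px")
        assert d(0, 1) == pytest.approx(d(1, 0))
        assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-9
        for i in range(3):
            assert d(i, i) == 0.0

    def test_roi_restriction_and_empty_roi_error(self):
        a = [[0, 0], [10, 10]]
        b = [[0, 1], [10, 50]]
        roi = RoiBox(0, 5, 0, 5)
        assert hausdorff(a, b, 1.0, roi=roi, units="px") == pytest.approx(1.0)
        with pytest.raises(InvalidArgumentError, match="second"):
            hausdorff([[1, 1]], [[40, 40]], 1.0, roi=roi)


class TestEvaluateSegmentation:
    def _masks(self, n=25):
        return [BinaryMask(data=square_mask((20, 20), 5, 15, 5, 15),
                           frame_id=i) for i in range(n)]

    def test_perfect_agreement(self):
        masks = self._masks()
        res = evaluate_segmentation(masks, masks, n_samples=20, seed=0)
        assert res["dice_pct"]["mean"] == pytest.approx(100.0)
        assert res["dice_pct"]["sd"] == 0.0
        assert res["hausdorff_px"]["mean"] == 0.0
        assert res["n_samples"] == 20

    def test_cross_dilated_reference_hand_computed(self):
        masks = self._masks(25)
        refs = [
            BinaryMask(data=ndimage.binary_dilation(m.data), frame_id=m.frame_id)
            for m in masks
        ]
        res = evaluate_segmentation(masks, refs, n_samples=20, seed=1)
        # cross-dilated 10x10 square: area 140, overlap 100 -> Dice 83.33 %
        assert res["dice_pct"]["mean"] == pytest.approx(100 * 200 / 240)
        assert res["hausdorff_px"]["mean"] == pytest.approx(1.0)

    def test_short_sequence_uses_all_frames_with_warning(self):
        masks = self._masks(5)
        res = evaluate_segmentation(masks, masks, n_samples=20, seed=0)
        assert res["n_samples"] == 5
        assert res["warnings"]

    def test_seeded_sampling_reproducible(self):
        masks = self._masks(30)
        a = evaluate_segmentation(masks, masks, seed=9)
        b = evaluate_segmentation(masks, masks, seed=9)
        assert a["frames"] == b["frames"]


class TestSummarizeDisplacement:
    def test_pure_sinusoid_30mm(self, sinusoid_trace):
        res = summarize_displacement(sinusoid_trace)
        assert res["amplitude_mean_mm"] == pytest.approx(30.0, abs=0.05)
        assert res["amplitude_sd_mm"] == pytest.approx(0.0, abs=0.05)

    def test_constant_trace_has_no_cycles(self):
        trace = DisplacementTrace(timestamps=np.arange(10.0), si_mm=np.full(10, 3.0))
        with pytest.raises(NoCyclesError):
            summarize_displacement(trace)

    def test_alternating_amplitudes_20_40(self):
        t = np.arange(0, 16, 1 / 20)
        phase = 2 * np.pi * 0.25 * t
        envelope = np.where((t // 4) % 2 == 0, 20.0, 40.0)
        y = envelope / 2 * (1 - np.cos(2 * np.pi * 0.25 * (t % 4)))
        trace = DisplacementTrace(timestamps=t, si_mm=y)
        res = summarize_displacement(trace)
        assert res["amplitude_mean_mm"] == pytest.approx(30.0, abs=1.0)
        amps = res["amplitudes_mm"]
        assert amps.min() == pytest.approx(20.0, abs=1.0)
        assert amps.max() == pytest.approx(40.0, abs=1.0)
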