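"""Edge-map normalization, intermode thresholding and the S/D/SD indicators."""

import numpy as np
import pytest

from busroi.boxes import Box
from busroi.edge_scoring import (
    BinaryEdgeMap,
    EdgeMap,
    RoiScore,
    binarize_edge_map,
    indicator_D,
    indicator_S,
    intermode_threshold,
    intermode_threshold_info,
    normalize_edge_map,
    score_roi,
)


# --- independent oracle: iterative 3-bin smoothing, written as plain loops ---

def intermode_oracle(hist):
    """Reference intermode threshold on a 256-bin histogram (bin index scale).

    Returns (threshold_bin, fallback_used).  Pure-Python reimplementation kept
    independent of the vectorized production code.
    """
    h = [float(v) for v in hist]

    def peaks(y):
        out = []
        for i in range(256):
            left = y[i - 1] if i > 0 else float("-inf")
            right = y[i + 1] if i < 255 else float("-inf")
            if y[i] > left and y[i] > right:
                out.append(i)
        return out

    mean = sum(i * v for i, v in enumerate(h)) / sum(h)
    for _ in range(10_000):
        p = peaks(h)
        if len(p) == 2:
            return (p[0] + p[1]) / 2.0, False
        if len(p) < 2:
            return mean, True
        h = [
            (h[max(0, i - 1)] + h[i] + h[min(255, i + 1)]) / 3.0
            for i in range(256)
        ]
    p = peaks(h)
    if len(p) == 2:
        return (p[0] + p[1]) / 2.0, False
    return mean, True


def map_from_hist(hist, rng):
    """An EdgeMap whose 256-bin intensity histogram equals ``hist``."""
    values = np.repeat(np.arange(256), hist).astype(float) / 255.0
    rng.shuffle(values)
    side = int(np.ceil(np.sqrt(len(values))))
    padded = np.zeros(side * side)
    padded[: len(values)] = values
    return EdgeMap(padded.reshape(side, side)), len(values), side * side


class TestNormalize:
    def test_divides_by_255(self):
        em = normalize_edge_map(np.array([[255, 0], [51, 102]]))
        assert np.allclose(em.values, [[1.0, 0.0], [0.2, 0.4]])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            normalize_edge_map(np.array([[0, 300]]))


class TestIntermodeThreshold:
    def test_symmetric_two_delta_histogram_gives_half(self):
        """Mass only at intensities 0 and 255 -> threshold 127.5/255 = 0.5."""
        em = EdgeMap(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert intermode_threshold(em) == pytest.approx(0.5)

    def test_constant_map_falls_back_to_mean(self, caplog):
        em = EdgeMap(np.full((8, 8), 51 / 255))
        with caplog.at_level("WARNING"):
            threshold, fallback = intermode_threshold_info(em)
        assert fallback
        assert threshold == pytest.approx(51 / 255)
        assert "unimodal" in caplog.text

    def test_matches_brute_force_oracle_on_bimodal_histograms(self):
        """100 random two-lobe histograms agree with the loop-based oracle."""
        rng = np.random.default_rng(2024_06)
        for _ in range(100):
            c1 = rng.integers(10, 90)
            c2 = rng.integers(150, 245)
            n1, n2 = rng.integers(200, 2000, size=2)
            s1, s2 = rng.uniform(3, 25, size=2)
            samples = np.concatenate(
                [rng.normal(c1, s1, n1), rng.normal(c2, s2, n2)]
            )
            hist = np.bincount(
                np.clip(np.rint(samples), 0, 255).astype(int), minlength=256
            )
            em, n, total = map_from_hist(hist, rng)
            # padding zeros land in bin 0 and merge into the low lobe
            hist_with_pad = hist.copy()
            hist_with_pad[0] += total - n
            expected_bin, expected_fb = intermode_oracle(hist_with_pad)
            got, fb = intermode_threshold_info(em)
            assert fb == expected_fb
            assert got * 255.0 == pytest.approx(expected_bin, abs=1e-9)


class TestBinarize:
    def test_strict_comparison(self):
        em = EdgeMap(np.array([[0.0, 0.5], [0.6, 1.0]]))
        bem = binarize_edge_map(em, 0.5)
        assert bem.values.tolist() == [[0, 0], [1, 1]]
        assert bem.threshold_used == 0.5

    def test_all_zero_map_stays_zero_under_zero_threshold(self):
        em = EdgeMap(np.zeros((4, 4)))
        assert binarize_edge_map(em, 0.0).values.sum() == 0

    def test_per_pixel_agreement_with_loops(self):
        rng = np.random.default_rng(5)
        v = rng.random((4, 4))
        bem = binarize_edge_map(EdgeMap(v), 0.5)
        for j in range(4):
            for i in range(4):
                assert bem.values[j, i] == (1 if v[j, i] > 0.5 else 0)


class TestIndicators:
    def test_S_on_constant_maps(self):
        roi = Box(0, 0, 2, 2)
        assert indicator_S(EdgeMap(np.ones((5, 5))), roi) == pytest.approx(9.0)
        assert indicator_S(EdgeMap(np.zeros((5, 5))), roi) == 0.0

    def test_S_equals_double_loop_sum(self):
        rng = np.random.default_rng(7)
        v = rng.random((4, 4))
        roi = Box(1, 1, 2, 2)
        expected = sum(v[j][i] for j in range(1, 3) for i in range(1, 3))
        assert indicator_S(EdgeMap(v), roi) == pytest.approx(expected, abs=1e-9)

    def test_D_density_examples(self):
        ones = BinaryEdgeMap(np.ones((4, 4), dtype=int), threshold_used=0.5)
        zeros = BinaryEdgeMap(np.zeros((4, 4), dtype=int), threshold_used=0.5)
        roi = Box(0, 0, 3, 1)  # 8 pixels
        assert indicator_D(ones, roi) == 1.0
        assert indicator_D(zeros, roi) == 0.0
        two_set = np.zeros((4, 4), dtype=int)
        two_set[0, 0] = two_set[1, 3] = 1
        assert indicator_D(BinaryEdgeMap(two_set, 0.5), roi) == pytest.approx(0.25)

    def test_out_of_frame_roi_errors(self):
        em = EdgeMap(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            indicator_S(em, Box(0, 0, 4, 4))

    def test_D_on_full_frame_is_global_set_fraction(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((6, 9)) > 0.6).astype(int)
        bem = BinaryEdgeMap(mask, 0.5)
        full = Box(0, 0, 8, 5)
        assert indicator_D(bem, full) == pytest.approx(mask.mean())

    def test_S_monotone_under_enlargement(self):
        rng = np.random.default_rng(9)
        em = EdgeMap(rng.random((16, 16)))
        inner = Box(4, 4, 8, 8)
        outer = Box(2, 3, 10, 11)
        assert indicator_S(em, outer) >= indicator_S(em, inner)


class TestScoreRoi:
    def test_sd_is_exact_product(self):
        sc = RoiScore(S=5507.0, D=0.25)
        assert sc.SD == 5507.0 * 0.25

    def test_zero_mass_annihilates(self):
        assert RoiScore(S=0.0, D=0.9).SD == 0.0

    def test_size_mismatch_errors(self):
        em = EdgeMap(np.zeros((4, 4)))
        bem = BinaryEdgeMap(np.zeros((5, 5), dtype=int), 0.5)
        with pytest.raises(ValueError):
            score_roi(em, bem, Box(0, 0, 1, 1))

    def test_intensity_scaling_scales_S_only(self):
        """Scaling the edge map by c scales S by c; D is fixed by the mask."""
        rng = np.random.default_rng(21)
        v = rng.random((10, 10))
        bem = binarize_edge_map(EdgeMap(v), 0.5)
        roi = Box(2, 2, 7, 7)
        base = score_roi(EdgeMap(v), bem, roi)
        scaled = score_roi(EdgeMap(0.5 * v), bem, roi)
        assert scaled.S == pytest.approx(0.5 * base.S)
        assert scaled.D == base.D
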