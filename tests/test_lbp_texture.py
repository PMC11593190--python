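"""LBP unit tests, including an independent pure-Python oracle."""
import math

import numpy as np
import pytest

from histofuse.imageio_preproc import GrayImage
from histofuse.lbp_texture import (LBPConfig, LBPNeighborhood, lbp_code,
                                   lbp_code_map, lbp_feature_vector,
                                   neighbor_offsets, sample_neighbors,
                                   threshold_s, uniform_bin)


def oracle_code_map(G: np.ndarray, P: int, R: float, mode: str) -> np.ndarray:
    """Naive double-loop LBP, sharing only the mathematical definition:
    neighbour p at (-R sin, +R cos) of angle 2*pi*p/P, bilinear sampling
    with near-integer snapping, threshold g_p >= g_c, raw power-of-two code
    or uniform transition binning."""
    b = math.ceil(R)
    H, W = G.shape
    out = np.empty((H - 2 * b, W - 2 * b), dtype=np.int64)
    for r in range(b, H - b):
        for c in range(b, W - b):
            gc = G[r, c]
            bits = []
            for p in range(P):
                th = 2.0 * math.pi * p / P
                dr = -R * math.sin(th)
                dc = R * math.cos(th)
                if abs(dr - round(dr)) < 1e-8:
                    dr = float(round(dr))
                if abs(dc - round(dc)) < 1e-8:
                    dc = float(round(dc))
                fr, fc = math.floor(dr), math.floor(dc)
                ar, ac = dr - fr, dc - fc
                v = (1 - ar) * (1 - ac) * G[r + fr, c + fc]
                if (1 - ar) * ac:
                    v += (1 - ar) * ac * G[r + fr, c + fc + 1]
                if ar * (1 - ac):
                    v += ar * (1 - ac) * G[r + fr + 1, c + fc]
                if ar * ac:
                    v += ar * ac * G[r + fr + 1, c + fc + 1]
                bits.append(1 if v >= gc else 0)
            if mode == "raw":
                out[r - b, c - b] = sum(bit << p for p, bit in enumerate(bits))
            else:
                trans = sum(bits[p] != bits[p - 1] for p in range(P))
                out[r - b, c - b] = sum(bits) if trans <= 2 else P + 1
    return out


class TestThreshold:
    @pytest.mark.parametrize("x,expected", [(-0.5, 0), (0.0, 1), (7.3, 1),
                                            (-1e-12, 0)])
    def test_sign_threshold(self, x, expected):
        assert threshold_s(x) == expected


class TestConfig:
    def test_paper_default_gives_1280_bins(self):
        cfg = LBPConfig()
        assert (cfg.P, cfg.R, cfg.mode) == (1278, 1.0, "uniform")
        assert cfg.n_bins == 1280

    def test_raw_mode_restricted_to_small_p(self):
        assert LBPConfig(P=16, mode="raw").n_bins == 2 ** 16
        with pytest.raises(ValueError, match="P <= 16"):
            LBPConfig(P=17, mode="raw")

    @pytest.mark.parametrize("kwargs", [dict(P=0), dict(R=0.0),
                                        dict(mode="rotinv")])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            LBPConfig(**kwargs)


class TestSampleNeighbors:
    def test_constant_image_all_neighbors_equal_center(self):
        gray = GrayImage(np.full((9, 9), 42.0))
        nb = sample_neighbors(gray, (4, 4), LBPConfig(P=12, R=2.0))
        assert np.allclose(nb.g_p, 42.0)
        assert nb.g_c == 42.0

    def test_axial_positions_read_exactly(self, rng):
        G = rng.uniform(0, 255, size=(7, 7))
        nb = sample_neighbors(GrayImage(G), (3, 3), LBPConfig(P=4, R=1.0))
        # p=0 east, p=1 north, p=2 west, p=3 south (ccw from east)
        expected = [G[3, 4], G[2, 3], G[3, 2], G[4, 3]]
        np.testing.assert_array_equal(nb.g_p, expected)

    def test_diagonal_neighbor_is_bilinear_blend_on_ramp(self):
        # ramp I(r, c) = c: bilinear interpolation is exact for a linear
        # field, so the diagonal neighbour value is c + sqrt(2)/2.
        G = np.tile(np.arange(9, dtype=float), (9, 1))
        nb = sample_neighbors(GrayImage(G), (4, 4), LBPConfig(P=8, R=1.0))
        d = math.sqrt(2) / 2
        assert nb.g_p[1] == pytest.approx(4 + d, abs=1e-12)  # north-east
        assert nb.g_p[3] == pytest.approx(4 - d, abs=1e-12)  # north-west

    def test_center_too_close_to_border(self):
        gray = GrayImage(np.zeros((9, 9)))
        with pytest.raises(ValueError, match="border"):
            sample_neighbors(gray, (0, 4), LBPConfig(P=8, R=1.0))

    def test_offsets_lie_on_circle(self):
        offs = neighbor_offsets(LBPConfig(P=30, R=2.5))
        radii = np.hypot(offs[:, 0], offs[:, 1])
        np.testing.assert_allclose(radii, 2.5, atol=1e-7)


class TestCodes:
    def test_all_equal_gives_all_ones_code(self):
        nb = LBPNeighborhood(g_c=5.0, g_p=np.full(8, 5.0))
        assert lbp_code(nb) == 255

    def test_all_below_gives_zero(self):
        nb = LBPNeighborhood(g_c=9.0, g_p=np.arange(8.0))
        assert lbp_code(nb) == 0

    def test_hand_worked_example(self):
        nb = LBPNeighborhood(g_c=4.0, g_p=[5, 1, 7, 2])
        assert lbp_code(nb) == 5  # bits 1,0,1,0 -> 2^0 + 2^2

    @pytest.mark.parametrize("bits,expected", [
        ([0, 0, 0, 0], 0),
        ([1, 1, 1, 1], 4),
        ([0, 1, 0, 1], 5),       # 4 circular transitions -> non-uniform bin
        ([1, 1, 0, 0], 2),       # 2 transitions, 2 ones
        ([0, 1, 1, 1, 1, 1, 1, 0], 6),
    ])
    def test_uniform_bin(self, bits, expected):
        assert uniform_bin(bits) == expected


class TestCodeMapOracle:
    @pytest.mark.parametrize("P", [4, 8])
    @pytest.mark.parametrize("mode", ["raw", "uniform"])
    def test_matches_naive_double_loop(self, P, mode, rng):
        for _ in range(10):
            G = rng.uniform(0, 255, size=(12, 12))
            cfg = LBPConfig(P=P, R=1.0, mode=mode)
            got = lbp_code_map(GrayImage(G), cfg)
            np.testing.assert_array_equal(
                got.codes, oracle_code_map(G, P, 1.0, mode))
            assert got.n_bins == cfg.n_bins

    def test_interpolated_radius_matches_oracle(self, rng):
        G = rng.uniform(0, 255, size=(10, 10))
        cfg = LBPConfig(P=6, R=1.5, mode="uniform")
        got = lbp_code_map(GrayImage(G), cfg)
        np.testing.assert_array_equal(got.codes,
                                      oracle_code_map(G, 6, 1.5, "uniform"))

    def test_monotone_shift_invariance(self, rng):
        G = rng.uniform(0, 200, size=(16, 16))
        cfg = LBPConfig(P=8, R=1.0, mode="raw")
        a = lbp_code_map(GrayImage(G), cfg)
        b = lbp_code_map(GrayImage(G + 37.5), cfg)
        np.testing.assert_array_equal(a.codes, b.codes)


class TestFeatureVector:
    def test_constant_image_concentrates_in_all_ones_bin(self):
        gray = GrayImage(np.full((224, 224), 90.0))
        block = lbp_feature_vector(gray, LBPConfig())
        assert block.dim == 1280
        assert block.values[1278] == 1.0  # all-ones uniform pattern
        assert np.count_nonzero(block.values) == 1

    def test_default_dimension_matches_deep_block(self):
        gray = GrayImage(np.linspace(0, 255, 20 * 20).reshape(20, 20))
        block = lbp_feature_vector(gray, LBPConfig())
        assert block.name == "textural"
        assert block.dim == 1280

    def test_histogram_is_a_distribution(self, rng):
        for _ in range(5):
            G = rng.uniform(0, 255, size=(16, 16))
            v = lbp_feature_vector(GrayImage(G), LBPConfig(P=8, R=1.0)).values
            assert v.min() >= 0.0
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_raw_histogram_matches_per_pixel_recount(self, rng):
        G = rng.uniform(0, 255, size=(8, 8))
        cfg = LBPConfig(P=8, R=1.0, mode="raw", normalize=False)
        hist = lbp_feature_vector(GrayImage(G), cfg).values
        counts = np.zeros(256)
        for code in oracle_code_map(G, 8, 1.0, "raw").ravel():
            counts[code] += 1
        np.testing.assert_array_equal(hist, counts)

    def test_uniform_dimension_always_p_plus_two(self, rng):
        G = rng.uniform(0, 255, size=(10, 10))
        for P in (4, 9, 17, 78):
            assert lbp_feature_vector(
                GrayImage(G), LBPConfig(P=P, R=1.0)).dim == P + 2

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_code_map(GrayImage(np.zeros((2, 2))), LBPConfig(P=8, R=1.0))
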