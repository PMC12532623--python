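"""AKAZE-style extractor: FED schedules, diffusion limits, Hessian
extrema vs brute-force oracle, M-LDB descriptor structure."""

import numpy as np
import pytest
from scipy import ndimage

from sinusid import akaze_extract
from sinusid._filters import gaussian, scharr_x, scharr_y
from sinusid.akaze import (MLDB_BITS, AkazeParams, ScaleSpaceLayer,
                           build_nonlinear_scale_space, conductivity_g2,
                           contrast_factor, detect_hessian_extrema, fed_schedule,
                           hessian_response, mldb_describe)
from sinusid.features import FeatureError


class TestContrastFactor:
    def test_constant_image_falls_back(self):
        assert contrast_factor(np.full((40, 40), 0.7)) == pytest.approx(0.03)

    def test_linear_ramp_recovers_slope(self):
        """A ramp has a single gradient magnitude; k lands within one
        histogram bin width of it (direct gradient-histogram oracle)."""
        slope = 0.01
        img = np.tile(np.arange(64) * slope, (64, 1))
        k = contrast_factor(img, presmooth_sigma=0.0)
        mags = np.hypot(scharr_x(img), scharr_y(img))
        target = float(np.median(mags[mags > 0]))
        bin_width = float(mags.max()) / 300
        assert abs(k - target) <= bin_width + 1e-12

    def test_intensity_scaling_scales_k(self):
        rng = np.random.default_rng(0)
        img = gaussian(rng.random((48, 48)), 1.5)
        k1 = contrast_factor(img)
        k2 = contrast_factor(2.0 * img)
        assert k2 == pytest.approx(2.0 * k1, rel=0.02)


class TestConductivity:
    def test_closed_forms(self):
        assert conductivity_g2(np.array(0.0), 0.5) == pytest.approx(1.0)
        assert conductivity_g2(np.array(0.5), 0.5) == pytest.approx(0.5)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        mag = rng.random((10, 12)) * 3
        k = 0.7
        g = conductivity_g2(mag, k)
        expected = np.array([[1.0 / (1.0 + mag[i, j] ** 2 / k ** 2)
                              for j in range(12)] for i in range(10)])
        np.testing.assert_allclose(g, expected, rtol=1e-12)
        assert (g > 0).all() and (g <= 1).all()

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            conductivity_g2(np.array(1.0), 0.0)


class TestFEDSchedule:
    def test_single_step_closed_form(self):
        """For n=1 the raw step is tau_max / (2 cos^2(pi/6)) = (2/3) tau_max
        and the cycle-time identity tau_max n(n+1)/3 holds."""
        tau_max = 0.25
        raw = tau_max / (2.0 * np.cos(np.pi / 6) ** 2)
        assert raw == pytest.approx(2.0 / 3.0 * tau_max)
        sched = fed_schedule(tau_max * 1 * 2 / 3.0, tau_max)
        assert sched.n_steps == 1
        assert sched.taus.sum() == pytest.approx(raw)

    @pytest.mark.parametrize("T", [0.05, 0.3, 1.7, 10.0])
    def test_steps_sum_to_target(self, T):
        sched = fed_schedule(T)
        assert abs(sched.taus.sum() - T) < 1e-9
        assert (sched.taus > 0).all()

    def test_exact_cycle_time_gives_exact_step_count(self):
        tau_max = 0.25
        T = tau_max * 4 * 5 / 3.0
        assert fed_schedule(T, tau_max).n_steps == 4


@pytest.fixture(scope="module")
def smooth_random_image():
    rng = np.random.default_rng(0)
    img = gaussian(rng.random((80, 120)), 2.0)
    return (img - img.min()) / (img.max() - img.min())


class TestScaleSpace:
    def test_sigma_schedule(self, smooth_random_image):
        layers = build_nonlinear_scale_space(smooth_random_image, octaves=2, sublevels=4)
        assert len(layers) == 8
        sigmas = [l.sigma for l in layers]
        assert all(b > a for a, b in zip(sigmas, sigmas[1:]))
        assert layers[4].sigma == pytest.approx(2 * layers[0].sigma)

    def test_linear_limit_matches_gaussian(self, smooth_random_image):
        """With conductivity forced to 1 the nonlinear evolution reduces to
        Gaussian smoothing (within 0.02 of the intensity range)."""
        layers = build_nonlinear_scale_space(smooth_random_image, octaves=1,
                                             sublevels=4, conductivity="one")
        for layer in layers:
            ref = ndimage.gaussian_filter(smooth_random_image, layer.sigma, mode="reflect")
            assert np.abs(layer.L - ref).max() < 0.02

    def test_intensity_conserved_within_octave(self, smooth_random_image):
        """Zero-flux divergence-form diffusion conserves the total
        intensity (< 0.5% drift per octave)."""
        layers = build_nonlinear_scale_space(smooth_random_image, octaves=2, sublevels=4)
        s0 = smooth_random_image.sum()
        for layer in layers:
            if layer.octave == 0:
                assert abs(layer.L.sum() - s0) / s0 < 0.005

    def test_small_image_reduces_octaves(self):
        rng = np.random.default_rng(3)
        layers = build_nonlinear_scale_space(gaussian(rng.random((40, 40)), 1), octaves=4)
        assert max(l.octave for l in layers) == 0  # 40/2 = 20 < 32


def _toy_layers(arrays, sigmas):
    layers = []
    for arr, s in zip(arrays, sigmas):
        layers.append(ScaleSpaceLayer(L=arr, Lx=scharr_x(arr), Ly=scharr_y(arr),
                                      sigma=s, sigma_local=s, octave=0, sublevel=0))
    return layers


class TestDetection:
    def test_constant_image_no_keypoints(self):
        arrs = [np.full((40, 40), 0.5)] * 3
        assert detect_hessian_extrema(_toy_layers(arrs, [1.6, 2.0, 2.4])) == []

    def test_blob_scale_selection(self):
        """A Gaussian blob of sigma_b = 4 is detected at a layer scale
        within one sublevel (factor 2^(1/4)) of sigma_b."""
        y, x = np.mgrid[0:100, 0:100]
        blob = np.exp(-((x - 50.0) ** 2 + (y - 50.0) ** 2) / (2 * 4.0 ** 2))
        layers = build_nonlinear_scale_space(blob, octaves=2, sublevels=4, conductivity="one")
        kps = detect_hessian_extrema(layers, 1e-4)
        assert kps
        top = max(kps, key=lambda k: k.response)
        assert 4.0 / 2 ** 0.25 <= top.scale <= 4.0 * 2 ** 0.25
        assert abs(top.x - 50) <= 2 and abs(top.y - 50) <= 2

    def test_matches_26_neighbour_oracle(self):
        """Detections equal an exhaustive 26-neighbour comparison on a
        3-layer toy stack of smoothed noise."""
        rng = np.random.default_rng(7)
        arrs = [gaussian(rng.random((36, 36)), s) for s in (1.5, 2.0, 2.5)]
        layers = _toy_layers(arrs, [1.6, 1.9, 2.3])
        thresh = 1e-6
        kps = detect_hessian_extrema(layers, thresh)
        got = {(k.x, k.y) for k in kps}

        resps = [hessian_response(l) for l in layers]
        expected = set()
        h, w = resps[1].shape
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                v = resps[1][y, x]
                if v <= thresh:
                    continue
                neigh = []
                for j, r in enumerate(resps):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if j == 1 and dx == 0 and dy == 0:
                                continue
                            neigh.append(r[y + dy, x + dx])
                if all(v > nv for nv in neigh):
                    expected.add((float(x), float(y)))
        assert got == expected

    def test_needs_three_layers(self):
        with pytest.raises(FeatureError):
            detect_hessian_extrema(_toy_layers([np.zeros((20, 20))] * 2, [1.6, 2.0]))


class TestMLDB:
    def test_bit_length_identity(self):
        """486 = (C(4,2) + C(9,2) + C(16,2)) * 3."""
        from math import comb
        assert MLDB_BITS == (comb(4, 2) + comb(9, 2) + comb(16, 2)) * 3 == 486

    def test_self_distance_zero(self, silhouette):
        layers = build_nonlinear_scale_space(silhouette.to_intensity(), octaves=1)
        kps = detect_hessian_extrema(layers)
        kp = max(kps, key=lambda k: k.response)
        d1 = mldb_describe(layers, kp, 0.3)
        d2 = mldb_describe(layers, kp, 0.3)
        assert np.array_equal(d1, d2)
        assert d1.shape == (61,)
        assert np.unpackbits(d1)[486:].sum() == 0  # pad bits stay zero

    def test_left_bright_right_dark_intensity_bits(self):
        """On a left-bright/right-dark patch at theta=0, every 2x2-grid
        intensity bit comparing a left cell (a) to a right cell (b) is 1;
        verified against directly computed cell means."""
        img = np.zeros((64, 64))
        img[:, :32] = 1.0
        layers = build_nonlinear_scale_space(img, octaves=1, sublevels=3, conductivity="one")
        from sinusid.features import Keypoint
        kp = Keypoint(x=32.0, y=32.0, octave=0, scale=layers[0].sigma)
        bits = np.unpackbits(mldb_describe(layers, kp, 0.0))
        # 2x2 grid, intensity channel = first 6 bits; row-major cells:
        # 0=TL, 1=TR, 2=BL, 3=BR; pairs (triu order): (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        pair_order = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        left, right = {0, 2}, {1, 3}
        # oracle cell means on the smoothed layer
        L = layers[0].L
        h = 5.0 * layers[0].sigma_local
        means = []
        for ci in range(4):
            row, col = divmod(ci, 2)
            x0 = int(round(32 + (col - 1) * h))
            x1 = int(round(32 + col * h))
            y0 = int(round(32 + (row - 1) * h))
            y1 = int(round(32 + row * h))
            means.append(L[y0:y1, x0:x1].mean())
        for idx, (a, b) in enumerate(pair_order):
            if a in left and b in right:
                assert bits[idx] == 1
                assert means[a] > means[b]


class TestAkazeExtract:
    def test_deterministic(self, silhouette):
        k1, d1 = akaze_extract(silhouette)
        k2, d2 = akaze_extract(silhouette)
        assert k1 == k2
        assert np.array_equal(d1.bits, d2.bits)

    def test_enough_keypoints_on_default_silhouette(self, silhouette):
        kps, desc = akaze_extract(silhouette)
        assert len(kps) >= 10
        assert desc.nbits == 486
        assert desc.bits.shape == (len(kps), 61)

    def test_rotation_robustness(self, silhouette):
        """Descriptors of geometrically matched keypoints between an image
        and its exact 90-degree rotation differ by <= 120/486 bits
        (median)."""
        img = silhouette.to_intensity()
        rot = np.rot90(img, k=-1)
        kp1, d1 = akaze_extract(img)
        kp2, d2 = akaze_extract(rot)
        H = img.shape[0]
        hams = []
        for i, k in enumerate(kp1):
            tx, ty = H - 1 - k.y, k.x
            dists = [(k2.x - tx) ** 2 + (k2.y - ty) ** 2 for k2 in kp2]
            j = int(np.argmin(dists))
            if dists[j] <= 9.0:
                hams.append(int(np.bitwise_count(d1.bits[i] ^ d2.bits[j]).sum()))
        assert len(hams) >= 10
        assert np.median(hams) <= 120
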