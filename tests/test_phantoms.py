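"""Phantom generators: blob closed forms, point-process statistics, signals,
and microcalcification maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from iqtask._rng import stream_rng
from iqtask.phantoms import (
    CLBParams,
    ClusterRealization,
    MCClusterSpec,
    ObjectImage,
    RayleighSignalSpec,
    blob_function,
    insert_mc,
    make_rayleigh_signal,
    render_clb,
    rotate_crop_cluster,
    sample_clb,
    synth_mc_cluster,
)


def single_blob(x=64.0, y=64.0, theta=0.0, **kw) -> tuple[CLBParams, ClusterRealization]:
    params = CLBParams(**kw)
    return params, ClusterRealization(1, [[x, y]], [1], [[0.0, 0.0]], [theta])


class TestCLB:
    @pytest.mark.parametrize("method", ["direct", "fft"])
    def test_single_blob_closed_form(self, method):
        """A centred, unrotated blob evaluates to the analytic profile."""
        params, real = single_blob(amplitude=3.0)
        img = render_clb(params, real, method=method)
        assert img[64, 64] == pytest.approx(3.0, rel=1e-5)
        # offset (1, 0): exp(-alpha * 1**beta / Lx) = exp(-2.1/5)
        assert img[64, 65] == pytest.approx(3.0 * math.exp(-2.1 / 5), rel=1e-5)
        # along the short axis the ellipse radius is Ly
        assert img[65, 64] == pytest.approx(3.0 * math.exp(-2.1 / 2), rel=1e-5)

    def test_empty_realization_is_zero(self):
        params = CLBParams()
        real = ClusterRealization(0, np.empty((0, 2)), [], np.empty((0, 2)), [])
        assert not render_clb(params, real).any()

    def test_rotated_blob_moves_long_axis(self):
        """Rotating the blob by 90 degrees swaps the anisotropy axes."""
        params, real = single_blob(theta=math.pi / 2)
        img = render_clb(params, real, method="direct")
        assert img[65, 64] == pytest.approx(math.exp(-2.1 / 5), rel=1e-5)
        assert img[64, 65] == pytest.approx(math.exp(-2.1 / 2), rel=1e-5)

    def test_images_nonnegative_and_finite(self):
        img, _ = sample_clb(CLBParams(), stream_rng(0, "clb"))
        assert np.all(img.pixels >= 0)
        assert np.all(np.isfinite(img.pixels))

    def test_poisson_counts_and_dispersion(self):
        """Cluster/blob counts match Poisson(Kbar), Poisson(Nbar) moments."""
        params = CLBParams()
        rng = stream_rng(1, "clb")
        n = 400
        ks, blob_counts = [], []
        for _ in range(n):
            _, real = sample_clb(params, rng)
            ks.append(real.n_clusters)
            blob_counts.extend(real.blobs_per_cluster.tolist())
        ks = np.asarray(ks, float)
        assert abs(ks.mean() - 150) < 3 * math.sqrt(150 / n)
        assert 0.8 < ks.var() / ks.mean() < 1.25  # Poisson dispersion
        bc = np.asarray(blob_counts, float)
        assert abs(bc.mean() - 20) < 3 * math.sqrt(20 / len(bc))
        assert 0.85 < bc.var() / bc.mean() < 1.15

    def test_stationary_mean_across_field(self):
        """Margin-extended sampling leaves no edge-intensity deficit."""
        params = CLBParams(field_size=64)
        rng = stream_rng(2, "clb")
        diffs, levels = [], []
        for _ in range(80):
            img, _ = sample_clb(params, rng)
            half = params.field_size // 2
            diffs.append(img.pixels[:, :half].mean() - img.pixels[:, half:].mean())
            levels.append(img.pixels.mean())
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean()) < max(4 * sem, 0.01 * np.mean(levels))

    def test_fft_renderer_matches_direct_oracle(self):
        """The fast FFT synthesis agrees with exact per-blob evaluation."""
        params = CLBParams(mean_clusters=12, field_size=64)
        _, real = sample_clb(params, stream_rng(3, "clb"))
        direct = render_clb(params, real, method="direct")
        fast = render_clb(params, real, method="fft")
        rel_rms = np.sqrt(np.mean((direct - fast) ** 2)) / direct.std()
        assert rel_rms < 0.08
        assert np.corrcoef(direct.ravel(), fast.ravel())[0, 1] > 0.995

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="field_size"):
            CLBParams(field_size=0)
        with pytest.raises(ValueError, match="amplitude"):
            CLBParams(amplitude=-1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        dx=st.floats(-40, 40), dy=st.floats(-40, 40),
        theta=st.floats(0, 2 * math.pi),
    )
    def test_blob_function_bounded_and_symmetric(self, dx, dy, theta):
        """0 < l <= 1 with max at the origin, and l(u) = l(-u)."""
        p = CLBParams()
        v = blob_function(dx, dy, theta, p)
        assert 0.0 < v <= 1.0
        assert v == pytest.approx(float(blob_function(-dx, -dy, theta, p)), rel=1e-9)


class TestRayleighSignal:
    def test_two_point_maxima_separation(self):
        """H0 on an odd grid has exactly two equal maxima L-2 pixels apart."""
        L = 8
        img = make_rayleigh_signal(RayleighSignalSpec(L), "H0", 129)
        row = img.pixels[64]
        peaks = signal.argrelmax(row)[0]
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == L - 2
        assert row[peaks[0]] == pytest.approx(row[peaks[1]], rel=1e-9)

    @pytest.mark.parametrize("L", [5, 6, 7, 8, 9])
    @pytest.mark.parametrize("hyp", ["H0", "H1"])
    def test_mirror_symmetry(self, L, hyp):
        img = make_rayleigh_signal(RayleighSignalSpec(L), hyp, 128)
        np.testing.assert_allclose(img.pixels, img.pixels[:, ::-1], atol=1e-12)

    def test_centroid_at_image_center(self):
        for hyp in ("H0", "H1"):
            px = make_rayleigh_signal(RayleighSignalSpec(7), hyp, 128).pixels
            yy, xx = np.mgrid[:128, :128]
            cx = (px * xx).sum() / px.sum()
            cy = (px * yy).sum() / px.sum()
            assert cx == pytest.approx(63.5, abs=1e-6)
            assert cy == pytest.approx(63.5, abs=1e-6)

    def test_line_signal_matches_brute_force_convolution(self):
        """H1 equals dense convolution of the line with the sampled kernel."""
        L, sigma, g = 5, 1.375, 65  # odd grid: line sites land on integers
        img = make_rayleigh_signal(RayleighSignalSpec(L, sigma), "H1", g)
        c = (g - 1) // 2
        imp = np.zeros((g, g))
        imp[c, c - (L - 1) // 2 : c + (L - 1) // 2 + 1] = 1.0
        # sampled Gaussian with the same 4-sigma truncation, normalized
        rad = int(4.0 * sigma + 0.5)
        ax = np.arange(-rad, rad + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        ref = signal.convolve2d(imp, np.outer(k1, k1), mode="same")
        np.testing.assert_allclose(img.pixels, ref, atol=1e-12)

    def test_compact_support_declared(self):
        img = make_rayleigh_signal(RayleighSignalSpec(9), "H1", 128)
        r0, r1, c0, c1 = img.bbox
        outside = img.pixels.copy()
        outside[r0:r1, c0:c1] = 0
        assert not outside.any()

    def test_signal_mass_ratio_reproducible(self):
        """H1/H0 total-intensity ratio is the deterministic L/2."""
        for L in (5, 8):
            h0 = make_rayleigh_signal(RayleighSignalSpec(L), "H0", 128).pixels.sum()
            h1 = make_rayleigh_signal(RayleighSignalSpec(L), "H1", 128).pixels.sum()
            assert h1 / h0 == pytest.approx(L / 2, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="hypothesis"):
            make_rayleigh_signal(RayleighSignalSpec(5), "H2", 64)
        with pytest.raises(ValueError, match="grid_size"):
            make_rayleigh_signal(RayleighSignalSpec(9), "H0", 17)


class TestMCCluster:
    def test_sparse_bounded_maps(self):
        rng = stream_rng(4, "mc")
        spec = MCClusterSpec()
        for _ in range(50):
            img = synth_mc_cluster(spec, rng)
            frac = np.count_nonzero(img.pixels) / img.pixels.size
            assert frac < 0.05
            assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_degenerate_single_pixel(self):
        spec = MCClusterSpec(n_mcs_range=(1, 1), mc_size_range=(1, 1))
        img = synth_mc_cluster(spec, stream_rng(5, "mc"))
        assert np.count_nonzero(img.pixels) == 1

    def test_blobs_within_cluster_radius(self):
        spec = MCClusterSpec(cluster_radius=15.0, centroid_spread=0.0, mc_size_range=(1, 3))
        img = synth_mc_cluster(spec, stream_rng(6, "mc"))
        ys, xs = np.nonzero(img.pixels)
        d = np.hypot(ys - 99.5, xs - 99.5)
        assert d.max() <= 15.0 + 3 + 1.5  # radius + blob size + rounding

    def test_rotate_crop_identity_and_periodicity(self):
        img = synth_mc_cluster(MCClusterSpec(), stream_rng(7, "mc"))
        crop0 = rotate_crop_cluster(img, 0.0)
        assert crop0.pixels.shape == (128, 128)
        np.testing.assert_allclose(crop0.pixels, img.pixels[36:164, 36:164], atol=1e-12)
        crop360 = rotate_crop_cluster(img, 360.0)
        np.testing.assert_allclose(crop360.pixels, crop0.pixels, atol=1e-5)

    def test_rotate_90_matches_quarter_turn(self):
        img = synth_mc_cluster(MCClusterSpec(), stream_rng(8, "mc"))
        by_rotate = rotate_crop_cluster(img, 90.0).pixels
        quarter = rotate_crop_cluster(np.rot90(img.pixels).copy(), 0.0).pixels
        np.testing.assert_allclose(by_rotate, quarter, atol=1e-4)

    def test_insert_identity_and_hand_value(self):
        fb = np.full((8, 8), 2.0)
        s = np.zeros((8, 8))
        s[3, 4] = 1.0
        assert np.array_equal(insert_mc(fb, s, 0.0).pixels, fb)
        out = insert_mc(fb, s, 0.05).pixels
        assert out[3, 4] == pytest.approx(2.1)
        assert np.count_nonzero(out != 2.0) == 1

    def test_insert_monotone_in_contrast(self):
        rng = stream_rng(9, "mc")
        fb = rng.uniform(1.0, 3.0, (16, 16))
        s = np.clip(rng.uniform(-0.5, 1.0, (16, 16)), 0, 1)
        lo = insert_mc(fb, s, 0.02).pixels
        hi = insert_mc(fb, s, 0.06).pixels
        mask = (s > 0) & (fb > 0)
        assert np.all(hi[mask] > lo[mask])

    def test_insert_errors(self):
        with pytest.raises(ValueError, match="c must be"):
            insert_mc(np.ones((4, 4)), np.ones((4, 4)), -0.1)
        with pytest.raises(ValueError, match="shape"):
            insert_mc(np.ones((4, 4)), np.ones((5, 5)), 0.1)

    def test_contrast_draw_mean(self):
        rng = stream_rng(10, "mc")
        draws = rng.uniform(0.05, 0.06, 10_000)
        se = 0.01 / math.sqrt(12) / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.055) < 3 * se
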