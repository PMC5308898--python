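"""Tests of ROI tiling, trace extraction, smoothing, dF/F and the PCA split."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

import burstnet as bn
from burstnet.signals import TraceMatrix, _elbow_index


class TestTileRois:
    @pytest.mark.parametrize("h,w,size,spacing,expected", [
        (128, 128, 11, 9, 196),
        (11, 11, 11, 9, 1),
        (64, 64, 11, 9, 36),
        (32, 32, 11, 9, 9),
    ])
    def test_roi_counts(self, h, w, size, spacing, expected):
        assert bn.tile_rois(h, w, size, spacing).n_rois == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(h=st.integers(11, 50), w=st.integers(11, 50),
           size=st.integers(3, 11), spacing=st.integers(1, 10))
    def test_count_matches_bruteforce_enumeration(self, h, w, size, spacing):
        grid = bn.tile_rois(h, w, size, spacing)
        brute = [(r, c)
                 for r in range(0, h, spacing) if r + size <= h
                 for c in range(0, w, spacing) if c + size <= w]
        assert grid.top_lefts == brute
        for r, c in grid.top_lefts:  # footprints fully inside the frame
            assert r + size <= h and c + size <= w

    def test_roi_larger_than_frame_raises(self):
        with pytest.raises(ValueError):
            bn.tile_rois(10, 10, 11, 9)

    def test_oval_footprint_shape(self):
        fp = bn.oval_footprint(11)
        assert fp[5, 5]                       # center included
        assert not fp[0, 0] and not fp[10, 10]  # corners excluded
        assert fp[0, 5] and fp[5, 0]          # axis extremes included
        np.testing.assert_array_equal(fp, fp.T)
        np.testing.assert_array_equal(fp, fp[::-1, ::-1])


class TestExtractTraces:
    def test_constant_movie_gives_constant_traces(self):
        movie = bn.MovieStack(np.full((20, 32, 32), 100, dtype=np.uint8), fps=20)
        grid = bn.tile_rois(32, 32)
        traces = bn.extract_traces(movie, grid)
        assert traces.stage == "raw"
        assert np.all(traces.values == 100.0)

    def test_spike_is_local_to_overlapping_rois(self):
        frames = np.zeros((10, 32, 32), dtype=np.uint8)
        grid = bn.tile_rois(32, 32)
        r0, c0 = grid.top_lefts[4]  # ROI at (9, 9)
        patch = np.zeros((11, 11), dtype=np.uint8)
        patch[grid.footprint] = 255
        frames[5, r0:r0 + 11, c0:c0 + 11] = patch
        traces = bn.extract_traces(bn.MovieStack(frames), grid)
        assert traces.values[4, 5] == pytest.approx(255.0)
        assert np.all(traces.values[4, [0, 1, 2, 3, 4, 6, 7, 8, 9]] == 0)
        far = [i for i, (r, c) in enumerate(grid.top_lefts)
               if abs(r - r0) > 11 or abs(c - c0) > 11]
        assert np.all(traces.values[far] == 0)

    def test_matches_bruteforce_pixel_loop(self, rng):
        frames = rng.integers(0, 256, size=(6, 30, 30), dtype=np.uint8)
        grid = bn.tile_rois(30, 30, 7, 5)
        traces = bn.extract_traces(bn.MovieStack(frames), grid)
        fp = grid.footprint
        for roi, (r0, c0) in enumerate(grid.top_lefts):
            for t in range(6):
                acc = [frames[t, r0 + i, c0 + j]
                       for i in range(7) for j in range(7) if fp[i, j]]
                assert traces.values[roi, t] == pytest.approx(np.mean(acc))


class TestSmoothTraces:
    def _raw(self, values, fps=20.0):
        return TraceMatrix(values=np.atleast_2d(values), fps=fps, stage="raw")

    def test_constant_trace_unchanged(self):
        out = bn.smooth_traces(self._raw(np.full(100, 3.0)))
        assert np.all(out.values == 3.0)
        assert out.stage == "smoothed"

    def test_unit_impulse_becomes_21_frame_plateau(self):
        x = np.zeros(100)
        x[50] = 1.0
        out = bn.smooth_traces(self._raw(x), window_s=1.0).values[0]
        np.testing.assert_allclose(out[40:61], 1 / 21)
        assert out[39] == 0 and out[61] == 0

    def test_alternating_trace_damped_to_one_twentyfirst(self):
        x = np.tile([1.0, -1.0], 50)
        out = bn.smooth_traces(self._raw(x)).values[0]
        assert np.all(np.abs(out[10:-10]) <= 1 / 21 + 1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_never_widens_the_range(self, seed):
        x = np.random.default_rng(seed).normal(size=(3, 80))
        out = bn.smooth_traces(TraceMatrix(x, fps=20.0, stage="raw")).values
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    def test_window_longer_than_trace_raises(self):
        with pytest.raises(ValueError):
            bn.smooth_traces(self._raw(np.zeros(10)), window_s=1.0)

    def test_requires_raw_stage(self):
        tm = TraceMatrix(np.zeros((1, 50)), fps=20.0, stage="dff")
        with pytest.raises(ValueError):
            bn.smooth_traces(tm)


class TestDff:
    def _smoothed(self, values, fps=20.0):
        return TraceMatrix(values=np.atleast_2d(values), fps=fps, stage="smoothed")

    def test_constant_trace_maps_to_zero(self):
        out = bn.dff(self._smoothed(np.full(50, 7.0)))
        assert np.all(out.values == 0.0)
        assert out.stage == "dff"

    def test_peak_of_doubled_baseline_is_one(self):
        x = np.full(100, 50.0)
        x[90:] = 100.0  # 10% of frames at 2*F0
        out = bn.dff(self._smoothed(x), baseline_percentile=10)
        assert out.values[0].max() == pytest.approx(1.0)
        assert out.values[0].min() == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 20, size=(2, 60))
        a = bn.dff(self._smoothed(x)).values
        b = bn.dff(self._smoothed(3 * x)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonpositive_baseline_names_roi(self):
        x = np.vstack([np.full(50, 5.0), np.full(50, -1.0)])
        with pytest.raises(ValueError, match=r"ROI\(s\) \[1\]"):
            bn.dff(self._smoothed(x))


class TestPcaSplit:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 25), t=st.integers(30, 120))
    def test_signal_plus_noise_reconstructs_input(self, seed, n, t):
        x = np.random.default_rng(seed).normal(size=(n, t))
        split = bn.pca_split(x)
        err = np.linalg.norm(split.signal + split.noise - x) / np.linalg.norm(x)
        assert err < 1e-8
        assert 1 <= split.n_signal_components <= n

    def test_rank_one_input_is_all_signal(self, rng):
        common = np.sin(np.linspace(0, 20, 200))
        weights = rng.uniform(0.5, 2.0, size=8)
        x = np.outer(weights, common)
        split = bn.pca_split(x)
        assert np.linalg.norm(split.noise) < 1e-8 * np.linalg.norm(x)
        np.testing.assert_allclose(split.signal, x, atol=1e-10)

    def test_three_strong_components_are_retained(self, rng):
        t = np.arange(600) / 20.0
        comps = np.stack([np.sin(2 * np.pi * f * t) for f in (0.2, 0.45, 0.8)])
        loadings = rng.normal(size=(30, 3))
        eps = 1e-3
        noise = eps * rng.normal(size=(30, 600))
        x = loadings @ comps + noise
        split = bn.pca_split(x)
        assert split.n_signal_components >= 3
        assert np.var(split.noise) <= 1.5 * np.var(noise)

    def test_degenerate_input_warns_and_returns_zero_noise(self, caplog):
        x = np.ones((5, 40))
        with caplog.at_level("WARNING", logger="burstnet"):
            split = bn.pca_split(x)
        assert split.n_signal_components == 1
        assert np.all(split.noise == 0)
        np.testing.assert_array_equal(split.signal, x)
        assert any("degenerate" in m for m in caplog.messages)

    def test_eigenvalues_descending(self, rng):
        split = bn.pca_split(rng.normal(size=(10, 100)))
        assert np.all(np.diff(split.eigenvalues) <= 1e-12)

    def test_elbow_of_sharp_spectrum(self):
        # one dominant value then a flat tail: elbow sits right after the drop
        assert _elbow_index([100.0, 1.0, 0.9, 0.8, 0.7, 0.6]) == 1

    def test_fewer_than_three_rois_raise(self):
        with pytest.raises(ValueError):
            bn.pca_split(np.zeros((2, 50)))


class TestLoadStack:
    def test_native_resolution_round_trip(self, tmp_path):
        arr = np.random.default_rng(0).integers(0, 256, (5, 128, 128), dtype=np.uint8)
        path = tmp_path / "a.tif"
        tifffile.imwrite(path, arr, photometric="minisblack")
        movie = bn.load_stack(path, target_size=128, fps=20)
        np.testing.assert_array_equal(movie.frames, arr)
        assert movie.fps == 20

    def test_integer_downscale_preserves_constant(self, tmp_path):
        arr = np.full((3, 256, 256), 100, dtype=np.uint8)
        path = tmp_path / "b.tif"
        tifffile.imwrite(path, arr, photometric="minisblack")
        movie = bn.load_stack(path, target_size=128)
        assert movie.frames.shape == (3, 128, 128)
        assert np.all(movie.frames == 100)

    def test_noninteger_resize_preserves_constant(self, tmp_path):
        arr = np.full((3, 100, 100), 57, dtype=np.uint8)
        path = tmp_path / "c.tif"
        tifffile.imwrite(path, arr, photometric="minisblack")
        movie = bn.load_stack(path, target_size=64)
        assert movie.frames.shape == (3, 64, 64)
        assert np.all(movie.frames == 57)

    def test_single_frame_raises(self, tmp_path):
        path = tmp_path / "d.tif"
        tifffile.imwrite(path, np.zeros((16, 16), dtype=np.uint8))
        with pytest.raises(ValueError, match="single frame"):
            bn.load_stack(path)


def test_full_chain_is_deterministic(synced_movie_analysis):
    """Re-analyzing the same movie reproduces every trace stage bit for bit."""
    cfg, movie, _, result = synced_movie_analysis
    again = bn.analyze_movie(movie, bn.PipelineConfig(fps=cfg.fps))
    np.testing.assert_array_equal(again.traces_dff.values, result.traces_dff.values)
    np.testing.assert_array_equal(again.split.signal, result.split.signal)
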