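import numpy as np
import pytest

import burstnet as bn


@pytest.fixture(scope="session")
def synced_movie_analysis():
    """A standard-geometry (128x128, 196-ROI) synchronized movie with mild
    period jitter and low noise, rendered once and analyzed once.

    Shared by the end-to-end pipeline tests and the detector-recovery checks.
    """
    cfg = bn.SyntheticConfig(n_frames=2400, height=128, width=128,
                             n_subnetworks=1, period_jitter_cv=0.1,
                             noise_sd=0.5, seed=42)
    movie, gt = bn.render_movie(cfg)
    result = bn.analyze_movie(movie, bn.PipelineConfig(fps=cfg.fps))
    return cfg, movie, gt, result


@pytest.fixture(scope="session")
def tiny_movie(tmp_path_factory):
    """A small (32x32, 9-ROI) movie written to disk for CLI tests."""
    cfg = bn.SyntheticConfig(n_frames=900, height=32, width=32,
                             period_jitter_cv=0.1, noise_sd=0.5, seed=7)
    movie, gt = bn.render_movie(cfg)
    path = tmp_path_factory.mktemp("movies") / "tiny.tif"
    bn.write_movie(movie, path)
    return cfg, movie, gt, path


def make_event(roi_id: int, frame: int, fps: float = 20.0,
               amplitude: float = 1.0) -> bn.BurstEvent:
    """A minimal synthetic burst event at a given base frame."""
    return bn.BurstEvent(roi_id=roi_id, base_frame=frame, peak_frame=frame + 5,
                         base_value=0.0, peak_value=amplitude, fps=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
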