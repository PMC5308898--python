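"""Ground-truthed synthetic calcium movies of bursting neuronal networks.

The generator emulates the movies the analysis pipeline is built for:
a field of view partitioned into one or more subnetworks, each following
its own burst schedule, every burst raising fluorescence across its whole
subnetwork through a fast-rise/slow-decay calcium transient on a constant
baseline, plus per-pixel Gaussian sensor noise, clipped and quantized to
8 bits.

Two knobs place a movie on the axes the analysis is meant to resolve:

* ``period_jitter_cv`` — coefficient of variation of inter-burst intervals;
  0 is perfectly rhythmic, larger values are increasingly irregular.
* ``n_subnetworks`` / ``shared_fraction`` — one fully synchronized network
  versus several spatially contiguous subnetworks that share only a
  fraction of their burst times (segmentation).

Burst intervals are drawn from a gamma distribution parameterized by mean
and CV (exactly periodic when CV is 0), floored at twice the kernel rise
time so that successive transients never merge into one rising edge.  The
gamma family is strictly positive, so the floor is essentially never active
at realistic jitter levels and the realized interval CV matches the
requested one.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import MovieStack, _round_half_up_u8

logger = logging.getLogger(__name__)

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic movie.

    Defaults describe a 2-minute recording at 20 frames/s of a single
    synchronized network bursting about six times per minute with mild
    period jitter, GCaMP-like transient kinetics (0.2 s rise, 2 s decay)
    and moderate sensor noise on an 8-bit intensity scale.
    """

    n_frames: int = 2400
    fps: float = 20.0
    height: int = 128
    width: int = 128
    n_subnetworks: int = 1
    mean_period: float = 10.0       # s between bursts
    period_jitter_cv: float = 0.1   # CV of inter-burst intervals
    shared_fraction: float = 0.0    # fraction of burst times common to all subnetworks
    amplitude_mean: float = 1.0     # peak dF/F of a transient
    amplitude_cv: float = 0.2
    tau_rise: float = 0.2           # s
    tau_decay: float = 2.0          # s
    baseline: float = 80.0          # 8-bit intensity units
    noise_sd: float = 1.0           # 8-bit intensity units
    seed: int = 0
    partition_mode: str = "stripes"  # "stripes" or "blobs"

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.fps <= 0:
            raise ValueError("need n_frames >= 2 and fps > 0")
        if self.height < 1 or self.width < 1:
            raise ValueError("frame dimensions must be positive")
        if self.n_subnetworks < 1:
            raise ValueError("n_subnetworks must be >= 1")
        if self.mean_period <= 0:
            raise ValueError("mean_period must be positive")
        if self.period_jitter_cv < 0:
            raise ValueError("period_jitter_cv must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("amplitude_mean > 0, amplitude_cv >= 0, noise_sd >= 0 required")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class GroundTruth:
    """What the generator actually drew: the spatial partition and schedules.

    ``partition_map`` labels every pixel with its subnetwork id;
    ``schedules`` is a tidy frame with columns ``subnetwork_id``,
    ``time_s`` and ``amplitude`` (one row per burst per subnetwork;
    shared bursts appear once per subnetwork).
    """

    partition_map: np.ndarray
    schedules: pd.DataFrame

    def subnetwork_times(self, label: int) -> np.ndarray:
        sub = self.schedules[self.schedules["subnetwork_id"] == label]
        return sub["time_s"].to_numpy()


def make_schedule(duration: float, mean_period: float, jitter_cv: float,
                  seed: SeedLike = 0, min_interval: float = 0.4) -> np.ndarray:
    """Draw an ordered array of burst times in ``(0, duration)``.

    Inter-burst intervals have mean ``mean_period`` and standard deviation
    ``jitter_cv * mean_period`` (gamma-distributed; degenerate when
    ``jitter_cv`` is 0), floored at ``min_interval`` so transients stay
    temporally resolvable.  Deterministic given ``seed``.  A duration
    shorter than one period yields an empty schedule.
    """
    if duration <= 0 or mean_period <= 0:
        raise ValueError("duration and mean_period must be positive")
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be >= 0")
    n_max = int(duration / mean_period * (1 + 4 * jitter_cv)) + 10
    if jitter_cv == 0:
        intervals = np.full(n_max, mean_period)
    else:
        shape = 1.0 / jitter_cv ** 2
        scale = mean_period * jitter_cv ** 2
        intervals = _rng(seed).gamma(shape, scale, size=n_max)
    intervals = np.maximum(intervals, min_interval)
    times = np.cumsum(intervals)
    while times[-1] < duration:  # pragma: no cover - n_max nearly always suffices
        extra = np.maximum(
            _rng(seed).gamma(shape, scale, size=n_max) if jitter_cv else np.full(n_max, mean_period),
            min_interval,
        )
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < duration]


def assign_partition(height: int, width: int, n_subnetworks: int,
                     seed: SeedLike = 0, mode: str = "stripes") -> np.ndarray:
    """Label every pixel with a subnetwork id (contiguous regions).

    ``stripes`` (default) splits the columns into near-equal vertical bands;
    ``blobs`` labels pixels by their nearest of ``n_subnetworks`` seeded
    random sites (a Voronoi partition).
    """
    if n_subnetworks < 1 or n_subnetworks > height * width:
        raise ValueError(f"cannot place {n_subnetworks} subnetworks on a {height}x{width} frame")
    if mode == "stripes":
        if n_subnetworks > width:
            raise ValueError("more stripe subnetworks than columns")
        labels = np.zeros((height, width), dtype=np.int64)
        for lab, cols in enumerate(np.array_split(np.arange(width), n_subnetworks)):
            labels[:, cols] = lab
        return labels
    if mode == "blobs":
        rng = _rng(seed)
        sites = np.column_stack([rng.uniform(0, height, n_subnetworks),
                                 rng.uniform(0, width, n_subnetworks)])
        rr, cc = np.mgrid[0:height, 0:width]
        d2 = (rr[..., None] - sites[:, 0]) ** 2 + (cc[..., None] - sites[:, 1]) ** 2
        return np.argmin(d2, axis=-1).astype(np.int64)
    raise ValueError(f"unknown partition mode {mode!r}")


def calcium_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to peak 1.

    ``K(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / K(t_peak)`` for t >= 0,
    zero for t < 0.
    """
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=np.float64)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                   - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    return out / peak


def _draw_amplitudes(n: int, mean: float, cv: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean * cv ** 2, size=n)


def _activity_trace(times: np.ndarray, amps: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Sum of amplitude-scaled kernels sampled on the frame grid."""
    trace = np.zeros(cfg.n_frames)
    if times.size == 0:
        return trace
    # template long enough for the decay tail to fall below 1e-6 of peak
    n_tpl = int(np.ceil(cfg.tau_decay * np.log(1e6) * cfg.fps)) + 1
    for t_b, a in zip(times, amps):
        f0 = max(0, int(np.ceil(t_b * cfg.fps - 1e-9)))
        f1 = min(cfg.n_frames, int(np.ceil(t_b * cfg.fps - 1e-9)) + n_tpl)
        if f0 >= cfg.n_frames or f1 <= 0:
            continue
        offsets = np.arange(f0, f1) / cfg.fps - t_b
        trace[f0:f1] += a * calcium_kernel(offsets, cfg.tau_rise, cfg.tau_decay)
    return trace


def render_movie(config: SyntheticConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a movie and its ground truth from a :class:`SyntheticConfig`.

    Pixel intensity at frame t is
    ``baseline * (1 + sum_b A_b * K(t - t_b)) + N(0, noise_sd)``,
    summed over the pixel's subnetwork schedule plus the schedule shared by
    all subnetworks, then clipped to [0, 255] and quantized (round half-up)
    to 8 bits.  Bit-identical output for identical config.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_part, s_shared, s_priv, s_amp, s_noise = ss.spawn(5)
    min_int = 2 * cfg.tau_rise

    partition = assign_partition(cfg.height, cfg.width, cfg.n_subnetworks,
                                 seed=s_part, mode=cfg.partition_mode)

    # The burst process is rendered in steady state: each schedule starts a
    # burn-in of 1.5 periods before frame 0, so the recording opens on the
    # decay tail of a pre-onset burst (as a camera started mid-activity would)
    # rather than on a cold baseline.
    def _schedule(period: float, seed) -> np.ndarray:
        burn_in = 1.5 * period
        times = make_schedule(cfg.duration_s + burn_in, period,
                              cfg.period_jitter_cv, seed=seed,
                              min_interval=min_int) - burn_in
        return times[times > -5 * cfg.tau_decay]

    f = cfg.shared_fraction
    if f > 0:
        shared_times = _schedule(cfg.mean_period / f, s_shared)
    else:
        shared_times = np.empty(0)
    priv_seeds = s_priv.spawn(cfg.n_subnetworks)
    if f < 1:
        priv_times = [_schedule(cfg.mean_period / (1 - f), sd) for sd in priv_seeds]
    else:
        priv_times = [np.empty(0)] * cfg.n_subnetworks

    amp_rng = _rng(s_amp)
    shared_amps = _draw_amplitudes(shared_times.size, cfg.amplitude_mean, cfg.amplitude_cv, amp_rng)
    priv_amps = [_draw_amplitudes(t.size, cfg.amplitude_mean, cfg.amplitude_cv, amp_rng)
                 for t in priv_times]

    rows = []
    traces = np.zeros((cfg.n_subnetworks, cfg.n_frames), dtype=np.float64)
    for k in range(cfg.n_subnetworks):
        times = np.concatenate([shared_times, priv_times[k]])
        amps = np.concatenate([shared_amps, priv_amps[k]])
        order = np.argsort(times, kind="stable")
        times, amps = times[order], amps[order]
        traces[k] = _activity_trace(times, amps, cfg)
        for t_b, a in zip(times, amps):
            if t_b >= 0:  # pre-onset bursts are rendered but precede the record
                rows.append((k, float(t_b), float(a)))
    schedules = pd.DataFrame(rows, columns=["subnetwork_id", "time_s", "amplitude"])

    frame_values = (cfg.baseline * (1.0 + traces)).astype(np.float32)  # (k, T)
    movie = frame_values.T[:, partition]       # (T, H, W)
    if cfg.noise_sd > 0:
        noise = _rng(s_noise).standard_normal(movie.shape, dtype=np.float32)
        noise *= cfg.noise_sd
        movie += noise
        del noise
    overflow = float(np.mean((movie > 255.5) | (movie < -0.5)))
    if overflow > 0.10:
        logger.warning("%.1f%% of rendered intensities fall outside the 8-bit range",
                       100 * overflow)
    stack = MovieStack(frames=_round_half_up_u8(movie), fps=cfg.fps)
    return stack, GroundTruth(partition_map=partition, schedules=schedules)


def write_movie(movie: MovieStack, path) -> None:
    """Write a movie as a multi-page 8-bit grayscale TIFF (one page per frame)."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(movie.frames, dtype=np.uint8),
                     photometric="minisblack")


def write_ground_truth(gt: GroundTruth, schedules_path, partition_path) -> None:
    """Write schedules and partition map as headed CSV files."""
    gt.schedules.to_csv(schedules_path, index=False)
    h, w = gt.partition_map.shape
    rr, cc = np.mgrid[0:h, 0:w]
    pd.DataFrame({"row": rr.ravel(), "col": cc.ravel(),
                  "label": gt.partition_map.ravel()}).to_csv(partition_path, index=False)


def rhythmic_config(**overrides) -> SyntheticConfig:
    """A rhythmic single-network movie (interval CV 0)."""
    return replace(SyntheticConfig(period_jitter_cv=0.0), **overrides)


def irregular_config(**overrides) -> SyntheticConfig:
    """An irregular single-network movie (interval CV 0.5)."""
    return replace(SyntheticConfig(period_jitter_cv=0.5), **overrides)


def segmented_config(n_subnetworks: int = 2, shared_fraction: float = 0.3,
                     **overrides) -> SyntheticConfig:
    """A movie segmented into partially synchronized subnetworks."""
    return replace(SyntheticConfig(n_subnetworks=n_subnetworks,
                                   shared_fraction=shared_fraction), **overrides)


def _write_run(cfg: SyntheticConfig, out_dir) -> dict:
    """Render and persist one movie; return paths (used by the CLI)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, gt = render_movie(cfg)
    paths = {
        "movie": out / "movie.tif",
        "schedules": out / "schedules.csv",
        "partition": out / "partition.csv",
    }
    write_movie(movie, paths["movie"])
    write_ground_truth(gt, paths["schedules"], paths["partition"])
    return {k: str(v) for k, v in paths.items()}
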