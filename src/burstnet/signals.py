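"""Movie loading, ROI trace extraction and PCA signal/noise separation.

The processing chain implemented here turns an 8-bit grayscale movie stack
into a matrix of per-ROI fluorescence traces and splits that matrix into a
"signal" part and a "noise" part:

1. ``load_stack`` reads a multi-page TIFF and (optionally) resizes each
   frame to a square analysis resolution (128 x 128 by default).
2. ``tile_rois`` covers the field of view with a regular lattice of
   oval regions of interest (11 x 11 pixels at 9-pixel spacing by default,
   which yields 196 ROIs on a 128 x 128 frame).
3. ``extract_traces`` averages pixel intensity over each ROI footprint,
   frame by frame.
4. ``smooth_traces`` applies a centered 1-s running mean.
5. ``dff`` converts each trace to dF/F against a low-percentile baseline.
6. ``pca_split`` decomposes the ROI x time matrix by PCA, keeps the
   components up to two past the scree-plot elbow as "signal" and assigns
   the remainder to "noise"; signal + noise reconstructs the input exactly.

The noise matrix calibrates the burst detector (see :mod:`burstnet.bursts`):
each ROI's burst threshold is a multiple of the standard deviation of its
noise trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Stage = Literal["raw", "smoothed", "dff"]

DEFAULT_FPS = 20.0
DEFAULT_TARGET_SIZE = 128
DEFAULT_ROI_SIZE = 11
DEFAULT_ROI_SPACING = 9


@dataclass
class MovieStack:
    """A grayscale movie: ``frames`` is (time, height, width) on a 0-255 scale."""

    frames: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (time, height, width) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _round_half_up_u8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-up to unsigned 8-bit."""
    return np.floor(np.clip(x, 0.0, 255.0) + 0.5).astype(np.uint8)


def load_stack(path, target_size: int | None = DEFAULT_TARGET_SIZE,
               fps: float = DEFAULT_FPS) -> MovieStack:
    """Read a multi-page grayscale TIFF as a :class:`MovieStack`.

    Frames are resized to ``target_size`` x ``target_size`` (pass ``None`` to
    keep the native resolution).  Integer-factor downscaling uses area-mean
    pooling, which conserves mean intensity; other resize factors use
    bilinear interpolation (anti-aliased when downscaling).

    Raises
    ------
    ValueError
        If the file holds a single frame, or is not grayscale.
    """
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: a single frame is not a movie")
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack (time, height, width); got shape {arr.shape}. "
            "Convert color movies to grayscale before loading."
        )
    if target_size is not None and arr.shape[1:] != (target_size, target_size):
        arr = _resize_stack(arr, target_size)
    return MovieStack(frames=arr, fps=fps)


def _resize_stack(arr: np.ndarray, target: int) -> np.ndarray:
    from skimage.measure import block_reduce
    from skimage.transform import resize

    t, h, w = arr.shape
    if h % target == 0 and w % target == 0 and h >= target and w >= target:
        # exact area-mean pooling
        out = block_reduce(arr.astype(np.float64), (1, h // target, w // target), np.mean)
    else:
        down = h > target or w > target
        out = np.empty((t, target, target), dtype=np.float64)
        for i in range(t):
            out[i] = resize(arr[i].astype(np.float64), (target, target),
                            order=1, anti_aliasing=down, preserve_range=True)
    return _round_half_up_u8(out)


def oval_footprint(roi_size: int) -> np.ndarray:
    """Boolean mask of the ellipse inscribed in a ``roi_size`` square.

    A pixel belongs to the footprint when its center lies inside the
    inscribed ellipse; the center pixel is always included.
    """
    if roi_size < 1:
        raise ValueError("roi_size must be >= 1")
    c = (roi_size - 1) / 2.0
    r = roi_size / 2.0
    i, j = np.mgrid[0:roi_size, 0:roi_size]
    return ((i - c) / r) ** 2 + ((j - c) / r) ** 2 <= 1.0


@dataclass
class RoiGrid:
    """A regular lattice of identical oval ROIs covering a frame."""

    roi_size: int
    spacing: int
    top_lefts: list[tuple[int, int]]
    footprint: np.ndarray = field(repr=False)
    height: int = 0
    width: int = 0

    @property
    def n_rois(self) -> int:
        return len(self.top_lefts)

    @property
    def centers(self) -> list[tuple[float, float]]:
        c = (self.roi_size - 1) / 2.0
        return [(r + c, col + c) for r, col in self.top_lefts]


def tile_rois(height: int, width: int, roi_size: int = DEFAULT_ROI_SIZE,
              spacing: int = DEFAULT_ROI_SPACING) -> RoiGrid:
    """Tile a frame with oval ROIs placed every ``spacing`` pixels.

    Top-left corners sit at multiples of ``spacing`` along each axis for as
    long as the full ``roi_size`` square fits inside the frame, so the ROI
    count is ``(floor((H - roi_size)/spacing) + 1) * (floor((W - roi_size)/spacing) + 1)``.
    With the defaults on a 128 x 128 frame this gives 14 x 14 = 196 ROIs,
    adjacent ovals overlapping by 2 pixels.
    """
    if roi_size > height or roi_size > width:
        raise ValueError(f"roi_size {roi_size} exceeds frame {height}x{width}")
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    rows = range(0, height - roi_size + 1, spacing)
    cols = range(0, width - roi_size + 1, spacing)
    tops = [(r, c) for r in rows for c in cols]
    return RoiGrid(roi_size=roi_size, spacing=spacing, top_lefts=tops,
                   footprint=oval_footprint(roi_size), height=height, width=width)


@dataclass
class TraceMatrix:
    """ROI x time matrix of fluorescence traces at a given processing stage."""

    values: np.ndarray
    fps: float
    stage: Stage
    grid: RoiGrid | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (ROI x time)")
        if self.grid is not None and self.values.shape[0] != self.grid.n_rois:
            raise ValueError("row count does not match the ROI grid")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def extract_traces(movie: MovieStack, grid: RoiGrid) -> TraceMatrix:
    """Average intensity over each ROI footprint, frame by frame."""
    if grid.height != movie.height or grid.width != movie.width:
        raise ValueError("grid was tiled for a different frame size")
    s = grid.roi_size
    traces = np.empty((grid.n_rois, movie.n_frames))
    for roi, (r0, c0) in enumerate(grid.top_lefts):
        patch = movie.frames[:, r0:r0 + s, c0:c0 + s]
        traces[roi] = patch[:, grid.footprint].mean(axis=1)
    return TraceMatrix(values=traces, fps=movie.fps, stage="raw", grid=grid)


def smooth_traces(traces: TraceMatrix, window_s: float = 1.0) -> TraceMatrix:
    """Centered running mean over ``round(window_s * fps)`` frames.

    The window length is forced to the nearest odd frame count so it can be
    centered.  Near the trace ends the full-width window is kept but shifted
    to stay inside the recording (no padding values are invented), so every
    output frame averages the same number of samples and noise suppression
    is uniform along the trace; the first and last half-window of frames are
    therefore constant.
    """
    if traces.stage != "raw":
        raise ValueError(f"expected raw traces, got stage={traces.stage!r}")
    w = int(round(window_s * traces.fps))
    if w < 1:
        raise ValueError("window shorter than one frame")
    if w % 2 == 0:
        w += 1
    t = traces.n_frames
    if w > t:
        raise ValueError(f"window of {w} frames longer than trace of {t} frames")
    half = w // 2
    idx = np.arange(t)
    lo = np.clip(idx - half, 0, t - w)
    cs = np.concatenate([np.zeros((traces.n_rois, 1)), np.cumsum(traces.values, axis=1)], axis=1)
    out = (cs[:, lo + w] - cs[:, lo]) / w
    return TraceMatrix(values=out, fps=traces.fps, stage="smoothed", grid=traces.grid)


def dff(traces: TraceMatrix, baseline_percentile: float = 10.0) -> TraceMatrix:
    """Per-ROI dF/F: ``(F - F0) / F0`` with F0 the trace's low percentile.

    A low-percentile baseline is robust when bursts occupy a minority of
    frames.  Raises if any baseline is non-positive (dF/F is then undefined),
    naming the offending ROIs.
    """
    if traces.stage != "smoothed":
        raise ValueError(f"expected smoothed traces, got stage={traces.stage!r}")
    f0 = np.percentile(traces.values, baseline_percentile, axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"non-positive dF/F baseline for ROI(s) {bad.tolist()}")
    out = (traces.values - f0[:, None]) / f0[:, None]
    return TraceMatrix(values=out, fps=traces.fps, stage="dff", grid=traces.grid)


@dataclass
class SignalNoiseSplit:
    """PCA decomposition of a trace matrix into signal + noise.

    ``signal + noise`` equals the PCA input exactly (the split is a
    partition of principal components, with the removed per-ROI means folded
    back into the signal matrix).
    """

    signal: np.ndarray
    noise: np.ndarray
    n_signal_components: int
    eigenvalues: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]


def _elbow_index(spectrum: Sequence[float]) -> int:
    """0-based elbow of a descending spectrum by the triangle method.

    Both axes are normalized to [0, 1]; the elbow is the point of maximum
    perpendicular distance from the chord joining the first and last values.
    """
    y = np.asarray(spectrum, dtype=np.float64)
    m = y.size
    if m < 3:
        return 0
    x = np.linspace(0.0, 1.0, m)
    span = y[0] - y[-1]
    if span <= 0:
        return 0
    yn = (y - y[-1]) / span
    # distance from the line through (0, 1) and (1, 0): |x + y - 1| / sqrt(2)
    return int(np.argmax(np.abs(x + yn - 1.0)))


def pca_split(traces: TraceMatrix | np.ndarray) -> SignalNoiseSplit:
    """Split a dF/F trace matrix into signal and noise by PCA.

    ROIs are the observations and time points the variables; each ROI trace
    is mean-centered over time before decomposition.  Components are ranked
    by eigenvalue; the retained ("signal") count is the scree-plot elbow
    plus two further components, capped at the ROI count.  The signal matrix
    is the reconstruction from the retained components (plus the removed
    means); the noise matrix is the reconstruction from the rest, so
    ``signal + noise`` reproduces the input to machine precision.
    """
    if isinstance(traces, TraceMatrix):
        if traces.stage != "dff":
            raise ValueError(f"expected dff traces, got stage={traces.stage!r}")
        x = traces.values
    else:
        x = np.asarray(traces, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError("input must be 2-D (ROI x time)")
    n, t = x.shape
    if n < 3:
        raise ValueError("PCA split needs at least 3 ROIs")

    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    scale = max(float(np.abs(x).max()), 1.0)
    if not np.any(np.abs(xc) > 1e-12 * scale):
        logger.warning("degenerate (zero-variance) input to pca_split; noise set to zero")
        return SignalNoiseSplit(signal=x.copy(), noise=np.zeros_like(x),
                                n_signal_components=1, eigenvalues=np.zeros(min(n, t)))

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s ** 2 / (t - 1)
    elbow = _elbow_index(eig)
    k = min(elbow + 1 + 2, s.size)  # elbow (1-based) plus two more components
    noise = (u[:, k:] * s[k:]) @ vt[k:]
    signal = x - noise
    return SignalNoiseSplit(signal=signal, noise=noise,
                            n_signal_components=k, eigenvalues=eig)
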