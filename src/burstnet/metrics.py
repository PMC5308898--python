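"""Burst-train and synchrony metrics: frequency, interval C.V. (rhythmicity),
amplitude C.V., rhythmic classification, pairwise correlation and t-tests.

Rhythmicity is summarized by the interval coefficient of variation (I.C.V.):
the sample SD of inter-burst intervals divided by their mean.  Low values
indicate rhythmic bursting; a train is classified rhythmic when its I.C.V.
falls strictly below 0.2 (the boundary value itself counts as non-rhythmic).
Network synchrony is the mean zero-lag Pearson correlation over all ROI
pairs of the dF/F traces.

Quantities that need more data than a train provides (fewer than 2
intervals for the I.C.V., fewer than 2 bursts for the amplitude C.V.) are
reported as NaN — "not computable" — rather than 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ICV_THRESHOLD = 0.2


@dataclass
class BurstTrain:
    """Ordered burst times (s) with per-burst amplitudes over a recording."""

    positions: np.ndarray
    amplitudes: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.positions.shape != self.amplitudes.shape or self.positions.ndim != 1:
            raise ValueError("positions and amplitudes must be matching 1-D arrays")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("burst positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] > self.duration:
                raise ValueError("burst positions must lie within [0, duration]")
            if np.any(self.amplitudes <= 0):
                raise ValueError("amplitudes must be positive")

    @property
    def n_bursts(self) -> int:
        return self.positions.size

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.positions)


@dataclass(frozen=True)
class RhythmicityResult:
    """Burst frequency plus I.C.V.-based rhythmicity classification."""

    frequency_bpm: float
    icv: float
    rhythmic: bool | None
    icv_threshold: float = DEFAULT_ICV_THRESHOLD


def burst_frequency(train: BurstTrain) -> float:
    """Bursts per minute: ``count / duration * 60``."""
    return train.n_bursts / train.duration * 60.0


def interval_cv(train: BurstTrain) -> float:
    """I.C.V. = sample SD of inter-burst intervals / mean interval.

    NaN when the train has fewer than 2 intervals (3 bursts).
    """
    iv = train.intervals
    if iv.size < 2:
        return math.nan
    return float(np.std(iv, ddof=1) / np.mean(iv))


def classify_rhythmic(icv: float, threshold: float = DEFAULT_ICV_THRESHOLD) -> bool:
    """True when the I.C.V. is strictly below the threshold."""
    if not math.isfinite(icv):
        raise ValueError("I.C.V. is not computable for this train")
    return icv < threshold


def rhythmicity(train: BurstTrain,
                icv_threshold: float = DEFAULT_ICV_THRESHOLD) -> RhythmicityResult:
    """Frequency + I.C.V. + rhythmic flag (None when the I.C.V. is undefined)."""
    icv = interval_cv(train)
    flag = classify_rhythmic(icv, icv_threshold) if math.isfinite(icv) else None
    return RhythmicityResult(frequency_bpm=burst_frequency(train), icv=icv,
                             rhythmic=flag, icv_threshold=icv_threshold)


def amplitude_stats(train: BurstTrain) -> tuple[float, float]:
    """(mean amplitude, amplitude C.V.); the C.V. is NaN below 2 bursts."""
    a = train.amplitudes
    if a.size == 0:
        return math.nan, math.nan
    mean = float(np.mean(a))
    if a.size < 2:
        return mean, math.nan
    return mean, float(np.std(a, ddof=1) / mean)


@dataclass
class SynchronyResult:
    """Pairwise zero-lag correlation matrix and its mean over valid pairs."""

    mean_correlation: float
    matrix: np.ndarray
    n_excluded_traces: int


def pairwise_synchrony(traces, max_lag_s: float = 0.0,
                       fps: float | None = None) -> SynchronyResult:
    """Pairwise Pearson correlation of dF/F traces.

    By default the zero-lag correlation is used.  Setting ``max_lag_s`` > 0
    instead takes, for each pair, the maximum correlation over integer-frame
    lags up to +/- ``max_lag_s`` (requires ``fps``; taken from the trace
    matrix when available).  Zero-variance traces cannot be correlated:
    their pairs are NaN, excluded from the mean, and counted.
    """
    values = np.asarray(getattr(traces, "values", traces), dtype=np.float64)
    if fps is None:
        fps = getattr(traces, "fps", None)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 traces")
    n, t = values.shape
    sd = values.std(axis=1)
    ok = sd > 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.warning("%d zero-variance trace(s) excluded from synchrony", n_excluded)

    if max_lag_s > 0:
        if fps is None:
            raise ValueError("max_lag_s > 0 requires fps")
        corr = _max_lag_correlation(values, int(round(max_lag_s * fps)))
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values)
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    np.fill_diagonal(corr, 1.0)

    iu = np.triu_indices(n, k=1)
    off = corr[iu]
    valid = np.isfinite(off)
    mean = float(np.mean(off[valid])) if valid.any() else math.nan
    return SynchronyResult(mean_correlation=mean, matrix=corr,
                           n_excluded_traces=n_excluded)


def _max_lag_correlation(values: np.ndarray, max_lag: int) -> np.ndarray:
    n, t = values.shape
    if max_lag >= t:
        raise ValueError("lag range longer than the traces")
    best = np.full((n, n), -np.inf)
    for lag in range(0, max_lag + 1):
        a = values[:, : t - lag] if lag else values
        b = values[:, lag:] if lag else values
        za = _zscore_rows(a)
        zb = _zscore_rows(b)
        c = (za @ zb.T) / (t - lag)
        best = np.maximum(best, np.maximum(c, c.T))
    best[~np.isfinite(best)] = np.nan
    return best


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x - mu) / sd


def group_ttest(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided Student t-test between two groups.

    Unpaired tests pool variances (classic equal-variance Student t);
    paired tests require equal lengths.  Degenerate inputs (e.g. identical
    paired samples, whose differences have zero variance) yield (NaN, NaN).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
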