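"""Eighteen handcrafted per-channel features and feature-level fusion.

Per channel series the features are, in fixed order:

====  ==================  =========================================================
slot  name                definition
====  ==================  =========================================================
0     max                 maximum sample
1     min                 minimum sample
2     mean                arithmetic mean
3     std                 sample standard deviation (n-1 denominator)
4     zero_crossings      sign changes between consecutive samples
5     p20                 20th percentile (linear interpolation)
6     p50                 median
7     p80                 80th percentile
8     iqr                 p75 - p25
9     kurtosis            sum((m-mu)^4) / (n * sigma^4), sigma the n-1 std
10    skewness            sum((m-mu)^3) / (n * sigma^3)
11    autocorr            lag-k autocorrelation (k = 1 by default)
12    fom                 mean of consecutive gaps of the sorted series
13    norm_fom            L1 norm of those gaps  (= max - min)
14    som                 mean of second-order gaps (diffs of diffs, sorted)
15    norm_som            L2 norm of the second-order gaps
16    spectral_entropy    Shannon entropy (nats) of the normalized magnitude
                          spectrum over non-negative frequencies
17    spectral_energy     sum of squared spectral magnitudes
====  ==================  =========================================================

The moment features deliberately compose the n-1 standard deviation into
the kurtosis/skewness denominators (rather than the population moment
convention), so a normal sample's kurtosis is close to — but not exactly —
3.  Degenerate inputs (constant window: sigma = 0, or all-zero spectrum)
map to 0 with a warning instead of NaN, keeping downstream classifiers
well-posed.

Fusion is plain concatenation: with 3 sensors x 3 axes the fused vector
has 3 * 3 * 18 = 162 entries, channel blocks in manifest/schema order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windowing import Window

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "max", "min", "mean", "std", "zero_crossings",
    "p20", "p50", "p80", "iqr",
    "kurtosis", "skewness", "autocorr",
    "fom", "norm_fom", "som", "norm_som",
    "spectral_entropy", "spectral_energy",
)

N_FEATURES = len(FEATURE_NAMES)  # 18


def basic_stats(series: np.ndarray) -> tuple[float, float, float, float]:
    """(max, min, mean, std) with the n-1 standard deviation."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("std undefined for fewer than 2 samples")
    return (
        float(series.max()),
        float(series.min()),
        float(series.mean()),
        float(series.std(ddof=1)),
    )


def zero_crossings(series: np.ndarray) -> int:
    """Count sign changes between consecutive samples.

    An exact zero adopts the sign of the previous nonzero sample, so a
    plateau touching zero is not double-counted; leading zeros carry no
    sign and cannot create a crossing.
    """
    s = np.sign(np.asarray(series, dtype=float))
    # forward-fill zeros with the last nonzero sign
    filled = s.copy()
    last = 0.0
    for i in range(filled.size):
        if filled[i] == 0.0:
            filled[i] = last
        else:
            last = filled[i]
    return int(np.sum(filled[:-1] * filled[1:] < 0))


def percentile_features(series: np.ndarray) -> tuple[float, float, float, float]:
    """(p20, p50, p80, iqr), percentiles by linear interpolation."""
    p20, p25, p50, p75, p80 = np.percentile(series, [20, 25, 50, 75, 80])
    return float(p20), float(p50), float(p80), float(p75 - p25)


def shape_features(series: np.ndarray) -> tuple[float, float]:
    """(kurtosis, skewness) with the n-1 sigma in the denominator."""
    series = np.asarray(series, dtype=float)
    n = series.size
    mu = series.mean()
    sigma = series.std(ddof=1)
    if sigma == 0.0:
        logger.warning("constant window: kurtosis/skewness set to 0")
        return 0.0, 0.0
    d = series - mu
    kurt = float(np.sum(d**4) / (n * sigma**4))
    skew = float(np.sum(d**3) / (n * sigma**3))
    return kurt, skew


def autocorrelation(series: np.ndarray, k: int = 1) -> float:
    """Lag-k autocorrelation R_k = sum d_i d_{i+k} / sum d_i^2."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if not 0 <= k < n:
        raise ValueError(f"lag k={k} out of range for n={n}")
    d = series - series.mean()
    denom = np.sum(d * d)
    if denom == 0.0:
        logger.warning("zero-variance window: autocorrelation set to 0")
        return 0.0
    return float(np.sum(d[: n - k] * d[k:]) / denom)


def order_mean_features(
    series: np.ndarray,
) -> tuple[float, float, float, float]:
    """(fom, norm_fom, som, norm_som) from gaps of the sorted series.

    Sort ascending; first-order gaps are consecutive differences of the
    sorted values, second-order gaps their differences again.  FOM/SOM are
    the gap means; the norms are L1 of the first-order and L2 of the
    second-order gaps.  For sorted data the gaps are non-negative, so the
    L1 norm telescopes to max - min.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("order-mean features need at least 3 samples")
    s = np.sort(series)
    d1 = np.diff(s)
    d2 = np.diff(d1)
    return (
        float(d1.mean()),
        float(np.sum(np.abs(d1))),
        float(d2.mean()),
        float(np.sqrt(np.sum(d2**2))),
    )


def spectral_features(series: np.ndarray) -> tuple[float, float]:
    """(spectral_entropy, spectral_energy) over non-negative frequencies.

    F is the magnitude of the one-sided DFT (no taper, DC included).
    Spectral energy is sum(F^2).  The magnitudes normalized to unit sum act
    as a probability distribution whose Shannon entropy (natural log) is
    the spectral entropy; zero-magnitude bins contribute nothing.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples")
    F = np.abs(np.fft.rfft(series))
    energy = float(np.sum(F**2))
    total = F.sum()
    if total == 0.0:
        logger.warning("all-zero window: spectral entropy set to 0")
        return 0.0, 0.0
    p = F / total
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    return entropy, energy


def channel_features(series: np.ndarray, *, autocorr_lag: int = 1) -> np.ndarray:
    """All 18 features of one channel, in :data:`FEATURE_NAMES` order."""
    mx, mn, mean, std = basic_stats(series)
    zc = zero_crossings(series)
    p20, p50, p80, iqr = percentile_features(series)
    kurt, skew = shape_features(series)
    ac = autocorrelation(series, autocorr_lag)
    fom, nfom, som, nsom = order_mean_features(series)
    sep, se = spectral_features(series)
    return np.array(
        [mx, mn, mean, std, zc, p20, p50, p80, iqr,
         kurt, skew, ac, fom, nfom, som, nsom, sep, se]
    )


@dataclass
class FusedFeatureVector:
    """Concatenated per-channel feature blocks for one window."""

    values: np.ndarray
    label: str
    subject_id: str
    channel_names: list[str]

    @property
    def feature_names(self) -> list[str]:
        return [f"{ch}_{f}" for ch in self.channel_names for f in FEATURE_NAMES]


def extract_features(
    win: Window, channel_names: list[str], *, autocorr_lag: int = 1
) -> FusedFeatureVector:
    """Fuse all channels' 18-feature blocks into one vector.

    Channel blocks follow ``channel_names`` order, so the output length is
    ``n_channels * 18`` (162 for a 3-sensor, 3-axis window).
    """
    if win.samples.shape[1] != len(channel_names):
        raise ValueError(
            f"window has {win.samples.shape[1]} channels, "
            f"{len(channel_names)} names given"
        )
    blocks = [
        channel_features(win.samples[:, j], autocorr_lag=autocorr_lag)
        for j in range(win.samples.shape[1])
    ]
    return FusedFeatureVector(
        values=np.concatenate(blocks),
        label=win.label,
        subject_id=win.subject_id,
        channel_names=list(channel_names),
    )


def feature_frame(
    windows: list[Window], channel_names: list[str], *, autocorr_lag: int = 1
) -> pd.DataFrame:
    """Feature matrix for many windows as a DataFrame.

    One row per window; ``<sensor>_<axis>_<feature>`` columns plus
    ``label`` and ``subject``.
    """
    rows = [extract_features(w, channel_names, autocorr_lag=autocorr_lag)
            for w in windows]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(
        np.stack([r.values for r in rows]), columns=rows[0].feature_names
    )
    df["label"] = [r.label for r in rows]
    df["subject"] = [r.subject_id for r in rows]
    return df
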