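"""Per-window, per-channel time-domain EEG features.

Two catalogues are provided:

* :class:`TimeFeatureSet` — raw-signal moments, first/second difference
  statistics and a battery of amplitude descriptors (RMS, peak indices,
  kurtosis, ...). Two of these, ``std_raw`` and ``var_raw``, deliberately use
  the *uncentred* second moment (sum of squares over N-1 with no mean
  subtraction); pass ``centred=True`` for the conventional centred variants.
* :class:`EpochStats` — the ten epoch statistics (mean, std, ptp, var, min,
  max, argmin, argmax, skewness, kurtosis) used to build classifier feature
  tables.

Peak locations (``lpk``, ``argminim``, ``argmaxim``) are reported as 1-based
sample indices; divide index differences by ``fs`` for seconds. Statistics
that are undefined on a degenerate window (zero variance, zero RMS) come back
as NaN with a warning rather than raising, so batch feature extraction never
aborts mid-run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TimeFeatureSet",
    "EpochStats",
    "raw_moments",
    "difference_stats",
    "cumulative_extrema",
    "channel_stats",
    "moving_median",
    "epoch_statistics",
    "compute_time_features",
    "time_feature_table",
    "epoch_feature_table",
]


@dataclass
class TimeFeatureSet:
    mu: float            # mean (uV)
    sigma: float         # sample standard deviation (uV)
    delta: float         # mean |first difference| (uV)
    gamma_diff: float    # mean |second difference| (uV)
    delta_norm: float    # delta / sigma
    gamma_norm: float    # gamma_diff / sigma
    mav: float           # mean amplitude (uV)
    med: float           # median (uV)
    min_amp: float       # minimum (uV)
    maxmin: float        # max - min (uV)
    rms: float           # root mean square (uV)
    prms: float          # max|x| / rms
    rss: float           # root sum of squares (uV)
    std_raw: float       # uncentred "std": sqrt(sum(x^2)/(N-1)) (uV)
    var_raw: float       # uncentred "variance": sum(x^2)/(N-1) (uV^2)
    pk: float            # maximum (uV)
    lpk: int             # argmax, 1-based sample index
    pp: int              # lpk minus index of the second-largest sample
    kurt: float          # non-excess kurtosis (moment ratio)


@dataclass
class EpochStats:
    mean: float
    std: float        # population (ddof=0)
    ptp: float
    var: float        # population (ddof=0); var == std**2
    minim: float
    maxim: float
    argminim: int     # 1-based, first occurrence
    argmaxim: int     # 1-based, first occurrence
    skewness: float   # standardised third central moment
    kurtosis: float   # Fisher excess


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    return x


def raw_moments(window_channel) -> tuple[float, float]:
    """Mean and sample (1/(N-1)) standard deviation of a raw window."""
    x = _as_vector(window_channel)
    if x.size < 2:
        raise ValueError("need at least 2 samples for the standard deviation")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def difference_stats(window_channel) -> tuple[float, float, float, float]:
    """Mean absolute first/second differences and their sigma-normalised forms.

    Returns ``(delta, gamma_diff, delta_norm, gamma_norm)`` where
    ``delta_norm = delta/sigma`` and ``gamma_norm = gamma_diff/sigma``. On a
    zero-variance window the normalised pair is NaN (with a warning).
    """
    x = _as_vector(window_channel)
    if x.size < 3:
        raise ValueError("need at least 3 samples for difference statistics")
    delta = float(np.mean(np.abs(np.diff(x))))
    gamma_diff = float(np.mean(np.abs(x[2:] - x[:-2])))
    sigma = float(np.std(x, ddof=1))
    if sigma > 0:
        delta_norm, gamma_norm = delta / sigma, gamma_diff / sigma
    else:
        warnings.warn("zero-variance window: normalised difference stats are NaN")
        delta_norm = gamma_norm = float("nan")
    return delta, gamma_diff, delta_norm, gamma_norm


def cumulative_extrema(window_channel) -> tuple[np.ndarray, np.ndarray]:
    """Running maximum and minimum up to each sample (both length N)."""
    x = _as_vector(window_channel)
    if x.size < 1:
        raise ValueError("empty window")
    return np.maximum.accumulate(x), np.minimum.accumulate(x)


def channel_stats(window_channel, centred: bool = False) -> dict[str, float]:
    """Amplitude descriptors of one channel window (``mav`` .. ``kurt``).

    With ``centred=True`` the ``std_raw``/``var_raw`` pair is replaced by the
    conventional mean-centred sample statistics.
    """
    x = _as_vector(window_channel)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    mav = float(np.mean(x))
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        prms = float(np.max(np.abs(x)) / rms)
    else:
        warnings.warn("zero-RMS window: prms is NaN")
        prms = float("nan")
    if centred:
        var_raw = float(np.var(x, ddof=1))
        std_raw = float(np.sqrt(var_raw))
    else:
        var_raw = float(np.sum(x**2) / (n - 1))
        std_raw = float(np.sqrt(var_raw))
    lpk0 = int(np.argmax(x))
    rival = x.copy()
    rival[lpk0] = -np.inf
    second0 = int(np.argmax(rival))
    m2 = float(np.mean((x - mav) ** 2))
    if m2 > 0:
        kurt = float(np.mean((x - mav) ** 4) / m2**2)
    else:
        warnings.warn("zero-variance window: kurtosis is NaN")
        kurt = float("nan")
    return {
        "mav": mav,
        "med": float(np.median(x)),
        "min_amp": float(np.min(x)),
        "maxmin": float(np.max(x) - np.min(x)),
        "rms": rms,
        "prms": prms,
        "rss": float(np.sqrt(np.sum(x**2))),
        "std_raw": std_raw,
        "var_raw": var_raw,
        "pk": float(np.max(x)),
        "lpk": lpk0 + 1,
        "pp": lpk0 - second0,
        "kurt": kurt,
    }


def moving_median(window_channel, k: int) -> np.ndarray:
    """Moving median with window size ``k``: output[i] = median(x[i:i+k])."""
    x = _as_vector(window_channel)
    if not 1 <= k <= x.size:
        raise ValueError(f"moving-median window k={k} outside [1, {x.size}]")
    return np.median(sliding_window_view(x, k), axis=1)


def compute_time_features(window_channel, centred: bool = False) -> TimeFeatureSet:
    """All :class:`TimeFeatureSet` fields for one channel window."""
    x = _as_vector(window_channel)
    mu, sigma = raw_moments(x)
    delta, gamma_diff, delta_norm, gamma_norm = difference_stats(x)
    return TimeFeatureSet(
        mu=mu, sigma=sigma, delta=delta, gamma_diff=gamma_diff,
        delta_norm=delta_norm, gamma_norm=gamma_norm,
        **channel_stats(x, centred=centred),
    )


def epoch_statistics(window) -> dict[str, EpochStats]:
    """The ten epoch statistics for every channel of a window.

    ``window`` may be a :class:`~arousalkit.signal_io.SignalWindow` or a plain
    (N x C) array paired with channel names via ``window.channel_names``;
    returns ``{channel_name: EpochStats}``.
    """
    samples = window.samples if hasattr(window, "samples") else np.asarray(window, float)
    if hasattr(window, "parent"):
        names = window.parent.channel_names
    elif hasattr(window, "channel_names"):
        names = window.channel_names
    else:
        names = [f"CH{j}" for j in range(samples.shape[1])]
    if samples.shape[0] < 3:
        raise ValueError("need at least 3 samples per epoch")
    out: dict[str, EpochStats] = {}
    for j, name in enumerate(names):
        x = samples[:, j]
        m = float(np.mean(x))
        m2 = float(np.mean((x - m) ** 2))
        if m2 > 0:
            skew = float(np.mean((x - m) ** 3) / m2**1.5)
            kurt = float(np.mean((x - m) ** 4) / m2**2 - 3.0)
        else:
            warnings.warn(f"zero-variance epoch on {name}: skew/kurtosis are NaN")
            skew = kurt = float("nan")
        out[name] = EpochStats(
            mean=m,
            std=float(np.sqrt(m2)),
            ptp=float(np.max(x) - np.min(x)),
            var=m2,
            minim=float(np.min(x)),
            maxim=float(np.max(x)),
            argminim=int(np.argmin(x)) + 1,
            argmaxim=int(np.argmax(x)) + 1,
            skewness=skew,
            kurtosis=kurt,
        )
    return out


def time_feature_table(windows, channels: list[str] | None = None) -> pd.DataFrame:
    """One row per (window, channel) of :class:`TimeFeatureSet` values."""
    rows = []
    for i, win in enumerate(windows):
        names = channels or win.parent.channel_names
        for name in names:
            feats = compute_time_features(win.channel(name))
            row = {"window": i, "channel": name}
            row.update({f.name: getattr(feats, f.name) for f in fields(TimeFeatureSet)})
            rows.append(row)
    return pd.DataFrame(rows)


def epoch_feature_table(windows, channels: list[str] | None = None) -> pd.DataFrame:
    """One row per window; epoch statistics flattened as ``<CH>__<stat>``."""
    rows = []
    for i, win in enumerate(windows):
        names = channels or win.parent.channel_names
        stats = epoch_statistics(win)
        row: dict[str, float] = {"window": i}
        for name in names:
            for f in fields(EpochStats):
                row[f"{name}__{f.name}"] = getattr(stats[name], f.name)
        rows.append(row)
    return pd.DataFrame(rows)
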