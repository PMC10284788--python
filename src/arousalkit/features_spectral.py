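"""Power spectral density estimation, band powers and median frequency.

The PSD is estimated with Welch's method (Hann taper, segment length
``min(N, fs)`` samples, 50% overlap) and band power is the trapezoidal
integral of the density over the band, so power is additive over disjoint
adjacent bands and the full-range integral equals total power exactly.

Two band presets ship, differing in the alpha/beta edges:

* ``"eq23"`` (default) — alpha [8, 15] Hz, beta [16, 31] Hz, delta [0, 4],
  theta [4, 7]; these are the edges the valence/arousal indices are defined
  over.
* ``"bandlist"`` — the conventional clinical list: delta 0.5-4, theta 4-8,
  alpha 8-12, beta 12-30 Hz.

In both presets gamma runs from the beta edge to min(45, fs/2) Hz, acquisition
low-pass filters typically removing everything above 45 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PSDEstimate",
    "BandPowerSet",
    "BAND_PRESETS",
    "estimate_psd",
    "band_power",
    "band_powers",
    "median_frequency",
    "window_band_powers",
]

BAND_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "eq23": {
        "delta": (0.0, 4.0),
        "theta": (4.0, 7.0),
        "alpha": (8.0, 15.0),
        "beta": (16.0, 31.0),
        "gamma": (31.0, 45.0),
    },
    "bandlist": {
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "beta": (12.0, 30.0),
        "gamma": (30.0, 45.0),
    },
}


@dataclass
class PSDEstimate:
    """One-sided power spectral density on [0, fs/2] (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")

    @property
    def total_power(self) -> float:
        """Integrated power over the full [0, fs/2] range (uV^2)."""
        return float(np.trapezoid(self.power, self.freqs))


@dataclass
class BandPowerSet:
    """Integrated band powers (uV^2) for one channel window."""

    alpha: float
    beta: float
    delta: float
    theta: float
    gamma: float
    band_edges: dict[str, tuple[float, float]]
    total: float = float("nan")


def estimate_psd(
    window_channel,
    fs: float,
    nperseg: int | None = None,
    overlap: float = 0.5,
    taper: str = "hann",
    detrend: str = "constant",
) -> PSDEstimate:
    """Welch PSD of one channel window.

    The default segment length is ``min(N, round(fs))`` (1-s segments on the
    standard 5-s window). If the window is shorter than one segment a single
    periodogram is used instead, with a warning. The integral of the returned
    density matches the (detrended) signal power to within a few percent —
    the Hann taper weights segment edges down, so per-window Parseval
    agreement is approximate, not exact.
    """
    x = np.asarray(window_channel, float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    n = x.size
    if nperseg is None:
        nperseg = min(n, int(round(fs)))
    if n < nperseg:
        warnings.warn("window shorter than one segment: using a single periodogram")
        freqs, power = sps.periodogram(x, fs=fs, detrend=detrend)
        meta = {"estimator": "periodogram", "nperseg": n}
    else:
        noverlap = int(nperseg * overlap)
        freqs, power = sps.welch(
            x, fs=fs, window=taper, nperseg=nperseg, noverlap=noverlap,
            detrend=detrend,
        )
        meta = {
            "estimator": "welch", "nperseg": nperseg,
            "noverlap": noverlap, "taper": taper,
        }
    return PSDEstimate(freqs=freqs, power=power, fs=fs, method=meta)


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over ``band`` = (lo, hi) Hz.

    Band edges falling between frequency bins are linearly interpolated, so
    power is exactly additive over adjacent bands. Edges beyond Nyquist are
    clipped.
    """
    lo, hi = float(band[0]), float(band[1])
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band [{lo}, {hi}]")
    nyq = psd.freqs[-1]
    lo, hi = min(lo, nyq), min(hi, nyq)
    if hi <= lo:
        return 0.0
    inside = psd.freqs[(psd.freqs > lo) & (psd.freqs < hi)]
    grid = np.concatenate(([lo], inside, [hi]))
    dens = np.interp(grid, psd.freqs, psd.power)
    return float(np.trapezoid(dens, grid))


def band_powers(psd: PSDEstimate, preset: str | dict = "eq23") -> BandPowerSet:
    """All five canonical band powers of one PSD under a preset."""
    edges = BAND_PRESETS[preset] if isinstance(preset, str) else dict(preset)
    powers = {name: band_power(psd, band) for name, band in edges.items()}
    return BandPowerSet(band_edges=edges, total=psd.total_power, **powers)


def median_frequency(psd: PSDEstimate, upper: float | None = None) -> float:
    """Frequency below which half of the power in [0, upper] lies.

    ``upper`` defaults to the Nyquist frequency. The crossing is linearly
    interpolated between frequency bins on the cumulative-power curve.
    Returns NaN if the band holds no power.
    """
    upper = psd.freqs[-1] if upper is None else min(float(upper), psd.freqs[-1])
    keep = psd.freqs <= upper
    f = psd.freqs[keep]
    p = psd.power[keep]
    if f[-1] < upper:
        f = np.append(f, upper)
        p = np.append(p, np.interp(upper, psd.freqs, psd.power))
    cum = np.concatenate(([0.0], np.cumsum(np.diff(f) * (p[:-1] + p[1:]) / 2.0)))
    total = cum[-1]
    if total <= 0:
        warnings.warn("zero spectral power: median frequency is NaN")
        return float("nan")
    return float(np.interp(total / 2.0, cum, f))


def window_band_powers(
    window,
    channels: list[str],
    preset: str | dict = "eq23",
    **psd_kwargs,
) -> dict[str, BandPowerSet]:
    """Band powers per channel for one :class:`SignalWindow`."""
    fs = window.parent.fs
    return {
        name: band_powers(estimate_psd(window.channel(name), fs, **psd_kwargs), preset)
        for name in channels
    }
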