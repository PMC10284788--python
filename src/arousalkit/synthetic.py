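"""Seeded synthetic EEG and inter-beat-interval generators.

The EEG generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without recorded data:

* each channel is a sum of band-limited noise components (band-filtered white
  noise, one per canonical band) plus 1/f background noise; a configurable
  fraction of the background is *common mode* — shared across channels, the
  way volume conduction correlates neighbouring scalp electrodes — so a
  bipolar derivation genuinely cancels EEG while doubling the cardiac
  artifact;
* a *rest* state is alpha-dominant and a *stress* state multiplies the beta
  gain and divides the alpha gain by a configurable factor — the classic
  alpha-suppression / beta-activation signature of cognitive load;
* FT9 and FT10 additionally carry an opposite-polarity train of Gaussian
  cardiac pulses (40 ms width) at a configured BPM with Gaussian inter-beat
  jitter, so the bipolar difference doubles the artifact;
* the right-hemisphere channels' (F4/AF4) alpha is scaled by an asymmetry
  ratio for laterality tests.

Band components are filtered noise rather than pure sinusoids so that PSD
estimation is exercised realistically; ``pure_tone=True`` switches to
sinusoids at band centres for closed-form checks.

The IBI generator produces per-state AR(1) Gaussian interval series, and
``hrv_features`` computes the standard time-domain HRV battery plus
Lomb-Scargle VLF power on beat windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import MultiChannelSignal, segment

__all__ = [
    "SyntheticEEGConfig",
    "SyntheticLabels",
    "generate_eeg",
    "generate_ibi",
    "hrv_features",
    "REST_STRESS_PRESET",
]

DEFAULT_CHANNELS = ("F3", "F4", "AF3", "AF4", "FT9", "FT10")
# relative band gains of the rest state (alpha-dominant idle EEG)
DEFAULT_BAND_GAINS = {
    "delta": 1.0, "theta": 0.8, "alpha": 2.0, "beta": 0.6, "gamma": 0.2,
}
BAND_EDGES = {
    "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0),
    "beta": (16.0, 30.0), "gamma": (30.0, 45.0),
}


@dataclass
class SyntheticEEGConfig:
    """Study conditions for one synthetic recording.

    ``schedule`` lists (state, seconds) blocks; states are "rest" or
    "stress". ``stress_beta_factor`` multiplies the beta gain and divides the
    alpha gain in stress blocks. The cardiac artifact amplitude is set via
    ``cardiac_snr`` (pulse peak over background RMS on FT9/FT10) unless an
    absolute ``cardiac_amplitude`` (uV) is given. ``cardiac_bpm`` is a scalar
    or a (start, end) ramp across the recording.
    """

    fs: float = 128.0
    schedule: tuple = (("rest", 30.0),)
    channels: tuple = DEFAULT_CHANNELS
    band_gains: dict = field(default_factory=lambda: dict(DEFAULT_BAND_GAINS))
    stress_beta_factor: float = 2.0
    noise_exponent: float = 1.0     # 1/f^exponent background
    noise_amplitude: float = 0.5    # relative to unit band-component RMS
    common_mode_fraction: float = 0.7  # variance fraction shared across channels
    cardiac_bpm: float | tuple = 72.0
    cardiac_snr: float = 5.0
    cardiac_amplitude: float | None = None
    cardiac_polarity: dict = field(default_factory=lambda: {"FT9": 1.0, "FT10": -1.0})
    jitter_sd_ms: float = 20.0
    pulse_width_ms: float = 40.0
    asymmetry: float = 1.0          # right/left alpha amplitude ratio
    spurious_spikes_per_min: float = 0.0
    spurious_amplitude_fraction: float = 0.25
    pure_tone: bool = False
    amplitude_uv: float = 10.0      # overall RMS scale of the background EEG
    seed: int = 0


@dataclass
class SyntheticLabels:
    """Per-window ground truth aligned with ``segment(signal, window_seconds)``."""

    window_seconds: float
    states: list[str]
    bpm: list[float]
    asymmetry: float
    beat_times: np.ndarray  # seconds, full recording


REST_STRESS_PRESET = SyntheticEEGConfig(
    schedule=(("rest", 150.0), ("stress", 150.0)),
    cardiac_bpm=(65.0, 95.0),
)


def _state_gains(config: SyntheticEEGConfig, state: str) -> dict[str, float]:
    g = dict(config.band_gains)
    if state == "stress":
        g["alpha"] = g["alpha"] / config.stress_beta_factor
        g["beta"] = g["beta"] * config.stress_beta_factor
    elif state != "rest":
        raise ValueError(f"unknown state {state!r}")
    return g


def _band_component(rng, n: int, fs: float, band: tuple[float, float],
                    pure_tone: bool) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    if hi <= lo:
        return np.zeros(n)
    if pure_tone:
        f0 = 0.5 * (lo + hi)
        phase = rng.uniform(0, 2 * np.pi)
        x = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * np.arange(n) / fs + phase)
        return x
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(2 * fs):]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def _beat_times(rng, config: SyntheticEEGConfig, duration: float) -> np.ndarray:
    bpm = config.cardiac_bpm
    if np.isscalar(bpm):
        bpm_at = lambda t: float(bpm)  # noqa: E731
    else:
        b0, b1 = bpm
        bpm_at = lambda t: b0 + (b1 - b0) * t / duration  # noqa: E731
    times = []
    t = rng.uniform(0.0, 60.0 / bpm_at(0.0))
    while t < duration:
        times.append(t)
        interval = 60.0 / bpm_at(t) + rng.normal(0.0, config.jitter_sd_ms / 1000.0)
        interval = max(interval, 0.25)
        t += interval
    return np.asarray(times)


def generate_eeg(config: SyntheticEEGConfig,
                 window_seconds: float = 5.0) -> tuple[MultiChannelSignal, SyntheticLabels]:
    """Generate one synthetic multichannel EEG recording with ground truth."""
    fs = config.fs
    duration = float(sum(secs for _, secs in config.schedule))
    if duration < window_seconds:
        raise ValueError("recording shorter than one analysis window")
    rng = np.random.default_rng(config.seed)
    n_total = int(round(duration * fs))

    # --- per-state band-structured EEG, block by block --------------------
    data = np.zeros((n_total, len(config.channels)))
    cm = np.sqrt(np.clip(config.common_mode_fraction, 0.0, 1.0))
    ind = np.sqrt(1.0 - cm**2)
    start = 0
    sample_state: list[str] = []
    for state, secs in config.schedule:
        n = int(round(secs * fs))
        gains = _state_gains(config, state)
        shared = {
            band: _band_component(rng, n, fs, BAND_EDGES[band], config.pure_tone)
            for band, gain in gains.items() if gain > 0
        }
        shared_pink = _pink_noise(rng, n, config.noise_exponent)
        for j, name in enumerate(config.channels):
            x = np.zeros(n)
            for band, gain in gains.items():
                if gain <= 0:
                    continue
                g = gain
                if band == "alpha" and name in ("F4", "AF4"):
                    g = g * config.asymmetry
                comp = cm * shared[band] + ind * _band_component(
                    rng, n, fs, BAND_EDGES[band], config.pure_tone)
                x += g * comp
            if config.noise_amplitude > 0:
                x += config.noise_amplitude * (
                    cm * shared_pink + ind * _pink_noise(rng, n, config.noise_exponent))
            data[start:start + n, j] = x
        sample_state.extend([state] * n)
        start += n
    data *= config.amplitude_uv

    # --- cardiac artifact on FT9/FT10 -------------------------------------
    beat_times = _beat_times(rng, config, duration)
    pulse_sd = config.pulse_width_ms / 1000.0 / 4.0
    t_axis = np.arange(n_total) / fs
    pulse = np.zeros(n_total)
    half = 4 * pulse_sd
    for tb in beat_times:
        i0 = max(int((tb - half) * fs), 0)
        i1 = min(int((tb + half) * fs) + 1, n_total)
        pulse[i0:i1] += np.exp(-0.5 * ((t_axis[i0:i1] - tb) / pulse_sd) ** 2)
    # spurious spikes: refractory-safe (>= 200 ms away from every true beat)
    n_spur = int(round(config.spurious_spikes_per_min * duration / 60.0))
    spur_times = []
    while len(spur_times) < n_spur:
        ts = rng.uniform(0.3, duration - 0.3)
        if beat_times.size and np.min(np.abs(beat_times - ts)) < 0.25:
            continue
        spur_times.append(ts)
    spur = np.zeros(n_total)
    for ts in spur_times:
        i0 = max(int((ts - half) * fs), 0)
        i1 = min(int((ts + half) * fs) + 1, n_total)
        spur[i0:i1] += np.exp(-0.5 * ((t_axis[i0:i1] - ts) / pulse_sd) ** 2)

    channel_arr = list(config.channels)
    if config.cardiac_amplitude is not None:
        amp = config.cardiac_amplitude
    else:
        ft_idx = [channel_arr.index(c) for c in ("FT9", "FT10") if c in channel_arr]
        bg_rms = (np.sqrt(np.mean(data[:, ft_idx] ** 2)) if ft_idx
                  else config.amplitude_uv)
        amp = config.cardiac_snr * bg_rms
    for name, pol in config.cardiac_polarity.items():
        if name in channel_arr:
            j = channel_arr.index(name)
            data[:, j] += pol * amp * (pulse + config.spurious_amplitude_fraction * spur)

    signal = MultiChannelSignal(data, fs=fs, channel_names=list(config.channels))

    # --- per-window ground truth ------------------------------------------
    w = int(round(window_seconds * fs))
    n_windows = n_total // w
    states, bpms = [], []
    for i in range(n_windows):
        seg_states = sample_state[i * w:(i + 1) * w]
        states.append(max(set(seg_states), key=seg_states.count))
        t0, t1 = i * w / fs, (i + 1) * w / fs
        beats = beat_times[(beat_times >= t0) & (beat_times < t1)]
        if beats.size >= 2:
            bpms.append(60.0 * (beats.size - 1) / (beats[-1] - beats[0]))
        else:
            bpms.append(float("nan"))
    labels = SyntheticLabels(
        window_seconds=window_seconds, states=states, bpm=bpms,
        asymmetry=config.asymmetry, beat_times=beat_times,
    )
    return signal, labels


# ---------------------------------------------------------------------------
# IBI series and HRV features
# ---------------------------------------------------------------------------

def generate_ibi(
    state_means,
    state_sds,
    n_beats,
    ar_coefficient: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state AR(1) Gaussian inter-beat-interval series (ms).

    ``state_means``/``state_sds``/``n_beats`` are parallel per-state lists
    (scalars accepted for a single state). Returns ``(ibi_ms, state_index)``
    with one label per beat. The AR(1) innovation variance is scaled so each
    state's stationary SD equals its configured SD.
    """
    means = np.atleast_1d(np.asarray(state_means, float))
    sds = np.atleast_1d(np.asarray(state_sds, float))
    counts = np.atleast_1d(np.asarray(n_beats, int))
    if not (means.shape == sds.shape == counts.shape):
        raise ValueError("state_means, state_sds and n_beats must align")
    if np.any((means < 333.0) | (means > 1500.0)):
        raise ValueError("state means must lie in [333, 1500] ms")
    if not abs(ar_coefficient) < 1:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    rng = np.random.default_rng(seed)
    phi = ar_coefficient
    series, labels = [], []
    for s, (mu, sd, n) in enumerate(zip(means, sds, counts)):
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        x = np.empty(n)
        prev = rng.normal(0.0, sd) if sd > 0 else 0.0
        for i in range(n):
            prev = phi * prev + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)
            x[i] = mu + prev
        series.append(x)
        labels.append(np.full(n, s))
    return np.concatenate(series), np.concatenate(labels)


_VLF_BAND = (0.0033, 0.04)  # Hz


def _vlf_power(ibi_ms: np.ndarray) -> tuple[float, float]:
    """Lomb-Scargle VLF power of an IBI window and its percentage of total.

    The tachogram is irregularly sampled (one point per beat), hence the
    Lomb-Scargle periodogram rather than an FFT.
    """
    t = np.cumsum(ibi_ms) / 1000.0
    y = ibi_ms - np.mean(ibi_ms)
    if np.allclose(y, 0):
        return 0.0, 0.0
    f_max = 0.5 / (np.mean(ibi_ms) / 1000.0)
    freqs = np.linspace(_VLF_BAND[0] / 2, min(0.5, f_max), 512)
    pgram = sps.lombscargle(t, y, 2 * np.pi * freqs)
    in_vlf = (freqs >= _VLF_BAND[0]) & (freqs <= _VLF_BAND[1])
    vlf = float(np.trapezoid(pgram[in_vlf], freqs[in_vlf]))
    total = float(np.trapezoid(pgram, freqs))
    return vlf, (100.0 * vlf / total if total > 0 else 0.0)


def hrv_features(
    ibi_ms,
    window_beats: int = 60,
    labels=None,
    rel_window: int = 10,
) -> pd.DataFrame:
    """Windowed HRV feature rows from an IBI series.

    Per window of ``window_beats`` consecutive beats: MEAN_RR, MEDIAN_RR,
    SDRR (sample SD), RMSSD, SDRR_RMSSD, the relative-RR variants (each RR
    divided by the rolling mean of the previous ``rel_window`` beats) and
    Lomb-Scargle VLF power with its percentage of total spectral power.
    Windows with fewer than 10 beats are skipped with a warning.
    """
    ibi = np.asarray(ibi_ms, float)
    rows = []
    for w0 in range(0, ibi.size, window_beats):
        x = ibi[w0:w0 + window_beats]
        if x.size < 10:
            warnings.warn(f"window at beat {w0} has {x.size} < 10 beats: skipped")
            continue
        diffs = np.diff(x)
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        sdrr = float(np.std(x, ddof=1))
        rel = x / pd.Series(x).rolling(rel_window, min_periods=1).mean().to_numpy()
        rel_diffs = np.diff(rel)
        rel_rmssd = float(np.sqrt(np.mean(rel_diffs**2)))
        rel_sdrr = float(np.std(rel, ddof=1))
        vlf, vlf_pct = _vlf_power(x)
        row = {
            "MEAN_RR": float(np.mean(x)),
            "MEDIAN_RR": float(np.median(x)),
            "SDRR": sdrr,
            "RMSSD": rmssd,
            "SDRR_RMSSD": sdrr / rmssd if rmssd > 0 else float("nan"),
            "MEAN_REL_RR": float(np.mean(rel)),
            "MEDIAN_REL_RR": float(np.median(rel)),
            "SDRR_REL_RR": rel_sdrr,
            "RMSSD_REL_RR": rel_rmssd,
            "SDRR_RMSSD_REL_RR": rel_sdrr / rel_rmssd if rel_rmssd > 0 else float("nan"),
            "VLF": vlf,
            "VLF_PCT": vlf_pct,
        }
        if labels is not None:
            lab = np.asarray(labels)[w0:w0 + window_beats]
            vals, counts = np.unique(lab, return_counts=True)
            row["label"] = vals[np.argmax(counts)]
        rows.append(row)
    return pd.DataFrame(rows)
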