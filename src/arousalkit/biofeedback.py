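"""Heart rate from the FT9-FT10 bipolar EEG derivation, frontal laterality
index, and biofeedback frame generation.

The cardiac (QRS-like) artifact is picked up by the mastoid-adjacent FT9 and
FT10 electrodes with opposite polarity, so the processing chain is

    per-channel baseline correction (1-s moving-median subtraction)
    -> 12-30 Hz zero-phase band-pass (keeps the sharp cardiac transient
       while rejecting the dominant alpha rhythm and residual drift)
    -> bipolar difference FT9 - FT10 (roughly doubles the artifact,
       cancels common-mode EEG)
    -> adaptive-threshold peak detection
    -> systematic false-peak rejection (refractory, rate gate, amplitude)
    -> BPM from the accepted peak train.

The laterality index is the standard normalised right-minus-left frontal
alpha-power asymmetry over {F3, AF3} vs {F4, AF4}; the index formula is this
package's choice of the standard frontal-asymmetry form (only the input
electrodes are prescribed by the acquisition protocol).

Each analysis window yields one :class:`BiofeedbackFrame` stamped at the
window *end* — a constant feedback delay of exactly one window length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .features_spectral import BandPowerSet, window_band_powers
from .signal_io import MultiChannelSignal, SignalWindow, segment

__all__ = [
    "HeartRateEstimate",
    "LateralityIndex",
    "BiofeedbackFrame",
    "FrameMapping",
    "PeakDetectionConfig",
    "baseline_correct",
    "bandpass_cardiac",
    "bipolar_difference",
    "extract_heart_rate",
    "laterality_index",
    "make_frame",
    "run_feedback_loop",
    "write_frame_log",
]

CARDIAC_CHANNELS = ("FT9", "FT10")
LEFT_CHANNELS = ("F3", "AF3")
RIGHT_CHANNELS = ("F4", "AF4")


@dataclass
class HeartRateEstimate:
    bpm: float
    accepted_peaks: np.ndarray            # sample indices into the window
    rejected_peaks: list[tuple[int, str]]  # (sample index, reason)
    window_span: float                     # seconds


@dataclass
class LateralityIndex:
    li: float             # (right - left) / (right + left), in [-1, 1]
    left_power: float     # alpha power, F3 + AF3 (uV^2)
    right_power: float    # alpha power, F4 + AF4 (uV^2)


@dataclass
class BiofeedbackFrame:
    bpm: float
    li: float
    heart_level: int
    brain_level: int
    timestamp: float      # seconds, stamped at window end
    valid: bool = True


@dataclass(frozen=True)
class FrameMapping:
    """Breakpoints mapping BPM and |laterality| onto discrete visual levels.

    ``heart_level`` counts how many BPM breakpoints the current rate has
    crossed (level 0 = "normal condition", a small pink heart); ``brain_level``
    does the same on |laterality index|. Breakpoints must be strictly
    increasing.
    """

    bpm_breakpoints: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0)
    li_breakpoints: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

    def __post_init__(self) -> None:
        for bps in (self.bpm_breakpoints, self.li_breakpoints):
            if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
                raise ValueError(f"breakpoints must be strictly increasing: {bps}")


@dataclass(frozen=True)
class PeakDetectionConfig:
    band: tuple[float, float] = (12.0, 30.0)  # cardiac band-pass (Hz)
    threshold_kappa: float = 4.0              # x rolling median envelope
    threshold_window_s: float = 2.0           # rolling-median span
    envelope_s: float = 0.1                   # squared-signal smoothing span
    edge_guard_s: float = 0.25                # ignore filter transients at ends
    refractory_s: float = 0.3                 # minimum inter-beat spacing
    rate_gate_bpm: tuple[float, float] = (40.0, 180.0)
    amplitude_fraction: float = 0.3           # of median accepted amplitude


def baseline_correct(channel, fs: float, baseline_window_s: float = 1.0) -> np.ndarray:
    """Remove slow drift by subtracting a moving-median baseline.

    The median is robust to the sparse high-amplitude cardiac pulses, so
    drift is tracked without flattening the beats.
    """
    x = np.asarray(channel, float)
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    k = int(round(baseline_window_s * fs))
    k = max(k, 1)
    baseline = ndimage.median_filter(x, size=k, mode="nearest")
    return x - baseline


def bandpass_cardiac(channel, fs: float, band: tuple[float, float] = (12.0, 30.0)) -> np.ndarray:
    """Zero-phase Butterworth band-pass emphasising the cardiac transient."""
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(channel, float))


def bipolar_difference(ch_a, ch_b) -> np.ndarray:
    """Elementwise a - b (the FT9 - FT10 bipolar derivation)."""
    a = np.asarray(ch_a, float)
    b = np.asarray(ch_b, float)
    if a.shape != b.shape:
        raise ValueError(f"channel length mismatch: {a.shape} vs {b.shape}")
    return a - b


def _detect_candidates(d: np.ndarray, fs: float, cfg: PeakDetectionConfig) -> np.ndarray:
    """Candidate beat locations in the bipolar derivation.

    The squared signal is smoothed into an energy envelope (QRS-style
    integration); local envelope maxima above kappa x the rolling median
    envelope are kept and each is refined to the nearby maximum of |d|.
    A short guard band at either end discards zero-phase filter transients.
    """
    mag = np.abs(d)
    env = ndimage.uniform_filter1d(d**2, size=max(int(round(cfg.envelope_s * fs)), 1),
                                   mode="nearest")
    k = max(int(round(cfg.threshold_window_s * fs)), 3)
    thr = cfg.threshold_kappa * ndimage.median_filter(env, size=k, mode="nearest")
    peaks, _ = sps.find_peaks(env, height=thr,
                              distance=max(int(round(cfg.refractory_s * fs / 2)), 1))
    guard = int(round(cfg.edge_guard_s * fs))
    peaks = peaks[(peaks >= guard) & (peaks < d.size - guard)]
    # refine each envelope peak to the sharpest point of the derivation
    half = max(int(round(cfg.envelope_s * fs / 2)), 1)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, d.size)
        refined.append(lo + int(np.argmax(mag[lo:hi])))
    return np.unique(refined).astype(int)


def _reject_false_peaks(
    peaks: np.ndarray,
    mag: np.ndarray,
    fs: float,
    cfg: PeakDetectionConfig,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    rejected: list[tuple[int, str]] = []
    accepted = list(peaks)

    def drop_smaller_of_close_pairs(max_rate_interval_s: float, reason: str) -> None:
        changed = True
        while changed:
            changed = False
            for i in range(len(accepted) - 1):
                if (accepted[i + 1] - accepted[i]) / fs < max_rate_interval_s:
                    loser = i if mag[accepted[i]] < mag[accepted[i + 1]] else i + 1
                    rejected.append((accepted.pop(loser), reason))
                    changed = True
                    break

    # (i) refractory violations: keep the larger of any too-close pair
    drop_smaller_of_close_pairs(cfg.refractory_s, "refractory")
    # (ii) rate gate: intervals implying a rate above the physiologic maximum
    drop_smaller_of_close_pairs(60.0 / cfg.rate_gate_bpm[1], "rate")
    # (iii) amplitude gate against the median surviving peak
    if accepted:
        med_amp = float(np.median(mag[accepted]))
        keep = []
        for p in accepted:
            if mag[p] < cfg.amplitude_fraction * med_amp:
                rejected.append((p, "amplitude"))
            else:
                keep.append(p)
        accepted = keep
    return np.asarray(accepted, int), rejected


def extract_heart_rate(
    signal: MultiChannelSignal,
    window: SignalWindow | None = None,
    config: PeakDetectionConfig = PeakDetectionConfig(),
) -> HeartRateEstimate:
    """BPM from the FT9/FT10 bipolar derivation of one window.

    BPM = 60 x (number of accepted peaks - 1) / (time between the first and
    last accepted peak). Fewer than two accepted peaks gives a NaN BPM.
    """
    for name in CARDIAC_CHANNELS:
        if name not in signal.channel_names:
            raise KeyError(f"cardiac channel {name} missing from {signal.channel_names}")
    if window is None:
        window = SignalWindow(signal, 0, signal.n_samples,
                              signal.n_samples / signal.fs)
    fs = signal.fs
    span = window.length_samples / fs
    if span < 5.0 - 1e-9:
        raise ValueError("heart-rate window must span at least 5 s")

    processed = {}
    for name in CARDIAC_CHANNELS:
        x = baseline_correct(window.channel(name), fs)
        processed[name] = bandpass_cardiac(x, fs, config.band)
    d = bipolar_difference(processed["FT9"], processed["FT10"])

    peaks = _detect_candidates(d, fs, config)
    accepted, rejected = _reject_false_peaks(peaks, np.abs(d), fs, config)
    if accepted.size >= 2:
        bpm = 60.0 * (accepted.size - 1) / ((accepted[-1] - accepted[0]) / fs)
    else:
        warnings.warn("fewer than 2 accepted peaks: BPM is NaN")
        bpm = float("nan")
    return HeartRateEstimate(
        bpm=bpm, accepted_peaks=accepted, rejected_peaks=rejected, window_span=span,
    )


def laterality_index(
    bp_f3: BandPowerSet,
    bp_f4: BandPowerSet,
    bp_af3: BandPowerSet,
    bp_af4: BandPowerSet,
) -> LateralityIndex:
    """Normalised right-minus-left frontal alpha asymmetry, in [-1, 1]."""
    left = bp_f3.alpha + bp_af3.alpha
    right = bp_f4.alpha + bp_af4.alpha
    if left < 0 or right < 0:
        raise ValueError("negative alpha power")
    if left + right <= 0:
        warnings.warn("zero frontal alpha power: laterality index is NaN")
        return LateralityIndex(float("nan"), left, right)
    return LateralityIndex((right - left) / (right + left), left, right)


def make_frame(
    bpm: float,
    li: float,
    mapping: FrameMapping = FrameMapping(),
    timestamp: float = 0.0,
) -> BiofeedbackFrame:
    """Bin BPM and |laterality| into discrete visual levels."""
    valid = bool(np.isfinite(bpm) and np.isfinite(li))
    heart = int(np.sum(np.asarray(mapping.bpm_breakpoints) <= bpm)) if np.isfinite(bpm) else 0
    brain = int(np.sum(np.asarray(mapping.li_breakpoints) <= abs(li))) if np.isfinite(li) else 0
    return BiofeedbackFrame(
        bpm=float(bpm), li=float(li), heart_level=heart, brain_level=brain,
        timestamp=float(timestamp), valid=valid,
    )


def run_feedback_loop(
    signal: MultiChannelSignal,
    window_seconds: float = 5.0,
    mapping: FrameMapping = FrameMapping(),
    preset: str = "eq23",
    config: PeakDetectionConfig = PeakDetectionConfig(),
) -> list[BiofeedbackFrame]:
    """One biofeedback frame per analysis window.

    Frames are stamped at the window end: feedback for data in
    [t, t + w) becomes available at t + w, the constant one-window delay of a
    windowed pipeline. Windows where BPM or laterality is undefined produce
    frames flagged invalid.
    """
    frames = []
    for win in segment(signal, window_seconds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hr = extract_heart_rate(signal, win, config)
            bp = window_band_powers(win, list(LEFT_CHANNELS + RIGHT_CHANNELS), preset=preset)
            lat = laterality_index(bp["F3"], bp["F4"], bp["AF3"], bp["AF4"])
        frames.append(make_frame(hr.bpm, lat.li, mapping, timestamp=win.t_end))
    return frames


def write_frame_log(frames: list[BiofeedbackFrame], path: str | Path) -> None:
    """Write frames as newline-delimited JSON records."""
    def _num(x: float):
        return float(x) if np.isfinite(x) else None

    with open(path, "w") as fh:
        for fr in frames:
            fh.write(json.dumps({
                "t": fr.timestamp, "bpm": _num(fr.bpm), "li": _num(fr.li),
                "heart_level": fr.heart_level, "brain_level": fr.brain_level,
                "valid": fr.valid,
            }) + "\n")
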