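"""Valence/arousal indices from frontal band powers and calm/stress rules.

The two indices are alpha/beta band-power ratios over the frontal channels:

* valence  V = alpha(F4)/beta(F4) - alpha(F3)/beta(F3) — relative right-
  versus-left frontal alpha suppression, increasing with pleasantness;
* arousal  A = sum of alpha powers over {F3, F4, AF3, AF4} divided by the
  matching sum of beta powers — alpha-dominant (relaxed) windows score high,
  beta-dominant (activated) windows score low.

The calm/stress decision rules live on a 1-9 self-assessment-style scale:
calm iff arousal < 4 and 4 < valence < 6; stress iff arousal > 5 and
valence < 3. The ratio-valued indices must therefore be passed through a
monotone calibration (:class:`LinearCalibration`) before classification;
boundary equalities fall to "undetermined" because both rules are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features_spectral import BandPowerSet, window_band_powers

__all__ = [
    "AffectIndices",
    "AffectState",
    "AffectThresholds",
    "LinearCalibration",
    "valence_index",
    "arousal_index",
    "classify_state",
    "rescale_indices",
    "affect_report",
]

FRONTAL_CHANNELS = ("F3", "F4", "AF3", "AF4")


@dataclass
class AffectIndices:
    valence: float
    arousal: float
    scaled_valence: float
    scaled_arousal: float


@dataclass
class AffectState:
    label: str                       # "calm" | "stress" | "undetermined"
    rule_inputs: tuple[float, float]  # (scaled_arousal, scaled_valence)


@dataclass(frozen=True)
class AffectThresholds:
    """Decision-rule thresholds on the calibrated 1-9 scale."""

    calm_arousal_max: float = 4.0
    calm_valence_low: float = 4.0
    calm_valence_high: float = 6.0
    stress_arousal_min: float = 5.0
    stress_valence_max: float = 3.0


@dataclass(frozen=True)
class LinearCalibration:
    """Monotone linear map from an observed index range onto a report scale.

    The default factory maps the empirical [p5, p95] of a calibration
    recording linearly onto [1, 9]; an identity map is ``None`` wherever a
    calibration is accepted.
    """

    in_low: float
    in_high: float
    out_low: float = 1.0
    out_high: float = 9.0

    def __post_init__(self) -> None:
        if not self.in_high > self.in_low:
            raise ValueError("degenerate calibration range")
        if not self.out_high > self.out_low:
            raise ValueError("degenerate output range")

    def apply(self, x: float) -> float:
        span = (self.out_high - self.out_low) / (self.in_high - self.in_low)
        return self.out_low + (x - self.in_low) * span

    @classmethod
    def from_samples(cls, values, percentiles=(5.0, 95.0), out=(1.0, 9.0)) -> "LinearCalibration":
        values = np.asarray(values, float)
        values = values[np.isfinite(values)]
        lo, hi = np.percentile(values, percentiles)
        return cls(in_low=float(lo), in_high=float(hi), out_low=out[0], out_high=out[1])


def _ratio(bp: BandPowerSet, channel: str) -> float:
    if bp.beta <= 0:
        warnings.warn(f"zero beta power on {channel}: alpha/beta ratio is NaN")
        return float("nan")
    return bp.alpha / bp.beta


def valence_index(bp_f3: BandPowerSet, bp_f4: BandPowerSet) -> float:
    """V = alpha(F4)/beta(F4) - alpha(F3)/beta(F3)."""
    return _ratio(bp_f4, "F4") - _ratio(bp_f3, "F3")


def arousal_index(
    bp_f3: BandPowerSet,
    bp_f4: BandPowerSet,
    bp_af3: BandPowerSet,
    bp_af4: BandPowerSet,
) -> float:
    """A = sum of frontal alpha powers / sum of frontal beta powers.

    The sum-of-powers reading of the four-channel aggregate is used (robust
    to inter-channel phase cancellation); averaging the four time series
    before the PSD is available at pipeline level via
    ``affect_report(..., aggregate="signal_mean")``.
    """
    four = (bp_f3, bp_f4, bp_af3, bp_af4)
    beta_sum = sum(bp.beta for bp in four)
    if beta_sum <= 0:
        warnings.warn("zero summed beta power: arousal index is NaN")
        return float("nan")
    return sum(bp.alpha for bp in four) / beta_sum


def rescale_indices(
    valence: float,
    arousal: float,
    valence_calibration: LinearCalibration | None = None,
    arousal_calibration: LinearCalibration | None = None,
) -> tuple[float, float]:
    """Map raw ratio-scale indices onto the decision-rule scale.

    ``None`` means identity (inputs are already on the rule scale).
    """
    sv = valence if valence_calibration is None else valence_calibration.apply(valence)
    sa = arousal if arousal_calibration is None else arousal_calibration.apply(arousal)
    return sv, sa


def classify_state(
    scaled_arousal: float,
    scaled_valence: float,
    thresholds: AffectThresholds = AffectThresholds(),
) -> AffectState:
    """Calm/stress/undetermined decision on calibrated indices.

    The calm and stress regions are disjoint by construction (calm needs
    arousal < 4, stress needs arousal > 5); every boundary equality and any
    non-finite input yields "undetermined".
    """
    a, v = scaled_arousal, scaled_valence
    if not (np.isfinite(a) and np.isfinite(v)):
        warnings.warn("non-finite affect index: state undetermined")
        return AffectState("undetermined", (a, v))
    t = thresholds
    if a < t.calm_arousal_max and t.calm_valence_low < v < t.calm_valence_high:
        return AffectState("calm", (a, v))
    if a > t.stress_arousal_min and v < t.stress_valence_max:
        return AffectState("stress", (a, v))
    return AffectState("undetermined", (a, v))


def affect_report(
    windows,
    preset: str = "eq23",
    valence_calibration: LinearCalibration | None = None,
    arousal_calibration: LinearCalibration | None = None,
    thresholds: AffectThresholds = AffectThresholds(),
    aggregate: str = "power_sum",
) -> pd.DataFrame:
    """Per-window affect table: V, A, scaled values and the state label.

    ``aggregate`` chooses how the four frontal channels combine into the
    arousal index: ``"power_sum"`` (default) sums per-channel band powers;
    ``"signal_mean"`` averages the four time series before the PSD.
    """
    from .features_spectral import band_powers, estimate_psd

    rows = []
    for i, win in enumerate(windows):
        bp = window_band_powers(win, list(FRONTAL_CHANNELS), preset=preset)
        v = valence_index(bp["F3"], bp["F4"])
        if aggregate == "power_sum":
            a = arousal_index(bp["F3"], bp["F4"], bp["AF3"], bp["AF4"])
        elif aggregate == "signal_mean":
            mean_sig = np.mean(
                [win.channel(c) for c in FRONTAL_CHANNELS], axis=0
            )
            agg = band_powers(estimate_psd(mean_sig, win.parent.fs), preset)
            a = agg.alpha / agg.beta if agg.beta > 0 else float("nan")
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        sv, sa = rescale_indices(v, a, valence_calibration, arousal_calibration)
        state = classify_state(sa, sv, thresholds)
        rows.append({
            "window": i, "valence": v, "arousal": a,
            "scaled_valence": sv, "scaled_arousal": sa, "label": state.label,
        })
    return pd.DataFrame(rows)
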