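"""Multichannel signal containers, file I/O and fixed-window segmentation.

EEG recordings are held as a samples-by-channels matrix in microvolts with a
single sampling rate. Two on-disk formats are supported:

* **CSV** — an optional first comment line ``# fs=<Hz>``, then a header row of
  channel names and one sample per row.
* **EDF** (European Data Format) — read through :mod:`mne`; a minimal EDF
  writer is provided for fixtures and round-trips (16-bit quantisation).

Analysis proceeds on contiguous, non-overlapping fixed-length windows
(default 5 s), the granularity at which every downstream feature is computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultiChannelSignal",
    "SignalWindow",
    "SignalFormatError",
    "read_signal",
    "write_signal",
    "segment",
]


class SignalFormatError(ValueError):
    """Raised when a signal file violates the container invariants."""


@dataclass
class MultiChannelSignal:
    """Sampled multichannel signal (N samples x C channels, microvolts).

    Channel names are 10-20 system labels, matched case-insensitively and
    stored uppercase.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise SignalFormatError("samples must be a 2-D (N x C) array")
        n, c = self.samples.shape
        if n < 2:
            raise SignalFormatError("need at least 2 samples")
        if c < 1:
            raise SignalFormatError("need at least 1 channel")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise SignalFormatError(f"sampling rate must be finite and > 0, got {self.fs}")
        names = [str(name).upper() for name in self.channel_names]
        if len(names) != c:
            raise SignalFormatError(
                f"{len(names)} channel names for {c} channels"
            )
        if len(set(names)) != len(names):
            raise SignalFormatError(f"duplicate channel names in {names}")
        self.channel_names = names

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name.upper())
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples as a 1-D array (view)."""
        return self.samples[:, self.channel_index(name)]


@dataclass
class SignalWindow:
    """A contiguous block of samples inside a parent recording."""

    parent: MultiChannelSignal
    start_index: int
    length_samples: int
    window_seconds: float

    def __post_init__(self) -> None:
        if self.length_samples != round(self.window_seconds * self.parent.fs):
            raise ValueError("length_samples inconsistent with window_seconds * fs")
        if self.start_index < 0 or self.start_index + self.length_samples > self.parent.n_samples:
            raise ValueError("window extends beyond the recording")

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start_index:self.start_index + self.length_samples]

    @property
    def t_start(self) -> float:
        """Window start time (s) relative to the recording origin."""
        return self.parent.start_time + self.start_index / self.parent.fs

    @property
    def t_end(self) -> float:
        return self.t_start + self.window_seconds

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.parent.channel_index(name)]


def segment(
    signal: MultiChannelSignal,
    window_seconds: float = 5.0,
    stride_seconds: float | None = None,
) -> list[SignalWindow]:
    """Tile the recording prefix with fixed-length windows.

    Windows are contiguous and non-overlapping by default; a trailing partial
    window is dropped so every window carries a full sample block. A sliding
    analysis is available through ``stride_seconds`` < ``window_seconds``.
    A window longer than the recording yields an empty list.
    """
    w = int(round(window_seconds * signal.fs))
    if w < 2:
        raise ValueError("window_seconds * fs must be at least 2 samples")
    stride = w if stride_seconds is None else int(round(stride_seconds * signal.fs))
    if stride < 1:
        raise ValueError("stride must be at least one sample")
    out: list[SignalWindow] = []
    start = 0
    while start + w <= signal.n_samples:
        out.append(SignalWindow(signal, start, w, window_seconds))
        start += stride
    return out


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path, fs: float | None) -> MultiChannelSignal:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            token = first.lstrip("#").strip()
            if token.lower().startswith("fs="):
                fs = float(token[3:])
            header_line = fh.readline()
        else:
            header_line = first
        names = [t.strip() for t in header_line.rstrip("\n").split(",")]
        upper = [n.upper() for n in names]
        if len(set(upper)) != len(upper):
            raise SignalFormatError(f"duplicate channel names in CSV header: {names}")
        if any(not n for n in names):
            raise SignalFormatError("empty channel name in CSV header")
        data = pd.read_csv(fh, header=None, names=names, dtype=float)
    if fs is None:
        raise SignalFormatError(
            "sampling rate unknown: no '# fs=<Hz>' line and no fs argument"
        )
    return MultiChannelSignal(data.to_numpy(), fs=fs, channel_names=upper)


def _write_csv(signal: MultiChannelSignal, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs:g}\n")
        fh.write(",".join(signal.channel_names) + "\n")
        np.savetxt(fh, signal.samples, delimiter=",", fmt="%.10g")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> MultiChannelSignal:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = [name.upper() for name in raw.ch_names]
    if len(set(names)) != len(names):
        raise SignalFormatError(f"duplicate channel names in EDF: {raw.ch_names}")
    # mne stores EEG in volts; the physical dimension written here is uV
    data = raw.get_data().T * 1e6
    return MultiChannelSignal(data, fs=float(raw.info["sfreq"]), channel_names=names)


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(signal: MultiChannelSignal, path: Path) -> None:
    """Minimal EDF writer: one data record spanning the whole signal.

    Samples are quantised to 16-bit integers against per-channel physical
    min/max, so a round-trip is exact only to that quantisation step.
    """
    n, c = signal.samples.shape
    duration = n / signal.fs
    header_bytes = 256 * (1 + c)
    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field("X X X X", 80))          # patient id
        fh.write(_ascii_field("Startdate X X X X", 80))  # recording id
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(1, 8))                   # number of data records
        fh.write(_ascii_field(f"{duration:.6g}", 8))
        fh.write(_ascii_field(c, 4))

        pmins, pmaxs = [], []
        for j in range(c):
            x = signal.samples[:, j]
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                hi = lo + 1.0
            pmins.append(lo)
            pmaxs.append(hi)

        for name in signal.channel_names:
            fh.write(_ascii_field(name, 16))
        for _ in range(c):
            fh.write(_ascii_field("", 80))             # transducer
        for _ in range(c):
            fh.write(_ascii_field("uV", 8))
        for lo in pmins:
            fh.write(_ascii_field(f"{lo:.6g}"[:8], 8))
        for hi in pmaxs:
            fh.write(_ascii_field(f"{hi:.6g}"[:8], 8))
        for _ in range(c):
            fh.write(_ascii_field(-32768, 8))
        for _ in range(c):
            fh.write(_ascii_field(32767, 8))
        for _ in range(c):
            fh.write(_ascii_field("", 80))             # prefiltering
        for _ in range(c):
            fh.write(_ascii_field(n, 8))               # samples per record
        for _ in range(c):
            fh.write(_ascii_field("", 32))

        for j in range(c):
            # the header stores rounded physical limits; scale against those
            lo = float(f"{pmins[j]:.6g}"[:8])
            hi = float(f"{pmaxs[j]:.6g}"[:8])
            x = signal.samples[:, j]
            dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            fh.write(dig.tobytes())


def read_signal(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> MultiChannelSignal:
    """Read a multichannel signal from EDF or CSV.

    ``format`` defaults to the file extension. ``fs`` overrides/supplies the
    sampling rate for CSV files without an ``# fs=`` line. Amplitudes are
    returned in microvolts (EDF physical scaling applied).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path, fs)
    raise ValueError(f"unsupported format {fmt!r} (expected 'edf' or 'csv')")


def write_signal(signal: MultiChannelSignal, path: str | Path, format: str | None = None) -> None:
    """Write a signal to CSV (lossless) or EDF (16-bit quantised)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        _write_edf(signal, path)
    elif fmt == "csv":
        _write_csv(signal, path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (expected 'edf' or 'csv')")
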