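"""Recording, annotation and result I/O plus resampling.

On-disk formats are deliberately plain: a recording is a delimited text file
whose first line is a ``# key=value`` metadata comment carrying the sampling
rate, followed by one header row of channel labels and one column per channel.
Beat annotations and IBI result tables are ordinary CSV.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

if TYPE_CHECKING:  # pragma: no cover
    from .fusion import FusedIbiSeries

__all__ = [
    "ChannelSignal", "Recording", "BeatAnnotations", "FormatError",
    "read_recording", "write_recording", "read_beat_annotations",
    "write_beat_annotations", "resample_quadratic_spline", "decimate",
    "write_ibi_table", "read_ibi_table",
]


class FormatError(ValueError):
    """Raised for malformed recording or annotation files."""


@dataclass
class ChannelSignal:
    """One sensor's waveform: amplitude series, sampling rate and label."""

    samples: np.ndarray
    sr_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("channel samples must be one-dimensional")
        if self.sr_hz <= 0:
            raise FormatError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sr_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sr_hz


@dataclass
class Recording:
    """Time-synchronised multichannel recording (equal length and rate)."""

    channels: list[ChannelSignal]

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("recording needs at least one channel")
        n0 = len(self.channels[0].samples)
        sr0 = self.channels[0].sr_hz
        for ch in self.channels:
            if len(ch.samples) != n0 or ch.sr_hz != sr0:
                raise FormatError(
                    "all channels must share length and sampling rate; "
                    "resample before assembling a Recording")

    @property
    def sr_hz(self) -> float:
        return self.channels[0].sr_hz

    @property
    def duration_s(self) -> float:
        return self.channels[0].duration_s

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def __len__(self) -> int:
        return len(self.channels)

    def select(self, labels: Sequence[str]) -> "Recording":
        by_label = {ch.label: ch for ch in self.channels}
        missing = [l for l in labels if l not in by_label]
        if missing:
            raise KeyError(f"unknown channel labels: {missing}")
        return Recording([by_label[l] for l in labels])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({ch.label: ch.samples for ch in self.channels})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sr_hz: float) -> "Recording":
        return cls([ChannelSignal(df[c].to_numpy(float), sr_hz, str(c))
                    for c in df.columns])


@dataclass
class BeatAnnotations:
    """Reference beat times (ECG R-peaks or simulator ground truth)."""

    beat_times_s: np.ndarray
    source: str = "reference"

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise FormatError("beat times must be strictly increasing")

    @property
    def ibi_ms(self) -> np.ndarray:
        """Reference inter-beat intervals in ms (length = n beats - 1)."""
        return np.diff(self.beat_times_s) * 1000.0

    def __len__(self) -> int:
        return len(self.beat_times_s)


# -- recording files -------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sr_hz={rec.sr_hz:g}\n")
        rec.to_dataframe().to_csv(fh, index=False, float_format="%.9g")


def read_recording(path: str | Path) -> Recording:
    """Read a delimited-text recording (metadata line, header, columns)."""
    p = Path(path)
    with open(p) as fh:
        first = fh.readline()
        sr_hz = None
        if first.startswith("#"):
            for token in first[1:].replace(",", " ").split():
                if token.startswith("sr_hz="):
                    sr_hz = float(token.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    if sr_hz is None:
        raise FormatError(f"{p}: missing '# sr_hz=<rate>' metadata line")
    first_line = body.splitlines()[0] if body.strip() else ""
    sep = "\t" if "\t" in first_line else ","
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep)
    except Exception as exc:  # ragged rows, empty body, ...
        raise FormatError(f"{p}: cannot parse signal table ({exc})") from exc
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{p}: no signal columns")
    if df.isna().any().any():
        raise FormatError(f"{p}: ragged or non-numeric signal columns")
    return Recording.from_dataframe(df, sr_hz)


def read_beat_annotations(path: str | Path, source: str = "reference") -> BeatAnnotations:
    df = pd.read_csv(path)
    col = "beat_time_s" if "beat_time_s" in df.columns else df.columns[0]
    return BeatAnnotations(df[col].to_numpy(float), source=source)


def write_beat_annotations(ann: BeatAnnotations, path: str | Path) -> None:
    pd.DataFrame({"beat_time_s": ann.beat_times_s}).to_csv(path, index=False,
                                                           float_format="%.6f")


# -- resampling ------------------------------------------------------------

def resample_quadratic_spline(x: ChannelSignal, sr_out: float) -> ChannelSignal:
    """Resample through a quadratic (order-2) spline fit.

    A second-order spline is fitted through the input samples and evaluated on
    the uniform ``sr_out`` grid spanning the same time interval.  The order-2
    choice (rather than the more common cubic) keeps the interpolant's local
    extrema sharp, which matters when beat times are read off waveform peaks.
    """
    if sr_out <= 0:
        raise ValueError("sr_out must be positive")
    n = len(x.samples)
    if n < 3:
        raise ValueError("need at least 3 samples for a quadratic spline")
    t_in = np.arange(n) / x.sr_hz
    m = int(round(n / x.sr_hz * sr_out))
    t_out = np.arange(m) / sr_out
    spline = make_interp_spline(t_in, x.samples, k=2)
    return ChannelSignal(spline(t_out), sr_out, x.label)


def decimate(x: ChannelSignal, factor: int) -> ChannelSignal:
    """Plain integer decimation (no anti-alias stage), keeping every
    ``factor``-th sample.  Aliasing of out-of-band noise is the caller's
    concern; pair with :func:`resample_quadratic_spline` to restore the rate.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    return ChannelSignal(x.samples[::int(factor)], x.sr_hz / factor, x.label)


# -- IBI result tables -----------------------------------------------------

_IBI_COLUMNS = ["beat_index", "time_s", "ibi_ms", "source_channel",
                "sqi_beat", "band_fl_hz"]


def write_ibi_table(result: "FusedIbiSeries", path: str | Path) -> None:
    """Write the fused beat table as CSV (header always present)."""
    df = result.to_frame()
    df.to_csv(path, index=False, float_format="%.6f", columns=_IBI_COLUMNS)


def read_ibi_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _IBI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IBI table missing columns: {missing}")
    return df
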