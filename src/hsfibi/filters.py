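"""Zero-phase Butterworth filter bank and band weighting.

All filtering in the pipeline is forward-backward (``sosfiltfilt``), so beat
peak positions are never displaced by filter group delay.  The band-selection
bank filters one channel into ``[fL, fH]`` for every candidate low cutoff and
attaches the weight ``beta = 1 + K * (fL - 1)``: bands with a higher low
cutoff carry proportionally more heart-valve signal, whose sharper peaks give
more trustworthy beat times, and are therefore up-weighted when per-beat
quality scores are compared across channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .config import HsfConfig
from .io import ChannelSignal

__all__ = ["BandCandidate", "bandpass_bidirectional", "build_band_candidates",
           "beta_weight"]

log = logging.getLogger(__name__)

#: cutoffs are clamped to this fraction of the sampling rate when the
#: configured high cutoff would reach the Nyquist frequency
_NYQUIST_CLAMP = 0.45


@dataclass
class BandCandidate:
    """One band-filtered view of a channel with its selection weight."""

    fl_hz: float
    fh_hz: float
    beta: float
    filtered: ChannelSignal


@lru_cache(maxsize=256)
def _design_sos(sr_hz: float, f_lo: float, f_hi: float, order: int) -> np.ndarray:
    # second-order sections for numerical stability at low relative cutoffs
    return sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=sr_hz,
                      output="sos")


def _effective_high_cutoff(sr_hz: float, f_hi: float) -> float:
    nyq = sr_hz / 2.0
    if f_hi >= nyq:
        clamped = _NYQUIST_CLAMP * sr_hz
        warnings.warn(
            f"high cutoff {f_hi:g} Hz >= Nyquist ({nyq:g} Hz); clamping to "
            f"{clamped:g} Hz — consider resampling the input instead",
            RuntimeWarning, stacklevel=3)
        return clamped
    return f_hi


def bandpass_bidirectional(x: ChannelSignal, f_lo: float, f_hi: float,
                           order: int = 3) -> ChannelSignal:
    """Forward-backward Butterworth band-pass (zero phase shift).

    The cascade's impulse response is symmetric, so symmetric pulses keep
    their peak sample exactly.  Output length equals input length.
    """
    if f_lo <= 0:
        raise ValueError("low cutoff must be positive")
    f_hi = _effective_high_cutoff(x.sr_hz, f_hi)
    if f_lo >= f_hi:
        raise ValueError(f"low cutoff {f_lo:g} Hz must be below the "
                         f"(possibly clamped) high cutoff {f_hi:g} Hz")
    sos = _design_sos(x.sr_hz, float(f_lo), float(f_hi), int(order))
    y = sps.sosfiltfilt(sos, x.samples)
    return ChannelSignal(y, x.sr_hz, x.label)


def beta_weight(fl_hz: float, k_weight: float) -> float:
    """Band weight beta = 1 + K * (fL - 1)."""
    return 1.0 + k_weight * (fl_hz - 1.0)


def build_band_candidates(x: ChannelSignal, cfg: HsfConfig) -> list[BandCandidate]:
    """Filter ``x`` into every configured candidate band.

    A candidate whose filter design or application fails is dropped with a log
    entry rather than aborting the whole channel.
    """
    if x.duration_s < cfg.window_s:
        raise ValueError(
            f"channel {x.label!r}: {x.duration_s:.2f} s is shorter than one "
            f"analysis window ({cfg.window_s:g} s)")
    out: list[BandCandidate] = []
    for fl in cfg.candidate_fl_hz:
        try:
            filtered = bandpass_bidirectional(x, fl, cfg.fh_hz, cfg.filter_order)
        except ValueError as exc:
            log.warning("channel %s: dropping band fL=%g Hz (%s)", x.label, fl, exc)
            continue
        out.append(BandCandidate(fl_hz=fl, fh_hz=cfg.fh_hz,
                                 beta=cfg.beta(fl), filtered=filtered))
    return out
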