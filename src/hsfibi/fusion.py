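"""Beat-level fusion of per-channel detections.

Beats from different channels that fall within a small tolerance of each
other are grouped into chronological slots (one beat per channel per slot).
Within each slot the channel with the highest band-weighted beat SQI supplies
the fused beat, with an eligibility gate on the *previous* slot: only
channels whose previous beat's SQI cleared the threshold compete normally;
if none did, the best available beat is taken and marked low-confidence.
Fused IBIs are differences of consecutive fused beat times, so switching
source channels between slots cannot double-count fixed inter-sensor lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HsfConfig
from .beats import Beat, BeatSequence

__all__ = ["FusedBeat", "FusedIbiSeries", "align_beats", "fuse"]


@dataclass
class FusedBeat:
    time_s: float
    ibi_ms: float  # nan for the first beat / after unmatched spans
    source_channel: str
    sqi_beat: float
    fl_hz: float | None
    low_confidence: bool = False


@dataclass
class FusedIbiSeries:
    """Fused beat timeline with per-beat provenance."""

    beats: list[FusedBeat] = field(default_factory=list)
    #: (n_covered_windows, n_total_windows) bookkeeping, if available
    coverage_windows: tuple[int, int] | None = None

    @property
    def times_s(self) -> np.ndarray:
        return np.array([b.time_s for b in self.beats])

    @property
    def ibis_ms(self) -> np.ndarray:
        return np.array([b.ibi_ms for b in self.beats])

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def coverage_pct(self) -> float:
        if not self.coverage_windows or self.coverage_windows[1] == 0:
            return float("nan")
        return 100.0 * self.coverage_windows[0] / self.coverage_windows[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat_index": np.arange(len(self.beats)),
            "time_s": [b.time_s for b in self.beats],
            "ibi_ms": [b.ibi_ms for b in self.beats],
            "source_channel": [b.source_channel for b in self.beats],
            "sqi_beat": [b.sqi_beat for b in self.beats],
            "band_fl_hz": [b.fl_hz for b in self.beats],
            "low_confidence": [b.low_confidence for b in self.beats],
        })


#: one slot: channel label -> Beat
Slot = dict[str, Beat]


def align_beats(sequences: list[BeatSequence], tol_s: float = 0.15
                ) -> list[Slot]:
    """Greedy chronological grouping of cross-channel beats.

    Beats within ``tol_s`` of the current slot's earliest member join the
    slot; each channel contributes at most one beat per slot (its earliest).
    """
    if not sequences:
        raise ValueError("need at least one beat sequence")
    entries = sorted(
        ((b.time_s, seq.channel, b) for seq in sequences for b in seq.beats),
        key=lambda e: e[0])
    slots: list[Slot] = []
    slot_start = None
    for t, ch, beat in entries:
        if slot_start is None or t - slot_start > tol_s or ch in slots[-1]:
            slots.append({})
            slot_start = t
        slots[-1].setdefault(ch, beat)
    return slots


def fuse(slots: list[Slot], cfg: HsfConfig,
         coverage_windows: tuple[int, int] | None = None) -> FusedIbiSeries:
    """Per-slot SQI-based channel selection into one fused IBI series."""
    fused: list[FusedBeat] = []
    prev_slot: Slot | None = None
    prev_trusted = False
    prev_time = None
    for slot in slots:
        eligible = [ch for ch in slot
                    if prev_slot is not None and ch in prev_slot
                    and prev_slot[ch].sqi_beat > cfg.theta_beat]
        trusted_now = [ch for ch in slot
                       if slot[ch].sqi_beat > cfg.theta_beat]
        low_conf = not eligible
        if eligible:
            pool = eligible
        elif trusted_now:
            # e.g. a channel resuming after its own gap: not formally
            # eligible (absent from the previous slot) but trustworthy now
            pool = trusted_now
        elif prev_slot is None or not prev_trusted:
            # sustained outage (or cold start): degrade to best effort
            pool = list(slot)
        else:
            # an untrusted slot sandwiched between trusted beats is noise:
            # emitting it would corrupt two otherwise-clean intervals
            prev_slot, prev_trusted = slot, False
            continue
        ch = max(pool, key=lambda c: slot[c].sqi_beat)
        beat = slot[ch]
        ibi = float("nan")
        if prev_time is not None:
            ibi = (beat.time_s - prev_time) * 1000.0
        fused.append(FusedBeat(beat.time_s, ibi, ch, beat.sqi_beat,
                               beat.fl_hz, low_confidence=low_conf))
        prev_slot, prev_time = slot, beat.time_s
        prev_trusted = bool(trusted_now) or bool(eligible)
    return FusedIbiSeries(fused, coverage_windows=coverage_windows)
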