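"""Per-channel optimal band selection and channel admission.

Each channel is filtered into every candidate band and scored by the
harmonic-summation SQI; one band (or none) is then kept per channel:

1. if any band's SQI exceeds ``Q1``, keep the *highest* low cutoff among
   those bands (higher bands carry the sharper heart-valve content, so they
   are preferred whenever their quality clears the strict threshold);
2. otherwise, if any band's SQI exceeds ``Q2``, keep the band with the
   maximum SQI (ties break toward the higher cutoff);
3. otherwise the channel is discarded for this decision epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import HsfConfig

__all__ = ["BandDecision", "select_band", "admit_channels"]


@dataclass(frozen=True)
class BandDecision:
    """Outcome of band selection for one channel at one decision epoch."""

    channel: str
    status: str  # "selected" | "discarded"
    fl_hz: float | None
    beta: float | None
    sqi: float
    rule: int  # which selection clause fired (1, 2 or 3)

    @property
    def selected(self) -> bool:
        return self.status == "selected"


def select_band(sqi_by_fl: Mapping[float, float], cfg: HsfConfig,
                channel: str = "") -> BandDecision:
    """Apply the three-clause band-selection scheme to one channel's SQIs."""
    if not sqi_by_fl:
        raise ValueError("sqi_by_fl must be non-empty")
    above_q1 = [fl for fl, s in sqi_by_fl.items() if s > cfg.q1]
    if above_q1:
        fl = max(above_q1)
        return BandDecision(channel, "selected", fl, cfg.beta(fl),
                            sqi_by_fl[fl], rule=1)
    above_q2 = [fl for fl, s in sqi_by_fl.items() if s > cfg.q2]
    if above_q2:
        # max SQI; ties break toward the higher cutoff
        fl = max(above_q2, key=lambda f: (sqi_by_fl[f], f))
        return BandDecision(channel, "selected", fl, cfg.beta(fl),
                            sqi_by_fl[fl], rule=2)
    best = max(sqi_by_fl.values())
    return BandDecision(channel, "discarded", None, None, best, rule=3)


def admit_channels(decisions: list[BandDecision]) -> list[BandDecision]:
    """Channels admitted for this epoch (possibly empty: window uncovered).

    Ties between channels are not broken here — all admitted channels proceed
    and fusion chooses per beat.
    """
    return [d for d in decisions if d.selected]
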