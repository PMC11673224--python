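"""Per-channel heartbeat localisation by peak-restricted template matching.

Rather than sliding the template over every sample, the Pearson correlation
between each template and the beat-period window centred on a signal peak is
evaluated *only at local maxima* of the band-filtered signal — heartbeat
positions coincide with peaks, and this keeps the cost at (number of peaks)
x (number of templates) correlations.

Detection walks the recording beat by beat: the first beat is the peak with
the best template match within the first two seconds, and each subsequent
beat is searched for in the window ``[(1-v) L, (1+v) L]`` after the previous
one, ``v`` being the short-term HRV allowance.  Template choice between the
one or two templates follows the higher current correlation, gated by which
templates were trustworthy (correlation above ``theta``) at the previous
beat; when neither was, both compete (cold-start rule).  Each beat carries
``SQI_beat = beta * max(ccf_1, ccf_2)``, the band-weighted matching score
used downstream for fusion and for the template-update triggers: five
consecutive low-SQI beats, too many consecutive missed beats, or a span in
which the harmonic-summation SQI of every channel has collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import HsfConfig
from .io import ChannelSignal
from .templates import TemplateGroup, local_maxima

__all__ = ["CcfSample", "Beat", "BeatSequence", "UpdateTrigger",
           "ccf_at_peaks", "detect_beats", "maybe_update_templates"]


@dataclass
class CcfSample:
    """Template correlations at one signal peak."""

    p_index: int
    r_by_template: np.ndarray


@dataclass
class Beat:
    """One detected heartbeat."""

    time_s: float
    p_index: int
    sqi_beat: float
    template_used: int  # 1-based template index
    ibi_ms: float = float("nan")  # nan for the first beat or after a gap
    fl_hz: float | None = None


@dataclass
class BeatSequence:
    """Time-ordered beats of one channel plus spans where tracking was lost."""

    channel: str
    beats: list[Beat] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([b.time_s for b in self.beats])

    @property
    def ibis_ms(self) -> np.ndarray:
        return np.array([b.ibi_ms for b in self.beats])

    @property
    def sqis(self) -> np.ndarray:
        return np.array([b.sqi_beat for b in self.beats])

    def __len__(self) -> int:
        return len(self.beats)


@dataclass
class UpdateTrigger:
    """A request to refresh band selection and templates."""

    reason: str  # "low_sqi" | "missed_beats" | "harsum_failed" | "no_bootstrap"
    sample: int


def _peak_correlations(samples: np.ndarray, peaks: np.ndarray,
                       templates: list[np.ndarray], L: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between each template and the L-window centred on each peak.

    Returns the subset of peaks whose centred window fits inside the signal
    and the (n_peaks, n_templates) correlation matrix.
    """
    half_lo = L // 2
    ok = (peaks - half_lo >= 0) & (peaks - half_lo + L <= len(samples))
    peaks = peaks[ok]
    if len(peaks) == 0:
        return peaks, np.zeros((0, len(templates)))
    idx = (peaks - half_lo)[:, None] + np.arange(L)[None, :]
    win = samples[idx]
    win = win - win.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(win, axis=1)
    norms[norms == 0] = np.inf  # zero-variance window -> r = 0
    win /= norms[:, None]
    tmat = np.vstack([t - t.mean() for t in templates])
    tnorm = np.linalg.norm(tmat, axis=1)
    tnorm[tnorm == 0] = np.inf
    tmat /= tnorm[:, None]
    return peaks, np.clip(win @ tmat.T, -1.0, 1.0)


def ccf_at_peaks(signal: ChannelSignal, group: TemplateGroup,
                 edge_trim_s: float = 0.5) -> list[CcfSample]:
    """Correlation-coefficient function sampled at signal peaks.

    The first and last ``edge_trim_s`` of the signal are excluded from peak
    detection (bidirectional-filter edge transients).
    """
    trim = int(round(edge_trim_s * signal.sr_hz))
    peaks = local_maxima(signal.samples)
    peaks = peaks[(peaks >= trim) & (peaks < len(signal.samples) - trim)]
    peaks, r = _peak_correlations(signal.samples, peaks, group.templates,
                                  group.L)
    return [CcfSample(int(p), r[i]) for i, p in enumerate(peaks)]


def maybe_update_templates(low_sqi_run: int, all_channels_harsum_failed: bool,
                           cfg: HsfConfig) -> bool:
    """True when either template-update trigger fires: the channel's beat SQI
    has been below threshold for the configured number of consecutive beats,
    or the harmonic-summation SQI of every channel has failed."""
    return (low_sqi_run >= cfg.consecutive_low_sqi_for_update
            or all_channels_harsum_failed)


def detect_beats(signal: ChannelSignal, group: TemplateGroup,
                 hr_mean_bpm: float, beta: float, cfg: HsfConfig,
                 start_sample: int = 0, end_sample: int | None = None,
                 forced_spans: list[tuple[int, int]] | None = None
                 ) -> tuple[list[Beat], list[tuple[float, float]],
                            UpdateTrigger | None]:
    """Track beats through ``signal`` from ``start_sample`` until the end of
    the analysis region or an update trigger.

    Returns ``(beats, gaps, trigger)``; ``trigger`` is None when the region
    was tracked to completion.  A missed beat (no candidate peak in the
    search window) advances the anchor by one expected period and opens a
    gap; no IBI is emitted across gaps.
    """
    sr = signal.sr_hz
    end = len(signal.samples) if end_sample is None else end_sample
    L = group.L
    v = cfg.v_hrv
    forced_spans = forced_spans or []

    ccf = ccf_at_peaks(signal, group, cfg.edge_trim_s)
    peaks = np.array([c.p_index for c in ccf], dtype=int)
    rmat = (np.vstack([c.r_by_template for c in ccf])
            if ccf else np.zeros((0, len(group.templates))))
    in_region = (peaks >= start_sample) & (peaks < end)
    peaks, rmat = peaks[in_region], rmat[in_region]
    best_r = rmat.max(axis=1) if len(peaks) else np.empty(0)

    beats: list[Beat] = []
    gaps: list[tuple[float, float]] = []

    if len(peaks) == 0:
        gaps.append((start_sample / sr, end / sr))
        return beats, gaps, UpdateTrigger("no_bootstrap", min(end, start_sample))

    # bootstrap: best-matching peak within the first 2 s of the region
    boot = np.flatnonzero(peaks < start_sample + int(2.0 * sr))
    if len(boot) == 0:
        return beats, gaps, UpdateTrigger("no_bootstrap",
                                          start_sample + int(2.0 * sr))
    i0 = boot[int(np.argmax(best_r[boot]))]
    prev_peak = int(peaks[i0])
    prev_r = rmat[i0]
    tpl = int(np.argmax(prev_r))
    sqi = beta * float(best_r[i0])
    beats.append(Beat(prev_peak / sr, prev_peak, sqi, tpl + 1))

    low_run = 1 if sqi < cfg.theta_beat else 0
    misses = 0
    anchor = prev_peak           # search anchor (may be virtual after a miss)
    last_real = prev_peak        # last accepted beat sample

    def in_forced(p: int) -> bool:
        return any(s0 <= p < s1 for s0, s1 in forced_spans)

    while True:
        lo = anchor + int(round((1 - v) * L))
        hi = anchor + int(round((1 + v) * L))
        if hi >= end:
            break
        cand = np.flatnonzero((peaks >= lo) & (peaks <= hi))
        if len(cand) == 0:
            misses += 1
            if misses == 1:
                gap_start = last_real / sr
            anchor = anchor + L
            if misses >= cfg.max_consecutive_misses:
                gaps.append((gap_start, anchor / sr))
                return beats, gaps, UpdateTrigger("missed_beats", anchor)
            continue
        # template eligibility from the previous accepted beat
        eligible = np.flatnonzero(prev_r > cfg.theta_beat)
        if len(eligible) == 0:
            eligible = np.arange(rmat.shape[1])  # cold start: all compete
        score = rmat[cand][:, eligible].max(axis=1)
        j = cand[int(np.argmax(score))]  # ties: earliest position
        p = int(peaks[j])
        tpl = int(eligible[int(np.argmax(rmat[j][eligible]))])
        sqi = beta * float(best_r[j])
        ibi = float("nan")
        if misses == 0:
            ibi = (p - last_real) / sr * 1000.0
        else:
            gaps.append((gap_start, p / sr))
        beats.append(Beat(p / sr, p, sqi, tpl + 1, ibi_ms=ibi))
        prev_r = rmat[j]
        anchor = last_real = p
        misses = 0
        low_run = low_run + 1 if sqi < cfg.theta_beat else 0
        if maybe_update_templates(low_run, in_forced(p), cfg):
            reason = ("harsum_failed" if in_forced(p) else "low_sqi")
            return beats, gaps, UpdateTrigger(reason, p)
    return beats, gaps, None
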