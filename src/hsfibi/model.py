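"""Model/Results interface orchestrating the full IBI-extraction pipeline.

:class:`HsfIbi` is constructed from a multichannel recording and a config;
:meth:`HsfIbi.fit` runs band candidates -> sliding harmonic-summation HR/SQI
-> band & channel selection -> template-group extraction -> per-channel beat
tracking with update triggers -> beat-level fusion, and returns an
:class:`HsfIbiResults` carrying the fused IBI series, per-channel sequences,
the full decision log and evaluation helpers.

Epoch structure: band selection and templates are established on the first
admissible window of each channel and refreshed only when an update trigger
fires (consecutive low-SQI beats, consecutive missed beats, or a span where
the harmonic-summation SQI of every channel collapses); the sliding HR/SQI
analysis itself runs on every window so triggers and coverage are always
informed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beats import BeatSequence, detect_beats
from .config import HsfConfig
from .filters import BandCandidate, build_band_candidates
from .fusion import FusedIbiSeries, align_beats, fuse
from .harsum import sliding_hr
from .io import BeatAnnotations, Recording
from .metrics import HrReport, IbiReport, hr_metrics, ibi_metrics
from .selection import BandDecision, select_band
from .templates import NoSegmentsError, build_template_group

__all__ = ["HsfIbi", "HsfIbiResults", "ChannelAnalysis", "run_hsf_ibi"]


@dataclass
class ChannelAnalysis:
    """Everything the pipeline derived for one channel."""

    label: str
    fl_values: list[float]
    #: (n_windows, n_bands) harmonic-summation SQI / HR tables
    sqi_table: np.ndarray
    hr_table: np.ndarray
    decisions: list[tuple[int, BandDecision]]
    sequence: BeatSequence


class HsfIbi:
    """Beat-to-beat interval extraction model for one recording.

    Parameters
    ----------
    recording:
        Time-synchronised multichannel recording.
    config:
        Pipeline hyperparameters; defaults are the published parameterisation.
    """

    def __init__(self, recording: Recording, config: HsfConfig | None = None):
        self.recording = recording
        self.config = config or HsfConfig()
        if recording.duration_s < self.config.window_s:
            raise ValueError("recording shorter than one analysis window")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sr_hz: float,
                       config: HsfConfig | None = None) -> "HsfIbi":
        return cls(Recording.from_dataframe(df, sr_hz), config)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "HsfIbiResults":
        cfg = self.config
        rec = self.recording
        sr = rec.sr_hz
        n = len(rec.channels[0].samples)
        n_win = int(round(cfg.window_s * sr))
        n_step = int(round(cfg.step_s * sr))
        n_windows = max(0, (n - n_win) // n_step + 1)
        window_starts = np.arange(n_windows) * cfg.step_s

        # stage 1-2: band candidates + sliding harmonic-summation tables
        per_channel: list[dict] = []
        for ch in rec.channels:
            cands = build_band_candidates(ch, cfg)
            sqi = np.zeros((n_windows, len(cands)))
            hr = np.full((n_windows, len(cands)), np.nan)
            for b, cand in enumerate(cands):
                results = sliding_hr(cand.filtered, cfg)
                sqi[:, b] = [r.sqi for r in results]
                hr[:, b] = [r.hr_bpm for r in results]
            per_channel.append({"channel": ch, "candidates": cands,
                                "sqi": sqi, "hr": hr})

        # windows where every channel's best band fails Q2 (forces updates)
        if n_windows:
            best = np.stack([d["sqi"].max(axis=1) if d["sqi"].size else
                             np.zeros(n_windows) for d in per_channel])
            all_fail = np.all(best <= cfg.q2, axis=0)
        else:
            all_fail = np.zeros(0, dtype=bool)
        forced_spans = [(int(w * n_step), int(w * n_step + n_win))
                        for w in np.flatnonzero(all_fail)]

        # stage 3-5: per-channel epochs of selection, templates, tracking
        analyses: list[ChannelAnalysis] = []
        for d in per_channel:
            analyses.append(self._track_channel(d, n, n_win, n_step,
                                                n_windows, forced_spans))

        sequences = [a.sequence for a in analyses if len(a.sequence)]
        if sequences:
            slots = align_beats(sequences, cfg.align_tol_s)
            covered = int(np.sum(~all_fail))
            fused = fuse(slots, cfg, coverage_windows=(covered, n_windows))
        else:
            fused = FusedIbiSeries([], coverage_windows=(0, n_windows))

        hr_track, hr_channel = self._fuse_hr_track(per_channel, n_windows)
        return HsfIbiResults(model=self, fused=fused, channels=analyses,
                             window_starts_s=window_starts,
                             hr_track_bpm=hr_track,
                             hr_track_channel=hr_channel)

    def _track_channel(self, d: dict, n: int, n_win: int, n_step: int,
                       n_windows: int,
                       forced_spans: list[tuple[int, int]]) -> ChannelAnalysis:
        cfg = self.config
        ch = d["channel"]
        cands: list[BandCandidate] = d["candidates"]
        fl_values = [c.fl_hz for c in cands]
        seq = BeatSequence(channel=ch.label)
        decisions: list[tuple[int, BandDecision]] = []
        w = 0
        resume_sample = 0
        while w < n_windows and cands:
            dec = select_band(dict(zip(fl_values, d["sqi"][w])), cfg, ch.label)
            if not dec.selected:
                w += 1
                continue
            b = fl_values.index(dec.fl_hz)
            hr = d["hr"][w, b]
            if not np.isfinite(hr):
                w += 1
                continue
            decisions.append((w, dec))
            win_start = w * n_step
            band_sig = cands[b].filtered
            try:
                group = build_template_group(
                    band_sig.samples[win_start:win_start + n_win], hr,
                    band_sig.sr_hz, cfg, channel=ch.label, fl_hz=dec.fl_hz,
                    created_at_s=win_start / band_sig.sr_hz)
            except NoSegmentsError:
                w += 1
                continue
            start = max(win_start, resume_sample)
            beats, gaps, trigger = detect_beats(
                band_sig, group, hr, dec.beta, cfg, start_sample=start,
                end_sample=n, forced_spans=forced_spans)
            for beat in beats:
                beat.fl_hz = dec.fl_hz
            seq.beats.extend(beats)
            seq.gaps.extend(gaps)
            if trigger is None:
                break
            resume_sample = max(trigger.sample, start + 1)
            # re-decide on the first window starting at/after the trigger: a
            # trailing window would be dominated by the very data that caused
            # the trigger, and detection would crawl through an artifact
            t_s = resume_sample / band_sig.sr_hz
            w_new = int(math.ceil(t_s / cfg.step_s))
            w = max(w + 1, w_new)
            if w >= n_windows:
                break
        return ChannelAnalysis(label=ch.label, fl_values=fl_values,
                               sqi_table=d["sqi"], hr_table=d["hr"],
                               decisions=decisions, sequence=seq)

    def _fuse_hr_track(self, per_channel: list[dict], n_windows: int
                       ) -> tuple[np.ndarray, list[str | None]]:
        """Per-window fused HR: best admitted channel's selected-band HR."""
        cfg = self.config
        track = np.full(n_windows, np.nan)
        source: list[str | None] = [None] * n_windows
        for w in range(n_windows):
            best_sqi = -np.inf
            for d in per_channel:
                if not d["candidates"]:
                    continue
                fl_values = [c.fl_hz for c in d["candidates"]]
                dec = select_band(dict(zip(fl_values, d["sqi"][w])), cfg,
                                  d["channel"].label)
                if dec.selected and dec.sqi > best_sqi:
                    b = fl_values.index(dec.fl_hz)
                    hr = d["hr"][w, b]
                    if np.isfinite(hr):
                        best_sqi = dec.sqi
                        track[w] = hr
                        source[w] = d["channel"].label
        return track, source


@dataclass
class HsfIbiResults:
    """Fit results: fused IBI series, per-channel detail, diagnostics."""

    model: HsfIbi
    fused: FusedIbiSeries
    channels: list[ChannelAnalysis]
    window_starts_s: np.ndarray
    hr_track_bpm: np.ndarray
    hr_track_channel: list[str | None] = field(default_factory=list)

    # -- accessors ---------------------------------------------------------

    @property
    def config(self) -> HsfConfig:
        return self.model.config

    def sequence(self, channel: str) -> BeatSequence:
        for a in self.channels:
            if a.label == channel:
                return a.sequence
        raise KeyError(channel)

    def to_frame(self) -> pd.DataFrame:
        return self.fused.to_frame()

    def decision_log(self) -> pd.DataFrame:
        rows = []
        for a in self.channels:
            for w, dec in a.decisions:
                rows.append({"window_start_s": float(self.window_starts_s[w]),
                             "channel": a.label, "rule": dec.rule,
                             "fl_hz": dec.fl_hz, "sqi": dec.sqi})
        return pd.DataFrame(rows, columns=["window_start_s", "channel",
                                           "rule", "fl_hz", "sqi"])

    # -- evaluation --------------------------------------------------------

    def evaluate_ibi(self, ref: BeatAnnotations, tol_ms: float = 30.0
                     ) -> IbiReport:
        return ibi_metrics(self.fused, ref, tol_ms=tol_ms)

    def evaluate_hr(self, ref: BeatAnnotations) -> HrReport:
        return hr_metrics(self.hr_track_bpm, self.window_starts_s, ref,
                          self.config)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        ibis = self.fused.ibis_ms
        valid = ibis[~np.isnan(ibis)]
        lines = [
            "HSF-IBI fit summary",
            "=" * 46,
            f"channels:           {', '.join(a.label for a in self.channels)}",
            f"duration:           {self.model.recording.duration_s:.1f} s at "
            f"{self.model.recording.sr_hz:g} Hz",
            f"fused beats:        {len(self.fused)}",
            f"window coverage:    {self.fused.coverage_pct:.1f} %",
        ]
        if len(valid):
            lines += [
                f"mean IBI:           {np.mean(valid):.1f} ms "
                f"(HR {60000.0 / np.mean(valid):.1f} bpm)",
                f"IBI range:          {np.min(valid):.0f}-{np.max(valid):.0f} ms",
            ]
        lines.append("per-channel band decisions (first epoch):")
        for a in self.channels:
            if a.decisions:
                w, dec = a.decisions[0]
                lines.append(f"  {a.label:16s} fL={dec.fl_hz:g} Hz  rule {dec.rule}"
                             f"  SQI {dec.sqi:.3f}  beats {len(a.sequence)}")
            else:
                lines.append(f"  {a.label:16s} discarded (no admissible window)")
        return "\n".join(lines)

    def plot_ibi(self, ax=None, ref: BeatAnnotations | None = None):
        """Fused IBI tachogram, optionally against reference intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.2))
        if ref is not None and len(ref) > 1:
            ax.plot(ref.beat_times_s[1:], ref.ibi_ms, lw=1, color="0.6",
                    label="reference")
        ax.plot(self.fused.times_s, self.fused.ibis_ms, ".", ms=4,
                label="fused estimate")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("IBI (ms)")
        ax.legend(loc="best", fontsize=8)
        return ax


def run_hsf_ibi(rec: Recording, cfg: HsfConfig | None = None
                ) -> tuple[FusedIbiSeries, HsfIbiResults]:
    """Functional wrapper: fit the pipeline and return the fused series."""
    results = HsfIbi(rec, cfg).fit()
    return results.fused, results
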