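"""Seeded generator of multichannel cardiac-vibration recordings.

The generator emulates the signal families the pipeline is built for —
bed-sensor ballistocardiograms (piezoelectric ceramic, EMFi film, load cell)
and radar Doppler cardiograms — well enough that every pipeline stage can be
exercised against known ground truth:

* a beat-time series with respiratory sinus arrhythmia (sinusoidal IBI
  modulation), white IBI jitter, and a short-term variability clip;
* per-archetype beat waveshapes composed of a low-frequency body-motion wave
  (Gaussian-windowed 2-6 Hz lobe) plus a high-frequency valve-like burst
  (Gaussian-windowed 15-25 Hz tone).  The burst is tightly locked to the true
  beat time while the body-motion component carries a small per-beat timing
  wobble, mirroring the physiological observation that valve vibrations are
  sharper and less variable than torso recoil;
* optional respiration-locked morphology alternation (two distinct waveshape
  variants for inhale/exhale) with a +/-20 % amplitude modulation;
* additive white noise at a per-channel SNR, powerline and baseline-wander
  sines, and channel-specific artifact epochs that multiply the noise.

All randomness flows through one seeded generator; identical scenarios are
bit-reproducible.  Waveshape constants are package choices (the real
morphologies are only known pictorially) and are exposed on
:class:`ArchetypeShape` for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BeatAnnotations, ChannelSignal, Recording

__all__ = ["Scenario", "ArchetypeShape", "ARCHETYPES", "generate_ibi_series",
           "render_channel", "generate_recording", "reference_segment"]


@dataclass(frozen=True)
class ArchetypeShape:
    """Waveshape constants for one sensor archetype.

    ``lf_*`` parameterise the Gaussian-windowed body-motion lobe,
    ``burst_*`` the valve-like high-frequency burst.  The ``alt_*`` fields
    define the second (exhale) morphology variant used when respiration-locked
    alternation is enabled.
    """

    lf_freq_hz: float
    lf_sigma_s: float
    lf_amp: float
    burst_freq_hz: float
    burst_sigma_s: float
    burst_amp: float
    # second morphology variant (respiration alternation)
    alt_lf_freq_hz: float
    alt_lf_sigma_s: float
    alt_lf_amp: float
    alt_burst_freq_hz: float


ARCHETYPES: dict[str, ArchetypeShape] = {
    "piezo": ArchetypeShape(
        lf_freq_hz=4.0, lf_sigma_s=0.10, lf_amp=1.0,
        burst_freq_hz=18.0, burst_sigma_s=0.035, burst_amp=0.9,
        alt_lf_freq_hz=1.8, alt_lf_sigma_s=0.16, alt_lf_amp=1.15,
        alt_burst_freq_hz=21.0),
    "emfi": ArchetypeShape(
        lf_freq_hz=4.5, lf_sigma_s=0.09, lf_amp=0.9,
        burst_freq_hz=22.0, burst_sigma_s=0.034, burst_amp=1.0,
        alt_lf_freq_hz=2.0, alt_lf_sigma_s=0.15, alt_lf_amp=1.1,
        alt_burst_freq_hz=17.0),
    "radar_lowfreq": ArchetypeShape(
        lf_freq_hz=2.0, lf_sigma_s=0.14, lf_amp=1.0,
        burst_freq_hz=16.0, burst_sigma_s=0.03, burst_amp=0.12,
        alt_lf_freq_hz=4.2, alt_lf_sigma_s=0.09, alt_lf_amp=0.9,
        alt_burst_freq_hz=16.0),
    "loadcell": ArchetypeShape(
        lf_freq_hz=3.0, lf_sigma_s=0.12, lf_amp=1.0,
        burst_freq_hz=15.0, burst_sigma_s=0.035, burst_amp=0.35,
        alt_lf_freq_hz=5.2, alt_lf_sigma_s=0.08, alt_lf_amp=0.95,
        alt_burst_freq_hz=19.0),
}

#: half-support of a rendered beat kernel (s)
_KERNEL_HALF_S = 0.35


@dataclass(frozen=True)
class Scenario:
    """Simulation conditions for one multichannel recording."""

    n_channels: int = 3
    archetypes: tuple[str, ...] = ("piezo", "radar_lowfreq", "emfi")
    mean_hr_bpm: float = 72.0
    rsa_amp_ms: float = 40.0
    rsa_freq_hz: float = 0.25
    jitter_sd_ms: float = 5.0
    resp_freq_hz: float = 0.25
    morphology_alternation: bool = False
    #: per-channel SNR (dB); a scalar applies to all channels
    snr_db: tuple[float, ...] | float = 15.0
    powerline_hz: float = 50.0
    powerline_amp: float = 0.2
    baseline_wander_hz: float = 0.3
    baseline_wander_amp: float = 1.0
    #: per-beat timing wobble of the body-motion component (ms)
    lowfreq_jitter_ms: float = 6.0
    #: scaling of the valve-burst amplitude (>1 emphasises heart-valve
    #: content, e.g. sensors placed close to the heart)
    burst_gain: float = 1.0
    #: per-channel artifact epochs [(start_s, end_s, noise_gain), ...]
    artifact_epochs: tuple[tuple[tuple[float, float, float], ...], ...] = ()
    duration_s: float = 120.0
    sr_hz: float = 250.0
    seed: int = 0
    #: short-term variability clip on consecutive-IBI ratios
    v_clip: float = 0.3

    def __post_init__(self) -> None:
        if len(self.archetypes) != self.n_channels:
            raise ValueError("need one archetype per channel")
        unknown = [a for a in self.archetypes if a not in ARCHETYPES]
        if unknown:
            raise ValueError(f"unknown archetypes: {unknown}")
        for epochs in self.artifact_epochs:
            for start, end, _gain in epochs:
                if not (0.0 <= start < end <= self.duration_s):
                    raise ValueError("artifact epoch outside recording span")

    def snr_for(self, channel: int) -> float:
        if isinstance(self.snr_db, (int, float)):
            return float(self.snr_db)
        return float(self.snr_db[channel])

    def epochs_for(self, channel: int) -> tuple[tuple[float, float, float], ...]:
        if channel < len(self.artifact_epochs):
            return self.artifact_epochs[channel]
        return ()

    def replace(self, **kw) -> "Scenario":
        return replace(self, **kw)


def generate_ibi_series(scn: Scenario,
                        rng: np.random.Generator | None = None
                        ) -> tuple[BeatAnnotations, np.ndarray]:
    """Ground-truth beat times and IBI series (ms).

    ``IBI_i = 60000/HR + rsa_amp * sin(2 pi rsa_freq t_i) + N(0, jitter)``,
    clipped so the consecutive-IBI ratio stays within ``(1 - v, 1 + v)``.
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    base_ms = 60000.0 / scn.mean_hr_bpm
    t = 1.0  # first beat (s); leaves room for the kernel support
    times = [t]
    prev_ibi = base_ms
    while True:
        ibi = base_ms + scn.rsa_amp_ms * np.sin(2 * np.pi * scn.rsa_freq_hz * t)
        if scn.jitter_sd_ms > 0:
            ibi += rng.normal(0.0, scn.jitter_sd_ms)
        ibi = float(np.clip(ibi, (1 - scn.v_clip) * prev_ibi,
                            (1 + scn.v_clip) * prev_ibi))
        t_next = t + ibi / 1000.0
        if t_next > scn.duration_s - 0.6:
            break
        times.append(t_next)
        t, prev_ibi = t_next, ibi
    beat_times = np.asarray(times)
    return (BeatAnnotations(beat_times, source="simulator"),
            np.diff(beat_times) * 1000.0)


def _beat_kernel(t: np.ndarray, shape: ArchetypeShape, variant: int,
                 lf_shift_s: float, burst_gain: float = 1.0) -> np.ndarray:
    """Evaluate one beat's waveshape on time offsets ``t`` (s, 0 = beat)."""
    if variant == 0:
        lf_f, lf_s, lf_a = shape.lf_freq_hz, shape.lf_sigma_s, shape.lf_amp
        b_f = shape.burst_freq_hz
    else:
        lf_f, lf_s, lf_a = (shape.alt_lf_freq_hz, shape.alt_lf_sigma_s,
                            shape.alt_lf_amp)
        b_f = shape.alt_burst_freq_hz
    ts = t - lf_shift_s
    lf = lf_a * np.exp(-0.5 * (ts / lf_s) ** 2) * np.cos(2 * np.pi * lf_f * ts)
    burst = (burst_gain * shape.burst_amp
             * np.exp(-0.5 * (t / shape.burst_sigma_s) ** 2)
             * np.cos(2 * np.pi * b_f * t))
    return lf + burst


def render_channel(beats: BeatAnnotations, archetype: str, scn: Scenario,
                   channel: int = 0,
                   rng: np.random.Generator | None = None,
                   label: str | None = None) -> ChannelSignal:
    """Render one channel: beat kernels + noise + interference + artifacts."""
    rng = rng if rng is not None else np.random.default_rng(scn.seed + 1 + channel)
    shape = ARCHETYPES[archetype]
    n = int(round(scn.duration_s * scn.sr_hz))
    sig = np.zeros(n)
    half = int(round(_KERNEL_HALF_S * scn.sr_hz))
    for t_beat in beats.beat_times_s:
        center = int(round(t_beat * scn.sr_hz))
        lo, hi = max(0, center - half), min(n, center + half + 1)
        if lo >= hi:
            continue
        t_rel = np.arange(lo, hi) / scn.sr_hz - t_beat
        resp_phase = np.sin(2 * np.pi * scn.resp_freq_hz * t_beat)
        if scn.morphology_alternation:
            variant = 0 if resp_phase >= 0 else 1
            amp = 1.0 + 0.2 * resp_phase
        else:
            variant, amp = 0, 1.0
        lf_shift = (rng.normal(0.0, scn.lowfreq_jitter_ms / 1000.0)
                    if scn.lowfreq_jitter_ms > 0 else 0.0)
        sig[lo:hi] += amp * _beat_kernel(t_rel, shape, variant, lf_shift,
                                         scn.burst_gain)

    t = np.arange(n) / scn.sr_hz
    # additive noise at the requested SNR w.r.t. the clean beat-train power
    snr_db = scn.snr_for(channel)
    p_sig = float(np.var(sig))
    noise_sd = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)) if p_sig > 0 else 1.0
    noise = rng.normal(0.0, noise_sd, n)
    for start, end, gain in scn.epochs_for(channel):
        i0, i1 = int(start * scn.sr_hz), int(end * scn.sr_hz)
        noise[i0:i1] *= gain
    sig = sig + noise
    if scn.powerline_amp:
        sig += scn.powerline_amp * np.sin(2 * np.pi * scn.powerline_hz * t)
    if scn.baseline_wander_amp:
        sig += scn.baseline_wander_amp * np.sin(
            2 * np.pi * scn.baseline_wander_hz * t)
    return ChannelSignal(sig, scn.sr_hz, label or f"{archetype}{channel}")


def generate_recording(scn: Scenario) -> tuple[Recording, BeatAnnotations, np.ndarray]:
    """All channels rendered from one shared beat series.

    Returns ``(recording, ground-truth beats, ground-truth IBI series in ms)``.
    """
    root = np.random.SeedSequence(scn.seed)
    streams = root.spawn(scn.n_channels + 1)
    beats, ibi_ms = generate_ibi_series(scn, np.random.default_rng(streams[0]))
    channels = [
        render_channel(beats, scn.archetypes[c], scn, channel=c,
                       rng=np.random.default_rng(streams[c + 1]))
        for c in range(scn.n_channels)
    ]
    return Recording(channels), beats, ibi_ms


def reference_segment(archetype: str, variant: int, scn: Scenario,
                      length: int) -> np.ndarray:
    """Canonical noise-free beat segment of ``length`` samples for one
    morphology variant, rendered inside a uniform beat train so neighbouring
    beats contribute their edge overlap exactly as in a real render."""
    shape = ARCHETYPES[archetype]
    period_s = 60.0 / scn.mean_hr_bpm
    n_beats = 9
    t_beats = 1.0 + period_s * np.arange(n_beats)
    n = int(round((t_beats[-1] + 1.0) * scn.sr_hz))
    sig = np.zeros(n)
    half = int(round(_KERNEL_HALF_S * scn.sr_hz))
    for tb in t_beats:
        center = int(round(tb * scn.sr_hz))
        lo, hi = max(0, center - half), min(n, center + half + 1)
        t_rel = np.arange(lo, hi) / scn.sr_hz - tb
        sig[lo:hi] += _beat_kernel(t_rel, shape, variant, 0.0, scn.burst_gain)
    center = int(round(t_beats[n_beats // 2] * scn.sr_hz))
    lo = center - length // 2
    return sig[lo:lo + length].copy()
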