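"""Framework configuration.

Every tunable hyperparameter of the IBI-extraction pipeline lives in a single
validated, immutable :class:`HsfConfig` object that is passed to all stages.
Defaults follow the published parameterisation of the framework: candidate
low cutoffs ``F = {1, 3, 5, 7}`` Hz under a fixed 40 Hz high cutoff, band
weighting coefficient ``K = 0.05``, harmonic-summation quality thresholds
``Q1 = 0.52`` / ``Q2 = 0.26``, correlation threshold ``theta = 0.75`` (used
both for sequential clustering and for per-beat quality), heart-rate-variability
search half-width ``v = 0.3``, an 8 s analysis window with 1 s step, a 1-10 Hz
harmonic-summation band, third-order Butterworth filters, at most seven
harmonics, and template refresh after five consecutive low-quality beats.

Shared conventions: all times are seconds from recording start, samples are
0-based, and analysis windows are half-open ``[t, t + window_s)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

__all__ = ["HsfConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for unknown configuration keys or invariant violations."""


@dataclass(frozen=True)
class HsfConfig:
    """Validated hyperparameter set for the whole pipeline.

    Notes
    -----
    The correlation threshold 0.75 plays two distinct roles (cluster admission
    during template extraction, and per-beat quality gating).  They share the
    same default but are stored as independent fields so either can be tuned
    without the other.
    """

    #: candidate low cutoffs of the band-selection filter bank (Hz)
    candidate_fl_hz: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    #: fixed high cutoff of the filter bank (Hz)
    fh_hz: float = 40.0
    #: band weighting coefficient K; beta = 1 + K * (fL - 1)
    k_weight: float = 0.05
    #: upper / lower harmonic-summation SQI thresholds
    q1: float = 0.52
    q2: float = 0.26
    #: sequential-clustering correlation admission threshold
    theta_bsas: float = 0.75
    #: per-beat SQI acceptance threshold
    theta_beat: float = 0.75
    #: short-term HRV search half-width as a fraction of the beat period
    v_hrv: float = 0.3
    #: analysis window length and step (s)
    window_s: float = 8.0
    step_s: float = 1.0
    #: harmonic-summation band-pass (Hz)
    harsum_band_hz: tuple[float, float] = (1.0, 10.0)
    #: candidate mean-heart-rate search range (bpm)
    hr_search_bpm: tuple[float, float] = (42.0, 180.0)
    #: harmonic cap for the summation kernel
    max_harmonics: int = 7
    #: kernel multiplier set (1 plus the primes up to max_harmonics)
    harmonic_multipliers: tuple[int, ...] = (1, 2, 3, 5, 7)
    #: consecutive low-SQI beats that trigger a template update
    consecutive_low_sqi_for_update: int = 5
    #: Butterworth filter order (applied bidirectionally)
    filter_order: int = 3
    #: edge margin excluded from peak detection after zero-phase filtering (s)
    edge_trim_s: float = 0.5
    #: candidate fundamental-frequency grid step (Hz); 0.005 Hz = 0.3 bpm
    f0_grid_step_hz: float = 0.005
    #: FFT zero-padding factor for the amplitude spectrum
    fft_pad_factor: int = 8
    #: consecutive missed beats tolerated before forcing a template update
    max_consecutive_misses: int = 3
    #: cross-channel beat alignment tolerance for fusion (s)
    align_tol_s: float = 0.15
    #: cluster ranking rule: "center" (mean centre-sample amplitude) or
    #: "l2" (mean member l2-norm).  With noisy in-band signals the centre
    #: rule is far more robust: every period-length window holds roughly the
    #: same energy, so l2-norm ranking degenerates, while the centre sample
    #: directly rewards clusters anchored on true beat peaks.
    cluster_rank: str = "center"

    def __post_init__(self) -> None:
        fl = self.candidate_fl_hz
        if len(fl) == 0:
            raise ConfigError("candidate_fl_hz must be non-empty")
        if any(b <= a for a, b in zip(fl, fl[1:])):
            raise ConfigError("candidate_fl_hz must be strictly increasing")
        if max(fl) >= self.fh_hz:
            raise ConfigError("all candidate_fl_hz must be below fh_hz")
        if not (0.0 < self.q2 < self.q1 < 1.0):
            raise ConfigError("thresholds must satisfy 0 < q2 < q1 < 1")
        for name in ("theta_bsas", "theta_beat", "v_hrv"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not (self.window_s >= self.step_s > 0.0):
            raise ConfigError("window_s >= step_s > 0 required")
        if self.max_harmonics > 7:
            raise ConfigError("max_harmonics must be <= 7")
        if any(m > self.max_harmonics for m in self.harmonic_multipliers):
            raise ConfigError("harmonic multipliers must not exceed max_harmonics")
        lo, hi = self.harsum_band_hz
        if not (0.0 < lo < hi):
            raise ConfigError("harsum_band_hz must be an increasing positive pair")
        lo, hi = self.hr_search_bpm
        if not (0.0 < lo < hi):
            raise ConfigError("hr_search_bpm must be an increasing positive pair")
        if self.cluster_rank not in ("l2", "center"):
            raise ConfigError("cluster_rank must be 'l2' or 'center'")
        for name in ("filter_order", "fft_pad_factor", "consecutive_low_sqi_for_update",
                     "max_consecutive_misses"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    # -- convenience -------------------------------------------------------

    @property
    def hr_search_hz(self) -> tuple[float, float]:
        lo, hi = self.hr_search_bpm
        return lo / 60.0, hi / 60.0

    def beta(self, fl_hz: float) -> float:
        """Band weight beta = 1 + K * (fL - 1)."""
        return 1.0 + self.k_weight * (fl_hz - 1.0)

    def replace(self, **overrides: Any) -> "HsfConfig":
        known = {f.name for f in dataclasses.fields(self)}
        for key in overrides:
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
        return dataclasses.replace(self, **_coerce(overrides))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def _coerce(values: Mapping[str, Any]) -> dict[str, Any]:
    """Lists from JSON/TOML become tuples so the config stays hashable."""
    out: dict[str, Any] = {}
    for k, v in values.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> HsfConfig:
    """Load a config file (JSON or TOML) and apply overrides.

    Unspecified fields take the package defaults.  ``path=None`` with no
    overrides returns the default configuration.
    """
    values: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        if p.suffix.lower() == ".toml":
            import tomllib

            values = tomllib.loads(text)
        else:
            values = json.loads(text) if text.strip() else {}
    if overrides:
        values.update(overrides)
    return HsfConfig().replace(**values)


def save_config(cfg: HsfConfig, path: str | Path) -> None:
    """Write the configuration as JSON (round-trips via :func:`load_config`)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
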