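"""Evaluation metrics for windowed heart rate and beat-to-beat intervals.

HR metrics compare per-window estimates against the reference rate
``60 / mean(reference IBI within the window)``; MAE (bpm), MRAE (%) and the
standard deviation of the absolute error are computed over analysed windows,
and coverage is the analysed fraction of all windows.

IBI metrics pair estimated beats to reference beats by nearest-neighbour
matching (within half the local reference interval) and compare interval
pairs whose endpoints map to *consecutive* reference beats — interval-level
comparison cancels any constant inter-sensor lag.  A pair is *correct* when
the absolute interval error is within 30 ms; precision is correct over all
paired estimates, while the detection rate divides by all reference
intervals, including those in spans the estimator discarded for low signal
quality.  Bland-Altman agreement (bias and 95 % limits) summarises the
paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HsfConfig
from .fusion import FusedIbiSeries
from .io import BeatAnnotations

__all__ = ["HrReport", "IbiReport", "hr_metrics", "ibi_metrics",
           "bland_altman", "match_beats", "pair_intervals"]


@dataclass
class HrReport:
    mae_bpm: float
    mrae_pct: float
    sdae_bpm: float
    cov_pct: float
    n_windows: int


@dataclass
class IbiReport:
    mae_ms: float
    mrae_pct: float
    sdae_ms: float
    prec_pct: float
    det_pct: float
    n_correct: int
    n_incorrect: int
    n_all_ref_beats: int
    bland_altman: tuple[float, float, float]  # bias, loa_low, loa_high (ms)


def hr_metrics(hr_est_bpm: np.ndarray, window_starts_s: np.ndarray,
               ref_beats: BeatAnnotations, cfg: HsfConfig) -> HrReport:
    """Windowed HR accuracy and coverage.

    ``hr_est_bpm`` holds one estimate per window (NaN = window not analysed).
    Analysed windows with fewer than two reference beats are excluded from
    the error statistics but still count toward the coverage denominator.
    """
    hr_est_bpm = np.asarray(hr_est_bpm, dtype=float)
    window_starts_s = np.asarray(window_starts_s, dtype=float)
    n_total = len(hr_est_bpm)
    analyzed = ~np.isnan(hr_est_bpm)
    errs, rels = [], []
    for hr, t0 in zip(hr_est_bpm[analyzed], window_starts_s[analyzed]):
        in_win = ref_beats.beat_times_s[
            (ref_beats.beat_times_s >= t0)
            & (ref_beats.beat_times_s < t0 + cfg.window_s)]
        if len(in_win) < 2:
            continue
        hr_ref = 60.0 / np.mean(np.diff(in_win))
        errs.append(abs(hr - hr_ref))
        rels.append(abs(hr - hr_ref) / hr_ref)
    cov = 100.0 * analyzed.sum() / n_total if n_total else float("nan")
    if not errs:
        return HrReport(float("nan"), float("nan"), float("nan"), cov, 0)
    ae = np.asarray(errs)
    mae = float(ae.mean())
    return HrReport(mae_bpm=mae,
                    mrae_pct=100.0 * float(np.mean(rels)),
                    sdae_bpm=float(np.sqrt(np.mean((ae - mae) ** 2))),
                    cov_pct=cov, n_windows=int(len(ae)))


def match_beats(est_times_s: np.ndarray, ref_times_s: np.ndarray) -> np.ndarray:
    """Match each estimated beat to its nearest reference beat.

    A match requires the gap to be within half the local reference interval
    (the smaller of the two adjacent intervals); when several estimates claim
    the same reference beat only the nearest is kept.  Returns an index array
    into the reference beats, -1 for unmatched estimates.
    """
    est = np.asarray(est_times_s, dtype=float)
    ref = np.asarray(ref_times_s, dtype=float)
    if len(ref) < 2:
        raise ValueError("need at least 2 reference beats")
    d_ref = np.diff(ref)
    # local half-interval tolerance per reference beat
    tol = np.empty(len(ref))
    tol[0] = d_ref[0] / 2
    tol[-1] = d_ref[-1] / 2
    if len(ref) > 2:
        tol[1:-1] = np.minimum(d_ref[:-1], d_ref[1:]) / 2
    nearest = np.clip(np.searchsorted(ref, est), 0, len(ref) - 1)
    left_ok = nearest > 0
    use_left = left_ok & (np.abs(est - ref[np.maximum(nearest - 1, 0)])
                          < np.abs(est - ref[nearest]))
    nearest[use_left] -= 1
    dist = np.abs(est - ref[nearest])
    match = np.where(dist <= tol[nearest], nearest, -1)
    # resolve duplicate claims: keep the nearest estimate
    for j in np.unique(match[match >= 0]):
        claim = np.flatnonzero(match == j)
        if len(claim) > 1:
            keep = claim[np.argmin(dist[claim])]
            match[claim] = -1
            match[keep] = j
    return match


def pair_intervals(est_times_s: np.ndarray, est_ibis_ms: np.ndarray,
                   ref_times_s: np.ndarray) -> np.ndarray:
    """Interval pairs (RR, JJ) in ms for estimated IBIs whose endpoints match
    consecutive reference beats.  Returns an (n, 2) array."""
    match = match_beats(est_times_s, np.asarray(ref_times_s, dtype=float))
    ref = np.asarray(ref_times_s, dtype=float)
    pairs = []
    for i in range(1, len(est_times_s)):
        jj = est_ibis_ms[i]
        if np.isnan(jj):
            continue
        a, b = match[i - 1], match[i]
        if a >= 0 and b == a + 1:
            rr = (ref[b] - ref[a]) * 1000.0
            pairs.append((rr, float(jj)))
    return np.asarray(pairs).reshape(-1, 2)


def bland_altman(paired_ms: np.ndarray) -> tuple[float, float, float]:
    """Bias and 95 % limits of agreement of JJ - RR differences."""
    paired_ms = np.asarray(paired_ms, dtype=float).reshape(-1, 2)
    if len(paired_ms) < 2:
        raise ValueError("need at least 2 pairs")
    diff = paired_ms[:, 1] - paired_ms[:, 0]
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def ibi_metrics(est: FusedIbiSeries | tuple[np.ndarray, np.ndarray],
                ref_beats: BeatAnnotations, tol_ms: float = 30.0) -> IbiReport:
    """Beat-to-beat interval accuracy against reference annotations.

    ``est`` is either a fused series or a raw ``(beat_times_s, ibis_ms)``
    pair.  The 30 ms correctness rule is applied inclusively.
    """
    if isinstance(est, FusedIbiSeries):
        times, ibis = est.times_s, est.ibis_ms
    else:
        times, ibis = est
        times = np.asarray(times, dtype=float)
        ibis = np.asarray(ibis, dtype=float)
    if len(ref_beats) < 2:
        raise ValueError("need at least 2 reference beats")
    n_ref_intervals = len(ref_beats) - 1
    if len(times) == 0:
        return IbiReport(float("nan"), float("nan"), float("nan"),
                         float("nan"), 0.0, 0, 0, n_ref_intervals,
                         (float("nan"),) * 3)
    pairs = pair_intervals(times, ibis, ref_beats.beat_times_s)
    if len(pairs) == 0:
        return IbiReport(float("nan"), float("nan"), float("nan"),
                         float("nan"), 0.0, 0, 0, n_ref_intervals,
                         (float("nan"),) * 3)
    err = pairs[:, 1] - pairs[:, 0]
    ae = np.abs(err)
    correct = int(np.sum(ae <= tol_ms))
    incorrect = int(len(ae) - correct)
    mae = float(ae.mean())
    ba = (bland_altman(pairs) if len(pairs) >= 2
          else (float(np.mean(err)),) * 3)
    return IbiReport(
        mae_ms=mae,
        mrae_pct=100.0 * float(np.mean(ae / pairs[:, 0])),
        sdae_ms=float(np.sqrt(np.mean((ae - mae) ** 2))),
        prec_pct=100.0 * correct / (correct + incorrect),
        det_pct=100.0 * correct / n_ref_intervals,
        n_correct=correct, n_incorrect=incorrect,
        n_all_ref_beats=n_ref_intervals,
        bland_altman=ba)
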