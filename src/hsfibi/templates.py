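"""Template-group extraction by sequential clustering of beat segments.

From the first analysis window of an admitted channel, one heartbeat-length
segment is cut around every local maximum and the segments are clustered with
the basic sequential algorithmic scheme (BSAS): each segment joins the
existing cluster whose *minimum* pairwise Pearson correlation with it is
highest, or opens a new cluster when that value falls below the threshold
``theta``.  The primary template ``T1`` is the most central member (highest
within-cluster correlation sum) of the highest-scoring cluster.  When the
chosen cluster shows a gap of more than 1.5 beat periods between consecutive
member positions — the signature of respiration-alternating morphology, where
the cluster only holds every other beat — a second template ``T2`` is taken
from the best competing cluster that occupies those gaps.  Cluster members
are never averaged, so template morphology stays sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import HsfConfig

__all__ = [
    "Segment", "Cluster", "TemplateGroup", "template_length",
    "extract_segments", "correlation_matrix", "bsas_cluster",
    "select_primary", "second_template", "build_template_group",
    "local_maxima",
]


class NoSegmentsError(ValueError):
    """No usable local maxima in the extraction window."""


@dataclass
class Segment:
    """One candidate heartbeat: ``L`` samples centred on a local maximum."""

    values: np.ndarray
    p_index: int  # centre sample position in the source signal (0-based)


@dataclass
class Cluster:
    """Members in insertion (temporal) order; indices refer to the segment list."""

    id: int
    member_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass
class TemplateGroup:
    """One or two heartbeat templates for a channel."""

    templates: list[np.ndarray]
    L: int
    channel: str = ""
    fl_hz: float | None = None
    created_at_s: float = 0.0

    def __len__(self) -> int:
        return len(self.templates)


def template_length(hr_mean_bpm: float, sr_hz: float) -> int:
    """Template length in samples: one mean beat period.

    ``L = round(60 / HR * SR)`` with round-half-to-even.
    """
    if hr_mean_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return int(round(60.0 / hr_mean_bpm * sr_hz))


def local_maxima(samples: np.ndarray) -> np.ndarray:
    """Strict local maxima; a plateau counts once, at its first sample."""
    peaks, props = find_peaks(samples, plateau_size=(1, None))
    return props["left_edges"]


def extract_segments(samples: np.ndarray, L: int) -> list[Segment]:
    """One segment per local maximum whose centred ``L``-window fits inside
    the signal; segments span ``[p - L//2, p + (L+1)//2)`` so the length is
    exactly ``L`` for odd or even ``L``.  Boundary maxima are skipped.
    """
    half_lo, half_hi = L // 2, L - L // 2
    peaks = local_maxima(samples)
    segments = [Segment(samples[p - half_lo:p + half_hi].copy(), int(p))
                for p in peaks
                if p - half_lo >= 0 and p + half_hi <= len(samples)]
    if not segments:
        raise NoSegmentsError("no interior local maxima in extraction window")
    return segments


def correlation_matrix(segments: list[Segment]) -> np.ndarray:
    """Pairwise Pearson correlations; zero-variance rows read 0 off-diagonal."""
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    data = np.vstack([s.values for s in segments])
    sd = data.std(axis=1)
    degenerate = sd == 0
    safe = data.copy()
    safe[degenerate] = np.random.default_rng(0).normal(size=(degenerate.sum(),
                                                             data.shape[1]))
    corr = np.corrcoef(safe)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def bsas_cluster(segments: list[Segment], corr: np.ndarray,
                 theta_bsas: float) -> list[Cluster]:
    """One-pass sequential clustering in temporal order.

    The affinity of a segment to a cluster is the *minimum* correlation with
    all current members, so every cluster stays internally coherent at level
    ``theta`` by construction.
    """
    clusters: list[Cluster] = []
    for i in range(len(segments)):
        best, best_aff = None, -np.inf
        for c in clusters:
            aff = min(corr[i, j] for j in c.member_indices)
            if aff > best_aff:  # ties keep the earliest cluster
                best, best_aff = c, aff
        if best is None or best_aff < theta_bsas:
            clusters.append(Cluster(id=len(clusters), member_indices=[i]))
        else:
            best.member_indices.append(i)
    return clusters


def _cluster_score(cluster: Cluster, segments: list[Segment],
                   mode: str) -> float:
    if mode == "center":
        vals = [s.values[len(s.values) // 2] for s in
                (segments[i] for i in cluster.member_indices)]
    else:  # mean member l2-norm
        vals = [np.linalg.norm(segments[i].values)
                for i in cluster.member_indices]
    return float(np.mean(vals))


def _representative(cluster: Cluster, corr: np.ndarray) -> int:
    """Member maximising the correlation sum to the rest of its cluster."""
    idx = cluster.member_indices
    if len(idx) == 1:
        return idx[0]
    sums = [sum(corr[j, k] for k in idx if k != j) for j in idx]
    return idx[int(np.argmax(sums))]  # ties: earliest member


def select_primary(clusters: list[Cluster], segments: list[Segment],
                   corr: np.ndarray, mode: str = "l2"
                   ) -> tuple[Cluster, int]:
    """Highest-scoring cluster and its representative segment index (T1)."""
    if not clusters:
        raise ValueError("need at least one cluster")
    scores = [_cluster_score(c, segments, mode) for c in clusters]
    c_s = clusters[int(np.argmax(scores))]  # ties: earliest cluster
    return c_s, _representative(c_s, corr)


def second_template(clusters: list[Cluster], c_s: Cluster,
                    segments: list[Segment], corr: np.ndarray, L: int,
                    mode: str = "l2") -> int | None:
    """Representative of the best competing cluster occupying the gaps of
    ``c_s``, or None when no gap exceeds 1.5 beat periods (or no competitor
    owns a segment inside one)."""
    centers = [segments[i].p_index for i in c_s.member_indices]
    gap_spans = [(a, b) for a, b in zip(centers, centers[1:]) if b - a > 1.5 * L]
    if not gap_spans:
        return None
    gamma = {i for i, s in enumerate(segments)
             if any(a < s.p_index < b for a, b in gap_spans)}
    if not gamma:
        return None
    candidates = [c for c in clusters
                  if c.id != c_s.id and any(i in gamma for i in c.member_indices)]
    if not candidates:
        return None
    _, rep = select_primary(candidates, segments, corr, mode)
    return rep


def build_template_group(samples: np.ndarray, hr_mean_bpm: float,
                         sr_hz: float, cfg: HsfConfig, channel: str = "",
                         fl_hz: float | None = None,
                         created_at_s: float = 0.0) -> TemplateGroup:
    """Full extraction chain on one window slice of an admitted channel."""
    L = template_length(hr_mean_bpm, sr_hz)
    segments = extract_segments(np.asarray(samples, dtype=float), L)
    if len(segments) == 1:
        return TemplateGroup([segments[0].values], L, channel, fl_hz,
                             created_at_s)
    corr = correlation_matrix(segments)
    clusters = bsas_cluster(segments, corr, cfg.theta_bsas)
    c_s, t1 = select_primary(clusters, segments, corr, cfg.cluster_rank)
    templates = [segments[t1].values]
    t2 = second_template(clusters, c_s, segments, corr, L, cfg.cluster_rank)
    if t2 is not None:
        templates.append(segments[t2].values)
    return TemplateGroup(templates, L, channel, fl_hz, created_at_s)
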