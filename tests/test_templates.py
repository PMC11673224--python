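import numpy as np
import pytest

from hsfibi.config import HsfConfig
from hsfibi.filters import bandpass_bidirectional
from hsfibi.simulate import Scenario, generate_recording, reference_segment
from hsfibi.templates import (Cluster, NoSegmentsError, Segment, bsas_cluster,
                              build_template_group, correlation_matrix,
                              extract_segments, local_maxima, second_template,
                              select_primary, template_length)


# -- independent brute-force references (used here and by the acceptance
#    suite): straightforward transliterations of the clustering scheme -------

def bsas_oracle(corr, theta):
    clusters = []
    for i in range(corr.shape[0]):
        affs = [min(corr[i, j] for j in c) for c in clusters]
        k = int(np.argmax(affs)) if affs else -1
        if k >= 0 and affs[k] >= theta:
            clusters[k].append(i)
        else:
            clusters.append([i])
    return clusters


def primary_oracle(member_lists, segments, corr, mode="center"):
    def score(members):
        if mode == "center":
            return np.mean([segments[i].values[len(segments[i].values) // 2]
                            for i in members])
        return np.mean([np.linalg.norm(segments[i].values) for i in members])

    scores = [score(m) for m in member_lists]
    s = int(np.argmax(scores))
    members = member_lists[s]
    if len(members) == 1:
        return s, members[0]
    sums = [sum(corr[j, k] for k in members if k != j) for j in members]
    return s, members[int(np.argmax(sums))]


def second_oracle(member_lists, s, segments, corr, L, mode="center"):
    centers = [segments[i].p_index for i in member_lists[s]]
    gaps = [(a, b) for a, b in zip(centers, centers[1:]) if b - a > 1.5 * L]
    if not gaps:
        return None
    gamma = [i for i, seg in enumerate(segments)
             if any(a < seg.p_index < b for a, b in gaps)]
    cands = [j for j, m in enumerate(member_lists)
             if j != s and any(i in gamma for i in m)]
    if not cands:
        return None
    sub = [member_lists[j] for j in cands]
    _, rep = primary_oracle(sub, segments, corr, mode)
    return rep


def random_segments(rng, n, L=16):
    """Segments drawn from two base shapes + noise, at plausible spacings."""
    bases = rng.normal(size=(2, L))
    p = 100
    segments = []
    for _ in range(n):
        shape = bases[rng.integers(2)] + rng.normal(0, rng.uniform(0.05, 1.0), L)
        segments.append(Segment(shape, p))
        p += int(rng.integers(L, 3 * L))
    return segments


class TestTemplateLength:
    @pytest.mark.parametrize("hr,sr,expected", [
        (60.0, 1000.0, 1000),
        (75.0, 250.0, 200),
        (72.0, 250.0, 208),  # 208.33 rounds down
    ])
    def test_values(self, hr, sr, expected):
        assert template_length(hr, sr) == expected

    def test_positive_rate_required(self):
        with pytest.raises(ValueError):
            template_length(0.0, 250.0)


class TestSegmentExtraction:
    def test_periodic_train_segment_spacing(self):
        rng = np.random.default_rng(0)
        L = 200
        t = np.arange(2000)
        sig = np.cos(2 * np.pi * t / L) + rng.normal(0, 1e-4, 2000)
        segs = extract_segments(sig, L)
        spacings = np.diff([s.p_index for s in segs])
        assert np.all(np.abs(spacings - L) <= 3)
        assert all(len(s.values) == L for s in segs)

    def test_monotone_ramp_has_no_interior_maxima(self):
        with pytest.raises(NoSegmentsError):
            extract_segments(np.linspace(0, 1, 500), 50)

    def test_plateau_takes_first_sample(self):
        sig = np.zeros(300)
        sig[100:105] = 1.0
        assert list(local_maxima(sig)) == [100]

    def test_even_and_odd_lengths_exact(self):
        sig = np.zeros(500)
        sig[250] = 1.0
        for L in (100, 101):
            seg = extract_segments(sig, L)[0]
            assert len(seg.values) == L


class TestCorrelationMatrix:
    def test_identical_and_negated(self):
        v = np.random.default_rng(1).normal(size=50)
        m = correlation_matrix([Segment(v, 0), Segment(v.copy(), 10),
                                Segment(-v, 20)])
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(2)
        segs = [Segment(rng.normal(size=40), 50 * i) for i in range(5)]
        m = correlation_matrix(segs)
        for i in range(5):
            for j in range(5):
                a, b = segs[i].values, segs[j].values
                r = (np.mean((a - a.mean()) * (b - b.mean()))
                     / (a.std() * b.std()))
                assert m[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_row_is_zero(self):
        rng = np.random.default_rng(3)
        segs = [Segment(rng.normal(size=30), 0),
                Segment(np.full(30, 2.0), 40)]
        m = correlation_matrix(segs)
        assert m[0, 1] == 0.0 and m[1, 0] == 0.0 and m[1, 1] == 1.0


class TestBsas:
    def _segments(self, n):
        return [Segment(np.zeros(4), 10 * i) for i in range(n)]

    def test_all_correlated_one_cluster(self):
        corr = np.ones((5, 5))
        clusters = bsas_cluster(self._segments(5), corr, 0.75)
        assert len(clusters) == 1
        assert clusters[0].member_indices == list(range(5))

    def test_alternating_orthogonal_shapes_two_clusters(self):
        n = 6
        corr = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                corr[i, j] = 1.0 if (i - j) % 2 == 0 else 0.0
        clusters = bsas_cluster(self._segments(n), corr, 0.75)
        assert len(clusters) == 2
        assert clusters[0].member_indices == [0, 2, 4]
        assert clusters[1].member_indices == [1, 3, 5]

    def test_all_dissimilar_singletons(self):
        n = 4
        corr = np.eye(n) * 1.0 + 0.1
        np.fill_diagonal(corr, 1.0)
        clusters = bsas_cluster(self._segments(n), corr, 0.75)
        assert len(clusters) == n
        assert all(len(c) == 1 for c in clusters)

    def test_partition_and_admission_postcondition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            segs = random_segments(rng, int(rng.integers(3, 12)))
            corr = correlation_matrix(segs)
            theta = rng.uniform(0.3, 0.9)
            clusters = bsas_cluster(segs, corr, theta)
            all_members = sorted(i for c in clusters for i in c.member_indices)
            assert all_members == list(range(len(segs)))  # disjoint cover
            for c in clusters:
                for pos, i in enumerate(c.member_indices[1:], start=1):
                    prior = c.member_indices[:pos]
                    assert min(corr[i, j] for j in prior) >= theta


class TestTemplateSelection:
    def test_primary_cluster_and_representative(self):
        rng = np.random.default_rng(4)
        base = np.zeros(11)
        base[5] = 1.0
        # cluster 0: small centre values; cluster 1: large centre values
        segs = ([Segment(0.5 * base + rng.normal(0, 0.01, 11), 100 * i)
                 for i in range(2)]
                + [Segment(2.0 * base + rng.normal(0, 0.01, 11), 300 + 100 * i)
                   for i in range(3)])
        corr = correlation_matrix(segs)
        clusters = [Cluster(0, [0, 1]), Cluster(1, [2, 3, 4])]
        c_s, t1 = select_primary(clusters, segs, corr, "center")
        assert c_s.id == 1
        assert t1 in (2, 3, 4)
        sums = [sum(corr[j, k] for k in (2, 3, 4) if k != j) for j in (2, 3, 4)]
        assert t1 == [2, 3, 4][int(np.argmax(sums))]

    def test_singleton_cluster_is_its_own_template(self):
        segs = [Segment(np.array([0, 2.0, 0]), 10),
                Segment(np.array([0, 1.0, 0]), 40)]
        corr = correlation_matrix(segs)
        c_s, t1 = select_primary([Cluster(0, [0]), Cluster(1, [1])],
                                 segs, corr, "center")
        assert (c_s.id, t1) == (0, 0)

    def test_l2_mode_prefers_high_norm_cluster(self):
        segs = [Segment(np.full(8, 0.5), 0), Segment(np.full(8, 0.5), 30),
                Segment(np.full(8, 5.0), 60)]
        corr = correlation_matrix(segs)
        c_s, _ = select_primary([Cluster(0, [0, 1]), Cluster(1, [2])],
                                segs, corr, "l2")
        assert c_s.id == 1


class TestSecondTemplate:
    def _alternating_setup(self, L=10):
        """Two interleaved morphologies: cluster 0 holds every other beat."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, L))
        segs, clusters = [], [Cluster(0), Cluster(1)]
        for k in range(8):
            shape = a if k % 2 == 0 else b
            segs.append(Segment(shape + rng.normal(0, 0.01, L), 100 + k * L))
            clusters[k % 2].member_indices.append(k)
        return segs, clusters

    def test_gap_triggers_second_template(self):
        segs, clusters = self._alternating_setup()
        corr = correlation_matrix(segs)
        t2 = second_template(clusters, clusters[0], segs, corr, L=10)
        assert t2 is not None and t2 in clusters[1].member_indices

    def test_no_gap_no_second_template(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=10)
        segs = [Segment(base + rng.normal(0, 0.01, 10), 100 + 10 * k)
                for k in range(6)]
        corr = correlation_matrix(segs)
        cluster = Cluster(0, list(range(6)))
        assert second_template([cluster], cluster, segs, corr, L=10) is None

    def test_gap_without_competitor_yields_none(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=10)
        # one beat missing: gap of 2 L but nothing inside it
        positions = [100, 110, 120, 140, 150]
        segs = [Segment(base + rng.normal(0, 0.01, 10), p) for p in positions]
        corr = correlation_matrix(segs)
        cluster = Cluster(0, list(range(5)))
        assert second_template([cluster], cluster, segs, corr, L=10) is None


class TestOracleEquivalence:
    def test_full_chain_matches_brute_force(self):
        cfg = HsfConfig()
        rng = np.random.default_rng(11)
        for _ in range(100):
            segs = random_segments(rng, int(rng.integers(3, 13)))
            corr = correlation_matrix(segs)
            theta = rng.uniform(0.3, 0.9)
            clusters = bsas_cluster(segs, corr, theta)
            assert [c.member_indices for c in clusters] == bsas_oracle(corr, theta)
            c_s, t1 = select_primary(clusters, segs, corr, cfg.cluster_rank)
            s_ref, t1_ref = primary_oracle(
                [c.member_indices for c in clusters], segs, corr,
                cfg.cluster_rank)
            assert (c_s.id, t1) == (s_ref, t1_ref)
            L = 16
            t2 = second_template(clusters, c_s, segs, corr, L, cfg.cluster_rank)
            t2_ref = second_oracle([c.member_indices for c in clusters],
                                   s_ref, segs, corr, L, cfg.cluster_rank)
            assert t2 == t2_ref


class TestOnRenderedData:
    def test_single_morphology_one_template(self, cfg):
        scn = Scenario(seed=2, snr_db=30.0)
        rec, _, _ = generate_recording(scn)
        filt = bandpass_bidirectional(rec.channels[0], 1.0, cfg.fh_hz)
        tg = build_template_group(filt.samples[:2000], scn.mean_hr_bpm, 250.0,
                                  cfg)
        assert len(tg) == 1
        ref = reference_segment("piezo", 0, scn, tg.L)
        assert abs(np.corrcoef(tg.templates[0], ref)[0, 1]) > 0.95

    def test_alternating_morphology_two_templates(self, cfg):
        scn = Scenario(seed=2, snr_db=30.0, morphology_alternation=True)
        rec, _, _ = generate_recording(scn)
        filt = bandpass_bidirectional(rec.channels[0], 1.0, cfg.fh_hz)
        tg = build_template_group(filt.samples[:2000], scn.mean_hr_bpm, 250.0,
                                  cfg)
        assert len(tg) == 2
        from hsfibi.experiments import aligned_corr

        matched = set()
        for t in tg.templates:
            rs = [aligned_corr(t, reference_segment("piezo", v, scn, tg.L),
                               max_lag=15)
                  for v in (0, 1)]
            assert max(rs) > 0.9
            matched.add(int(np.argmax(rs)))
        assert matched == {0, 1}  # one template per injected morphology
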