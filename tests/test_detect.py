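import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emkmer.detect import (
    DetectionConfig,
    detect_motifs,
    detect_phase1,
    detect_phase2,
    neighbor_stats,
)
from emkmer.kmers import (
    MotifKey,
    children,
    detection_neighborhood,
    enumerate_motif_space,
    parents,
    shift_families,
)


def score_frame(entries):
    """entries: (MotifKey, llr, gamma_corr) or (MotifKey, llr, gamma_corr, direction)."""
    rows = []
    for e in entries:
        key, llr, corr = e[:3]
        direction = e[3] if len(e) > 3 else "native_higher"
        rows.append(
            (key.seq, key.offset, key.k, 50, 50, 50, llr, direction, True,
             np.nan, corr)
        )
    return pd.DataFrame(
        rows,
        columns=["seq", "offset", "k", "n_occ", "n_native", "n_wga", "llr",
                 "direction", "scorable", "p_gamma", "gamma_corr"],
    )


def transcribed_detector(scores, cfg):
    """Independent, deliberately naive transcription of the two-phase greedy
    procedure (recursive argmax formulation, no sorting/caching), used as the
    oracle for detect_motifs.  Shares only the combinatorial neighborhood
    relations, which are tested on their own.
    """
    pool = {}
    for _, r in scores.iterrows():
        if r.scorable and np.isfinite(r.gamma_corr):
            pool[MotifKey(r.seq, int(r.offset))] = (float(r.llr), float(r.gamma_corr))
    all_scores = dict(pool)

    # Phase 1
    accepted = []
    live = dict(pool)
    while live:
        m = min(live, key=lambda q: (-live[q][0], q.seq, q.offset))
        llr_m, corr_m = live[m]
        if not corr_m < cfg.t_gamma:
            break
        pmax = -np.inf
        for p in parents(m):
            if p in all_scores:
                pmax = max(pmax, all_scores[p][0])
        if llr_m > pmax:
            accepted.append(m)
            for q in detection_neighborhood(m, cfg.kmin, cfg.kmax):
                live.pop(q, None)
        live.pop(m, None)

    # Phase 2: per-anchor relation classes, robust location/scale
    best = {}
    for anchor in accepted:
        groups = [parents(anchor), children(anchor)]
        groups += list(shift_families(anchor).values())
        for grp in groups:
            members = [q for q in grp if q in all_scores and q not in accepted]
            if len(members) < 3:
                continue
            vals = np.array([all_scores[q][0] for q in members])
            if cfg.robust_neighbor_stats:
                mu = np.median(vals)
                sigma = 1.4826 * np.median(np.abs(vals - mu))
            else:
                mu, sigma = vals.mean(), vals.std(ddof=1)
            if sigma <= 0 and np.allclose(vals, mu):
                continue
            for q in members:
                dev = all_scores[q][0] - mu
                z = dev / sigma if sigma > 0 else (np.inf if dev > 0 else 0.0)
                if q not in best or z > best[q]:
                    best[q] = z
    rescued = []
    order = sorted(best, key=lambda q: (sps.norm.sf(best[q]), q.seq, q.offset))
    for q in order:
        if not (best[q] >= cfg.t_n if cfg.t_n_is_z else sps.norm.sf(best[q]) < cfg.t_n):
            break
        if all_scores[q][1] < cfg.t_gamma:
            rescued.append(q)
    return accepted, rescued


def random_score_table(rng, n_motifs=80):
    space = enumerate_motif_space(4, 6)
    idx = rng.choice(len(space), size=n_motifs, replace=False)
    keys = {space[i] for i in idx}
    # graft in some relatives so removal/rescue paths are exercised
    for key in list(keys)[:10]:
        keys |= set(list(parents(key))[:1])
        keys |= set(list(children(key))[:2])
    entries = []
    for key in keys:
        llr = float(rng.exponential(3.0))
        if rng.random() < 0.25:
            llr += float(rng.exponential(40.0))  # heavy-tail signal motifs
        corr = float(10 ** rng.uniform(-12, 2))
        direction = "wga_higher" if rng.random() < 0.3 else "native_higher"
        if direction == "wga_higher":
            corr = 1.0
        entries.append((key, llr, corr, direction))
    return score_frame(entries)


class TestPhase1:
    def test_gate_terminates_immediately(self):
        scores = score_frame([(MotifKey("GATC", 1), 100.0, 0.5)])
        assert detect_phase1(scores, DetectionConfig()) == []

    def test_parent_with_higher_llr_blocks_child(self):
        entries = [
            (MotifKey("GGATC", 2), 50.0, 1e-9),
            (MotifKey("GATC", 1), 80.0, 1e-12),
        ]
        accepted = detect_phase1(score_frame(entries), DetectionConfig())
        # GGATC examined first? no: GATC has higher llr, accepted, child removed
        assert accepted == [MotifKey("GATC", 1)]

    def test_child_outranking_parent_is_accepted_and_suppresses(self):
        entries = [
            (MotifKey("GGATC", 2), 90.0, 1e-12),
            (MotifKey("GATC", 1), 40.0, 1e-9),
            (MotifKey("ACCACC", 3), 30.0, 1e-8),
        ]
        accepted = detect_phase1(score_frame(entries), DetectionConfig())
        # GATC is GGATC's parent and is suppressed on acceptance
        assert accepted == [MotifKey("GGATC", 2), MotifKey("ACCACC", 3)]

    def test_tie_broken_lexicographically(self):
        entries = [
            (MotifKey("TTTT", 0), 50.0, 1e-9),
            (MotifKey("AAAA", 0), 50.0, 1e-9),
        ]
        accepted = detect_phase1(score_frame(entries), DetectionConfig())
        assert accepted[0] == MotifKey("AAAA", 0)

    def test_raising_t_gamma_never_removes_acceptances(self):
        rng = np.random.default_rng(0)
        scores = random_score_table(rng)
        strict = detect_phase1(scores, DetectionConfig(t_gamma=1e-8))
        loose = detect_phase1(scores, DetectionConfig(t_gamma=1e-3))
        assert set(strict) <= set(loose)

    def test_no_two_accepted_are_neighbors(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            accepted = detect_phase1(random_score_table(rng), DetectionConfig())
            for a in accepted:
                for b in accepted:
                    assert b not in parents(a) and b not in children(a)


class TestNeighborStats:
    def _children_scores(self, llrs, anchor=MotifKey("GATC", 1)):
        kids = sorted(children(anchor))
        entries = [(anchor, 500.0, 1e-20)]
        entries += [(k, llr, 1e-9) for k, llr in zip(kids, llrs)]
        return score_frame(entries)

    def test_robust_z_matches_hand_computation(self):
        scores = self._children_scores([1, 2, 3, 4, 5, 6, 7, 20])
        stats = neighbor_stats([MotifKey("GATC", 1)], scores, DetectionConfig())
        by_llr = {round(s.llr): s for s in stats}
        # median 4.5, MAD 2.0 -> scale 2.9652
        assert by_llr[20].z == pytest.approx((20 - 4.5) / (1.4826 * 2.0))
        assert by_llr[20].normal_prob == pytest.approx(
            sps.norm.sf((20 - 4.5) / (1.4826 * 2.0))
        )

    def test_mean_sd_mode_matches_hand_computation(self):
        scores = self._children_scores([1, 2, 3, 4, 5, 6, 7, 20])
        cfg = DetectionConfig(robust_neighbor_stats=False)
        stats = neighbor_stats([MotifKey("GATC", 1)], scores, cfg)
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 20.0])
        expected = (20 - vals.mean()) / vals.std(ddof=1)
        by_llr = {round(s.llr): s for s in stats}
        assert by_llr[20].z == pytest.approx(expected)

    def test_member_at_location_gets_half_tail(self):
        scores = self._children_scores([1, 2, 3, 4.5, 4.5, 6, 7, 20])
        stats = neighbor_stats([MotifKey("GATC", 1)], scores, DetectionConfig())
        at_center = [s for s in stats if s.llr == 4.5]
        for s in at_center:
            assert s.normal_prob == pytest.approx(0.5)

    def test_degenerate_identical_class_unscored(self):
        scores = self._children_scores([5.0] * 8)
        assert neighbor_stats([MotifKey("GATC", 1)], scores, DetectionConfig()) == []

    def test_zero_mad_with_real_outlier_gives_infinite_z(self):
        scores = self._children_scores([5, 5, 5, 5, 5, 5, 5, 900])
        stats = neighbor_stats([MotifKey("GATC", 1)], scores, DetectionConfig())
        top = max(stats, key=lambda s: s.z)
        assert np.isinf(top.z) and top.llr == 900


class TestPhase2:
    def test_no_outlier_returns_phase1_set(self):
        scores = self._scores_with_outlier(outlier_llr=6.0)
        cfg = DetectionConfig()
        p1 = detect_phase1(scores, cfg)
        stats = neighbor_stats(p1, scores, cfg)
        full, rescued = detect_phase2(stats, cfg, p1)
        assert full == p1 and rescued == []

    def _scores_with_outlier(self, outlier_llr, outlier_corr=1e-12):
        anchor = MotifKey("GATC", 1)
        kids = sorted(children(anchor))
        entries = [(anchor, 500.0, 1e-20)]
        entries += [(k, 5.0 + 0.1 * i, 0.5) for i, k in enumerate(kids[:-1])]
        entries += [(kids[-1], outlier_llr, outlier_corr)]
        return score_frame(entries)

    def test_outlier_with_both_gates_is_rescued(self):
        scores = self._scores_with_outlier(outlier_llr=300.0)
        cfg = DetectionConfig()
        p1 = detect_phase1(scores, cfg)
        stats = neighbor_stats(p1, scores, cfg)
        full, rescued = detect_phase2(stats, cfg, p1)
        assert len(rescued) == 1 and rescued[0].llr == 300.0

    def test_outlier_failing_gamma_gate_not_rescued(self):
        scores = self._scores_with_outlier(outlier_llr=300.0, outlier_corr=0.1)
        cfg = DetectionConfig()
        p1 = detect_phase1(scores, cfg)
        stats = neighbor_stats(p1, scores, cfg)
        _, rescued = detect_phase2(stats, cfg, p1)
        assert rescued == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("block", range(4))
    def test_matches_literal_transcription(self, block):
        rng = np.random.default_rng(100 + block)
        cfg = DetectionConfig(t_gamma=1e-6, t_n=10.0)
        for _ in range(50):
            scores = random_score_table(rng, n_motifs=int(rng.integers(20, 90)))
            result = detect_motifs(scores, cfg)
            want_p1, want_p2 = transcribed_detector(scores, cfg)
            assert result.phase(1) == want_p1
            assert result.phase(2) == want_p2

    def test_determinism(self):
        rng = np.random.default_rng(7)
        scores = random_score_table(rng)
        a = detect_motifs(scores, DetectionConfig())
        b = detect_motifs(scores.sample(frac=1, random_state=1), DetectionConfig())
        pd.testing.assert_frame_equal(a.table, b.table)


class TestEndToEnd:
    def test_planted_motif_recovered_from_simulation(self, small_sim):
        from emkmer.model import MotifModel

        res = MotifModel(small_sim.ref, small_sim.native, small_sim.wga).fit()
        motifs = res.detection.motifs
        assert MotifKey("GATC", 1) in motifs
        for m in motifs:  # anything else must be family of the plant
            assert m == MotifKey("GATC", 1) or m in detection_neighborhood(
                MotifKey("GATC", 1), 4, 7
            )
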