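import numpy as np
import pytest

from conftest import full_period, make_traj
from flock.leadership import (HierarchyGraph, best_lag, build_hierarchy,
                              directional_correlation, hcs_ratio,
                              hierarchy_quality, leadership_instability,
                              pairwise_delays)


def heading_series(angles):
    return np.column_stack([np.cos(angles), np.sin(angles)])


def wiggly_angles(rng, n, sd=0.4, rho=0.9):
    out = np.empty(n)
    w = 0.0
    for k in range(n):
        w = rho * w + sd * np.sqrt(1 - rho**2) * rng.standard_normal()
        out[k] = w
    return out


class TestDirectionalCorrelation:
    def test_copy_with_delay(self):
        rng = np.random.default_rng(0)
        ang = wiggly_angles(rng, 300)
        hi = heading_series(ang)
        hj = heading_series(np.concatenate([[ang[0]] * 2, ang[:-2]]))  # j lags 2 s
        lags, corr = directional_correlation(hi, hj, dt=1.0, max_lag=10.0)
        assert best_lag(lags, corr) == 2.0

    def test_identical_headings(self):
        hi = heading_series(np.full(100, 0.3))
        lags, corr = directional_correlation(hi, hi, dt=1.0)
        assert best_lag(lags, corr) == 0.0
        assert np.nanmax(corr) == pytest.approx(1.0)

    def test_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(1)
        hi = heading_series(rng.uniform(-np.pi, np.pi, 200))
        hj = heading_series(rng.uniform(-np.pi, np.pi, 200))
        lags, cij = directional_correlation(hi, hj, dt=1.0)
        _, cji = directional_correlation(hj, hi, dt=1.0)
        ok = np.isfinite(cij)
        assert (np.abs(cij[ok]) <= 1.0).all()
        assert np.allclose(cij[ok], cji[::-1][ok], atol=1e-12)

    def test_independent_headings_below_permutation_floor(self):
        rng = np.random.default_rng(2)
        hi = heading_series(rng.uniform(-np.pi, np.pi, 500))
        hj = heading_series(rng.uniform(-np.pi, np.pi, 500))
        _, corr = directional_correlation(hi, hj, dt=1.0)
        # permutation floor: max |C| over shuffled copies of hj
        floor = []
        for _ in range(20):
            perm = rng.permutation(500)
            _, c = directional_correlation(hi, hj[perm], dt=1.0)
            floor.append(np.nanmax(np.abs(c)))
        assert np.nanmax(corr) < np.quantile(floor, 0.99) + 0.05

    def test_min_overlap_masks_sparse_lags(self):
        hi = heading_series(np.zeros(12))
        lags, corr = directional_correlation(hi, hi, dt=1.0, max_lag=10.0,
                                             min_overlap=10)
        assert np.isnan(corr[0])   # lag -10: only 2 overlapping samples
        assert np.isfinite(corr[len(corr) // 2])


def chain_period(delays=(1.0, 2.0, 3.0), seed=0, duration=800):
    from flock.synthetic import SimConfig, simulate_march
    influencers = {m + 1: (0, d) for m, d in enumerate(delays)}
    cfg = SimConfig(n_members=len(delays) + 1, influencers=influencers,
                    heading_noise_sd=0.25, follower_noise_sd=0.03,
                    duration_s=duration, seed=seed,
                    waypoints=np.array([[0.0, 0.0], [3000.0, 0.0]]))
    res = simulate_march(cfg)
    return full_period(res.traj)


class TestHierarchy:
    def test_chain_recovery(self):
        period = chain_period()
        g = build_hierarchy(period)
        ids = g.member_ids
        scores = [g.scores[m] for m in ids]
        assert np.argmax(scores) == 0
        assert sorted(scores, reverse=True) == scores  # m00 > m01 > m02 > m03
        assert ("m00", "m01") in g.edges
        assert ("m00", "m03") in g.edges

    def test_pairwise_delay_values(self):
        period = chain_period()
        d = pairwise_delays(period)
        assert d[("m00", "m01")] == pytest.approx(1.0, abs=1.0)
        assert d[("m00", "m02")] == pytest.approx(2.0, abs=1.0)
        assert d[("m00", "m03")] == pytest.approx(3.0, abs=1.0)
        # antisymmetry
        for (a, b), tau in d.items():
            assert d[(b, a)] == -tau

    def test_tie_contributes_no_edge(self):
        t = np.arange(200.0)
        base = np.column_stack([1.3 * t, np.zeros_like(t)])
        pos = np.stack([base, base + [0.0, 3.0]])
        g = build_hierarchy(full_period(make_traj(pos)))
        assert g.edges == {}
        assert g.scores == {"m00": 0.0, "m01": 0.0}

    def test_independent_group_near_zero_scores(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 1.0, size=(4, 400, 2)), axis=1)
        g = build_hierarchy(full_period(make_traj(pos)))
        assert all(abs(s) <= 10.0 for s in g.scores.values())


class TestHcsRatio:
    def test_identical_headings_always_proximate(self):
        t = np.arange(300.0)
        base = np.column_stack([1.3 * t, np.zeros_like(t)])
        pos = np.stack([base, base + [0.0, 3.0]])
        ratio, flagged = hcs_ratio(full_period(make_traj(pos)), "m00", "m01")
        assert ratio == np.inf
        assert flagged

    def test_independent_random_walks_low_ratio(self):
        rng = np.random.default_rng(4)
        steps = rng.normal(0, 1.0, size=(2, 600, 2))
        pos = np.cumsum(steps, axis=1) * 0.5
        ratio, flagged = hcs_ratio(full_period(make_traj(pos)), "m00", "m01",
                                   proximity_m=1e9)
        if not flagged:
            assert ratio < 0.5

    def test_half_locked_half_independent(self):
        rng = np.random.default_rng(5)
        n = 600
        ang = wiggly_angles(rng, n, sd=0.3)
        noise = rng.uniform(-np.pi, np.pi, n)
        # first half: identical headings; second half: independent
        ang_j = np.where(np.arange(n) < n // 2, ang, noise)
        pos_i = np.cumsum(heading_series(ang), axis=0)
        pos_j = np.cumsum(heading_series(ang_j), axis=0) + [0.0, 3.0]
        period = full_period(make_traj(np.stack([pos_i, pos_j])))
        ratio, flagged = hcs_ratio(period, "m00", "m01", proximity_m=1e9)
        assert not flagged
        assert 0.3 <= ratio <= 3.0


class TestQualityAndInstability:
    def g(self, scores, edges):
        return HierarchyGraph(member_ids=list(scores), scores=scores,
                              edges=edges)

    def test_consistent_chain(self):
        g = self.g({"a": 2.0, "b": 0.0, "c": -2.0},
                   {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 2.0})
        q = hierarchy_quality(g)
        assert q["downward_ratio"] == 1.0
        assert q["loop_count"] == 0

    def test_three_cycle(self):
        g = self.g({"a": 0.0, "b": 0.0, "c": 0.0},
                   {("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "a"): 1.0})
        assert hierarchy_quality(g)["loop_count"] >= 1

    def test_empty_edges_flagged(self):
        q = hierarchy_quality(self.g({"a": 0.0, "b": 0.0}, {}))
        assert q["flagged"]
        assert np.isnan(q["downward_ratio"])

    def test_identical_graphs_zero_instability(self):
        g = self.g({"a": 1.0, "b": -1.0}, {("a", "b"): 1.0})
        assert leadership_instability([g, g]) == 0.0

    def test_all_flipped_is_one(self):
        ids = ["a", "b", "c", "d"]
        scores = {m: 0.0 for m in ids}
        import itertools
        e1 = {(x, y): 1.0 for x, y in itertools.combinations(ids, 2)}
        e2 = {(y, x): 1.0 for x, y in itertools.combinations(ids, 2)}
        g1 = self.g(scores, e1)
        g2 = self.g(scores, e2)
        assert leadership_instability([g1, g2]) == 1.0

    def test_one_flip_in_fifteen_pairs(self):
        import itertools
        ids = list("abcdef")  # 15 unordered pairs
        scores = {m: 0.0 for m in ids}
        e1 = {(x, y): 1.0 for x, y in itertools.combinations(ids, 2)}
        e2 = dict(e1)
        del e2[("a", "b")]
        e2[("b", "a")] = 1.0
        assert leadership_instability(
            [self.g(scores, e1), self.g(scores, e2)]) == pytest.approx(1 / 15)

    def test_single_period_absent(self):
        g = self.g({"a": 0.0}, {})
        assert leadership_instability([g]) is None


def test_score_order_invariant_to_constant_rotation():
    period = chain_period(seed=6)
    g1 = build_hierarchy(period)
    ang = 0.9
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    traj = period.traj
    rotated = make_traj(traj.pos @ R.T)
    g2 = build_hierarchy(full_period(rotated))
    order1 = sorted(g1.member_ids, key=g1.scores.get)
    order2 = sorted(g2.member_ids, key=g2.scores.get)
    assert order1 == order2
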