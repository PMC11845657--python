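import numpy as np
import pytest

from conftest import full_period, make_traj
from flock.grouping import (OUTLIER, cluster_consistency, cluster_frames,
                            membership_confidence, nearest_neighbor_features,
                            outlier_metrics)
from flock.pacs import PacsSeries
from sklearn.metrics import adjusted_rand_score


def static_period(points, n_t=5):
    pos = np.repeat(np.asarray(points, float)[:, None, :], n_t, axis=1)
    return full_period(make_traj(pos))


def two_knots(gap=100.0):
    a = np.array([(0, 0), (2, 0), (0, 2), (2, 2)], float)
    b = a + [gap, 0]
    return np.vstack([a, b])


def brute_force_dbscan(points, eps):
    """Connected components of the eps-graph (min cluster size 2)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    adj = (d <= eps) & ~np.eye(n, dtype=bool)
    labels = np.full(n, OUTLIER)
    nxt = 0
    for i in range(n):
        if labels[i] != OUTLIER or not adj[i].any():
            continue
        stack = [i]
        comp = []
        seen = {i}
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(comp) >= 2:
            labels[np.array(comp)] = nxt
            nxt += 1
    return labels


class TestClusterFrames:
    def test_two_separated_knots(self):
        frames = cluster_frames(static_period(two_knots()), "dbscan",
                                min_cluster_size=2, distance_threshold=10.0)
        for f in frames:
            assert (f.labels != OUTLIER).all()
            assert len(set(f.labels.tolist())) == 2

    def test_straggler_is_outlier(self):
        knot = np.array([(i % 3 * 2.0, i // 3 * 2.0) for i in range(7)])
        pts = np.vstack([knot, [[50.0, 0.0]]])
        frames = cluster_frames(static_period(pts), "dbscan", 2, 10.0)
        for f in frames:
            assert f.labels[-1] == OUTLIER
            assert (f.labels[:-1] != OUTLIER).all()

    def test_chain_density_reachability(self):
        pts = np.column_stack([4.0 * np.arange(8), np.zeros(8)])
        frames = cluster_frames(static_period(pts), "dbscan", 2, 5.0)
        assert len(set(frames[0].labels.tolist())) == 1
        assert (frames[0].labels != OUTLIER).all()

    def test_matches_brute_force_reachability(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(0, 30, size=(8, 2))
            frames = cluster_frames(static_period(pts, n_t=2), "dbscan", 2, 6.0)
            oracle = brute_force_dbscan(pts, 6.0)
            got = frames[0].labels
            assert np.array_equal(got == OUTLIER, oracle == OUTLIER)
            both = got != OUTLIER
            if both.sum() >= 2:  # same partition up to relabeling
                assert adjusted_rand_score(got[both], oracle[both]) == 1.0

    def test_methods_agree_on_separated_knots(self):
        period = static_period(two_knots())
        db = cluster_frames(period, "dbscan", 2, 10.0)
        hd = cluster_frames(period, "hdbscan", 2, 10.0)
        for a, b in zip(db, hd):
            assert adjusted_rand_score(a.labels, b.labels) == 1.0

    def test_too_few_members_warns(self):
        with pytest.warns(UserWarning):
            frames = cluster_frames(static_period([(0, 0), (1, 1)]), "dbscan",
                                    min_cluster_size=3, distance_threshold=5.0)
        assert (frames[0].labels == OUTLIER).all()

    def test_parameter_validation(self):
        p = static_period(two_knots())
        with pytest.raises(ValueError):
            cluster_frames(p, "dbscan", 1, 5.0)
        with pytest.raises(ValueError):
            cluster_frames(p, "dbscan", 2, 0.0)


class TestOutlierMetrics:
    def test_persistent_straggler(self):
        knot = np.array([(i * 2.0, 0.0) for i in range(7)])
        pts = np.vstack([knot, [[100.0, 50.0]]])
        period = static_period(pts, n_t=200)
        frames = cluster_frames(period, "dbscan", 2, 10.0)
        m = outlier_metrics(frames, period.traj.member_ids, dt=1.0)
        assert m["per_member_outlier_time"]["m07"] == 200.0
        assert m["n_outlier_members"] == 1

    def test_no_outliers(self):
        frames = cluster_frames(static_period(two_knots()), "dbscan", 2, 10.0)
        m = outlier_metrics(frames, [f"m{i:02d}" for i in range(8)], dt=1.0)
        assert m["n_outlier_members"] == 0
        assert m["total_outlier_time"] == 0.0

    def test_alternating_outliers_accounting(self):
        from flock.grouping import ClusterFrame
        frames = []
        for k in range(10):
            labels = np.array([0, 0, OUTLIER if k % 2 == 0 else 0,
                               0 if k % 2 == 0 else OUTLIER])
            frames.append(ClusterFrame(float(k), labels, None))
        m = outlier_metrics(frames, list("abcd"), dt=1.0)
        assert m["n_outlier_members"] == 2
        assert m["total_outlier_time"] == 10.0

    def test_relabel_invariance(self):
        pts = np.vstack([two_knots(), [[300.0, 0.0]]])
        period = static_period(pts)
        frames = cluster_frames(period, "dbscan", 2, 10.0)
        m1 = outlier_metrics(frames, period.traj.member_ids, 1.0)
        perm = list(reversed(period.traj.member_ids))
        m2 = outlier_metrics(frames, perm, 1.0)
        assert m1["total_outlier_time"] == m2["total_outlier_time"]
        assert m1["n_outlier_members"] == m2["n_outlier_members"]


class TestClusterConsistency:
    def test_static_formation(self):
        frames = cluster_frames(static_period(two_knots(), n_t=10), "dbscan", 2, 10.0)
        assert cluster_consistency(frames) == 1.0

    def test_single_cluster_throughout(self):
        pts = np.array([(0, 0), (2, 0), (4, 0)], float)
        frames = cluster_frames(static_period(pts, n_t=10), "dbscan", 2, 5.0)
        assert cluster_consistency(frames) == 1.0

    def test_flipping_partitions(self):
        from flock.grouping import ClusterFrame
        la = np.array([0, 0, 1, 1])
        lb = np.array([0, 1, 0, 1])
        frames = [ClusterFrame(float(k), la if k % 2 == 0 else lb, None)
                  for k in range(6)]
        expected = adjusted_rand_score(la, lb)
        assert cluster_consistency(frames) == pytest.approx(expected)


class TestConfidence:
    def test_hdbscan_confidence_available(self):
        period = static_period(two_knots(), n_t=3)
        frames = cluster_frames(period, "hdbscan", 2, 10.0)
        conf = membership_confidence(frames, period.traj.member_ids)
        assert set(conf) == set(period.traj.member_ids)
        assert all(0.0 <= v <= 1.0 for v in conf.values() if np.isfinite(v))

    def test_dbscan_has_no_confidence(self):
        period = static_period(two_knots(), n_t=3)
        frames = cluster_frames(period, "dbscan", 2, 10.0)
        with pytest.raises(ValueError):
            membership_confidence(frames, period.traj.member_ids)


class TestNearestNeighbor:
    def test_two_members(self):
        period = static_period([(0, 0), (7, 0)])
        out = nearest_neighbor_features(period)
        assert np.allclose(out["nn"], 7.0)

    def test_single_file_pacs_axes(self):
        n = 4
        x = np.zeros((n, 6))
        y = 3.0 * np.arange(n)[:, None] * np.ones((1, 6))
        pacs = PacsSeries(t=np.arange(6.0), member_ids=[f"m{i:02d}" for i in range(n)],
                          x=x, y=y, far_flags=np.zeros_like(x, dtype=bool))
        period = static_period([(0, 3.0 * i) for i in range(n)], n_t=6)
        out = nearest_neighbor_features(period, pacs)
        assert np.allclose(out["nn_y"], 3.0)
        assert np.allclose(out["nn_x"], 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(6, 2))
        period = static_period(pts, n_t=2)
        out = nearest_neighbor_features(period)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(out["nn"][:, 0], d.min(axis=1))

    def test_symmetry_and_bound(self):
        period = static_period([(0, 0), (9, 0)])
        out = nearest_neighbor_features(period)
        assert out["nn"][0, 0] == out["nn"][1, 0]
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 20, size=(7, 2))
        out = nearest_neighbor_features(static_period(pts, n_t=2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert (out["nn"][:, 0] <= d.max()).all()
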