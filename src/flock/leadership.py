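"""Leader-follower analysis from directional correlation time delays.

For a pair (i, j), C_ij(tau) is the mean dot product of i's unit heading at
time t with j's at time t + tau. If j copies i's heading with delay d, the
correlation peaks at tau = +d, so a positive best lag means i leads j. Mean
best lag over partners ranks members into a hierarchy graph whose edges
point leader -> follower.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .segmentation import MovementPeriod

MIN_HEADING_SPEED = 0.3   # m/s; slower samples have noise-dominated direction
DEFAULT_MAX_LAG = 10.0    # s
DEFAULT_MIN_OVERLAP = 10  # valid sample pairs needed per lag
HCS_THRESHOLD = 0.99
DEFAULT_HCS_WINDOW = 30.0
DEFAULT_PROXIMITY = 10.0


@dataclass
class HierarchyGraph:
    member_ids: list[str]
    scores: dict[str, float]                       # mean best lag, s
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    # key (leader, follower) -> |tau*| in seconds; at most one edge per pair

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for mid in self.member_ids:
            g.add_node(mid, score=self.scores.get(mid, 0.0))
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, delay_s=w)
        return g


def headings(period: MovementPeriod,
             min_speed: float = MIN_HEADING_SPEED) -> np.ndarray:
    """(n, T, 2) unit heading vectors from smoothed velocity; NaN when too slow."""
    traj = period.traj
    vel = np.gradient(traj.pos, traj.t_grid, axis=1)
    speed = np.linalg.norm(vel, axis=2)
    h = np.full_like(vel, np.nan)
    ok = speed >= min_speed
    h[ok] = vel[ok] / speed[ok, None]
    return h


def directional_correlation(hi: np.ndarray, hj: np.ndarray, dt: float,
                            max_lag: float = DEFAULT_MAX_LAG,
                            min_overlap: int = DEFAULT_MIN_OVERLAP,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """C_ij over the lag grid [-max_lag, +max_lag] in steps of dt.

    Returns (lags_seconds, correlations); lags with fewer than
    ``min_overlap`` jointly valid samples are NaN. Satisfies
    C_ij(tau) = C_ji(-tau) and |C| <= 1.
    """
    L = int(round(max_lag / dt))
    T = hi.shape[0]
    lags = np.arange(-L, L + 1)
    corr = np.full(lags.size, np.nan)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = hi[:T - lag], hj[lag:]
        else:
            a, b = hi[-lag:], hj[:T + lag]
        dots = np.sum(a * b, axis=1)
        ok = np.isfinite(dots)
        if ok.sum() >= min_overlap:
            corr[k] = float(dots[ok].mean())
    return lags * dt, corr


def best_lag(lags: np.ndarray, corr: np.ndarray) -> float | None:
    """Lag of maximum correlation; ties broken toward the smallest |lag|."""
    ok = np.isfinite(corr)
    if not ok.any():
        return None
    cmax = np.nanmax(corr)
    cand = lags[ok][corr[ok] >= cmax - 1e-12]
    return float(cand[np.argmin(np.abs(cand))])


def pairwise_delays(period: MovementPeriod, max_lag: float = DEFAULT_MAX_LAG,
                    min_speed: float = MIN_HEADING_SPEED,
                    min_overlap: int = DEFAULT_MIN_OVERLAP,
                    ) -> dict[tuple[str, str], float]:
    """tau*_ij for every ordered pair; antisymmetric by construction."""
    h = headings(period, min_speed)
    ids = period.traj.member_ids
    dt = period.traj.dt
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(ids)), 2):
        lags, corr = directional_correlation(h[i], h[j], dt, max_lag, min_overlap)
        tau = best_lag(lags, corr)
        if tau is None:
            continue
        out[(ids[i], ids[j])] = tau
        out[(ids[j], ids[i])] = -tau
    return out


def build_hierarchy(period: MovementPeriod, max_lag: float = DEFAULT_MAX_LAG,
                    min_speed: float = MIN_HEADING_SPEED) -> HierarchyGraph:
    """Hierarchy graph: node scores are mean best lags, edges leader -> follower.

    A pair with tau* = 0 is a tie: it contributes no edge (and zero to both
    scores). Edge weight is |tau*| seconds.
    """
    ids = list(period.traj.member_ids)
    delays = pairwise_delays(period, max_lag, min_speed)
    scores = {}
    for mid in ids:
        taus = [tau for (a, b), tau in delays.items() if a == mid]
        scores[mid] = float(np.mean(taus)) if taus else 0.0
    edges = {}
    for (a, b), tau in delays.items():
        if tau > 0:
            edges[(a, b)] = abs(tau)
    return HierarchyGraph(member_ids=ids, scores=scores, edges=edges)


def hcs_ratio(period: MovementPeriod, i: str, j: str,
              window_s: float = DEFAULT_HCS_WINDOW,
              proximity_m: float = DEFAULT_PROXIMITY,
              max_lag: float = DEFAULT_MAX_LAG,
              min_speed: float = MIN_HEADING_SPEED) -> tuple[float, bool]:
    """Highly-correlated-segment ratio for a pair.

    The period is cut into windows of ``window_s``. Windows where the pair's
    mean distance is within ``proximity_m`` are "proximate"; a proximate
    window whose maximum directional correlation exceeds 0.99 is an HCS. The
    ratio is HCS time over proximate non-HCS time; if there is no proximate
    non-HCS time the ratio is +inf and the flag is set.
    """
    traj = period.traj
    ids = traj.member_ids
    mi, mj = ids.index(i), ids.index(j)
    h = headings(period, min_speed)
    dt = traj.dt
    w = max(2, int(round(window_s / dt)))
    dist = np.linalg.norm(traj.pos[mi] - traj.pos[mj], axis=1)

    hcs = 0
    prox_non = 0
    for s in range(0, traj.t_grid.size - w + 1, w):
        sl = slice(s, s + w)
        if dist[sl].mean() > proximity_m:
            continue
        _, corr = directional_correlation(h[mi][sl], h[mj][sl], dt, max_lag,
                                          min_overlap=2)
        if np.isfinite(corr).any() and np.nanmax(corr) > HCS_THRESHOLD:
            hcs += 1
        else:
            prox_non += 1
    if prox_non == 0:
        return (float("inf"), True) if hcs else (0.0, True)
    return hcs / prox_non, False


def hierarchy_quality(graph: HierarchyGraph) -> dict:
    """Downward-influence ratio and loop count of a hierarchy graph.

    The loop count is the number of strongly connected components with more
    than one node (a bounded, deterministic proxy for cycle enumeration).
    An empty edge set yields a NaN ratio with a flag.
    """
    if not graph.edges:
        return {"downward_ratio": float("nan"), "loop_count": 0, "flagged": True}
    down = sum(1 for (a, b) in graph.edges
               if graph.scores[a] > graph.scores[b])
    g = graph.to_networkx()
    loops = sum(1 for comp in nx.strongly_connected_components(g) if len(comp) > 1)
    return {"downward_ratio": down / len(graph.edges), "loop_count": loops,
            "flagged": False}


def _edge_state(graph: HierarchyGraph, a: str, b: str) -> int:
    if (a, b) in graph.edges:
        return 1
    if (b, a) in graph.edges:
        return -1
    return 0


def leadership_instability(graphs: list[HierarchyGraph]) -> float | None:
    """Mean normalized edit distance between hierarchy graphs across periods.

    For each pair of periods, the distance is the fraction of unordered
    member pairs whose edge differs (present vs absent, or direction
    flipped). ``None`` with fewer than two periods.
    """
    if len(graphs) < 2:
        return None
    ids = graphs[0].member_ids
    pairs = list(itertools.combinations(ids, 2))
    dists = []
    for ga, gb in itertools.combinations(graphs, 2):
        diff = sum(1 for a, b in pairs
                   if _edge_state(ga, a, b) != _edge_state(gb, a, b))
        dists.append(diff / len(pairs))
    return float(np.mean(dists))
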