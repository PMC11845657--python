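"""Rest detection and movement-period extraction.

A member is "resting" while their positions stay inside a disc of a
configured area (default 100 m^2, i.e. diameter ~11.28 m) for at least a
minimum duration (default 120 s). Group rests are episodes where every
member is simultaneously inside one of their individual rests; the group
interval runs from the earliest member arrival to the latest departure.
The rest-free complement, trimmed at both ends, forms the movement periods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectory_io import GroupTrajectory

DEFAULT_AREA_M2 = 100.0
DEFAULT_MIN_DURATION_S = 120.0
DEFAULT_TRIM_S = 30.0
DEFAULT_MIN_PERIOD_S = 120.0


@dataclass(frozen=True)
class RestInterval:
    start: float
    end: float
    scope: str  # member id, or "group"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("rest interval must have positive length")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MovementPeriod:
    """A rest-free, trimmed slice of a group trajectory."""

    index: int
    start: float
    end: float
    traj: GroupTrajectory = field(repr=False)

    @property
    def duration(self) -> float:
        return self.end - self.start


def disc_diameter(area_m2: float) -> float:
    """Diameter of the disc with the given area."""
    return 2.0 * math.sqrt(area_m2 / math.pi)


def detect_individual_rests(t: np.ndarray, xy: np.ndarray,
                            area_m2: float = DEFAULT_AREA_M2,
                            min_duration_s: float = DEFAULT_MIN_DURATION_S,
                            ) -> list[RestInterval]:
    """Maximal intervals where one member stays within a disc of ``area_m2``.

    Containment is operationalized as the window's maximum pairwise distance
    not exceeding the disc diameter (sliding-window scan). Windows shorter
    than ``min_duration_s`` do not count; overlapping qualifying windows are
    merged into maximal intervals.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n = t.size
    diam = disc_diameter(area_m2)

    # two-pointer scan: for each start i, the largest j with diameter <= diam.
    # the window diameter is monotone in j, so j never moves backwards.
    intervals: list[tuple[float, float]] = []
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n:
            cand = xy[j + 1]
            d = np.hypot(xy[i:j + 2, 0] - cand[0], xy[i:j + 2, 1] - cand[1])
            if d.max() <= diam:
                j += 1
            else:
                break
        if t[j] - t[i] >= min_duration_s:
            intervals.append((t[i], t[j]))
        if j == n - 1:
            break
    return [RestInterval(s, e, "member") for s, e in _merge_overlaps(intervals)]


def _merge_overlaps(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def rests_for_group(traj: GroupTrajectory,
                    area_m2: float = DEFAULT_AREA_M2,
                    min_duration_s: float = DEFAULT_MIN_DURATION_S,
                    ) -> dict[str, list[RestInterval]]:
    """Individual rests for every member of a trajectory."""
    out = {}
    for m, mid in enumerate(traj.member_ids):
        rests = detect_individual_rests(traj.t_grid, traj.pos[m], area_m2,
                                        min_duration_s)
        out[mid] = [RestInterval(r.start, r.end, mid) for r in rests]
    return out


def merge_group_rests(individual_rests: dict[str, list[RestInterval]],
                      n_members: int | None = None) -> list[RestInterval]:
    """Group rests: episodes where all members rest simultaneously.

    For each maximal interval of time covered by some rest of *every*
    member, the group rest spans from the earliest start to the latest end
    of the member intervals involved. Resulting group intervals that touch
    are merged.
    """
    if n_members is None:
        n_members = len(individual_rests)
    if len(individual_rests) < n_members or n_members == 0:
        return []

    # sweep: common cores are intervals where member coverage count == n
    events: list[tuple[float, int]] = []
    for rests in individual_rests.values():
        for r in rests:
            events.append((r.start, +1))
            events.append((r.end, -1))
    if not events:
        return []
    events.sort()
    cores: list[tuple[float, float]] = []
    depth = 0
    core_start = None
    for time, delta in events:
        depth += delta
        if depth == n_members and core_start is None:
            core_start = time
        elif depth < n_members and core_start is not None:
            if time > core_start:
                cores.append((core_start, time))
            core_start = None

    group: list[tuple[float, float]] = []
    for cs, ce in cores:
        start = cs
        end = ce
        for rests in individual_rests.values():
            covering = [r for r in rests if r.start <= cs and r.end >= ce]
            if not covering:  # numeric edge: core boundary touches interval edge
                continue
            start = min(start, covering[0].start)
            end = max(end, covering[-1].end)
        group.append((start, end))
    return [RestInterval(s, e, "group") for s, e in _merge_overlaps(group)]


def extract_movement_periods(traj: GroupTrajectory,
                             group_rests: Sequence[RestInterval],
                             trim_s: float = DEFAULT_TRIM_S,
                             min_period_s: float = DEFAULT_MIN_PERIOD_S,
                             ) -> list[MovementPeriod]:
    """Complement of the group rests, trimmed by ``trim_s`` at each boundary.

    With no rests at all the span is split into two equal halves (so that
    cross-period consistency features still have two periods to compare),
    each half then trimmed. Periods shorter than ``min_period_s`` after
    trimming are dropped.
    """
    span_start = float(traj.t_grid[0])
    span_end = float(traj.t_grid[-1])

    if group_rests:
        rests = sorted(group_rests, key=lambda r: r.start)
        raw: list[tuple[float, float]] = []
        cursor = span_start
        for r in rests:
            if r.start > cursor:
                raw.append((cursor, min(r.start, span_end)))
            cursor = max(cursor, r.end)
        if cursor < span_end:
            raw.append((cursor, span_end))
    else:
        mid = 0.5 * (span_start + span_end)
        raw = [(span_start, mid), (mid, span_end)]

    periods = []
    for s, e in raw:
        s2, e2 = s + trim_s, e - trim_s
        if e2 - s2 >= max(min_period_s, 1e-9):
            periods.append(MovementPeriod(index=len(periods), start=s2, end=e2,
                                          traj=traj.slice_time(s2, e2)))
    return periods


def segment(traj: GroupTrajectory,
            area_m2: float = DEFAULT_AREA_M2,
            min_duration_s: float = DEFAULT_MIN_DURATION_S,
            trim_s: float = DEFAULT_TRIM_S,
            min_period_s: float = DEFAULT_MIN_PERIOD_S,
            ) -> tuple[list[RestInterval], list[MovementPeriod]]:
    """Full segmentation: individual rests -> group rests -> movement periods."""
    individual = rests_for_group(traj, area_m2, min_duration_s)
    group = merge_group_rests(individual, traj.n_members)
    periods = extract_movement_periods(traj, group, trim_s, min_period_s)
    return group, periods
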