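"""Doctrine-compliance metrics for foot marches.

Reference values: members keep a reasonable pace (below 1.7 m/s), stay 2-5 m
from their nearest neighbour during the day, take breaks on a regular
schedule, and keep the marching column compact.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pacs import PacsSeries
from .segmentation import RestInterval


@dataclass(frozen=True)
class DoctrineConfig:
    pace_limit: float = 1.7          # m/s, "fast pace" threshold
    spacing_low: float = 2.0         # m
    spacing_high: float = 5.0        # m
    expected_speed: float = 1.0      # m/s reference (~4 km/h)

    def __post_init__(self):
        if self.spacing_low >= self.spacing_high:
            raise ValueError("spacing interval must be increasing")
        if self.pace_limit <= 0:
            raise ValueError("pace_limit must be positive")


def reasonable_pace_ratio(speeds: np.ndarray,
                          cfg: DoctrineConfig | None = None) -> float:
    """Fraction of movement samples below the pace limit."""
    cfg = cfg or DoctrineConfig()
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size == 0:
        raise ValueError("empty speed series")
    return float((speeds < cfg.pace_limit).mean())


def spacing_compliance(nn_distances: np.ndarray,
                       cfg: DoctrineConfig | None = None) -> float:
    """Fraction of time the nearest neighbour is within [2, 5] m (closed)."""
    cfg = cfg or DoctrineConfig()
    nn = np.asarray(nn_distances, dtype=float)
    nn = nn[np.isfinite(nn)]
    if nn.size == 0:
        raise ValueError("empty nearest-neighbour series")
    return float(((nn >= cfg.spacing_low) & (nn <= cfg.spacing_high)).mean())


def break_regularity(group_rests: Sequence[RestInterval]) -> dict | None:
    """Population SDs of rest-onset gaps and rest durations; None if < 2 rests."""
    if len(group_rests) < 2:
        return None
    rests = sorted(group_rests, key=lambda r: r.start)
    onsets = np.array([r.start for r in rests])
    durations = np.array([r.duration for r in rests])
    return {"doc.break_onset_sd": float(np.diff(onsets).std()),
            "doc.break_dur_sd": float(durations.std())}


def column_length(pacs: PacsSeries) -> dict:
    """Largest along-path spread (max y - min y) per frame, with mean and max."""
    series = np.nanmax(pacs.y, axis=0) - np.nanmin(pacs.y, axis=0)
    finite = series[np.isfinite(series)]
    return {"series": series,
            "mean": float(finite.mean()) if finite.size else np.nan,
            "max": float(finite.max()) if finite.size else np.nan}
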