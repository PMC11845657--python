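"""Reading raw GPS tracks and turning them into a gridded group trajectory.

The pipeline is: read (GPX or CSV) -> project to UTM -> smooth each member's
track with a smoothing spline -> resample everybody onto one uniform time
grid covering the intersection of the members' time ranges.
"""
from __future__ import annotations

import datetime as _dt
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, UnivariateSpline, make_smoothing_spline

from .utm import UtmZone, geographic_to_utm, zone_for

DEFAULT_DT = 1.0
DEFAULT_MAX_GAP = 60.0


class TrackFormatError(ValueError):
    """Raised for malformed or inconsistent track files."""


@dataclass(frozen=True)
class GeoSample:
    """One raw GPS fix: member id, time (s), latitude and longitude (deg)."""

    member_id: str
    t: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise TrackFormatError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise TrackFormatError(f"longitude out of range: {self.lon}")


@dataclass
class MemberTrack:
    """Irregularly sampled planar track of one member (UTM metres)."""

    member_id: str
    t: np.ndarray
    xy: np.ndarray  # (n, 2) easting/northing

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("t must be 1-D and xy of shape (len(t), 2)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")


@dataclass
class GroupTrajectory:
    """Positions of every group member on a shared uniform time grid."""

    member_ids: list[str]
    t_grid: np.ndarray                # (T,), uniform step dt
    pos: np.ndarray                   # (n_members, T, 2) easting/northing, m
    utm_zone: UtmZone | None = None
    gap_mask: np.ndarray | None = None  # (n_members, T) True where interpolated over a long gap
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        steps = np.diff(self.t_grid)
        if steps.size == 0:
            raise ValueError("time grid needs at least two points")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("time grid is not uniform")
        self.dt = float(steps[0])
        if self.pos.shape != (len(self.member_ids), self.t_grid.size, 2):
            raise ValueError("pos shape does not match members x grid")
        if np.any(~np.isfinite(self.pos)):
            raise ValueError("positions contain non-finite values")
        if self.gap_mask is None:
            self.gap_mask = np.zeros((len(self.member_ids), self.t_grid.size), dtype=bool)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def centroid(self) -> np.ndarray:
        """(T, 2) per-timepoint mean position of all members."""
        return self.pos.mean(axis=0)

    def slice_time(self, start: float, end: float) -> "GroupTrajectory":
        sel = (self.t_grid >= start - 1e-9) & (self.t_grid <= end + 1e-9)
        if sel.sum() < 2:
            raise ValueError(f"empty trajectory slice [{start}, {end}]")
        return GroupTrajectory(
            member_ids=list(self.member_ids),
            t_grid=self.t_grid[sel],
            pos=self.pos[:, sel, :],
            utm_zone=self.utm_zone,
            gap_mask=self.gap_mask[:, sel],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with columns time,id,easting,northing,zone."""
        rows = []
        zone = str(self.utm_zone) if self.utm_zone else ""
        for m, mid in enumerate(self.member_ids):
            rows.append(pd.DataFrame({
                "time": self.t_grid,
                "id": mid,
                "easting": self.pos[m, :, 0],
                "northing": self.pos[m, :, 1],
                "zone": zone,
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroupTrajectory":
        ids = sorted(df["id"].astype(str).unique())
        grids = None
        pos = []
        for mid in ids:
            sub = df[df["id"].astype(str) == mid].sort_values("time")
            t = sub["time"].to_numpy(dtype=float)
            if grids is None:
                grids = t
            elif t.shape != grids.shape or not np.allclose(t, grids):
                raise TrackFormatError("members do not share a common time grid")
            pos.append(np.column_stack([sub["easting"].to_numpy(dtype=float),
                                        sub["northing"].to_numpy(dtype=float)]))
        zone = None
        if "zone" in df.columns:
            zvals = df["zone"].astype(str).str.strip()
            zvals = zvals[~zvals.str.lower().isin(["", "nan", "none"])]
            if len(zvals):
                z = zvals.iloc[0]
                zone = UtmZone(int(z[:-1]), z[-1].upper() == "N")
        return cls(member_ids=ids, t_grid=grids, pos=np.asarray(pos), utm_zone=zone)


# ---------------------------------------------------------------------------
# reading

def _parse_time(value: str, line_no: int) -> float:
    value = value.strip()
    try:
        return float(value)
    except ValueError:
        pass
    try:
        stamp = _dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError as exc:
        raise TrackFormatError(f"line {line_no}: cannot parse time {value!r}") from exc
    if stamp.tzinfo is None:
        stamp = stamp.replace(tzinfo=_dt.timezone.utc)
    return stamp.timestamp()


def read_tracks(path: str | Path, format: str | None = None) -> list[GeoSample]:
    """Read raw samples from a GPX or CSV file.

    Samples are grouped by member and time-sorted; duplicate timestamps within
    a member keep the first occurrence. CSV files must carry either
    ``time,id,lat,lon`` or ``time,id,easting,northing,zone`` headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if format == "gpx":
        samples = _read_gpx(path)
    elif format == "csv":
        samples = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _dedupe_sort(samples)


def _dedupe_sort(samples: Iterable[GeoSample]) -> list[GeoSample]:
    by_member: dict[str, dict[float, GeoSample]] = {}
    order: list[str] = []
    for s in samples:
        if s.member_id not in by_member:
            by_member[s.member_id] = {}
            order.append(s.member_id)
        by_member[s.member_id].setdefault(s.t, s)  # keep first duplicate
    out: list[GeoSample] = []
    for mid in order:
        out.extend(sorted(by_member[mid].values(), key=lambda s: s.t))
    return out


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx(path: Path) -> list[GeoSample]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise TrackFormatError(f"{path}: malformed GPX: {exc}") from exc
    samples = []
    for trk in root.iter(f"{_GPX_NS}trk"):
        name_el = trk.find(f"{_GPX_NS}name")
        member = name_el.text.strip() if name_el is not None and name_el.text else path.stem
        for pt in trk.iter(f"{_GPX_NS}trkpt"):
            time_el = pt.find(f"{_GPX_NS}time")
            if time_el is None or time_el.text is None:
                raise TrackFormatError(f"{path}: trkpt without time element")
            t = _parse_time(time_el.text, 0)
            samples.append(GeoSample(member, t, float(pt.get("lat")), float(pt.get("lon"))))
    return samples


def _read_csv(path: Path) -> list[GeoSample]:
    df = pd.read_csv(path, dtype=str)
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    geographic = {"time", "id", "lat", "lon"} <= cols
    planar = {"time", "id", "easting", "northing"} <= cols
    if geographic and planar:
        raise TrackFormatError(f"{path}: mixed coordinate conventions in one file")
    if not geographic and not planar:
        raise TrackFormatError(
            f"{path}: need columns time,id,lat,lon or time,id,easting,northing")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            t = _parse_time(str(row.time), i)
            if geographic:
                lat, lon = float(row.lat), float(row.lon)
            else:
                # planar input: invert to lat/lon so downstream is uniform
                from .utm import utm_to_geographic
                zone_str = str(getattr(row, "zone", "")).strip()
                if not zone_str or zone_str.lower() == "nan":
                    raise ValueError("planar rows require a zone column")
                zone = UtmZone(int(zone_str[:-1]), zone_str[-1].upper() == "N")
                lat, lon = utm_to_geographic(float(row.easting), float(row.northing), zone)
                lat, lon = float(lat), float(lon)
            samples.append(GeoSample(str(row.id), t, lat, lon))
        except (TypeError, ValueError, TrackFormatError) as exc:
            raise TrackFormatError(f"{path}: line {i}: {exc}") from exc
    return samples


# ---------------------------------------------------------------------------
# projection

def to_utm(samples: Sequence[GeoSample], zone: UtmZone | None = None
           ) -> tuple[list[MemberTrack], UtmZone]:
    """Project raw samples into one UTM zone chosen from their mean location.

    All members are forced into the single zone (group spans are km-scale).
    Samples spanning more than two natural zones raise, advising an explicit
    zone override.
    """
    if not samples:
        raise ValueError("no samples")
    lats = np.array([s.lat for s in samples])
    lons = np.array([s.lon for s in samples])
    if zone is None:
        natural = {zone_for(la, lo).number for la, lo in zip(lats, lons)}
        if len(natural) > 2:
            raise TrackFormatError(
                f"samples span {len(natural)} UTM zones {sorted(natural)}; "
                "pass an explicit zone override")
        zone = zone_for(float(lats.mean()), float(lons.mean()))
    tracks: dict[str, list[GeoSample]] = {}
    order: list[str] = []
    for s in samples:
        if s.member_id not in tracks:
            tracks[s.member_id] = []
            order.append(s.member_id)
        tracks[s.member_id].append(s)
    out = []
    for mid in order:
        ss = sorted(tracks[mid], key=lambda s: s.t)
        e, n = geographic_to_utm([s.lat for s in ss], [s.lon for s in ss], zone)
        out.append(MemberTrack(mid, np.array([s.t for s in ss]),
                               np.column_stack([e, n])))
    return out, zone


# ---------------------------------------------------------------------------
# smoothing and resampling

def smooth_track(track: MemberTrack, smoothing: float | None = None) -> MemberTrack:
    """Smoothing-spline fit of each coordinate against time.

    ``smoothing=None`` picks the penalty per coordinate by generalized
    cross-validation; ``smoothing=0`` interpolates (output equals input);
    a positive value is passed through as the residual-sum bound of a
    classic smoothing spline.
    """
    if track.t.size < 4:
        raise ValueError("need at least 4 points to smooth a track")
    xy = np.empty_like(track.xy)
    for d in range(2):
        y = track.xy[:, d]
        if smoothing is None:
            spl = make_smoothing_spline(track.t, y)
            xy[:, d] = spl(track.t)
        elif smoothing == 0:
            xy[:, d] = y
        else:
            spl = UnivariateSpline(track.t, y, k=3, s=float(smoothing))
            xy[:, d] = spl(track.t)
    return MemberTrack(track.member_id, track.t.copy(), xy)


def resample_group(tracks: Sequence[MemberTrack], dt: float = DEFAULT_DT,
                   max_gap: float = DEFAULT_MAX_GAP,
                   utm_zone: UtmZone | None = None) -> GroupTrajectory:
    """Evaluate every member on a common uniform grid via cubic splines.

    The grid spans the intersection of the member time ranges. Grid points
    that fall inside an input gap longer than ``max_gap`` seconds are still
    filled by the spline but flagged in ``gap_mask`` so downstream features
    can ignore them.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not tracks:
        raise ValueError("no tracks")
    t0 = max(tr.t[0] for tr in tracks)
    t1 = min(tr.t[-1] for tr in tracks)
    if t1 <= t0:
        raise ValueError("member time ranges do not overlap")
    n_steps = int(math.floor((t1 - t0) / dt + 1e-9))
    grid = t0 + dt * np.arange(n_steps + 1)

    pos = np.empty((len(tracks), grid.size, 2))
    gap_mask = np.zeros((len(tracks), grid.size), dtype=bool)
    for m, tr in enumerate(tracks):
        if tr.t.size >= 4:
            for d in range(2):
                pos[m, :, d] = CubicSpline(tr.t, tr.xy[:, d])(grid)
        else:
            for d in range(2):
                pos[m, :, d] = np.interp(grid, tr.t, tr.xy[:, d])
        gaps = np.diff(tr.t)
        for k in np.nonzero(gaps > max_gap)[0]:
            inside = (grid > tr.t[k]) & (grid < tr.t[k + 1])
            gap_mask[m, inside] = True
    return GroupTrajectory(member_ids=[tr.member_id for tr in tracks],
                           t_grid=grid, pos=pos, utm_zone=utm_zone,
                           gap_mask=gap_mask)


def ingest(path: str | Path, format: str | None = None, dt: float = DEFAULT_DT,
           smoothing: float | None = None, max_gap: float = DEFAULT_MAX_GAP
           ) -> GroupTrajectory:
    """Full raw-file -> GroupTrajectory pipeline (read, project, smooth, resample)."""
    samples = read_tracks(path, format=format)
    tracks, zone = to_utm(samples)
    smoothed = [smooth_track(tr, smoothing) if tr.t.size >= 4 else tr for tr in tracks]
    return resample_group(smoothed, dt=dt, max_gap=max_gap, utm_zone=zone)
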