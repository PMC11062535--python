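"""Discretization of 10 Hz GPS traces into symbolic movement sequences.

Each 0.1 s sample is reduced to a (velocity, acceleration, turning-angle)
descriptor triple, encoded as one character of the 48-symbol movement-unit
alphabet, and the per-match character stream is split on sustained
low-velocity (inactive) periods into the discrete movement sequences over
which patterns are mined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import (
    DEFAULT_ALPHABET,
    MovementAlphabet,
    encode_bands,
    indices_to_symbols,
)

SAMPLE_INTERVAL_S = 0.1
EARTH_RADIUS_M = 6371008.8

#: Inactive-period rule: velocity below V_MIN sustained for at least T_MIN seconds.
DEFAULT_V_MIN = 0.2
DEFAULT_T_MIN = 2.0
#: Displacements shorter than this (metres) do not define a heading.
DEFAULT_MOTION_EPSILON = 0.01


@dataclass(frozen=True)
class GpsFix:
    """One 10 Hz GPS sample.

    ``turning_angle`` (degrees, absolute heading change in [0, 180]) may be
    supplied by the device; otherwise latitude/longitude must be present so
    the angle can be derived from consecutive bearings.
    """

    time_s: float
    velocity: float
    acceleration: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    turning_angle: float | None = None

    def __post_init__(self) -> None:
        if self.velocity < 0:
            raise ValueError(f"velocity must be >= 0, got {self.velocity}")
        if self.turning_angle is not None and not (0 <= self.turning_angle <= 180):
            raise ValueError(f"turning angle must lie in [0, 180], got {self.turning_angle}")
        has_coords = self.latitude is not None and self.longitude is not None
        if not has_coords and self.turning_angle is None:
            raise ValueError("a fix needs either coordinates or a turning angle")


@dataclass
class GpsTrace:
    """All fixes of one player in one match, on a strict 0.1 s grid."""

    player_id: str
    match_id: str
    position: str
    fixes: list[GpsFix]

    def __post_init__(self) -> None:
        if not self.fixes:
            raise ValueError("a trace needs at least one fix")
        t = np.array([f.time_s for f in self.fixes])
        if len(t) > 1 and not np.allclose(np.diff(t), SAMPLE_INTERVAL_S, atol=1e-6):
            raise ValueError("fix times must increase in constant 0.1 s steps")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def velocity(self) -> np.ndarray:
        return np.array([f.velocity for f in self.fixes], dtype=float)

    @property
    def device_acceleration(self) -> np.ndarray | None:
        acc = [f.acceleration for f in self.fixes]
        if any(a is None for a in acc):
            return None
        return np.array(acc, dtype=float)

    @property
    def device_turning_angle(self) -> np.ndarray | None:
        ang = [f.turning_angle for f in self.fixes]
        if any(a is None for a in ang):
            return None
        return np.array(ang, dtype=float)

    @property
    def coordinates(self) -> tuple[np.ndarray, np.ndarray] | None:
        lat = [f.latitude for f in self.fixes]
        lon = [f.longitude for f in self.fixes]
        if any(v is None for v in lat) or any(v is None for v in lon):
            return None
        return np.array(lat, dtype=float), np.array(lon, dtype=float)


@dataclass(frozen=True)
class MovementSequence:
    """One discrete (active-period) movement-unit string of a player-match."""

    player_id: str
    match_id: str
    position: str
    segment_index: int
    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("a movement sequence must be nonempty")
        bad = set(self.symbols) - set(DEFAULT_ALPHABET.chars)
        if bad:
            raise ValueError(f"symbols outside the movement alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class DiscreteSequenceSet:
    """The mining corpus of one player-match: its discrete movement sequences."""

    player_id: str
    match_id: str
    position: str
    sequences: list[MovementSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sequences:
            if (s.player_id, s.match_id, s.position) != (
                self.player_id,
                self.match_id,
                self.position,
            ):
                raise ValueError("all sequences must share the corpus player/match/position")
        idx = [s.segment_index for s in self.sequences]
        if sorted(set(idx)) != idx:
            raise ValueError("segment indices must be unique and ordered")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def symbols(self) -> list[str]:
        return [s.symbols for s in self.sequences]

    @property
    def corpus_id(self) -> tuple[str, str, str]:
        return (self.player_id, self.match_id, self.position)


def _initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing, degrees clockwise from north (vectorized)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.degrees(np.arctan2(y, x)) % 360.0


def _haversine_m(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _fold_angle(delta: np.ndarray) -> np.ndarray:
    """Absolute bearing difference folded into [0, 180]."""
    d = np.abs(np.asarray(delta)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def heading_change(prev: GpsFix, cur: GpsFix, next_: GpsFix,
                   motion_epsilon: float = DEFAULT_MOTION_EPSILON) -> float:
    """Turning angle at ``cur``: absolute change between the bearings
    prev->cur and cur->next, folded into [0, 180] degrees.

    Returns 0.0 when either displacement is shorter than ``motion_epsilon``
    metres (no defined heading at walking-on-the-spot noise level).
    """
    for f in (prev, cur, next_):
        if f.latitude is None or f.longitude is None:
            raise ValueError("heading_change requires coordinates on all three fixes")
    d1 = _haversine_m(prev.latitude, prev.longitude, cur.latitude, cur.longitude)
    d2 = _haversine_m(cur.latitude, cur.longitude, next_.latitude, next_.longitude)
    if d1 < motion_epsilon or d2 < motion_epsilon:
        return 0.0
    b1 = _initial_bearing(prev.latitude, prev.longitude, cur.latitude, cur.longitude)
    b2 = _initial_bearing(cur.latitude, cur.longitude, next_.latitude, next_.longitude)
    return float(_fold_angle(b2 - b1))


def turning_angle_series(trace: GpsTrace,
                         motion_epsilon: float = DEFAULT_MOTION_EPSILON) -> np.ndarray:
    """Per-fix turning angles for a whole trace.

    Prefers the device turning-angle channel; otherwise derives angles from
    coordinates. The first and last fix get angle 0 (no three-fix corner).
    Over stationary steps the heading is carried from the last moving step;
    a fix that never moved contributes angle 0.
    """
    device = trace.device_turning_angle
    if device is not None:
        return device
    coords = trace.coordinates
    if coords is None:
        raise ValueError(
            f"trace {trace.player_id}/{trace.match_id} has neither a turning-angle "
            "channel nor complete coordinates"
        )
    lat, lon = coords
    n = len(lat)
    angles = np.zeros(n)
    if n < 3:
        return angles
    dist = _haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    bearing = _initial_bearing(lat[:-1], lon[:-1], lat[1:], lon[1:])
    moving = dist >= motion_epsilon
    # Carry the last defined heading across stationary steps.
    eff = np.full(n - 1, np.nan)
    last = np.nan
    for i in range(n - 1):
        if moving[i]:
            last = bearing[i]
        eff[i] = last
    for i in range(1, n - 1):
        if moving[i] and not np.isnan(eff[i - 1]):
            angles[i] = _fold_angle(bearing[i] - eff[i - 1])
    return angles


def derive_acceleration(trace: GpsTrace) -> np.ndarray:
    """Acceleration (m/s^2) by finite differences of the velocity channel:
    central at interior fixes, one-sided at the endpoints."""
    if len(trace) < 2:
        raise ValueError("acceleration needs at least two fixes")
    return np.gradient(trace.velocity, SAMPLE_INTERVAL_S)


def acceleration_series(trace: GpsTrace) -> np.ndarray:
    """Device acceleration channel when complete, else finite differences.
    A single fix without a device channel gets acceleration 0 (no slope)."""
    device = trace.device_acceleration
    if device is not None:
        return device
    if len(trace) < 2:
        return np.zeros(len(trace))
    return derive_acceleration(trace)


def discretize_trace(trace: GpsTrace,
                     alphabet: MovementAlphabet = DEFAULT_ALPHABET,
                     motion_epsilon: float = DEFAULT_MOTION_EPSILON) -> str:
    """One movement-unit character per fix, in time order."""
    if len(trace) == 0:
        return ""
    vel = trace.velocity
    acc = acceleration_series(trace)
    ang = turning_angle_series(trace, motion_epsilon=motion_epsilon)
    try:
        idx = encode_bands(vel, acc, ang)
    except ValueError:
        # Re-run scalar banding to report the offending fix index.
        for i in range(len(trace)):
            try:
                encode_bands(vel[i : i + 1], acc[i : i + 1], ang[i : i + 1])
            except ValueError as exc:
                raise ValueError(f"fix {i}: {exc}") from None
        raise
    return indices_to_symbols(idx)


def split_inactive(symbols: str,
                   velocities: Sequence[float] | np.ndarray,
                   v_min: float = DEFAULT_V_MIN,
                   t_min: float = DEFAULT_T_MIN,
                   *,
                   player_id: str = "", match_id: str = "", position: str = "",
                   ) -> list[MovementSequence]:
    """Delete sustained low-velocity runs and return the remaining maximal
    active runs as discrete movement sequences.

    A run is inactive when velocity < ``v_min`` m/s for at least ``t_min``
    seconds (>= t_min/0.1 consecutive samples). Sub-threshold runs shorter
    than ``t_min`` are kept in place. May return an empty list.
    """
    velocities = np.asarray(velocities, dtype=float)
    if len(symbols) != len(velocities):
        raise ValueError(
            f"symbols ({len(symbols)}) and velocities ({len(velocities)}) differ in length"
        )
    if len(symbols) == 0:
        return []
    min_run = int(round(t_min / SAMPLE_INTERVAL_S))
    below = velocities < v_min
    # Boundaries of maximal below-threshold runs.
    padded = np.concatenate([[False], below, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    keep = np.ones(len(symbols), dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            keep[s:e] = False
    # Remaining maximal kept runs become segments (deleting an inactive run
    # splits its two sides into separate sequences).
    padded = np.concatenate([[False], keep, [False]])
    seg_starts = np.flatnonzero(~padded[:-1] & padded[1:])
    seg_ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    out = []
    for k, (s, e) in enumerate(zip(seg_starts, seg_ends)):
        out.append(
            MovementSequence(player_id, match_id, position, k, symbols[s:e])
        )
    return out


def discretize_and_split(trace: GpsTrace,
                         v_min: float = DEFAULT_V_MIN,
                         t_min: float = DEFAULT_T_MIN,
                         motion_epsilon: float = DEFAULT_MOTION_EPSILON) -> DiscreteSequenceSet:
    """Full per-trace pipeline: discretize, then split on inactive periods."""
    symbols = discretize_trace(trace, motion_epsilon=motion_epsilon)
    seqs = split_inactive(
        symbols, trace.velocity, v_min=v_min, t_min=t_min,
        player_id=trace.player_id, match_id=trace.match_id, position=trace.position,
    )
    return DiscreteSequenceSet(trace.player_id, trace.match_id, trace.position, seqs)


class MovementDiscretizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: list of ``GpsTrace`` -> list of
    ``DiscreteSequenceSet`` (one mining corpus per player-match).

    Parameters
    ----------
    v_min : float
        Inactive-period velocity threshold, m/s.
    t_min : float
        Minimum inactive duration, seconds.
    motion_epsilon : float
        Displacement (m) below which a step defines no heading.
    """

    def __init__(self, v_min: float = DEFAULT_V_MIN, t_min: float = DEFAULT_T_MIN,
                 motion_epsilon: float = DEFAULT_MOTION_EPSILON):
        self.v_min = v_min
        self.t_min = t_min
        self.motion_epsilon = motion_epsilon

    def fit(self, X: Iterable[GpsTrace], y=None):
        # Stateless: banding thresholds are fixed domain constants.
        self.n_traces_ = len(list(X))
        return self

    def transform(self, X: Iterable[GpsTrace]) -> list[DiscreteSequenceSet]:
        return [
            discretize_and_split(
                tr, v_min=self.v_min, t_min=self.t_min,
                motion_epsilon=self.motion_epsilon,
            )
            for tr in X
        ]


# ---------------------------------------------------------------------------
# File formats

GPS_CSV_COLUMNS = [
    "time_s", "velocity", "acceleration", "latitude", "longitude",
    "turning_angle", "player_id", "match_id", "position",
]
_REQUIRED_CSV_COLUMNS = ["time_s", "velocity", "player_id", "match_id", "position"]


def read_gps_csv(path) -> list[GpsTrace]:
    """Read the GPS CSV dialect (header required) into one trace per
    (player_id, match_id) group, fixes in time order."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GPS CSV is missing required columns: {missing}")
    for c in ("acceleration", "latitude", "longitude", "turning_angle"):
        if c not in df.columns:
            df[c] = np.nan
    traces = []
    for (pid, mid), grp in df.groupby(["player_id", "match_id"], sort=True):
        grp = grp.sort_values("time_s")
        pos = str(grp["position"].iloc[0])
        fixes = [
            GpsFix(
                time_s=float(r.time_s),
                velocity=float(r.velocity),
                acceleration=None if pd.isna(r.acceleration) else float(r.acceleration),
                latitude=None if pd.isna(r.latitude) else float(r.latitude),
                longitude=None if pd.isna(r.longitude) else float(r.longitude),
                turning_angle=None if pd.isna(r.turning_angle) else float(r.turning_angle),
            )
            for r in grp.itertuples()
        ]
        traces.append(GpsTrace(str(pid), str(mid), pos, fixes))
    return traces


def write_gps_csv(traces: Iterable[GpsTrace], path) -> None:
    rows = []
    for tr in traces:
        for f in tr.fixes:
            rows.append(
                (f.time_s, f.velocity, f.acceleration, f.latitude, f.longitude,
                 f.turning_angle, tr.player_id, tr.match_id, tr.position)
            )
    pd.DataFrame(rows, columns=GPS_CSV_COLUMNS).to_csv(path, index=False)


def write_sequences(corpora: Iterable[DiscreteSequenceSet], path) -> None:
    """Tab-separated sequence file: player_id match_id position segment symbols."""
    rows = []
    for corpus in corpora:
        for s in corpus.sequences:
            rows.append((s.player_id, s.match_id, s.position, s.segment_index, s.symbols))
    pd.DataFrame(
        rows, columns=["player_id", "match_id", "position", "segment", "symbols"]
    ).to_csv(path, sep="\t", index=False)


def read_sequences(path) -> list[DiscreteSequenceSet]:
    df = pd.read_csv(path, sep="\t", dtype={"player_id": str, "match_id": str})
    out = []
    for (pid, mid), grp in df.groupby(["player_id", "match_id"], sort=True):
        grp = grp.sort_values("segment")
        pos = str(grp["position"].iloc[0])
        seqs = [
            MovementSequence(str(pid), str(mid), pos, int(r.segment), str(r.symbols))
            for r in grp.itertuples()
        ]
        out.append(DiscreteSequenceSet(str(pid), str(mid), pos, seqs))
    return out
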