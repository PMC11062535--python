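"""Seeded synthetic GPS cohorts for end-to-end pipeline testing.

Real match GPS from elite cohorts is rarely shareable, so this module
generates traces whose discretized movement-unit streams follow
position-specific Markov dynamics with *planted motifs* (short unit
strings inserted as atomic blocks at a configured rate) and sustained
low-velocity gaps, giving every downstream stage a ground truth:
discretization must invert the band-interval emission exactly (angle
mode), inactive splitting must recover the active segments, miners must
recover planted motifs, and classifiers must separate positions exactly
when (and only when) their archetypes differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET_CHARS
from .discretize import SAMPLE_INTERVAL_S, GpsFix, GpsTrace

#: Default band-interval emission bounds (see Table of thresholds in
#: :mod:`movemine.alphabet`): open ends are shrunk by EPS; the unbounded
#: Sprint/extreme-acceleration ends are capped at plausible athlete values.
EPS = 1e-3
V_CAP = 9.0     # m/s, elite sprint ceiling
A_CAP = 4.0     # m/s^2
WALK_FLOOR = 0.3  # m/s; active Walk samples stay above the inactive threshold

_VEL_INTERVALS = ((WALK_FLOOR, 1.70 - EPS), (1.70, 3.90), (3.90 + EPS, 5.00 - EPS), (5.00, V_CAP))
_ACC_INTERVALS = ((-A_CAP, -0.20), (-0.20 + EPS, 0.20 - EPS), (0.20, A_CAP))
_TURN_INTERVALS = ((0.0, 10.0 - EPS), (10.0, 45.0 - EPS), (45.0, 90.0 - EPS), (90.0, 180.0))

_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET_CHARS)}


@dataclass
class PositionArchetype:
    """Generative model of one playing position's movement-unit stream:
    a 48-state Markov chain plus motifs planted at ``rate`` insertions
    per 100 symbols."""

    label: str
    transition: np.ndarray
    initial: np.ndarray
    motifs: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (48, 48):
            raise ValueError("transition matrix must be 48 x 48")
        if (self.transition < 0).any() or not np.allclose(
            self.transition.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("transition rows must be nonnegative and sum to 1")
        if self.initial.shape != (48,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must be a length-48 simplex vector")
        for motif, rate in self.motifs:
            if rate < 0:
                raise ValueError("motif insertion rate must be >= 0")
            if set(motif) - set(ALPHABET_CHARS):
                raise ValueError(f"motif {motif!r} uses characters outside the alphabet")


def _kinematic_transition_matrix(turning_probs, velocity_persistence=0.97):
    """A plausible movement chain: velocity band persists and drifts to
    neighbours; the acceleration band reflects the velocity change; the
    turning band is drawn independently."""
    turning_probs = np.asarray(turning_probs, dtype=float)
    P = np.zeros((48, 48))
    vel_step = np.zeros((4, 4))
    for v in range(4):
        vel_step[v, v] = velocity_persistence
        nbrs = [u for u in (v - 1, v + 1) if 0 <= u < 4]
        for u in nbrs:
            vel_step[v, u] = (1 - velocity_persistence) / len(nbrs)
    acc_given = {  # P(acceleration band | velocity moved down/stayed/up)
        -1: np.array([0.70, 0.25, 0.05]),
        0: np.array([0.15, 0.70, 0.15]),
        1: np.array([0.05, 0.25, 0.70]),
    }
    for v in range(4):
        for a in range(3):
            for t in range(4):
                src = 12 * v + 4 * a + t
                for v2 in range(4):
                    pv = vel_step[v, v2]
                    if pv == 0:
                        continue
                    pa = acc_given[int(np.sign(v2 - v))]
                    for a2 in range(3):
                        for t2 in range(4):
                            P[src, 12 * v2 + 4 * a2 + t2] = pv * pa[a2] * turning_probs[t2]
    return P


def default_archetypes(distinct: bool = True,
                       motif_rate: float = 2.0) -> dict[str, PositionArchetype]:
    """Two-position cohort archetypes (hooker vs winger).

    Both share the same base kinematic chain; when ``distinct``, each
    position plants its own disjoint motifs (hookers: accelerated-jog
    runs "uuv"/"mn"-style close-quarter work; wingers: accelerated walks
    "ji" and straight sprints "SS"). With ``distinct=False`` the two
    labels share one identical archetype (the null cohort).
    """
    turning = np.array([0.70, 0.22, 0.06, 0.02])
    P = _kinematic_transition_matrix(turning)
    initial = np.zeros(48)
    initial[_CHAR_INDEX["e"]] = 1.0  # start at Walk/Neutral/Straight
    hooker_motifs = [("uuv", motif_rate), ("mn", motif_rate)]
    winger_motifs = [("ji", motif_rate), ("SS", motif_rate)]
    if not distinct:
        winger_motifs = hooker_motifs
    return {
        "hooker": PositionArchetype("hooker", P, initial, hooker_motifs),
        "winger": PositionArchetype("winger", P, initial, winger_motifs),
    }


def sample_unit_sequence(archetype: PositionArchetype, length: int,
                         rng: np.random.Generator) -> str:
    """Markov sample of exactly ``length`` movement-unit characters with
    motifs inserted as atomic blocks.

    Before each step, with probability (total rate / 100) a motif is
    chosen (rate-weighted) and appended whole when it still fits; the
    chain resumes from the motif's last character.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    trans = archetype.transition
    rates = np.array([r for _, r in archetype.motifs], dtype=float)
    total_rate = rates.sum() / 100.0
    motif_probs = rates / rates.sum() if rates.sum() > 0 else None
    out: list[str] = []
    state = int(rng.choice(48, p=archetype.initial))
    out.append(ALPHABET_CHARS[state])
    while len(out) < length:
        if total_rate > 0 and rng.random() < total_rate:
            m = archetype.motifs[int(rng.choice(len(rates), p=motif_probs))][0]
            if len(out) + len(m) <= length:
                out.append(m)
                state = _CHAR_INDEX[m[-1]]
                continue
        state = int(rng.choice(48, p=trans[state]))
        out.append(ALPHABET_CHARS[state])
    return "".join(out)[:length]


def _draw_channels(symbols: str, rng: np.random.Generator):
    v = np.empty(len(symbols))
    a = np.empty(len(symbols))
    t = np.empty(len(symbols))
    for i, ch in enumerate(symbols):
        idx = _CHAR_INDEX.get(ch)
        if idx is None:
            raise ValueError(f"{ch!r} is not a movement-unit character")
        vi, rem = divmod(idx, 12)
        ai, ti = divmod(rem, 4)
        v[i] = rng.uniform(*_VEL_INTERVALS[vi])
        a[i] = rng.uniform(*_ACC_INTERVALS[ai])
        t[i] = rng.uniform(*_TURN_INTERVALS[ti])
    return v, a, t


def units_to_gps(symbols: str, rng: np.random.Generator, mode: str = "angle",
                 *, player_id: str = "p0", match_id: str = "m0",
                 position: str = "hooker", start_time: float = 0.0,
                 origin: tuple[float, float] = (53.0, -1.5)) -> GpsTrace | None:
    """Invert the banding: emit one 0.1 s fix per character with velocity,
    acceleration and turning angle drawn uniformly inside the character's
    band intervals.

    In ``"angle"`` mode the turning angle is emitted as a device channel,
    making discretization an exact round trip. In ``"coordinate"`` mode
    latitude/longitude are synthesized so consecutive bearings realize
    the drawn angles (interior fixes only; the trace ends carry no
    defined corner). Returns None for the empty string.
    """
    if mode not in ("angle", "coordinate"):
        raise ValueError(f"unknown mode {mode!r}")
    if not symbols:
        return None
    v, a, t = _draw_channels(symbols, rng)
    times = start_time + SAMPLE_INTERVAL_S * np.arange(len(symbols))
    if mode == "angle":
        fixes = [
            GpsFix(time_s=ts, velocity=vv, acceleration=aa, turning_angle=tt)
            for ts, vv, aa, tt in zip(times, v, a, t)
        ]
        return GpsTrace(player_id, match_id, position, fixes)
    n = len(symbols)
    lat = np.empty(n)
    lon = np.empty(n)
    lat[0], lon[0] = origin
    heading = rng.uniform(0.0, 360.0)
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(origin[0]))
    for i in range(n - 1):
        if i >= 1:  # realize fix i's drawn angle as a heading change
            heading = (heading + rng.choice((-1.0, 1.0)) * t[i]) % 360.0
        step = v[i] * SAMPLE_INTERVAL_S
        lat[i + 1] = lat[i] + step * np.cos(np.radians(heading)) / m_per_deg_lat
        lon[i + 1] = lon[i] + step * np.sin(np.radians(heading)) / m_per_deg_lon
    fixes = [
        GpsFix(time_s=ts, velocity=vv, acceleration=aa, latitude=la, longitude=lo)
        for ts, vv, aa, la, lo in zip(times, v, a, lat, lon)
    ]
    return GpsTrace(player_id, match_id, position, fixes)


@dataclass
class SyntheticCohortConfig:
    """Study conditions of a synthetic cohort.

    ``gap_every_s`` controls the inactive-gap rate: active bursts last
    uniform(0.5, 1.5) x that many seconds, each followed by an inactive
    gap of uniform ``gap_duration_s`` seconds below ``gap_velocity`` m/s.
    """

    players_per_position: int = 10
    matches_per_player: int = 5
    duration_s: float = 600.0
    sample_interval_s: float = SAMPLE_INTERVAL_S
    gap_every_s: float = 8.0
    gap_duration_s: tuple[float, float] = (2.5, 6.0)
    gap_velocity: float = 0.15
    mode: str = "angle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.players_per_position < 1 or self.matches_per_player < 1:
            raise ValueError("player and match counts must be >= 1")
        if self.duration_s <= 0 or abs(self.sample_interval_s - SAMPLE_INTERVAL_S) > 1e-12:
            raise ValueError("duration must be positive on the fixed 0.1 s grid")
        if self.gap_duration_s[0] > self.gap_duration_s[1] or self.gap_duration_s[0] <= 0:
            raise ValueError("gap duration range must be positive and ordered")


@dataclass
class SyntheticCohort:
    """Generated traces plus the ground truth that produced them."""

    traces: list[GpsTrace]
    labels: list[str]
    active_segments: list[list[str]]  # per trace: the true active unit strings
    motifs: dict[str, list[tuple[str, float]]]
    config: SyntheticCohortConfig

    def __len__(self) -> int:
        return len(self.traces)


def _trace_layout(cfg: SyntheticCohortConfig, rng: np.random.Generator):
    """Alternating (is_active, n_samples) blocks filling the duration."""
    total = int(round(cfg.duration_s / SAMPLE_INTERVAL_S))
    min_gap = int(round(cfg.gap_duration_s[0] / SAMPLE_INTERVAL_S))
    blocks = []
    used = 0
    while used < total:
        burst = int(round(rng.uniform(0.5, 1.5) * cfg.gap_every_s / SAMPLE_INTERVAL_S))
        burst = min(max(burst, 10), total - used)
        blocks.append((True, burst))
        used += burst
        if used >= total:
            break
        gap = int(round(rng.uniform(*cfg.gap_duration_s) / SAMPLE_INTERVAL_S))
        if total - used < min_gap:
            # Too little room for a full gap: extend the final burst so a
            # truncated sub-threshold run cannot leak into an active segment.
            blocks[-1] = (True, blocks[-1][1] + total - used)
            break
        gap = min(gap, total - used)
        blocks.append((False, gap))
        used += gap
    return blocks


def generate_trace(archetype: PositionArchetype, cfg: SyntheticCohortConfig,
                   rng: np.random.Generator, *, player_id: str,
                   match_id: str) -> tuple[GpsTrace, list[str]]:
    """One player-match trace: active Markov bursts spliced with
    sub-threshold gaps; returns the trace and its true active segments."""
    blocks = _trace_layout(cfg, rng)
    segments: list[str] = []
    vs, accs, angs = [], [], []
    coords_mode = cfg.mode == "coordinate"
    for is_active, n in blocks:
        if is_active:
            sym = sample_unit_sequence(archetype, n, rng)
            segments.append(sym)
            v, a, t = _draw_channels(sym, rng)
        else:
            v = rng.uniform(0.0, cfg.gap_velocity, n)
            a = rng.uniform(-0.1, 0.1, n)
            t = rng.uniform(0.0, 5.0, n)
        vs.append(v)
        accs.append(a)
        angs.append(t)
    v = np.concatenate(vs)
    a = np.concatenate(accs)
    t = np.concatenate(angs)
    times = SAMPLE_INTERVAL_S * np.arange(len(v))
    if not coords_mode:
        fixes = [
            GpsFix(time_s=ts, velocity=vv, acceleration=aa, turning_angle=tt)
            for ts, vv, aa, tt in zip(times, v, a, t)
        ]
    else:
        lat = np.empty(len(v))
        lon = np.empty(len(v))
        lat[0], lon[0] = 53.0, -1.5
        heading = rng.uniform(0.0, 360.0)
        m_lat = 111_320.0
        m_lon = m_lat * np.cos(np.radians(53.0))
        for i in range(len(v) - 1):
            if i >= 1:
                heading = (heading + rng.choice((-1.0, 1.0)) * t[i]) % 360.0
            step = v[i] * SAMPLE_INTERVAL_S
            lat[i + 1] = lat[i] + step * np.cos(np.radians(heading)) / m_lat
            lon[i + 1] = lon[i] + step * np.sin(np.radians(heading)) / m_lon
        fixes = [
            GpsFix(time_s=ts, velocity=vv, acceleration=aa, latitude=la, longitude=lo)
            for ts, vv, aa, la, lo in zip(times, v, a, lat, lon)
        ]
    return GpsTrace(player_id, match_id, archetype.label, fixes), segments


def generate_cohort(cfg: SyntheticCohortConfig,
                    archetypes: dict[str, PositionArchetype] | None = None
                    ) -> SyntheticCohort:
    """Full two-position cohort, bit-reproducible under ``cfg.seed``.

    Produces players_per_position x matches_per_player traces per
    position (one child RNG stream per trace, spawned from the master
    seed so trace identity does not depend on generation order).
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if len(archetypes) != 2:
        raise ValueError("exactly two position archetypes required")
    master = np.random.SeedSequence(cfg.seed)
    n_traces = 2 * cfg.players_per_position * cfg.matches_per_player
    children = master.spawn(n_traces)
    traces, labels, segments = [], [], []
    i = 0
    for label in sorted(archetypes):
        arch = archetypes[label]
        for p in range(cfg.players_per_position):
            for m in range(cfg.matches_per_player):
                rng = np.random.default_rng(children[i])
                i += 1
                tr, segs = generate_trace(
                    arch, cfg, rng,
                    player_id=f"{label[0]}{p:02d}", match_id=f"m{m:02d}",
                )
                traces.append(tr)
                labels.append(label)
                segments.append(segs)
    return SyntheticCohort(
        traces=traces, labels=labels, active_segments=segments,
        motifs={lbl: list(archetypes[lbl].motifs) for lbl in archetypes},
        config=cfg,
    )
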