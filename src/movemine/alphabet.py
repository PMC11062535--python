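"""The 48-symbol movement-unit alphabet.

A *movement unit* is one 0.1 s GPS sample summarized by three kinematic
descriptors — a velocity band, an acceleration band and a turning-angle
band — and encoded as a single character so that a match half becomes a
string amenable to sequence mining.

The alphabet enumerates the 4 x 3 x 4 = 48 descriptor triples in
velocity-major order (Walk < Jog < Run < Sprint), acceleration next
(Deceleration < Neutral < Acceleration) and turning last (Straight <
Acute-change < Large-change < Backwards), mapped onto ``"a"–"z"`` then
``"A"–"V"``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

VELOCITY_BANDS = ("Walk", "Jog", "Run", "Sprint")
ACCELERATION_BANDS = ("Deceleration", "Neutral", "Acceleration")
TURNING_BANDS = ("Straight", "Acute-change", "Large-change", "Backwards")

#: Velocity thresholds (m/s): Walk [0, 1.7), Jog [1.7, 3.9], Run (3.9, 5.0), Sprint [5.0, inf)
VELOCITY_EDGES = (1.70, 3.90, 5.00)
#: Acceleration thresholds (m/s^2): Deceleration (-inf, -0.2], Neutral (-0.2, 0.2), Acceleration [0.2, inf)
ACCELERATION_EDGES = (-0.20, 0.20)
#: Turning-angle thresholds (deg): Straight [0,10), Acute [10,45), Large [45,90), Backwards [90,180]
TURNING_EDGES = (10.0, 45.0, 90.0)

ALPHABET_CHARS = string.ascii_lowercase + string.ascii_uppercase[:22]


@dataclass(frozen=True)
class DescriptorTriple:
    """One movement unit before character encoding."""

    velocity_band: str
    acceleration_band: str
    turning_band: str

    def __post_init__(self) -> None:
        if self.velocity_band not in VELOCITY_BANDS:
            raise ValueError(f"unknown velocity band {self.velocity_band!r}")
        if self.acceleration_band not in ACCELERATION_BANDS:
            raise ValueError(f"unknown acceleration band {self.acceleration_band!r}")
        if self.turning_band not in TURNING_BANDS:
            raise ValueError(f"unknown turning band {self.turning_band!r}")


class MovementAlphabet:
    """Bijection between the 48 descriptor triples and single characters.

    Index of a triple = 12 * velocity + 4 * acceleration + turning, with
    each descriptor indexed in its band order above.
    """

    chars: str = ALPHABET_CHARS

    def __init__(self) -> None:
        self._triples = tuple(
            DescriptorTriple(v, a, t)
            for v in VELOCITY_BANDS
            for a in ACCELERATION_BANDS
            for t in TURNING_BANDS
        )
        self._by_triple = {tr: self.chars[i] for i, tr in enumerate(self._triples)}
        self._by_char = {c: tr for tr, c in self._by_triple.items()}

    def __len__(self) -> int:
        return 48

    def __contains__(self, char: str) -> bool:
        return char in self._by_char

    def encode(self, triple: DescriptorTriple) -> str:
        """Character for a descriptor triple (total on all 48 triples)."""
        return self._by_triple[triple]

    def decode(self, char: str) -> DescriptorTriple:
        try:
            return self._by_char[char]
        except KeyError:
            raise KeyError(f"{char!r} is not a movement-unit character") from None

    def triples(self) -> tuple[DescriptorTriple, ...]:
        return self._triples


#: Module-level default; the mapping is fixed, so one shared instance suffices.
DEFAULT_ALPHABET = MovementAlphabet()


def band_velocity(v: float) -> str:
    """Velocity band of a speed in m/s.

    Walk [0, 1.70), Jog [1.70, 3.90], Run (3.90, 5.00), Sprint [5.00, inf).
    """
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"velocity must be finite and >= 0, got {v}")
    if v < 1.70:
        return "Walk"
    if v <= 3.90:
        return "Jog"
    if v < 5.00:
        return "Run"
    return "Sprint"


def band_acceleration(a: float) -> str:
    """Acceleration band of a value in m/s^2.

    Deceleration (-inf, -0.20], Neutral (-0.20, 0.20), Acceleration [0.20, inf).
    """
    if not np.isfinite(a):
        raise ValueError(f"acceleration must be finite, got {a}")
    if a <= -0.20:
        return "Deceleration"
    if a < 0.20:
        return "Neutral"
    return "Acceleration"


def band_turning(theta: float) -> str:
    """Turning-angle band of an absolute heading change in degrees.

    Straight [0, 10), Acute-change [10, 45), Large-change [45, 90),
    Backwards [90, 180].
    """
    if not np.isfinite(theta) or theta < 0 or theta > 180:
        raise ValueError(f"turning angle must lie in [0, 180], got {theta}")
    if theta < 10.0:
        return "Straight"
    if theta < 45.0:
        return "Acute-change"
    if theta < 90.0:
        return "Large-change"
    return "Backwards"


def encode_unit(triple: DescriptorTriple, alphabet: MovementAlphabet = DEFAULT_ALPHABET) -> str:
    """Single character for one descriptor triple."""
    return alphabet.encode(triple)


def encode_bands(
    velocity: np.ndarray, acceleration: np.ndarray, turning: np.ndarray
) -> np.ndarray:
    """Vectorized banding + encoding: three aligned float arrays -> index array 0..47.

    Raises on any out-of-domain value, mirroring the scalar banders.
    """
    velocity = np.asarray(velocity, dtype=float)
    acceleration = np.asarray(acceleration, dtype=float)
    turning = np.asarray(turning, dtype=float)
    if not (np.isfinite(velocity).all() and (velocity >= 0).all()):
        raise ValueError("velocity must be finite and >= 0")
    if not np.isfinite(acceleration).all():
        raise ValueError("acceleration must be finite")
    if not (np.isfinite(turning).all() and (turning >= 0).all() and (turning <= 180).all()):
        raise ValueError("turning angle must lie in [0, 180]")
    # np.digitize with right=... cannot express the mixed inclusivity of the
    # Jog/Run boundary (Jog closed at 3.90, Run open), so spell it out.
    vi = np.select(
        [velocity < 1.70, velocity <= 3.90, velocity < 5.00], [0, 1, 2], default=3
    )
    ai = np.select([acceleration <= -0.20, acceleration < 0.20], [0, 1], default=2)
    ti = np.select([turning < 10.0, turning < 45.0, turning < 90.0], [0, 1, 2], default=3)
    return 12 * vi + 4 * ai + ti


def indices_to_symbols(indices: np.ndarray) -> str:
    return "".join(ALPHABET_CHARS[i] for i in indices)
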