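import numpy as np
import pytest

from movemine import (
    DiscreteSequenceSet,
    GpsFix,
    GpsTrace,
    MovementSequence,
)

#: Descriptor rows of the worked 10-sample example (seconds 1469–1469.9)
#: and the movement-unit string they must encode to.
TABLE1_ROWS = [
    ("Walk", "Acceleration", "Straight"),
    ("Walk", "Acceleration", "Acute-change"),
    ("Walk", "Neutral", "Acute-change"),
    ("Walk", "Neutral", "Straight"),
    ("Walk", "Acceleration", "Straight"),
    ("Walk", "Acceleration", "Large-change"),
    ("Walk", "Neutral", "Backwards"),
    ("Walk", "Deceleration", "Backwards"),
    ("Walk", "Deceleration", "Backwards"),
    ("Walk", "Deceleration", "Acute-change"),
]
TABLE1_STRING = "ijfeikhddb"

#: Mid-band numeric representatives used to rebuild raw channel values
#: from descriptor rows.
BAND_VALUES = {
    "velocity": {"Walk": 0.8, "Jog": 2.8, "Run": 4.5, "Sprint": 6.0},
    "acceleration": {"Deceleration": -1.0, "Neutral": 0.0, "Acceleration": 1.0},
    "turning": {"Straight": 5.0, "Acute-change": 25.0, "Large-change": 60.0,
                "Backwards": 120.0},
}


def table1_trace() -> GpsTrace:
    """The worked example rebuilt as a raw 10 Hz trace with device
    acceleration and turning-angle channels at mid-band values."""
    fixes = [
        GpsFix(
            time_s=1469.0 + 0.1 * i,
            velocity=BAND_VALUES["velocity"][v],
            acceleration=BAND_VALUES["acceleration"][a],
            turning_angle=BAND_VALUES["turning"][t],
        )
        for i, (v, a, t) in enumerate(TABLE1_ROWS)
    ]
    return GpsTrace("p1", "m1", "hooker", fixes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_corpus(seqs, player="p0", match="m0", position="hooker"):
    return DiscreteSequenceSet(
        player, match, position,
        [MovementSequence(player, match, position, i, s) for i, s in enumerate(seqs)],
    )


def random_corpora(rng, n_corpora, alphabet, max_seqs, max_len, min_len=1):
    """Random small string corpora for oracle-equivalence testing."""
    letters = list(alphabet)
    out = []
    for _ in range(n_corpora):
        n = int(rng.integers(1, max_seqs + 1))
        out.append([
            "".join(rng.choice(letters, size=int(rng.integers(min_len, max_len + 1))))
            for _ in range(n)
        ])
    return out
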