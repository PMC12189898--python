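"""Shared fixtures: synthetic warming-pad scenes generated at test time.

The packaged study conditions: 13 frames at 5-minute intervals on the
fixed 25-45 degC scale, ambient 26 degC, plateau 42 degC, sensor noise
0.3 degC, pad strictly inside a 120x160 frame.  Seeds are fixed so every
run sees bit-identical sequences.
"""

from __future__ import annotations

import pytest

from thermopad import PadScene, TemperatureScale, generate_sequence

FIXTURE_SEED = 7
SHAPES = ("ellipse", "u_band", "annulus")


def make_scene(shape: str, bit_depth: int = 8, seed: int = FIXTURE_SEED) -> PadScene:
    return PadScene(
        shape=shape, seed=seed, scale=TemperatureScale(bit_depth=bit_depth)
    )


@pytest.fixture(scope="session")
def standard_fixtures():
    """{(shape, bit_depth): (sequence, ground_truth)} for the six standard
    scenes (three pad shapes x 8/10-bit)."""
    out = {}
    for shape in SHAPES:
        for depth in (8, 10):
            out[(shape, depth)] = generate_sequence(make_scene(shape, depth))
    return out


@pytest.fixture(scope="session")
def ellipse_sequence(standard_fixtures):
    return standard_fixtures[("ellipse", 8)]
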