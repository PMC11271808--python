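"""Shared fixtures: generated display batches are expensive, so they are
built once per session and reused by the generator, property, matcher and
acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from numaniso.generator import GeneratorConfig, generate_display

PERCENT_LEVELS = (0, 25, 50, 75, 100)


@pytest.fixture(scope="session")
def display_batch():
    """100 mixture displays: 10 seeds x 2 arrangements x 5 percent levels."""
    displays = []
    for seed in range(10):
        for arrangement in ("radial", "tangential"):
            for pp in PERCENT_LEVELS:
                cfg = GeneratorConfig(
                    seed=seed, arrangement=arrangement, percent_pairs=pp
                )
                displays.append(generate_display(cfg))
    return displays


@pytest.fixture(scope="session")
def triplet_displays():
    """A few all-triplet displays per arrangement."""
    displays = []
    for seed in range(3):
        for arrangement in ("radial", "tangential"):
            cfg = GeneratorConfig(
                seed=seed, arrangement=arrangement,
                mode="all_triplets", percent_pairs=None,
            )
            displays.append(generate_display(cfg))
    return displays


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
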