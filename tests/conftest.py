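"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest

from cafkit import (
    MarkerReference,
    QuantileThresholds,
    SectionSimParams,
    generate_serial_sections,
)
from cafkit.subtyping import MarkerThresholds, MARKERS


@pytest.fixture(scope="session")
def even_thresholds() -> QuantileThresholds:
    """Quartile thresholds at 75/150/225 for every marker (H-score scale)."""
    return QuantileThresholds(
        {m: MarkerThresholds(75.0, 150.0, 225.0) for m in MARKERS}
    )


#: Representative value at the center of each quartile band of the
#: even thresholds above.
BAND_CENTER = {"Neg": 37.5, "Low": 112.5, "Med": 187.5, "Hi": 262.5}


@pytest.fixture(scope="session")
def marker_reference() -> MarkerReference:
    return MarkerReference.generate(seed=11)


@pytest.fixture(scope="session")
def noise_free_sections():
    """Small noise-free serial-section stack with a modest warp."""
    params = SectionSimParams(
        image_size=128, warp_amplitude=3.0, n_landmarks=12, od_noise_sd=0.0, seed=3
    )
    return generate_serial_sections(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
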