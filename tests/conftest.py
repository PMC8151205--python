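"""Shared fixtures: small fast geometries and 20-gut study batches.

The 20-gut batches use one shared seed, so gut *i* has identical organ
geometry across conditions (the structure stream draws geometry before
clones) — which makes cross-condition gut-area comparisons exact.
"""

import numpy as np
import pytest

from cloneburden.pipeline import analyze_synthetic_batch
from cloneburden.presets import MidgutGeometry, RenderConfig, get_preset
from cloneburden.synth import generate_midgut

STUDY_SEED = 1
STUDY_N_GUTS = 20


@pytest.fixture(scope="session")
def small_geometry():
    """A short gut for fast single-image unit tests."""
    return MidgutGeometry(length_um=1500.0, width_um=240.0, curvature_amplitude_um=30.0)


@pytest.fixture(scope="session")
def small_control_gut(small_geometry):
    image, truth = generate_midgut(get_preset("control"), geometry=small_geometry, seed=42)
    return image, truth


@pytest.fixture(scope="session")
def apcras_gut():
    """One full-size tumour-model gut with ground truth."""
    image, truth = generate_midgut(get_preset("apcras"), seed=7)
    return image, truth


@pytest.fixture(scope="session")
def control_batch():
    return analyze_synthetic_batch("control", n_guts=STUDY_N_GUTS, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def snail_batch():
    return analyze_synthetic_batch("snail", n_guts=STUDY_N_GUTS, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def apcras_batch():
    return analyze_synthetic_batch("apcras", n_guts=STUDY_N_GUTS, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def treated_batch():
    return analyze_synthetic_batch("apcras_treated", n_guts=STUDY_N_GUTS, seed=STUDY_SEED)
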