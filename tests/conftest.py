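"""Shared fixtures: a designable synthetic locus, its panel, simulated data.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mippseq.design import DesignConfig, TargetVariant, design_panel
from mippseq.dna import random_reference
from mippseq.simulate import ErrorModel

LOCUS_SEED = 42  # yields a designable 2 kb locus (checked at fixture build)


@pytest.fixture(scope="session")
def locus() -> str:
    return random_reference(2000, LOCUS_SEED)


@pytest.fixture(scope="session")
def target(locus) -> TargetVariant:
    ref_base = locus[1000]
    alt = "A" if ref_base != "A" else "G"
    return TargetVariant("locus", 1001, ref_base, alt)


@pytest.fixture(scope="session")
def panel(locus, target):
    p = design_panel(locus, target, config=DesignConfig(), seed=1)
    p.validate()
    return p


@pytest.fixture(scope="session")
def error_free() -> ErrorModel:
    return ErrorModel(sub_rate=0.0, polymerase_rate=0.0, indel_rate=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
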