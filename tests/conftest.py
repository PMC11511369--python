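"""Shared fixtures: deterministic synthetic scenes rendered once per session."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from pestpulse.synth import make_fixture_suite

SUITE_SEED = 1


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory) -> Path:
    """The standard synthetic fixture ladder, rendered once into a tmp dir."""
    out = tmp_path_factory.mktemp("scenes")
    make_fixture_suite(out, seed=SUITE_SEED)
    return out


@pytest.fixture(scope="session")
def suite_truth(fixture_suite):
    """Ground-truth JSON per scene name."""
    return {
        p.stem.removesuffix("_truth"): json.loads(p.read_text())
        for p in fixture_suite.glob("*_truth.json")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
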