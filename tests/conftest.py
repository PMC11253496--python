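"""Shared fixtures: small synthetic datasets and reduced grids.

Everything is generated programmatically with fixed seeds; no fixture files.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import minpverse as mv

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", module="sklearn")
warnings.filterwarnings("ignore", module="lightgbm")


@pytest.fixture(scope="session")
def grid48() -> mv.SpecificationGrid:
    return mv.default_grid()


@pytest.fixture(scope="session")
def glm_grid() -> mv.SpecificationGrid:
    """A cheap 6-strategy sub-grid (imputation + regularized GLM only)."""
    return mv.enumerate_grid(
        {
            "missing_handling": ["impute"],
            "surrogate_model": ["regularized_glm"],
            "aggregation": ["mean"],
        }
    )


@pytest.fixture(scope="session")
def null_data_100() -> mv.SurgeryDataset:
    """One global-null dataset at n=100 (outcome is a fair coin flip)."""
    return mv.generate_part1_null(100, seed=424242)


@pytest.fixture(scope="session")
def evaluator_100(null_data_100, grid48) -> mv.GridEvaluator:
    """The 48-strategy grid preprocessed once on the shared null dataset."""
    return mv.GridEvaluator(null_data_100, grid48, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
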