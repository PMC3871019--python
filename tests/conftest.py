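import logging

import numpy as np
import pytest

from maternorm import (
    DesignConfig,
    ModelSpec,
    build_design,
    intercept_truth,
    reduced_design,
    simulate_experiment,
)

# quieten expected design warnings (dropped factors, aliased columns)
logging.getLogger("maternorm").setLevel(logging.ERROR)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=15, deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass


@pytest.fixture(scope="session")
def tiny_dataset():
    """One ewe per maternal group, one ram per direct group: 54 records."""
    cfg = DesignConfig(n_ewes_per_maternal_group=1, n_rams_per_direct_group=1)
    return simulate_experiment(cfg, intercept_truth(), seed=5, group_shifts=False)


@pytest.fixture(scope="session")
def reduced_dataset():
    """The reduced calibration-scale design (9 ewes, 4 rams, 162 records)."""
    return simulate_experiment(reduced_design(), intercept_truth(), seed=7, group_shifts=False)


@pytest.fixture(scope="session")
def tiny_bundles(tiny_dataset):
    design, _, milk, growth = tiny_dataset
    return {
        kind: build_design(milk, None if kind == "milk_only" else growth,
                           design.pedigree, ModelSpec(kind=kind))
        for kind in ("intercept", "reaction_norm", "milk_only")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
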