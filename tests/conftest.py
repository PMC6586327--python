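import dataclasses

import numpy as np
import pytest

from nutrigeo.diets import reference_designs
from nutrigeo.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def designs():
    return reference_designs()


@pytest.fixture(scope="session")
def rmt_points(designs):
    """The seven (P%, C%) design compositions of the 3-D experiment."""
    return np.array(
        [(d.p_frac, d.c_frac) for d in designs["nochoice_3d"].treatments]
    )


@pytest.fixture
def quiet_config(designs):
    """A noise-free choice-experiment generator configuration."""
    return GeneratorConfig(
        design=designs["choice_2d"],
        total_intake_cv=0.0,
        hoard_frac=0.0,
        hoard_sd=0.0,
        scatter_frac=0.0,
        scatter_sd=0.0,
        death_hazard_fn=lambda p, c: 0.0,
        bin_effect_sd=0.0,
        seed=11,
    )


def small_design(designs, kind, replicates):
    return dataclasses.replace(designs[kind], replicates_per_treatment=replicates)
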