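import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from kinotox import synth


@pytest.fixture(scope="session")
def default_registry():
    return synth.make_registry(80, 23, seed=7)


@pytest.fixture()
def zero_noise_params():
    return synth.TraceParams(noise_sd=0.0)


@pytest.fixture()
def neutral_model(default_registry):
    """Effect model with all multipliers 1 and no well noise."""
    effects = {
        (c.compound_id, conc): synth.EndpointEffects(1.0, 1.0, 1.0, 1.0)
        for c in default_registry.compounds
        for conc in synth.DEFAULT_CONCENTRATIONS
    }
    return synth.EffectModel(
        effects=effects,
        noise_cv={"viability": 0.0, "live_cells": 0.0, "magnitude": 0.0, "frequency": 0.0},
        seed=0,
    )
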