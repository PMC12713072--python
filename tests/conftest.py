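"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pytest

from lyosim import ModelConfig, Protocol, Ramp, make_case


@pytest.fixture
def cfg():
    """Default model configuration."""
    return ModelConfig()


@pytest.fixture
def flat_protocol():
    """Everything constant at 265 K / atmospheric pressure: a vial in
    thermal equilibrium with its surroundings (no driving forces)."""
    T = 265.0
    return Protocol(T_b=Ramp.constant(T), T_g=Ramp.constant(T),
                    T_c=Ramp.constant(T), T_u=Ramp.constant(T),
                    p_t=Ramp.constant(1e5), p_w_c=Ramp.constant(0.0))


@pytest.fixture
def visf_case():
    return make_case("visf-study")


@pytest.fixture
def default_case():
    return make_case("default")
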