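"""Shared fixtures: packaged parameters and pre-solved reference chains."""

from __future__ import annotations

import pytest

import dairyherd as dh


@pytest.fixture(scope="session")
def defaults():
    """Packaged parameter set (rates, effects, scenario)."""
    return dh.default_params()


@pytest.fixture(scope="session")
def base_space():
    return dh.enumerate_states("base")


@pytest.fixture(scope="session")
def ext_space():
    return dh.enumerate_states("extended")


@pytest.fixture(scope="session")
def validation_policy():
    """Open-cow culling at month 11 (first parity) / 10 (later parities)."""
    return dh.default_policy()


@pytest.fixture(scope="session")
def validation_run(defaults, base_space, validation_policy):
    """Solved base model under the validation policy."""
    rates, effects, scenario = defaults
    return dh.evaluate_policy(
        rates, effects, scenario, validation_policy, "base", base_space
    )


@pytest.fixture(scope="session")
def optimal_extended_run(defaults, ext_space):
    """Solved extended model at the published optimal steady state
    (primiparous culled at month 6, multiparous at month 10)."""
    rates, effects, scenario = defaults
    return dh.evaluate_policy(
        rates, effects, scenario, dh.Policy(6, 10), "extended", ext_space
    )
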