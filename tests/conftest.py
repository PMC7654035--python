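"""Shared fixtures: full-batch simulations are expensive, so the three study
conditions are simulated once per session and reused across test modules."""

import numpy as np
import pytest

from magnetoferm.bioreactor import observe, run_preset


@pytest.fixture(scope="session")
def oxic_record():
    """35 h closed-loop batch at a 95% dO2 set point (dense 1-min sampling)."""
    return run_preset("oxic95", seed=1)


@pytest.fixture(scope="session")
def microoxic_records():
    """Three replicate 35 h closed-loop batches at a 1% dO2 set point."""
    return [run_preset("microoxic1", seed=s) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def anoxic_record():
    """35 h open-loop anoxic batch (100 rpm, 0.2 SLPM N2, 10 mM nitrate)."""
    return run_preset("anoxic0", seed=1)


@pytest.fixture(scope="session")
def microoxic_observations(microoxic_records):
    """At-line observations: 30-min sampling, 2% multiplicative noise."""
    return [
        observe(rec, 0.5, 0.02, seed=100 + k)
        for k, rec in enumerate(microoxic_records, start=1)
    ]
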