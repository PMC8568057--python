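"""Shared fixtures.

Expensive single-cell simulations are session-scoped so several tests can
share one run; everything is generated programmatically (no stored data).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from neuromodnet.cellmodel import ClampProtocol, build_surrogate, run_protocol

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dspn_rest_run():
    """1 s dSPN run with no input (resting behavior)."""
    model = build_surrogate("dSPN")
    proto = ClampProtocol.current_step(200.0, 500.0, 0.0)
    return run_protocol(model, proto, 1000.0, dt_ms=0.05)


@pytest.fixture(scope="session")
def fs_rest_run():
    model = build_surrogate("FS")
    proto = ClampProtocol.current_step(200.0, 500.0, 0.0)
    return run_protocol(model, proto, 1000.0, dt_ms=0.05)


@pytest.fixture(scope="session")
def dspn_step_run():
    """Suprathreshold dSPN step (reference current, 500 ms)."""
    model = build_surrogate("dSPN")
    proto = ClampProtocol.current_step(200.0, 500.0, 250.0)
    return run_protocol(model, proto, 800.0, dt_ms=0.05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
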