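import math

import pytest

from coldphase import DEFAULT_TANH
from coldphase.model import TanhParameterSet
from coldphase.scenarios import STEADY_TEMPS, run_steady


@pytest.fixture(scope="session")
def steady_runs():
    """Steady runs at the six standard temperatures (shared, ~5 s)."""
    return {T: run_steady(DEFAULT_TANH, T) for T in STEADY_TEMPS}


@pytest.fixture
def adler_set():
    """Unmodulated set (A = 0) with b = 1.25: pure Adler rotation."""
    return TanhParameterSet(
        b0=1.25, b1=0.0, A0=0.0, A1=0.0,
        Omega0=3 * math.pi / 200, Omega1=0.0, C=0.055, Tbar=33.75,
    )


@pytest.fixture
def excitable_set():
    """Unmodulated set with b = 0.9 < 1: a stable phase fixed point."""
    return TanhParameterSet(
        b0=0.9, b1=0.0, A0=0.0, A1=0.0,
        Omega0=3 * math.pi / 200, Omega1=0.0, C=0.055, Tbar=33.75,
    )
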