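import numpy as np
import pytest

from asdphase import TernarySystem, builtin_fixture, trace_binodal

T37 = 310.15   # 37 C
T50 = 323.15   # 50 C
P_ATM = 1e5    # 0.1 MPa

np.seterr(over="ignore", under="ignore")


@pytest.fixture(scope="session")
def pset():
    return builtin_fixture()


@pytest.fixture(scope="session")
def nap_sys(pset):
    return TernarySystem(pset, "naproxen", "PVPVA64")


@pytest.fixture(scope="session")
def ven_sys(pset):
    return TernarySystem(pset, "venetoclax", "PVPVA64")


@pytest.fixture(scope="session")
def ven_ties37(ven_sys):
    """Traced venetoclax binodal at 37 C (coarse continuation)."""
    binodal, ties = trace_binodal(ven_sys, T37, P_ATM, step_wt=0.015,
                                  max_points=200)
    assert len(ties) > 10
    return ties


@pytest.fixture(scope="session")
def nap_ties37(nap_sys):
    """Traced naproxen binodal at 37 C (coarse continuation)."""
    binodal, ties = trace_binodal(nap_sys, T37, P_ATM, step_wt=0.015,
                                  max_points=200)
    assert len(ties) > 10
    return ties


@pytest.fixture(scope="session")
def ven_ties50(ven_sys):
    """Traced venetoclax binodal at 50 C."""
    binodal, ties = trace_binodal(ven_sys, T50, P_ATM, step_wt=0.02,
                                  max_points=160)
    assert len(ties) > 10
    return ties
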