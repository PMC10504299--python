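"""Shared fixtures: anchovy-like configuration and small simulated series."""

import numpy as np
import pytest

from comsim import operating_model as om


@pytest.fixture(scope="session")
def lh() -> om.LifeHistory:
    return om.LifeHistory()


@pytest.fixture(scope="session")
def fleet() -> om.FleetSpec:
    return om.FleetSpec()


@pytest.fixture(scope="session")
def obs() -> om.ObservationSpec:
    return om.ObservationSpec()


@pytest.fixture(scope="session")
def refs(lh, fleet) -> om.RefPoints:
    """MSY reference points of the default operating model (computed once)."""
    return om.find_fmsy(lh, fleet)


@pytest.fixture(scope="session")
def schaefer_series():
    """A noiseless Schaefer catch series with known parameters.

    Harvest rate ramps up so the stock depletes to a known final
    saturation; used for inversion/self-consistency checks.
    """
    r_true, k_true = 0.8, 10_000.0
    b = [k_true]
    catches = []
    for t in range(30):
        u = 0.05 + 0.1 * t / 29  # rising exploitation
        c = u * b[-1]
        catches.append(c)
        b.append(b[-1] + r_true * b[-1] * (1 - b[-1] / k_true) - c)
    return {
        "r": r_true,
        "k": k_true,
        "catch": np.array(catches),
        "biomass": np.array(b),
        "final_saturation": b[-1] / k_true,
    }
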