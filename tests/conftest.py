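"""Shared fixtures; the expensive flow computations are session-scoped."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from fdanozzle.benchmarks import (
    desk_nozzle_case,
    open_pipe_case,
    poiseuille_convergence,
)
from fdanozzle.geometry import NozzleGeometry
from fdanozzle.scaling import BLOOD_ANALOG


@pytest.fixture(scope="session")
def nozzle_geometry() -> NozzleGeometry:
    return NozzleGeometry()


@pytest.fixture(scope="session")
def fluid():
    return BLOOD_ANALOG


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def poiseuille_study():
    """Placement-averaged pipe errors at 10/20/40 cells per diameter."""
    results, errs, order = poiseuille_convergence()
    return {"results": results, "errors": errs, "order": order}


@pytest.fixture(scope="session")
def open_pipe():
    """Steady laminar pipe with parabolic inflow and open outflow."""
    return open_pipe_case()


@pytest.fixture(scope="session")
def nozzle_run():
    """The laminar scaled-down nozzle case (truncated domain, Re_th = 500)."""
    return desk_nozzle_case()
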