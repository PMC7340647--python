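"""Diffusive scaling between physical flow specifications and lattice units.

A lattice-Boltzmann run is prescribed by a fluid (density, viscosity), a
throat Reynolds number, a grid spacing and the principal relaxation rate.
Under diffusive scaling the time step follows from the grid spacing and the
relaxation rate,

    nu_lattice = cs2 (1/Omega - 1/2),
    dt         = nu_lattice dx^2 / nu,
    u_lattice  = u dt / dx,

and the lattice velocity must stay below a Mach guard (0.15 here) for the
low-Mach expansion of the method to hold.  The Reynolds number computed from
lattice quantities must reproduce the physical one exactly, which
:func:`build_case` verifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .stencil import CS2

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import NozzleGeometry

MACH_LIMIT: float = 0.15


class ScalingError(ValueError):
    """Invalid physical or lattice parameter."""


class StabilityDomainError(ScalingError):
    """Relaxation rate outside the open interval (0, 2)."""


class MachLimitError(ScalingError):
    """Lattice velocity at or above the Mach guard.

    Carries the offending velocity in :attr:`u_lattice`; a simulation setup
    receiving this error must refuse to start.
    """

    def __init__(self, u_lattice: float, limit: float = MACH_LIMIT):
        self.u_lattice = u_lattice
        self.limit = limit
        super().__init__(
            f"lattice velocity {u_lattice:.4f} exceeds the Mach guard {limit}; "
            "reduce dx or adjust Omega"
        )


class UnderResolvedError(ScalingError):
    """Grid spacing leaves fewer than the minimum cells across a feature."""


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid: density [kg/m^3] and dynamic viscosity [Pa s]."""

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ScalingError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho [m^2/s]."""
        return self.dynamic_viscosity / self.density


#: Blood-analog fluid used throughout the benchmark.
BLOOD_ANALOG = FluidSpec(density=1056.0, dynamic_viscosity=0.0035)


@dataclass(frozen=True)
class FlowCase:
    """Physical description of one nozzle flow case."""

    re_throat: float
    throat_diameter: float          # m
    u_mean_throat: float            # m/s
    u_mean_inlet: float             # m/s
    throat_length: float            # m
    flow_through_time: float        # s, based on the inlet-section mean velocity


@dataclass(frozen=True)
class LatticeScaling:
    """Lattice-unit translation of a flow case under diffusive scaling."""

    dx: float                       # m
    dt: float                       # s
    omega: float
    nu_lattice: float
    u_lattice: float                # throat-mean velocity, lattice units
    cs2: float = CS2
    mach_ok: bool = True
    meta: dict = field(default_factory=dict)


def compute_reynolds(u_mean: float, d: float, nu: float) -> float:
    """Reynolds number ``u d / nu`` for a characteristic length ``d``."""
    if d <= 0 or nu <= 0:
        raise ScalingError("d and nu must be positive")
    if u_mean < 0:
        raise ScalingError("u_mean must be non-negative")
    return u_mean * d / nu


def lattice_viscosity(omega: float) -> float:
    """Lattice viscosity ``cs2 (1/Omega - 1/2)``; positive on (0, 2)."""
    if not 0.0 < omega < 2.0:
        raise StabilityDomainError(f"omega={omega} outside (0, 2)")
    return CS2 * (1.0 / omega - 0.5)


def timestep_from_dx(dx: float, omega: float, nu: float) -> float:
    """Physical time step ``nu_lattice dx^2 / nu`` (diffusive scaling)."""
    if dx <= 0 or nu <= 0:
        raise ScalingError("dx and nu must be positive")
    return lattice_viscosity(omega) * dx * dx / nu


def omega_for_timestep(dt: float, dx: float, nu: float) -> float:
    """Relaxation rate whose diffusive-scaling time step equals ``dt``."""
    if dt <= 0 or dx <= 0 or nu <= 0:
        raise ScalingError("dt, dx and nu must be positive")
    nu_lat = dt * nu / (dx * dx)
    omega = 1.0 / (nu_lat / CS2 + 0.5)
    if not 0.0 < omega < 2.0:
        raise StabilityDomainError(f"required omega={omega} outside (0, 2)")
    return omega


def lattice_velocity(
    u_mean: float, dt: float, dx: float, *, limit: float = MACH_LIMIT, check: bool = True
) -> float:
    """Lattice velocity ``u dt / dx``; raises :class:`MachLimitError` at >= limit."""
    if dt <= 0 or dx <= 0:
        raise ScalingError("dt and dx must be positive")
    u_lat = u_mean * dt / dx
    if check and u_lat >= limit:
        raise MachLimitError(u_lat, limit)
    return u_lat


def flow_through_time(length: float, u_ref: float) -> float:
    """Residence time ``L / u`` of the reference section."""
    if length <= 0 or u_ref <= 0:
        raise ScalingError("length and u_ref must be positive")
    return length / u_ref


def build_case(
    fluid: FluidSpec,
    re_throat: float,
    dx: float,
    omega: float,
    geometry: "NozzleGeometry",
    *,
    mach: str = "raise",
) -> tuple[FlowCase, LatticeScaling]:
    """Translate a physical specification into a consistent lattice setup.

    Parameters
    ----------
    mach : {"raise", "warn"}
        Behaviour when the throat-mean lattice velocity reaches the Mach
        guard.  ``"warn"`` records the violation in ``LatticeScaling.mach_ok``
        instead of raising, which is needed to reproduce production-scale
        parameter tables whose throat velocities exceed the guard.

    The flow-through time uses the inlet-section mean velocity (throat mean
    divided by the inlet:throat area ratio) with the throat length as the
    reference length; the convention is echoed in the scaling metadata.
    """
    if re_throat <= 0:
        raise ScalingError("re_throat must be positive")
    nu = fluid.kinematic_viscosity
    d = geometry.throat_diameter
    n_cells = d / dx
    if n_cells < 4:
        raise UnderResolvedError(
            f"dx={dx} leaves {n_cells:.1f} cells across the {d} m throat (minimum 4)"
        )
    u_th = re_throat * nu / d
    area_ratio = (geometry.inlet_radius / geometry.throat_radius) ** 2
    u_in = u_th / area_ratio
    dt = timestep_from_dx(dx, omega, nu)
    nu_lat = lattice_viscosity(omega)
    try:
        u_lat = lattice_velocity(u_th, dt, dx)
        mach_ok = True
    except MachLimitError:
        if mach != "warn":
            raise
        u_lat = u_th * dt / dx
        mach_ok = False

    re_lattice = compute_reynolds(u_lat, n_cells, nu_lat)
    if not math.isclose(re_lattice, re_throat, rel_tol=1e-10):
        raise ScalingError(
            f"lattice Reynolds {re_lattice} != physical Reynolds {re_throat}"
        )

    case = FlowCase(
        re_throat=re_throat,
        throat_diameter=d,
        u_mean_throat=u_th,
        u_mean_inlet=u_in,
        throat_length=geometry.throat_length,
        flow_through_time=flow_through_time(geometry.throat_length, u_in),
    )
    scal = LatticeScaling(
        dx=dx,
        dt=dt,
        omega=omega,
        nu_lattice=nu_lat,
        u_lattice=u_lat,
        mach_ok=mach_ok,
        meta={
            "flow_through_reference": "inlet-section mean velocity, throat length",
            "area_ratio": area_ratio,
            "cells_across_throat": n_cells,
        },
    )
    return case, scal
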