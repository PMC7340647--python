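"""D3Q19 lattice-Boltzmann solver with curved walls and open boundaries.

The time loop is collide -> boundary fill -> stream.  Collision is either
BGK (all moments relaxed at the principal rate) or full MRT in the
d'Humieres basis; the two coincide when every rate equals the principal one.
Walls use the linear interpolated bounce-back with sub-cell distances ``q``,
which reduces algebraically to half-way bounce-back at ``q = 1/2``.  The
inflow imposes a parabolic axial profile through a velocity bounce-back on
the inlet face, ramped from zero over a configurable startup window; the
outflow extrapolates the populations of the last interior plane and pins the
outlet density to the reference (zero gauge pressure).

All state is in lattice units; :class:`~fdanozzle.scaling.LatticeScaling`
converts probe series and fields to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import kernels
from .geometry import FLUID, OUTLET, SOLID, FlagField
from .scaling import LatticeScaling
from .stencil import C, CS2, OPP, Q, W, MRTConfig, equilibrium


class DivergenceError(RuntimeError):
    """Simulation left the stable domain (NaN or Mach-guard violation)."""

    def __init__(self, step: int, location: tuple[int, int, int], value: float):
        self.step = step
        self.location = location
        self.value = value
        super().__init__(
            f"divergence at step {step}, cell {location}: |u|={value:.4f}"
        )


@dataclass
class InletSpec:
    """Parabolic inflow on the low-z face.

    ``u_mean`` is the section-mean axial lattice velocity; the imposed
    profile is ``2 u_mean (1 - (r/R)^2)``.  ``ramp_steps`` linearly scales
    the target from zero to avoid the startup pressure shock.
    """

    u_mean: float
    radius_cells: float
    axis: tuple[float, float]
    ramp_steps: int = 0
    direction: int = 1


@dataclass
class SolverConfig:
    omega: float
    rates: np.ndarray | None = None     # per-moment MRT rates; None -> all omega
    force: tuple[float, float, float] = (0.0, 0.0, 0.0)  # lattice force density
    inlet: InletSpec | None = None
    wall_velocity: tuple[float, float, float] | None = None
    rho0: float = 1.0
    mach_limit: float = 0.15
    check_every: int = 200
    # outlet reconstruction: 1 = extrapolated populations with density pin
    # (default), 0 = equilibrium at reference density with backflow
    # suppression (robust when recirculation reaches a truncated outlet)
    outlet_order: int = 1

    def mrt(self) -> MRTConfig:
        return MRTConfig(self.omega, self.rates)


@dataclass
class RunResult:
    steps: int
    probe_steps: np.ndarray          # (nt,)
    probe_u: np.ndarray              # (nt, n_probe, 3) lattice units
    probe_rho: np.ndarray            # (nt, n_probe)
    u_mean: np.ndarray | None = None       # (nx, ny, nz, 3)
    u2_mean: np.ndarray | None = None      # component-wise second moment
    rho_mean: np.ndarray | None = None
    stress_mean: np.ndarray | None = None  # (nx, ny, nz, 3, 3), lattice units
    n_samples: int = 0
    residual_history: list = field(default_factory=list)

    @property
    def tke_field(self) -> np.ndarray:
        """Time-averaged turbulent kinetic energy ½ sum var(u_i), lattice units."""
        if self.u_mean is None:
            raise ValueError("run was not accumulated")
        var = np.clip(self.u2_mean - self.u_mean**2, 0.0, None)
        return 0.5 * var.sum(axis=-1)


def macroscopic(f: np.ndarray, force: Sequence[float] | None = None):
    """Density and velocity moments; includes the half-force shift if forced."""
    rho = f.sum(axis=-1)
    mom = f @ C.astype(float)
    if force is not None and any(force):
        mom = mom + 0.5 * np.asarray(force, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = mom / rho[..., None]
    return rho, u


def shear_stress(f: np.ndarray, omega: float, rho: np.ndarray | None = None,
                 u: np.ndarray | None = None) -> np.ndarray:
    """Deviatoric viscous stress from non-equilibrium second moments.

    Local (no finite differences):
    ``tau_ab = -(1 - omega/2) sum_i c_ia c_ib (f_i - f_i_eq)``, traceless.
    Lattice units; multiply by ``rho_phys (dx/dt)^2`` for Pa.
    """
    if rho is None or u is None:
        rho, u = macroscopic(f)
    fneq = f - equilibrium(rho, u)
    cf = C.astype(float)
    pi = np.einsum("...i,ia,ib->...ab", fneq, cf, cf)
    tr = np.trace(pi, axis1=-2, axis2=-1)
    pi -= tr[..., None, None] / 3.0 * np.eye(3)
    return -(1.0 - 0.5 * omega) * pi


def vorticity(u: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Vorticity magnitude |curl u| via second-order central differences.

    One-sided differences close the stencil at array boundaries.  With the
    velocity nondimensionalized by the throat mean and lengths by the throat
    diameter, multiplying by the Reynolds number gives the 0..2 Re display
    convention used for instantaneous snapshots.
    """
    dux = np.gradient(u[..., 0], dx, axis=(0, 1, 2))
    duy = np.gradient(u[..., 1], dx, axis=(0, 1, 2))
    duz = np.gradient(u[..., 2], dx, axis=(0, 1, 2))
    wx = duz[1] - duy[2]
    wy = dux[2] - duz[0]
    wz = duy[0] - dux[1]
    return np.sqrt(wx * wx + wy * wy + wz * wz)


class Simulation:
    """Time-stepping container binding a flag field to a solver config."""

    def __init__(self, ff: FlagField, config: SolverConfig,
                 scaling: LatticeScaling | None = None):
        self.ff = ff
        self.config = config
        self.scaling = scaling
        nx, ny, nz = ff.shape
        self.f = np.tile(W * config.rho0, (nx, ny, nz, 1))
        self.fpost = np.empty_like(self.f)
        self.step_count = 0
        self._mrt = config.mrt()
        # explicit rates select the moment-space kernel even when they all
        # equal the principal rate (the BGK-equivalence oracle needs that)
        self._A = None if config.rates is None else self._mrt.collision_matrix()
        if ff.q is None:
            self.q = np.full((nx, ny, nz, Q), np.nan)
        else:
            self.q = ff.q
        self._out_idx = np.argwhere(ff.flags == OUTLET).astype(np.int64)
        self._fluid = ff.flags == FLUID
        # kernel-private flags with the interior fast-path marking
        self._kflags = kernels.refine_bulk(ff.flags)
        self._Carr = C.copy()
        self._CXf = C[:, 0].astype(float)
        self._CYf = C[:, 1].astype(float)
        self._CZf = C[:, 2].astype(float)
        self._W = W.copy()
        self._OPP = OPP.copy()
        self._prev_u: np.ndarray | None = None
        self.residual_history: list[tuple[int, float]] = []

    # -- state helpers ---------------------------------------------------
    def set_state(self, rho: np.ndarray | float, u: np.ndarray) -> None:
        """Initialize distributions to the local equilibrium of (rho, u)."""
        rho = np.broadcast_to(np.asarray(rho, dtype=float), self.ff.shape)
        u = np.broadcast_to(np.asarray(u, dtype=float), self.ff.shape + (3,))
        self.f[...] = equilibrium(rho, u)

    def mass(self) -> float:
        """Total mass over non-solid cells."""
        wet = self.ff.flags != SOLID
        return float(self.f[wet].sum())

    def macroscopic(self):
        return macroscopic(self.f, self.config.force)

    def shear_stress(self) -> np.ndarray:
        return shear_stress(self.f, self.config.omega)

    # -- stepping --------------------------------------------------------
    def _ramp(self) -> float:
        inlet = self.config.inlet
        if inlet is None or inlet.ramp_steps <= 0:
            return 1.0
        return min(1.0, self.step_count / inlet.ramp_steps)

    def _advance(self) -> None:
        cfg = self.config
        fx, fy, fz = cfg.force
        if self._A is None:
            kernels.collide_bgk(
                self.f, self.fpost, self._kflags, self._CXf, self._CYf,
                self._CZf, self._W, cfg.omega, fx, fy, fz,
            )
        else:
            kernels.collide_mrt(
                self.f, self.fpost, self._kflags, self._CXf, self._CYf,
                self._CZf, self._W, self._A
            )
        if len(self._out_idx):
            kernels.fill_outlet(
                self.fpost, self._kflags, self._out_idx, self._CXf, self._CYf,
                self._CZf, self._W, 1, cfg.rho0, cfg.outlet_order,
            )
        inlet = cfg.inlet
        if inlet is not None:
            umax = 2.0 * inlet.u_mean * self._ramp()
            ax_x, ax_y = inlet.axis
            r2 = inlet.radius_cells**2
            idir = inlet.direction
        else:
            umax, ax_x, ax_y, r2, idir = 0.0, 0.0, 0.0, 1.0, 1
        wu = cfg.wall_velocity or (0.0, 0.0, 0.0)
        kernels.stream(
            self.fpost, self.f, self._kflags, self.q, self._Carr, self._W,
            self._OPP, umax, ax_x, ax_y, r2, idir, wu[0], wu[1], wu[2], cfg.rho0,
        )
        self.step_count += 1

    def _check(self) -> None:
        rho, u = self.macroscopic()
        sp = np.linalg.norm(u, axis=-1)
        sp = np.where(self._fluid, sp, 0.0)
        bad = ~np.isfinite(sp)
        if bad.any():
            loc = tuple(int(v) for v in np.argwhere(bad)[0])
            raise DivergenceError(self.step_count, loc, float("nan"))
        mx = float(sp.max()) if sp.size else 0.0
        if mx >= self.config.mach_limit:
            loc = tuple(int(v) for v in np.argwhere(sp == sp.max())[0])
            raise DivergenceError(self.step_count, loc, mx)
        if self._prev_u is not None:
            scale = max(mx, 1e-30)
            res = float(np.abs(u[..., 2] - self._prev_u).max() / scale)
            self.residual_history.append((self.step_count, res))
        self._prev_u = u[..., 2].copy()

    def run(
        self,
        n_steps: int,
        *,
        sample_every: int = 0,
        probe_cells: np.ndarray | None = None,
        accumulate_after: int | None = None,
        accumulate_stress: bool = False,
    ) -> RunResult:
        """Advance ``n_steps`` with probe sampling and moment accumulation.

        ``accumulate_after`` (step index relative to this call) opens the
        averaging window for the mean/second-moment fields; by default the
        final 80% of the run is averaged, mirroring a development window of
        one-fifth of the simulated interval.
        """
        if accumulate_after is None:
            accumulate_after = n_steps // 5
        check = max(1, self.config.check_every)
        probes = (
            np.asarray(probe_cells, dtype=np.int64)
            if probe_cells is not None
            else np.empty((0, 3), dtype=np.int64)
        )
        t_list: list[int] = []
        u_list: list[np.ndarray] = []
        rho_list: list[np.ndarray] = []
        acc_u = acc_u2 = acc_rho = acc_stress = None
        n_acc = 0

        for local in range(n_steps):
            self._advance()
            if self.step_count % check == 0:
                self._check()
            if sample_every and (local + 1) % sample_every == 0:
                rho, u = self.macroscopic()
                if len(probes):
                    px, py, pz = probes[:, 0], probes[:, 1], probes[:, 2]
                    t_list.append(self.step_count)
                    u_list.append(u[px, py, pz])
                    rho_list.append(rho[px, py, pz])
                if local + 1 > accumulate_after:
                    if acc_u is None:
                        acc_u = np.zeros(self.ff.shape + (3,))
                        acc_u2 = np.zeros(self.ff.shape + (3,))
                        acc_rho = np.zeros(self.ff.shape)
                        if accumulate_stress:
                            acc_stress = np.zeros(self.ff.shape + (3, 3))
                    un = np.nan_to_num(u)
                    acc_u += un
                    acc_u2 += un * un
                    acc_rho += np.nan_to_num(rho)
                    if accumulate_stress:
                        acc_stress += np.nan_to_num(
                            shear_stress(self.f, self.config.omega, rho, u)
                        )
                    n_acc += 1

        return RunResult(
            steps=n_steps,
            probe_steps=np.array(t_list, dtype=np.int64),
            probe_u=(np.stack(u_list) if u_list else np.empty((0, len(probes), 3))),
            probe_rho=(np.stack(rho_list) if rho_list else np.empty((0, len(probes)))),
            u_mean=None if acc_u is None else acc_u / n_acc,
            u2_mean=None if acc_u is None else acc_u2 / n_acc,
            rho_mean=None if acc_rho is None else acc_rho / n_acc,
            stress_mean=None if acc_stress is None else acc_stress / n_acc,
            n_samples=n_acc,
            residual_history=list(self.residual_history),
        )


def gauge_pressure(rho: np.ndarray, rho0: float = 1.0) -> np.ndarray:
    """Lattice gauge pressure ``cs2 (rho - rho0)``."""
    return CS2 * (rho - rho0)
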