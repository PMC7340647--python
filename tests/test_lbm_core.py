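"""Solver-core tests: equilibrium, collision, streaming, boundaries, moments."""

import numpy as np
import pytest

from fdanozzle.geometry import (
    FLUID,
    INLET,
    OUTLET,
    SOLID,
    WALL_MOVING,
    FlagField,
)
from fdanozzle.solver import (
    DivergenceError,
    InletSpec,
    Simulation,
    SolverConfig,
    gauge_pressure,
    macroscopic,
    shear_stress,
    vorticity,
)
from fdanozzle.scaling import lattice_viscosity
from fdanozzle.stencil import C, CS2, OPP, Q, W, MRTConfig, dhumieres_rates, equilibrium


def periodic_box(n=8, rho0=1.0):
    flags = np.full((n, n, n), FLUID, np.uint8)
    ff = FlagField(flags=flags, dx=1.0, origin=(0.0, 0.0, 0.0))
    return ff


def random_admissible_state(sim, rng, amp=0.05):
    """Random near-equilibrium distributions (positive, low Mach)."""
    shape = sim.ff.shape
    rho = 1.0 + amp * (rng.random(shape) - 0.5)
    u = amp * (rng.random(shape + (3,)) - 0.5)
    sim.f[...] = equilibrium(rho, u) * (1.0 + 0.02 * (rng.random(shape + (Q,)) - 0.5))


class TestEquilibrium:
    def test_rest_state_is_weights(self):
        f = equilibrium(np.array(1.0), np.zeros(3))
        assert np.allclose(f, W, atol=1e-16)

    def test_moment_identities(self, rng):
        rho = 1.0 + 0.2 * rng.random(50)
        u = 0.1 * (rng.random((50, 3)) - 0.5)
        feq = equilibrium(rho, u)
        assert np.abs(feq.sum(-1) - rho).max() < 1e-14
        assert np.abs(feq @ C - rho[:, None] * u).max() < 1e-14
        P = np.einsum("ni,ia,ib->nab", feq, C.astype(float), C.astype(float))
        Pex = rho[:, None, None] * (
            CS2 * np.eye(3) + np.einsum("na,nb->nab", u, u)
        )
        assert np.abs(P - Pex).max() < 1e-14


class TestCollision:
    def test_equilibrium_is_fixed_point(self, rng):
        ff = periodic_box(6)
        sim = Simulation(ff, SolverConfig(omega=1.6, check_every=10**9))
        rho = 1.0 + 0.1 * rng.random(ff.shape)
        u = 0.05 * (rng.random(ff.shape + (3,)) - 0.5)
        sim.set_state(rho, u)
        f0 = sim.f.copy()
        from fdanozzle import kernels
        kernels.collide_bgk(sim.f, sim.fpost, sim._kflags, sim._CXf, sim._CYf,
                            sim._CZf, sim._W, 1.6, 0.0, 0.0, 0.0)
        assert np.abs(sim.fpost - f0).max() < 1e-14

    def test_density_and_momentum_conserved(self, rng):
        ff = periodic_box(6)
        for rates in (None, dhumieres_rates(1.7)):
            sim = Simulation(ff, SolverConfig(omega=1.7, rates=rates,
                                              check_every=10**9))
            random_admissible_state(sim, rng)
            rho0, u0 = macroscopic(sim.f)
            mom0 = sim.f @ C.astype(float)
            sim._advance()  # collide + stream; streaming permutes, conserving sums
            assert sim.mass() == pytest.approx(float(rho0.sum()), rel=1e-13)

    def test_per_cell_conservation_of_collision(self, rng):
        ff = periodic_box(5)
        sim = Simulation(ff, SolverConfig(omega=1.9, rates=dhumieres_rates(1.9),
                                          check_every=10**9))
        random_admissible_state(sim, rng)
        from fdanozzle import kernels
        kernels.collide_mrt(sim.f, sim.fpost, sim._kflags, sim._CXf, sim._CYf,
                            sim._CZf, sim._W, sim._A)
        rho_a = sim.f.sum(-1)
        rho_b = sim.fpost.sum(-1)
        mom_a = sim.f @ C.astype(float)
        mom_b = sim.fpost @ C.astype(float)
        assert np.abs(rho_a - rho_b).max() < 1e-12
        assert np.abs(mom_a - mom_b).max() < 1e-12

    def test_equal_rate_mrt_matches_bgk(self, rng):
        """Moment-space collision with all rates equal reduces to BGK."""
        ff = periodic_box(6)
        bgk = Simulation(ff, SolverConfig(omega=1.85, check_every=10**9))
        mrt = Simulation(ff, SolverConfig(omega=1.85, rates=np.full(Q, 1.85),
                                          check_every=10**9))
        assert mrt._A is not None and bgk._A is None
        random_admissible_state(bgk, rng)
        mrt.f[...] = bgk.f
        for _ in range(20):
            bgk._advance()
            mrt._advance()
        assert np.abs(bgk.f - mrt.f).max() < 1e-12


class TestStreaming:
    def test_single_pulse_advects(self):
        ff = periodic_box(5)
        sim = Simulation(ff, SolverConfig(omega=1.0, check_every=10**9))
        from fdanozzle import kernels
        i = 7  # a diagonal link
        sim.fpost[...] = 0.0
        sim.fpost[2, 2, 2, i] = 1.0
        fnew = np.zeros_like(sim.fpost)
        kernels.stream(sim.fpost, fnew, sim._kflags, sim.q, sim._Carr, sim._W,
                       sim._OPP, 0.0, 0.0, 0.0, 1.0, 1, 0.0, 0.0, 0.0, 1.0)
        tgt = tuple(np.array([2, 2, 2]) + C[i])
        assert fnew[tgt][i] == 1.0
        fnew[tgt][i] = 0.0
        assert np.abs(fnew).max() == 0.0

    def test_streaming_is_a_permutation(self, rng):
        ff = periodic_box(6)
        sim = Simulation(ff, SolverConfig(omega=1.0, check_every=10**9))
        from fdanozzle import kernels
        sim.fpost[...] = rng.random(sim.fpost.shape)
        fnew = np.empty_like(sim.fpost)
        kernels.stream(sim.fpost, fnew, sim._kflags, sim.q, sim._Carr, sim._W,
                       sim._OPP, 0.0, 0.0, 0.0, 1.0, 1, 0.0, 0.0, 0.0, 1.0)
        for i in range(Q):
            assert np.sort(fnew[..., i], axis=None) == pytest.approx(
                np.sort(sim.fpost[..., i], axis=None)
            )
        assert fnew.sum() == pytest.approx(sim.fpost.sum(), rel=1e-14)


class TestBouzidi:
    def test_halfway_reduction_at_q_half(self, rng):
        """q = 0.5 must reproduce standard half-way bounce-back exactly."""
        n = 8
        flags = np.full((4, n, 4), FLUID, np.uint8)
        flags[:, 0, :] = SOLID
        flags[:, -1, :] = SOLID
        ff = FlagField(flags=flags, dx=1.0, origin=(0, 0, 0))
        simA = Simulation(ff, SolverConfig(omega=1.5, check_every=10**9))
        simB = Simulation(ff, SolverConfig(omega=1.5, check_every=10**9))
        # A: explicit q = 0.5 on every cut link; B: missing q -> half-way path
        simA.q = np.where(np.isfinite(simA.q), simA.q, np.nan)
        for j in range(1, Q):
            cy = C[j, 1]
            if cy == -1:
                simA.q[:, 1, :, j] = 0.5
            elif cy == 1:
                simA.q[:, -2, :, j] = 0.5
        fpost = rng.random(simA.fpost.shape)
        simA.fpost[...] = fpost
        simB.fpost[...] = fpost
        outA = np.zeros_like(fpost)
        outB = np.zeros_like(fpost)
        from fdanozzle import kernels
        for sim, out in ((simA, outA), (simB, outB)):
            kernels.stream(sim.fpost, out, sim._kflags, sim.q, sim._Carr,
                           sim._W, sim._OPP, 0.0, 0.0, 0.0, 1.0, 1,
                           0.0, 0.0, 0.0, 1.0)
        assert np.abs(outA - outB).max() < 1e-14
        # independent half-way oracle on the bottom-wall row
        for i in range(Q):
            if C[i, 1] != 1:
                continue
            j = int(OPP[i])
            assert outA[2, 1, 2, i] == pytest.approx(fpost[2, 1, 2, j], abs=1e-15)

    def test_couette_profile_is_exact(self):
        ny = 14
        flags = np.full((4, ny, 4), FLUID, np.uint8)
        flags[:, 0, :] = SOLID
        flags[:, -1, :] = WALL_MOVING
        ff = FlagField(flags=flags, dx=1.0, origin=(0, 0, 0))
        U = 0.04
        sim = Simulation(ff, SolverConfig(omega=1.3, wall_velocity=(U, 0, 0),
                                          check_every=10**9))
        sim.run(4000)
        _, u = sim.macroscopic()
        ys = np.arange(ny, dtype=float)
        ana = U * (ys - 0.5) / (ny - 2)
        assert np.abs(u[2, 1:-1, 2, 0] - ana[1:-1]).max() < 1e-10

    def test_pipe_velocity_error_small_and_decreasing(self, poiseuille_study):
        errs = poiseuille_study["errors"]
        assert errs[1] < 1e-2          # 20 cells per diameter
        assert errs[2] < errs[1] < errs[0]


class TestOpenBoundaries:
    def test_quiescent_fluid_unchanged(self):
        n = 10
        flags = np.full((6, 6, n), FLUID, np.uint8)
        flags[:, :, 0] = INLET
        flags[:, :, -1] = OUTLET
        ff = FlagField(flags=flags, dx=1.0, origin=(0, 0, 0))
        inlet = InletSpec(u_mean=0.0, radius_cells=1e9, axis=(2.5, 2.5))
        sim = Simulation(ff, SolverConfig(omega=1.4, inlet=inlet))
        f0 = sim.f.copy()
        sim.run(50)
        assert np.abs(sim.f[:, :, 1:-1] - f0[:, :, 1:-1]).max() < 1e-14

    def test_uniform_flow_passes_outlet(self):
        """Plug flow in a frictionless duct leaves through the outlet
        without distortion upstream."""
        n = 24
        u0 = 0.05
        flags = np.full((6, 6, n), FLUID, np.uint8)
        flags[:, :, 0] = INLET
        flags[:, :, -1] = OUTLET
        ff = FlagField(flags=flags, dx=1.0, origin=(0, 0, 0))
        # huge radius makes the imposed parabola flat: u(0) = 2 u_mean = u0
        inlet = InletSpec(u_mean=u0 / 2, radius_cells=1e9, axis=(2.5, 2.5))
        sim = Simulation(ff, SolverConfig(omega=1.4, inlet=inlet))
        sim.set_state(1.0, np.array([0.0, 0.0, u0]))
        sim.run(200)
        _, u = sim.macroscopic()
        interior = u[:, :, 2:-6, 2]
        assert np.abs(interior - u0).max() < 1e-6

    def test_outlet_gauge_pressure_zero(self, open_pipe):
        assert abs(open_pipe.outlet_gauge_pressure) < 1e-8

    def test_inlet_flux_matches_parabolic_target(self, open_pipe):
        """Voxel quadrature of the imposed profile vs. pi R^2 u_mean."""
        sim = open_pipe.sim
        target = np.pi * sim.config.inlet.radius_cells**2 * sim.config.inlet.u_mean
        assert open_pipe.flux_in == pytest.approx(target, rel=0.01)

    def test_developed_profile_ratio(self, open_pipe):
        assert open_pipe.centerline_over_mean == pytest.approx(2.0, rel=0.02)


class TestMacroscopicAndDerived:
    def test_rest_state_moments(self):
        f = np.tile(W, (3, 3, 3, 1))
        rho, u = macroscopic(f)
        assert np.allclose(rho, 1.0, atol=1e-15)
        assert np.allclose(u, 0.0, atol=1e-15)

    def test_recovers_equilibrium_inputs(self, rng):
        rho = 1.0 + 0.2 * rng.random((4, 4, 4))
        u = 0.08 * (rng.random((4, 4, 4, 3)) - 0.5)
        r2, u2 = macroscopic(equilibrium(rho, u))
        assert np.abs(r2 - rho).max() < 1e-14
        assert np.abs(u2 - u).max() < 1e-13

    def test_moments_match_brute_force(self, rng):
        f = 0.5 + rng.random((5, 5, 5, Q))
        rho, u = macroscopic(f)
        rho_b = sum(f[..., i] for i in range(Q))
        mom_b = sum(f[..., i, None] * C[i] for i in range(Q))
        assert np.abs(rho - rho_b).max() < 1e-12
        assert np.abs(u - mom_b / rho[..., None]).max() < 1e-12

    def test_uniform_flow_has_zero_stress(self):
        f = equilibrium(np.ones((4, 4, 4)), np.full((4, 4, 4, 3), 0.03))
        tau = shear_stress(f, 1.5)
        assert np.abs(tau).max() < 1e-12

    def test_couette_stress_matches_viscous_law(self):
        ny = 14
        flags = np.full((4, ny, 4), FLUID, np.uint8)
        flags[:, 0, :] = SOLID
        flags[:, -1, :] = WALL_MOVING
        ff = FlagField(flags=flags, dx=1.0, origin=(0, 0, 0))
        U, om = 0.04, 1.3
        sim = Simulation(ff, SolverConfig(omega=om, wall_velocity=(U, 0, 0),
                                          check_every=10**9))
        sim.run(4000)
        gamma = U / (ny - 2)
        tau = shear_stress(sim.f, om)
        expected = lattice_viscosity(om) * gamma  # rho = 1
        assert tau[2, 5, 2, 0, 1] == pytest.approx(expected, rel=0.01)

    def test_poiseuille_wall_shear(self, poiseuille_study):
        """Extrapolated wall shear of the pipe matches 2 mu u_max / R.

        The stress profile is linear in radius; its slope over the interior
        cells, times R, is the wall value.
        """
        res = poiseuille_study["results"][2][0]  # D = 40, centred placement
        sim = res.sim
        om, R = res.omega, res.diameter_cells / 2.0
        tau = shear_stress(sim.f, om)
        x, _, _ = sim.ff.cell_centers()
        iy = sim.ff.shape[1] // 2
        row_ok = sim.ff.flags[:, iy, 2] != SOLID
        sel = row_ok & (np.abs(x) < 0.6 * R)
        slope = np.polyfit(x[sel], tau[sel, iy, 2, 0, 2], 1)[0]
        expected_slope = -2.0 * lattice_viscosity(om) * res.u_max / R**2
        assert slope == pytest.approx(expected_slope, rel=0.02)

    def test_vorticity_linear_fields(self):
        n = 9
        x = np.arange(n, dtype=float)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        u = np.zeros((n, n, n, 3))
        assert np.abs(vorticity(u + 0.3)).max() < 1e-14  # uniform flow
        # rigid rotation about z at rate w: |curl| = 2w, exact for linear fields
        w = 0.01
        u_rot = np.zeros_like(u)
        u_rot[..., 0] = -w * (Y - 4)
        u_rot[..., 1] = w * (X - 4)
        assert np.abs(vorticity(u_rot) - 2 * w).max() < 1e-10
        # plane shear u_x = k y: |curl| = |k|
        k = 0.02
        u_sh = np.zeros_like(u)
        u_sh[..., 0] = k * Y
        assert np.abs(vorticity(u_sh) - abs(k)).max() < 1e-10


class TestRunLoop:
    def test_zero_steps_returns_initial_state(self):
        ff = periodic_box(5)
        sim = Simulation(ff, SolverConfig(omega=1.2))
        f0 = sim.f.copy()
        res = sim.run(0)
        assert res.steps == 0
        assert np.array_equal(sim.f, f0)

    def test_mass_conserved_in_periodic_box(self, rng):
        ff = periodic_box(6)
        sim = Simulation(ff, SolverConfig(omega=1.8, check_every=10**9))
        random_admissible_state(sim, rng, amp=0.04)
        m0 = sim.mass()
        sim.run(1000)
        assert abs(sim.mass() - m0) / m0 < 1e-12

    def test_mach_guard_aborts_with_diagnostics(self):
        ff = periodic_box(6)
        sim = Simulation(ff, SolverConfig(omega=1.2, check_every=1))
        sim.set_state(1.0, np.array([0.0, 0.0, 0.2]))  # beyond the 0.15 guard
        with pytest.raises(DivergenceError) as exc:
            sim.run(5)
        assert exc.value.value >= 0.15
        assert len(exc.value.location) == 3

    def test_probe_series_deterministic(self, rng):
        ff = periodic_box(6)
        probes = np.array([[2, 2, 2], [3, 1, 4]])
        series = []
        for _ in range(2):
            sim = Simulation(ff, SolverConfig(omega=1.6, check_every=10**9))
            rng2 = np.random.default_rng(11)
            random_admissible_state(sim, rng2)
            res = sim.run(60, sample_every=5, probe_cells=probes)
            series.append(res.probe_u.copy())
        assert np.array_equal(series[0], series[1])

    def test_gauge_pressure_convention(self):
        assert gauge_pressure(np.array(1.0)) == 0.0
        assert gauge_pressure(np.array(1.3)) == pytest.approx(0.1)
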