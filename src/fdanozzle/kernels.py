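"""Hot loops of the lattice-Boltzmann solver (numba-compiled).

Array layout is array-of-structures: distributions have shape
(nx, ny, nz, 19) so that one cell's populations are contiguous.  Streaming
is written in pull form: each fluid cell gathers post-collision values from
its neighbours, applying the interpolated (Bouzidi, linear) bounce-back on
links cut by a wall, a velocity bounce-back on inlet faces and extrapolated
populations on outlet faces.  Indices wrap periodically; non-periodic
domains simply carry solid/inlet/outlet cells on their boundary planes so
the wrap is never observed.

Interior cells whose full neighbourhood is fluid take a branch-free gather
path (the BULK marking below); everything else goes through the general
per-link logic.  The collision step conserves density and momentum per cell
by construction; kernels use plain double arithmetic (no fast-math) so
those invariants hold to round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .geometry import FLUID, INLET, OUTLET, SOLID, WALL_MOVING  # noqa: F401
from .stencil import C

#: kernel-private refinement of FLUID: an interior cell (not on the array
#: boundary) whose 19 neighbours are all fluid, eligible for the branch-free
#: streaming path.  Never appears in user-visible flag fields.
BULK = 5

_Q = 19


def refine_bulk(flags: np.ndarray) -> np.ndarray:
    """Return a kernel flag array with interior all-fluid cells marked BULK."""
    kf = flags.copy()
    fluid = flags == FLUID
    ok = np.zeros_like(fluid)
    ok[1:-1, 1:-1, 1:-1] = True
    nx, ny, nz = flags.shape
    padded = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
    padded[1:-1, 1:-1, 1:-1] = fluid
    allf = fluid.copy()
    for cx, cy, cz in C[1:]:
        allf &= padded[
            1 + cx: nx + 1 + cx, 1 + cy: ny + 1 + cy, 1 + cz: nz + 1 + cz
        ]
    kf[fluid & ok & allf] = BULK
    return kf


@njit(cache=True)
def collide_bgk(f, fpost, flags, CXf, CYf, CZf, W, omega, fx, fy, fz):
    """BGK collision with Guo forcing; fills ``fpost`` on fluid cells."""
    nx, ny, nz, _ = f.shape
    half_om = 1.0 - 0.5 * omega
    omr = 1.0 - omega
    forced = fx != 0.0 or fy != 0.0 or fz != 0.0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                flg = flags[ix, iy, iz]
                if flg != FLUID and flg != BULK:
                    continue
                fr = f[ix, iy, iz]
                po = fpost[ix, iy, iz]
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(_Q):
                    fi = fr[i]
                    rho += fi
                    mx += fi * CXf[i]
                    my += fi * CYf[i]
                    mz += fi * CZf[i]
                inv = 1.0 / rho
                ux = (mx + 0.5 * fx) * inv
                uy = (my + 0.5 * fy) * inv
                uz = (mz + 0.5 * fz) * inv
                usq = 1.5 * (ux * ux + uy * uy + uz * uz)
                for i in range(_Q):
                    cu = 3.0 * (CXf[i] * ux + CYf[i] * uy + CZf[i] * uz)
                    feq = W[i] * rho * (1.0 + cu + 0.5 * cu * cu - usq)
                    val = omr * fr[i] + omega * feq
                    if forced:
                        cf = CXf[i] * fx + CYf[i] * fy + CZf[i] * fz
                        val += half_om * W[i] * (
                            3.0 * (cf - (ux * fx + uy * fy + uz * fz))
                            + 3.0 * cu * cf
                        )
                    po[i] = val


@njit(cache=True)
def collide_mrt(f, fpost, flags, CXf, CYf, CZf, W, A):
    """Multiple-relaxation-time collision, ``f + A (f_eq - f)`` per cell."""
    nx, ny, nz, _ = f.shape
    g = np.empty(_Q)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                flg = flags[ix, iy, iz]
                if flg != FLUID and flg != BULK:
                    continue
                fr = f[ix, iy, iz]
                po = fpost[ix, iy, iz]
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(_Q):
                    fi = fr[i]
                    rho += fi
                    mx += fi * CXf[i]
                    my += fi * CYf[i]
                    mz += fi * CZf[i]
                inv = 1.0 / rho
                ux = mx * inv
                uy = my * inv
                uz = mz * inv
                usq = 1.5 * (ux * ux + uy * uy + uz * uz)
                for i in range(_Q):
                    cu = 3.0 * (CXf[i] * ux + CYf[i] * uy + CZf[i] * uz)
                    feq = W[i] * rho * (1.0 + cu + 0.5 * cu * cu - usq)
                    g[i] = feq - fr[i]
                for i in range(_Q):
                    acc = 0.0
                    for k in range(_Q):
                        acc += A[i, k] * g[k]
                    po[i] = fr[i] + acc


@njit(cache=True)
def fill_outlet(fpost, flags, out_idx, CXf, CYf, CZf, W, out_dir, rho0,
                extrapolation_order):
    """Populate the outlet layer from the inward axial neighbour.

    ``extrapolation_order = 1``: copy the neighbour's populations and shift
    them so the layer density equals the reference (zero gauge pressure).
    ``extrapolation_order = 0``: reconstruct the layer at local equilibrium
    with the neighbour's velocity and the reference density, additionally
    suppressing re-entrant axial flow (``u_z`` clipped towards outflow) —
    the robust choice when recirculation reaches a truncated outlet.
    """
    n = out_idx.shape[0]
    for m in range(n):
        ix = out_idx[m, 0]
        iy = out_idx[m, 1]
        iz = out_idx[m, 2]
        kz = iz - out_dir
        nf = flags[ix, iy, kz]
        if nf == FLUID or nf == BULK:
            rho = 0.0
            mx = 0.0
            my = 0.0
            mz = 0.0
            for i in range(_Q):
                fi = fpost[ix, iy, kz, i]
                rho += fi
                mx += fi * CXf[i]
                my += fi * CYf[i]
                mz += fi * CZf[i]
            if extrapolation_order == 1:
                for i in range(_Q):
                    fpost[ix, iy, iz, i] = (
                        fpost[ix, iy, kz, i] + W[i] * (rho0 - rho)
                    )
            else:
                inv = 1.0 / rho
                ux = mx * inv
                uy = my * inv
                uz = mz * inv
                if out_dir > 0 and uz < 0.0:
                    uz = 0.0
                elif out_dir < 0 and uz > 0.0:
                    uz = 0.0
                usq = 1.5 * (ux * ux + uy * uy + uz * uz)
                for i in range(_Q):
                    cu = 3.0 * (CXf[i] * ux + CYf[i] * uy + CZf[i] * uz)
                    fpost[ix, iy, iz, i] = W[i] * rho0 * (
                        1.0 + cu + 0.5 * cu * cu - usq
                    )
        else:
            for i in range(_Q):
                fpost[ix, iy, iz, i] = W[i] * rho0


@njit(cache=True)
def stream(
    fpost,
    fnew,
    flags,
    q,
    Carr,
    W,
    OPP,
    inlet_umax,
    inlet_ax_x,
    inlet_ax_y,
    inlet_r2,
    inlet_dir,
    wall_ux,
    wall_uy,
    wall_uz,
    rho0,
):
    """Pull streaming with Bouzidi walls, inlet velocity BB, outlet pull.

    ``inlet_umax`` is the (ramped) centreline lattice velocity of the
    parabolic inflow profile, ``2 * u_mean``; the profile is evaluated at the
    cut-link midpoint on the inlet face.  ``inlet_dir`` is the axial flow
    direction (+1 for an inlet on the low-z face).
    """
    nx, ny, nz, _ = fpost.shape
    flat_post = fpost.reshape(-1)
    offs = np.empty(_Q, np.int64)
    for i in range(_Q):
        offs[i] = (-(Carr[i, 0] * ny + Carr[i, 1]) * nz - Carr[i, 2]) * _Q + i
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                flg = flags[ix, iy, iz]
                if flg == BULK:
                    base = (((ix * ny) + iy) * nz + iz) * _Q
                    out = fnew[ix, iy, iz]
                    for i in range(_Q):
                        out[i] = flat_post[base + offs[i]]
                    continue
                if flg != FLUID:
                    continue
                for i in range(_Q):
                    cx = Carr[i, 0]
                    cy = Carr[i, 1]
                    cz = Carr[i, 2]
                    sx = ix - cx
                    sy = iy - cy
                    sz = iz - cz
                    if sx < 0:
                        sx += nx
                    elif sx >= nx:
                        sx -= nx
                    if sy < 0:
                        sy += ny
                    elif sy >= ny:
                        sy -= ny
                    if sz < 0:
                        sz += nz
                    elif sz >= nz:
                        sz -= nz
                    sf = flags[sx, sy, sz]
                    if sf == FLUID or sf == BULK or sf == OUTLET:
                        fnew[ix, iy, iz, i] = fpost[sx, sy, sz, i]
                    elif sf == INLET:
                        j = OPP[i]
                        # parabolic target at the link midpoint on the face
                        px = ix + 0.5 * Carr[j, 0] - inlet_ax_x
                        py = iy + 0.5 * Carr[j, 1] - inlet_ax_y
                        r2 = px * px + py * py
                        uw = inlet_umax * (1.0 - r2 / inlet_r2)
                        if uw < 0.0:
                            uw = 0.0
                        uwz = inlet_dir * uw
                        term = 6.0 * W[j] * rho0 * (Carr[j, 2] * uwz)
                        fnew[ix, iy, iz, i] = fpost[ix, iy, iz, j] - term
                    else:
                        # wall: interpolated bounce-back on the cut link
                        j = OPP[i]
                        qv = q[ix, iy, iz, j]
                        if not (qv > 0.0):  # NaN or missing -> half-way
                            qv = 0.5
                        if qv < 0.5:
                            ux2 = ix + cx
                            uy2 = iy + cy
                            uz2 = iz + cz
                            if ux2 < 0:
                                ux2 += nx
                            elif ux2 >= nx:
                                ux2 -= nx
                            if uy2 < 0:
                                uy2 += ny
                            elif uy2 >= ny:
                                uy2 -= ny
                            if uz2 < 0:
                                uz2 += nz
                            elif uz2 >= nz:
                                uz2 -= nz
                            uf = flags[ux2, uy2, uz2]
                            if uf == FLUID or uf == BULK:
                                val = (
                                    2.0 * qv * fpost[ix, iy, iz, j]
                                    + (1.0 - 2.0 * qv) * fpost[ux2, uy2, uz2, j]
                                )
                            else:
                                val = fpost[ix, iy, iz, j]
                                qv = 0.5
                        else:
                            inv = 1.0 / (2.0 * qv)
                            val = (
                                inv * fpost[ix, iy, iz, j]
                                + (2.0 * qv - 1.0) * inv * fpost[ix, iy, iz, i]
                            )
                        if sf == WALL_MOVING:
                            b = 3.0 * W[j] * rho0 * (
                                Carr[j, 0] * wall_ux
                                + Carr[j, 1] * wall_uy
                                + Carr[j, 2] * wall_uz
                            )
                            if qv < 0.5:
                                val -= 2.0 * b
                            else:
                                val -= b / qv
                        fnew[ix, iy, iz, i] = val
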