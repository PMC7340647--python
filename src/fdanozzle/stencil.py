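"""D3Q19 lattice stencil and the multiple-relaxation-time moment basis.

The stencil carries 19 discrete velocities: one rest vector, six along the
coordinate axes and twelve along the face diagonals.  The speed of sound at
reference state satisfies ``c_s^2 = 1/3`` in lattice units.  The moment basis
is the standard d'Humieres set for D3Q19: density, kinetic energy and its
square, momentum and heat-flux vectors, the five viscous-stress moments and
three third-order moments.  Rows of the transformation matrix ``M`` are
mutually orthogonal with respect to the plain dot product, so the inverse is
``M^T`` scaled by the row norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CS2: float = 1.0 / 3.0

# Discrete velocities: rest, axis-aligned, face diagonals.
C: np.ndarray = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

W: np.ndarray = np.array(
    [1.0 / 3.0]
    + [1.0 / 18.0] * 6
    + [1.0 / 36.0] * 12
)

Q: int = 19

# Index of the opposite (bounce-back) direction for each link.
OPP: np.ndarray = np.array(
    [int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C], dtype=np.int64
)

#: Indices of the five viscous (second-order) moments in the d'Humieres basis.
VISCOUS_MOMENTS = (9, 11, 13, 14, 15)
#: Indices of the conserved moments (density and momentum).
CONSERVED_MOMENTS = (0, 3, 5, 7)


def moment_matrix() -> np.ndarray:
    """Return the 19x19 d'Humieres moment transformation matrix for D3Q19."""
    cx, cy, cz = C[:, 0].astype(float), C[:, 1].astype(float), C[:, 2].astype(float)
    c2 = cx * cx + cy * cy + cz * cz
    rows = [
        np.ones(Q),                       # density
        19.0 * c2 - 30.0,                 # kinetic energy e
        (21.0 * c2 * c2 - 53.0 * c2 + 24.0) / 2.0,  # e^2
        cx,                               # j_x
        (5.0 * c2 - 9.0) * cx,            # q_x
        cy,                               # j_y
        (5.0 * c2 - 9.0) * cy,            # q_y
        cz,                               # j_z
        (5.0 * c2 - 9.0) * cz,            # q_z
        3.0 * cx * cx - c2,               # 3 p_xx
        (3.0 * c2 - 5.0) * (3.0 * cx * cx - c2),  # 3 pi_xx
        cy * cy - cz * cz,                # p_ww
        (3.0 * c2 - 5.0) * (cy * cy - cz * cz),   # pi_ww
        cx * cy,                          # p_xy
        cy * cz,                          # p_yz
        cx * cz,                          # p_xz
        (cy * cy - cz * cz) * cx,         # m_x
        (cz * cz - cx * cx) * cy,         # m_y
        (cx * cx - cy * cy) * cz,         # m_z
    ]
    return np.array(rows)


_M = moment_matrix()
_MINV = _M.T / (_M * _M).sum(axis=1)


@dataclass(frozen=True)
class MRTConfig:
    """Relaxation configuration for the MRT collision operator.

    ``omega`` is the principal rate fixing the kinematic viscosity through
    the viscous moments.  ``rates`` holds all 19 per-moment rates; conserved
    moments carry rate 0 (they are unaffected by collision).  By default every
    non-conserved moment relaxes at ``omega``, which reduces the operator
    exactly to the single-relaxation-time (BGK) form.  Use
    :func:`dhumieres_rates` for the classical stabilised rate set.
    """

    omega: float
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 2.0:
            raise ValueError(f"omega={self.omega} outside stability domain (0, 2)")
        if self.rates is None:
            r = np.full(Q, self.omega)
        else:
            r = np.asarray(self.rates, dtype=float).copy()
            if r.shape != (Q,):
                raise ValueError("rates must have 19 entries")
        r[list(CONSERVED_MOMENTS)] = 0.0
        r[list(VISCOUS_MOMENTS)] = self.omega
        object.__setattr__(self, "rates", r)

    @property
    def is_srt(self) -> bool:
        """True when all non-conserved rates equal the principal rate."""
        mask = np.ones(Q, dtype=bool)
        mask[list(CONSERVED_MOMENTS)] = False
        return bool(np.all(self.rates[mask] == self.omega))

    def collision_matrix(self) -> np.ndarray:
        """Velocity-space collision matrix ``A = M^-1 diag(s) M``.

        The post-collision state is ``f + A (f_eq - f)``.
        """
        return _MINV @ (self.rates[:, None] * _M)


def dhumieres_rates(omega: float) -> np.ndarray:
    """Classical d'Humieres rate set with viscous moments at ``omega``."""
    s = np.full(Q, omega)
    s[list(CONSERVED_MOMENTS)] = 0.0
    s[1] = 1.19    # kinetic energy
    s[2] = 1.4     # energy squared
    s[4] = s[6] = s[8] = 1.2   # heat flux
    s[10] = s[12] = 1.4        # fourth-order
    s[16] = s[17] = s[18] = 1.98  # third-order
    return s


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium on the D3Q19 stencil.

    Parameters
    ----------
    rho : array, shape (...)
        Density field (lattice units).
    u : array, shape (..., 3)
        Velocity field (lattice units).

    Returns
    -------
    array, shape (..., 19)
        ``f_eq_i = w_i rho (1 + c.u/cs2 + (c.u)^2/(2 cs4) - u^2/(2 cs2))``.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    cu = u @ C.T.astype(float)            # (..., 19)
    usq = (u * u).sum(axis=-1)[..., None]
    return W * rho[..., None] * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
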