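"""Parametric sudden-expansion nozzle geometry, voxelization and wall links.

The benchmark device is a cylindrical pipe (diameter 12 mm) with a conical
contraction (10 degree half-angle) into a 4 mm throat of length 40 mm,
followed by a sudden expansion back to 12 mm.  The axial coordinate places
``z = 0`` at the sudden-expansion plane, so the throat occupies
``[-0.04, 0)`` m.  Radial profiles are compared at twelve axial measurement
stations.

Voxelization is cell-centred on a uniform lattice whose cross-section is
arranged so that the symmetry axis passes through a cell corner; a cell is
fluid when its centre lies strictly inside the analytic surface.  For the
curved-wall boundary condition, each fluid-to-solid lattice link stores the
fraction ``q in (0, 1]`` of the link cut off by the analytic surface,
obtained by bisection on the inside/outside predicate (converged to
``~1e-15`` of the link length).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stencil import C, Q

# Cell classification flags (shared with the solver kernels).
SOLID, FLUID, INLET, OUTLET, WALL_MOVING = 0, 1, 2, 3, 4

#: The twelve axial measurement stations [m], z6 = 0 at the expansion plane.
STATIONS_Z: tuple[float, ...] = (
    -0.088, -0.064, -0.048, -0.02, -0.008, 0.0,
    0.008, 0.016, 0.024, 0.032, 0.06, 0.08,
)


class GeometryError(ValueError):
    """Inconsistent geometric request (out of range, under-resolved...)."""


@dataclass(frozen=True)
class StationSet:
    """Ordered axial measurement stations."""

    z: tuple[float, ...] = STATIONS_Z

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.z, self.z[1:])):
            raise GeometryError("stations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.z)

    def bracket(self, z: float) -> tuple[float, float] | None:
        """Adjacent station pair (z_i, z_j) with z_i <= z < z_j, if any."""
        for a, b in zip(self.z, self.z[1:]):
            if a <= z < b:
                return (a, b)
        return None


@dataclass(frozen=True)
class NozzleGeometry:
    """Analytic sudden-expansion nozzle as a surface of revolution.

    The radius profile is right-continuous at the expansion plane: the limit
    from upstream equals the throat radius while ``r(0)`` already takes the
    outlet value.
    """

    throat_radius: float = 0.002
    inlet_radius: float = 0.006
    outlet_radius: float = 0.006
    throat_length: float = 0.04
    cone_half_angle_deg: float = 10.0
    z_min: float = -0.14
    z_max: float = 0.253

    @property
    def throat_diameter(self) -> float:
        return 2.0 * self.throat_radius

    @property
    def z_expansion(self) -> float:
        return 0.0

    @property
    def z_throat_start(self) -> float:
        return -self.throat_length

    @property
    def cone_length(self) -> float:
        return (self.inlet_radius - self.throat_radius) / math.tan(
            math.radians(self.cone_half_angle_deg)
        )

    @property
    def z_cone_start(self) -> float:
        return self.z_throat_start - self.cone_length

    def radius_profile(self, z: np.ndarray) -> np.ndarray:
        """Vectorized analytic radius r(z) (no range check)."""
        z = np.asarray(z, dtype=float)
        slope = math.tan(math.radians(self.cone_half_angle_deg))
        return np.select(
            [
                z >= self.z_expansion,
                z >= self.z_throat_start,
                z >= self.z_cone_start,
            ],
            [
                self.outlet_radius,
                self.throat_radius,
                self.throat_radius + (self.z_throat_start - z) * slope,
            ],
            default=self.inlet_radius,
        )

    def radius_at(self, z: float) -> float:
        """Analytic radius at axial position ``z`` (range-checked)."""
        if not self.z_min <= z <= self.z_max:
            raise GeometryError(f"z={z} outside [{self.z_min}, {self.z_max}]")
        return float(self.radius_profile(z))

    def inside(self, x, y, z) -> np.ndarray:
        """True where the point lies strictly inside the wetted surface."""
        r = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return r < self.radius_profile(z)


@dataclass(frozen=True)
class CylinderGeometry:
    """Straight circular pipe; shares the voxelization machinery.

    ``center`` shifts the axis off the default cell-corner position, which
    changes how the circle cuts the lattice without changing the physics —
    used to average out voxelization luck in convergence studies.
    """

    radius: float
    z_min: float
    z_max: float
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def throat_radius(self) -> float:
        return self.radius

    @property
    def throat_diameter(self) -> float:
        return 2.0 * self.radius

    def radius_profile(self, z: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(z, dtype=float), self.radius)

    def radius_at(self, z: float) -> float:
        if not self.z_min <= z <= self.z_max:
            raise GeometryError(f"z={z} outside [{self.z_min}, {self.z_max}]")
        return self.radius

    def inside(self, x, y, z) -> np.ndarray:
        r = np.hypot(
            np.asarray(x, dtype=float) - self.center[0],
            np.asarray(y, dtype=float) - self.center[1],
        )
        return (r < self.radius) & np.ones_like(np.asarray(z, dtype=float), dtype=bool)


@dataclass
class FlagField:
    """Voxel classification plus per-link wall distances.

    ``flags`` has shape (nx, ny, nz); ``q`` has shape (nx, ny, nz, 19) and is
    NaN on links that are not cut by a wall.  ``origin`` is the physical
    coordinate of the centre of cell (0, 0, 0); the symmetry axis lies at
    x = y = 0, between cell columns.
    """

    flags: np.ndarray
    dx: float
    origin: tuple[float, float, float]
    q: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape  # type: ignore[return-value]

    def cell_centers(self):
        """Coordinate vectors (x, y, z) of the cell centres."""
        nx, ny, nz = self.shape
        x = self.origin[0] + self.dx * np.arange(nx)
        y = self.origin[1] + self.dx * np.arange(ny)
        z = self.origin[2] + self.dx * np.arange(nz)
        return x, y, z

    def plane_index(self, z: float) -> int:
        """Index of the lattice plane nearest to axial position ``z``."""
        k = int(round((z - self.origin[2]) / self.dx))
        if not 0 <= k < self.shape[2]:
            raise GeometryError(f"z={z} outside the voxelized extent")
        return k

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            flags=self.flags,
            q=self.q if self.q is not None else np.array([]),
            dx=self.dx,
            origin=np.array(self.origin),
            meta=np.array([json.dumps(self.meta)]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FlagField":
        d = np.load(path, allow_pickle=False)
        q = d["q"] if d["q"].size else None
        return cls(
            flags=d["flags"],
            dx=float(d["dx"]),
            origin=tuple(float(v) for v in d["origin"]),
            q=q,
            meta=json.loads(str(d["meta"][0])),
        )


def voxelize(
    geometry,
    dx: float,
    *,
    z_range: tuple[float, float] | None = None,
    pad: int = 1,
    min_cells: int = 4,
    check_connectivity: bool = True,
) -> FlagField:
    """Voxelize a surface of revolution onto a uniform lattice.

    Cell centres strictly inside the surface become fluid; the first and last
    axial planes are flagged inlet and outlet over their wetted cross-section.
    ``z_range`` truncates the axial extent (defaults to the full geometry).
    """
    if z_range is None:
        z_range = (geometry.z_min, geometry.z_max)
    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise GeometryError("empty z_range")

    nz = int(round((z_hi - z_lo) / dx))
    if nz < 3:
        raise GeometryError("z_range shorter than 3 cells")
    zc = z_lo + dx * (np.arange(nz) + 0.5)
    r_of_z = geometry.radius_profile(zc)
    if 2.0 * r_of_z.min() / dx < min_cells:
        raise GeometryError(
            f"dx={dx} leaves fewer than {min_cells} cells across the narrowest "
            f"section (diameter {2 * r_of_z.min()} m)"
        )

    r_max = float(r_of_z.max())
    half = int(math.ceil(r_max / dx)) + pad
    nx = ny = 2 * half
    xc = dx * (np.arange(nx) - half + 0.5)
    yc = dx * (np.arange(ny) - half + 0.5)

    inside = geometry.inside(
        xc[:, None, None], yc[None, :, None], zc[None, None, :]
    )                                                 # (nx, ny, nz)

    flags = np.where(inside, FLUID, SOLID).astype(np.uint8)
    flags[:, :, 0][inside[:, :, 0]] = INLET
    flags[:, :, -1][inside[:, :, -1]] = OUTLET

    if check_connectivity:
        wet = flags != SOLID
        _, n_comp = ndimage.label(wet, structure=ndimage.generate_binary_structure(3, 1))
        if n_comp != 1:
            raise GeometryError(f"fluid region has {n_comp} connected components")

    origin = (float(xc[0]), float(yc[0]), float(zc[0]))
    return FlagField(
        flags=flags,
        dx=dx,
        origin=origin,
        meta={
            "z_range": (float(z_lo), float(z_hi)),
            "axis_index": half - 0.5,
            "geometry": type(geometry).__name__,
        },
    )


def wall_link_distances(geometry, ff: FlagField) -> FlagField:
    """Fill ``ff.q`` with wall-cut fractions against the analytic surface.

    For every fluid cell whose neighbour along link ``c_j`` is solid,
    ``q[j] = |centre -> surface| / |link|``, found by bisection on the
    geometry's inside/outside predicate.  Fluid centres are strictly inside
    and solid centres are not, so a sign change is guaranteed.
    """
    nx, ny, nz = ff.shape
    q = np.full((nx, ny, nz, Q), np.nan)
    x, y, z = ff.cell_centers()
    # padded flags: outside the array counts as solid
    padded = np.zeros((nx + 2, ny + 2, nz + 2), dtype=np.uint8)
    padded[1:-1, 1:-1, 1:-1] = ff.flags
    fluid = ff.flags == FLUID

    for j in range(1, Q):
        cx, cy, cz = (int(v) for v in C[j])
        nb = padded[
            1 + cx : nx + 1 + cx,
            1 + cy : ny + 1 + cy,
            1 + cz : nz + 1 + cz,
        ]
        cut = fluid & (nb == SOLID)
        if not cut.any():
            continue
        ii, jj, kk = np.nonzero(cut)
        p0 = np.stack([x[ii], y[jj], z[kk]], axis=1)
        link = ff.dx * np.array([cx, cy, cz], dtype=float)

        lo = np.zeros(len(ii))
        hi = np.ones(len(ii))
        # fluid centre inside, solid centre outside -> bisect the transition
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            pm = p0 + mid[:, None] * link
            ins = geometry.inside(pm[:, 0], pm[:, 1], pm[:, 2])
            lo = np.where(ins, mid, lo)
            hi = np.where(ins, hi, mid)
        qj = 0.5 * (lo + hi)
        # a centre exactly on the surface is excluded by strict insideness,
        # so q is positive; clamp the upper end to 1 for neighbours on the wall
        q[ii, jj, kk, j] = np.minimum(qj, 1.0)

    ff.q = q
    return ff


@dataclass(frozen=True)
class StationMask:
    """Lattice addressing of one measurement station."""

    z_request: float
    z_actual: float
    plane: int
    cross_section: np.ndarray        # (nx, ny) bool over wetted cells
    radial_rows: tuple[int, int]     # the two y-rows bracketing the axis
    centerline_cells: tuple[tuple[int, int], ...]  # 4 (ix, iy) columns nearest axis


def station_profiles_mask(ff: FlagField, stations: StationSet | None = None):
    """Map stations to lattice planes, cross-section masks and axis cells."""
    stations = stations or StationSet()
    nx, ny, _ = ff.shape
    rows = (ny // 2 - 1, ny // 2)
    center = tuple(
        (ix, iy) for ix in (nx // 2 - 1, nx // 2) for iy in rows
    )
    out = []
    for z in stations.z:
        k = ff.plane_index(z)
        cross = ff.flags[:, :, k] != SOLID
        if not cross.any():
            raise GeometryError(f"station z={z} has no wetted cells")
        _, _, zc = ff.cell_centers()
        out.append(
            StationMask(
                z_request=z,
                z_actual=float(zc[k]),
                plane=k,
                cross_section=cross,
                radial_rows=rows,
                centerline_cells=center,
            )
        )
    return out


def cells_across_diameter(ff: FlagField, z: float) -> int:
    """Fluid-cell count along a diameter of the cross-section at ``z``."""
    k = ff.plane_index(z)
    ny = ff.shape[1]
    row = ff.flags[:, ny // 2, k]
    return int(np.count_nonzero(row != SOLID))


def stations_to_csv(path: str | Path, stations: StationSet | None = None) -> None:
    stations = stations or StationSet()
    with open(path, "w") as fh:
        fh.write("station,z_m\n")
        for i, z in enumerate(stations.z, start=1):
            fh.write(f"z{i},{z}\n")


def _mesh_contains_grid(vertices, faces, xc, yc, zc) -> np.ndarray:
    """Even-odd containment of grid cell centres in a watertight mesh.

    Casts one +z ray per (x, y) column and toggles parity at every triangle
    crossing; vectorized over columns per triangle.  Column positions are
    nudged by a tiny epsilon so rays avoid triangle edges.
    """
    nx, ny, nz = len(xc), len(yc), len(zc)
    scale = max(np.ptp(xc), np.ptp(yc), 1e-30)
    eps = 1e-7 * scale
    X, Y = np.meshgrid(xc + eps, yc + 2 * eps, indexing="ij")
    cross_count = np.zeros((nx, ny, nz), dtype=np.int64)
    tri = vertices[faces]                     # (ntri, 3, 3)
    for v0, v1, v2 in tri:
        lox, hix = min(v0[0], v1[0], v2[0]), max(v0[0], v1[0], v2[0])
        loy, hiy = min(v0[1], v1[1], v2[1]), max(v0[1], v1[1], v2[1])
        isel = (X >= lox) & (X <= hix) & (Y >= loy) & (Y <= hiy)
        if not isel.any():
            continue
        px, py = X[isel], Y[isel]
        d = (v1[1] - v2[1]) * (v0[0] - v2[0]) + (v2[0] - v1[0]) * (v0[1] - v2[1])
        if d == 0.0:
            continue  # degenerate in projection: grazing, no parity toggle
        a = ((v1[1] - v2[1]) * (px - v2[0]) + (v2[0] - v1[0]) * (py - v2[1])) / d
        b = ((v2[1] - v0[1]) * (px - v2[0]) + (v0[0] - v2[0]) * (py - v2[1])) / d
        c = 1.0 - a - b
        hit = (a >= 0) & (b >= 0) & (c >= 0)
        if not hit.any():
            continue
        z_hit = a[hit] * v0[2] + b[hit] * v1[2] + c[hit] * v2[2]
        ii, jj = np.nonzero(isel)
        ii, jj = ii[hit], jj[hit]
        # a crossing below a cell centre toggles that cell's parity
        k0 = np.searchsorted(zc, z_hit, side="right")
        for i, j, k in zip(ii, jj, k0):
            if k < nz:
                cross_count[i, j, k:] += 1
    return (cross_count % 2) == 1


def voxelize_stl(
    path: str | Path,
    dx: float,
    *,
    pad: int = 1,
    check_connectivity: bool = True,
) -> FlagField:
    """Voxelize a watertight triangulated surface (STL, ASCII or binary).

    Optional parity path with the analytic geometry; STL parsing goes
    through ``trimesh``, containment through an internal even-odd ray test.
    The flow axis is assumed to be z; the first and last wetted planes are
    flagged inlet and outlet.
    """
    try:
        import trimesh
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("STL voxelization requires the optional 'trimesh' extra") from exc

    mesh = trimesh.load_mesh(str(path))
    (x0, y0, z0), (x1, y1, z1) = mesh.bounds
    cxm, cym = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    half = int(math.ceil(max(x1 - x0, y1 - y0) / 2.0 / dx)) + pad
    nx = ny = 2 * half
    nz = int(round((z1 - z0) / dx))
    xc = cxm + dx * (np.arange(nx) - half + 0.5)
    yc = cym + dx * (np.arange(ny) - half + 0.5)
    zc = z0 + dx * (np.arange(nz) + 0.5)
    inside = _mesh_contains_grid(
        np.asarray(mesh.vertices, dtype=float),
        np.asarray(mesh.faces, dtype=np.int64),
        xc, yc, zc,
    )

    flags = np.where(inside, FLUID, SOLID).astype(np.uint8)
    flags[:, :, 0][inside[:, :, 0]] = INLET
    flags[:, :, -1][inside[:, :, -1]] = OUTLET
    if check_connectivity:
        wet = flags != SOLID
        _, n_comp = ndimage.label(wet, structure=ndimage.generate_binary_structure(3, 1))
        if n_comp != 1:
            raise GeometryError(f"fluid region has {n_comp} connected components")
    return FlagField(
        flags=flags,
        dx=dx,
        origin=(float(xc[0]), float(yc[0]), float(zc[0])),
        meta={"source": str(path)},
    )
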