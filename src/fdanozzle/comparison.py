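"""Comparison observables and PIV-style reference datasets.

Extracts the benchmark's comparison quantities from time-averaged fields —
centreline velocity, radial profiles, section-averaged normalized pressure,
normalized shear stress, and an operational jet-breakdown locator — and
quantifies agreement with particle-image-velocimetry (PIV) reference data
via simple relative percentage errors
``delta = |(U_ref - U_h) / U_ref| * 100``.

Reference datasets use a long-format CSV dialect with columns
``experiment, quantity, z_m, r_m, value`` where ``quantity`` is one of
``u_z_m_s`` (axial velocity), ``p_Pa`` (pressure) or ``tau_Pa`` (shear);
centreline entries carry ``r_m = 0``.  Experiments without pressure data are
tolerated (the benchmark archive itself has such gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FlagField, SOLID, StationSet

PIV_COLUMNS = ("experiment", "quantity", "z_m", "r_m", "value")
PIV_QUANTITIES = ("u_z_m_s", "p_Pa", "tau_Pa")


class ComparisonError(ValueError):
    pass


class PIVParseError(ComparisonError):
    pass


@dataclass
class PIVDataset:
    """One laboratory experiment: per-station profiles and centreline data."""

    experiment: str
    table: pd.DataFrame   # long format, validated

    @property
    def has_pressure(self) -> bool:
        return bool((self.table["quantity"] == "p_Pa").any())

    def centerline_velocity(self) -> pd.DataFrame:
        t = self.table
        sel = (t["quantity"] == "u_z_m_s") & (t["r_m"] == 0.0)
        return t[sel][["z_m", "value"]].reset_index(drop=True)

    def radial_profile(self, z: float, quantity: str = "u_z_m_s",
                       atol: float = 1e-9) -> pd.DataFrame:
        t = self.table
        sel = (t["quantity"] == quantity) & (np.abs(t["z_m"] - z) <= atol)
        return t[sel][["r_m", "value"]].reset_index(drop=True)

    def pressure(self) -> pd.DataFrame | None:
        if not self.has_pressure:
            return None
        t = self.table
        return t[t["quantity"] == "p_Pa"][["z_m", "value"]].reset_index(drop=True)


@dataclass
class PressureProfile:
    z: np.ndarray
    p: np.ndarray              # section-averaged gauge pressure [Pa]
    z0: float
    p0: float
    dp_norm: np.ndarray        # (p - p0) / (0.5 rho u^2)


@dataclass
class ComparisonReport:
    """Station-wise relative errors against one or more reference datasets."""

    errors: pd.DataFrame       # columns: experiment, quantity, z_m, delta_pct
    breakdown_z: float | None
    breakdown_bracket: tuple[float, float] | None
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.errors.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# profile extraction

def centerline_profile(ff: FlagField, u_mean_field: np.ndarray,
                       z_lo: float, z_hi: float, n_points: int = 86):
    """Mean axial velocity on the axis at ``n_points`` stations in [z_lo, z_hi].

    The axis passes between cell columns, so the value is the average of the
    four columns nearest the axis at the lattice plane closest to each
    requested position.
    """
    nx, ny, _ = ff.shape
    cols = [(nx // 2 - 1, ny // 2 - 1), (nx // 2 - 1, ny // 2),
            (nx // 2, ny // 2 - 1), (nx // 2, ny // 2)]
    if any(ff.flags[ix, iy, ff.plane_index(0.5 * (z_lo + z_hi))] == SOLID
           for ix, iy in cols):
        raise ComparisonError("axis is not inside the fluid at the mid-station")
    zq = np.linspace(z_lo, z_hi, n_points)
    uz = np.empty(n_points)
    for m, z in enumerate(zq):
        k = ff.plane_index(z)
        uz[m] = np.mean([u_mean_field[ix, iy, k, 2] for ix, iy in cols])
    return zq, uz


def radial_profile(ff: FlagField, u_field: np.ndarray, z: float,
                   normalization: float = 1.0):
    """Axial-velocity profile along a diameter at the station plane.

    Returns (r, u_z / normalization) over the wetted cells of the two
    x-rows bracketing the axis (averaged), positions at the cell centres.
    """
    k = ff.plane_index(z)
    if normalization == 0:
        raise ComparisonError("zero normalization velocity")
    nx, ny, _ = ff.shape
    x, _, _ = ff.cell_centers()
    rows = (ny // 2 - 1, ny // 2)
    wet = (ff.flags[:, rows[0], k] != SOLID) & (ff.flags[:, rows[1], k] != SOLID)
    if not wet.any():
        raise ComparisonError(f"station z={z} lies in solid")
    u = 0.5 * (u_field[:, rows[0], k, 2] + u_field[:, rows[1], k, 2])
    return x[wet], u[wet] / normalization


def section_mean(ff: FlagField, fieldvals: np.ndarray, z: float) -> float:
    """Area-weighted mean of a cell field over the wetted cross-section."""
    k = ff.plane_index(z)
    wet = ff.flags[:, :, k] != SOLID
    return float(fieldvals[:, :, k][wet].mean())


def normalized_pressure(p_sections: np.ndarray, z_sections: np.ndarray,
                        z0: float, rho: float, u_throat: float) -> PressureProfile:
    """Pressure difference normalized by the throat dynamic pressure.

    ``dp_norm = (p_z - p_z0) / (0.5 rho u^2)``; zero at the reference station.
    """
    if u_throat == 0:
        raise ComparisonError("zero throat velocity")
    z_sections = np.asarray(z_sections, dtype=float)
    p_sections = np.asarray(p_sections, dtype=float)
    i0 = int(np.argmin(np.abs(z_sections - z0)))
    p0 = p_sections[i0]
    dyn = 0.5 * rho * u_throat**2
    return PressureProfile(
        z=z_sections, p=p_sections, z0=float(z_sections[i0]), p0=float(p0),
        dp_norm=(p_sections - p0) / dyn,
    )


def normalized_shear(profile: np.ndarray) -> np.ndarray:
    """Shear profile divided by its mean magnitude; scale-invariant."""
    profile = np.asarray(profile, dtype=float)
    m = np.abs(profile).mean()
    if m == 0:
        raise ComparisonError("zero-mean shear profile")
    return profile / m


def relative_error(u_ref, u_h):
    """Percentage error ``|(U_ref - U_h)/U_ref| * 100``."""
    u_ref = np.asarray(u_ref, dtype=float)
    u_h = np.asarray(u_h, dtype=float)
    if np.any(u_ref == 0):
        raise ComparisonError("zero reference value in relative error")
    return np.abs((u_ref - u_h) / u_ref) * 100.0


def jet_breakdown_location(
    z: np.ndarray,
    tke: np.ndarray,
    u_ref: float,
    *,
    stations: StationSet | None = None,
    threshold: float = 0.1,
    floor: float = 1e-3,
    z_start: float = 0.0,
):
    """Operational jet-breakdown locator from a centreline TKE profile.

    The breakdown position is the first axial location downstream of
    ``z_start`` where the TKE exceeds ``threshold`` times its downstream
    maximum.  Profiles whose maximum stays below ``floor * u_ref^2`` are
    laminar and yield ``(None, None)``.  Raising the threshold can only move
    the estimate downstream.
    """
    z = np.asarray(z, dtype=float)
    tke = np.asarray(tke, dtype=float)
    sel = z >= z_start
    if not sel.any():
        return None, None
    zd, kd = z[sel], tke[sel]
    kmax = kd.max()
    if kmax < floor * u_ref**2:
        return None, None
    above = kd >= threshold * kmax
    zb = float(zd[np.argmax(above)])
    bracket = (stations or StationSet()).bracket(zb)
    return zb, bracket


# ---------------------------------------------------------------------------
# PIV dataset I/O

def read_piv_table(path: str | Path) -> PIVDataset:
    """Read and validate a reference dataset in the long CSV dialect."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:
        raise PIVParseError(f"{path}: {exc}") from exc
    missing = set(PIV_COLUMNS) - set(raw.columns)
    if missing:
        raise PIVParseError(f"{path}: missing columns {sorted(missing)}")
    table = raw.copy()
    for col in ("z_m", "r_m", "value"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            lineno = int(bad.idxmax()) + 2
            raise PIVParseError(f"{path}:{lineno}: non-numeric {col!r} value")
        table[col] = vals
    bad_q = ~table["quantity"].isin(PIV_QUANTITIES)
    if bad_q.any():
        lineno = int(bad_q.idxmax()) + 2
        raise PIVParseError(
            f"{path}:{lineno}: unknown quantity {table['quantity'][bad_q.idxmax()]!r} "
            f"(units must be one of {PIV_QUANTITIES})"
        )
    ids = table["experiment"].unique()
    if len(ids) != 1:
        raise PIVParseError(f"{path}: expected one experiment id, found {list(ids)}")
    return PIVDataset(experiment=str(ids[0]), table=table.reset_index(drop=True))


def write_piv_table(path: str | Path, dataset: PIVDataset, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        dataset.table.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# report assembly

def compare_centerline(
    z_sim: np.ndarray,
    u_sim: np.ndarray,
    datasets: list[PIVDataset],
) -> pd.DataFrame:
    """Station-wise relative errors of the simulated centreline velocity."""
    rows = []
    for ds in datasets:
        ref = ds.centerline_velocity()
        for _, row in ref.iterrows():
            zi = float(row["z_m"])
            if not (z_sim.min() <= zi <= z_sim.max()):
                continue
            uh = float(np.interp(zi, z_sim, u_sim))
            rows.append(
                {
                    "experiment": ds.experiment,
                    "quantity": "u_z_m_s",
                    "z_m": zi,
                    "delta_pct": float(relative_error(row["value"], uh)),
                }
            )
    return pd.DataFrame(rows, columns=["experiment", "quantity", "z_m", "delta_pct"])


def plot_centerline(z_sim, u_sim, datasets, path, ylabel="u_z [m/s]"):
    """Publication-style centreline comparison figure (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(z_sim, u_sim, "k-", lw=1.5, label="LBM")
    for ds in datasets:
        ref = ds.centerline_velocity()
        ax.plot(ref["z_m"], ref["value"], "o", ms=4, label=f"#{ds.experiment}")
    ax.set_xlabel("z [m]")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
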