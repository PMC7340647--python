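"""Staged pipeline: mesh -> run -> characterize -> compare.

Each stage reads only the previous stage's on-disk artifacts plus the run
configuration, writes its outputs into the run directory and appends to a
JSON manifest holding the config snapshot, a geometry checksum, stage
timings and a checksummed file inventory — enough to re-run bit-identically.

Configuration is a YAML mapping::

    fluid:    {density_kg_m3: 1056.0, dynamic_viscosity_Pa_s: 0.0035}
    case:     {re_throat: 500.0, cells_across_throat: 12, u_lattice: 0.08}
    geometry: {inlet_extension_m: 0.008, outlet_extension_m: 0.02}
    run:      {steps: 2000, ramp_steps: 300, sample_every: 10}

All derived lattice quantities are echoed into the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scaling as sc
from .characterization import (
    average_strain_over_stations,
    fluctuating_strain,
    kolmogorov_scales,
    resolution_quality,
    welch_psd,
)
from .comparison import (
    ComparisonReport,
    compare_centerline,
    jet_breakdown_location,
    plot_centerline,
    read_piv_table,
)
from .geometry import (
    FlagField,
    NozzleGeometry,
    StationSet,
    stations_to_csv,
    voxelize,
    wall_link_distances,
)
from .benchmarks import sim_centerline_tke
from .solver import InletSpec, Simulation, SolverConfig, gauge_pressure
from .vtk_io import write_vtk_image

MANIFEST = "manifest.json"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("fluid", {})
    cfg.setdefault("case", {})
    cfg.setdefault("geometry", {})
    cfg.setdefault("run", {})
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_load(outdir: Path) -> dict:
    p = outdir / MANIFEST
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}, "files": {}, "echo": {}}


def _manifest_save(outdir: Path, man: dict) -> None:
    (outdir / MANIFEST).write_text(json.dumps(man, indent=2, sort_keys=True))


def _register(man: dict, outdir: Path, *paths: Path) -> None:
    for p in paths:
        man["files"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}


def _fluid(cfg: dict) -> sc.FluidSpec:
    f = cfg["fluid"]
    return sc.FluidSpec(
        density=float(f.get("density_kg_m3", 1056.0)),
        dynamic_viscosity=float(f.get("dynamic_viscosity_Pa_s", 0.0035)),
    )


def _setup(cfg: dict):
    """Geometry, scaling and solver parameters shared by mesh and run."""
    geom = NozzleGeometry()
    case_cfg = cfg["case"]
    re_th = float(case_cfg.get("re_throat", 500.0))
    n_th = int(case_cfg.get("cells_across_throat", 12))
    u_lat = float(case_cfg.get("u_lattice", 0.08))
    dx = geom.throat_diameter / n_th
    nu_lat = u_lat * n_th / re_th
    omega = 1.0 / (3.0 * nu_lat + 0.5)
    case, lat = sc.build_case(_fluid(cfg), re_th, dx, omega, geom)
    g = cfg["geometry"]
    z_lo = geom.z_cone_start - float(g.get("inlet_extension_m", 0.008))
    z_hi = geom.z_expansion + float(g.get("outlet_extension_m", 0.02))
    return geom, case, lat, dx, omega, (z_lo, z_hi)


def cmd_mesh(cfg: dict, outdir: str | Path) -> Path:
    """Voxelize the nozzle, compute wall-link distances, persist the mesh."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    geom, case, lat, dx, omega, z_range = _setup(cfg)
    ff = voxelize(geom, dx, z_range=z_range)
    wall_link_distances(geom, ff)
    mesh_path = outdir / "mesh.npz"
    ff.save(mesh_path)
    st_path = outdir / "stations.csv"
    stations_to_csv(st_path, StationSet())

    man = _manifest_load(outdir)
    man["config"] = cfg
    man["echo"].update(
        {
            "dx_m": lat.dx,
            "dt_s": lat.dt,
            "omega": lat.omega,
            "nu_lattice": lat.nu_lattice,
            "u_lattice_throat": lat.u_lattice,
            "flow_through_time_s": case.flow_through_time,
            "cells_across_throat": int(round(geom.throat_diameter / dx)),
            "z_range_m": list(z_range),
            "shape": list(ff.shape),
        }
    )
    man["stages"]["mesh"] = {"seconds": time.time() - t0}
    _register(man, outdir, mesh_path, st_path)
    _manifest_save(outdir, man)
    return mesh_path


def cmd_run(cfg: dict, outdir: str | Path) -> Path:
    """Time-step the solver on a persisted mesh; write probes and fields."""
    outdir = Path(outdir)
    t0 = time.time()
    geom, case, lat, dx, omega, _ = _setup(cfg)
    ff = FlagField.load(outdir / "mesh.npz")

    run_cfg = cfg["run"]
    n_steps = int(run_cfg.get("steps", 2000))
    ramp = int(run_cfg.get("ramp_steps", max(1, n_steps // 8)))
    sample_every = int(run_cfg.get("sample_every", 10))

    half = ff.shape[0] // 2
    area_ratio = (geom.inlet_radius / geom.throat_radius) ** 2
    inlet = InletSpec(
        u_mean=lat.u_lattice / area_ratio,
        radius_cells=geom.inlet_radius / dx,
        axis=(half - 0.5, half - 0.5),
        ramp_steps=ramp,
    )
    sim = Simulation(ff, SolverConfig(omega=omega, inlet=inlet), scaling=lat)

    # probes: the four near-axis columns at every fourth lattice plane
    nx, ny, nz = ff.shape
    cols = [(nx // 2 - 1, ny // 2 - 1), (nx // 2 - 1, ny // 2),
            (nx // 2, ny // 2 - 1), (nx // 2, ny // 2)]
    probes = np.array(
        [(ix, iy, k) for k in range(1, nz - 1, 4) for ix, iy in cols],
        dtype=np.int64,
    )
    result = (
        sim.run(
            n_steps,
            sample_every=sample_every,
            probe_cells=probes,
            accumulate_after=int(0.6 * n_steps),
        )
        if n_steps > 0
        else None
    )

    written = []
    if result is not None and len(result.probe_steps):
        x, y, z = ff.cell_centers()
        conv_u = lat.dx / lat.dt
        rows = []
        for it, step in enumerate(result.probe_steps):
            for m, (ix, iy, k) in enumerate(probes):
                rows.append(
                    (
                        step * lat.dt,
                        x[ix], y[iy], z[k],
                        *(result.probe_u[it, m] * conv_u),
                        result.probe_rho[it, m],
                        float(gauge_pressure(result.probe_rho[it, m]))
                        * _fluid(cfg).density * conv_u**2,
                    )
                )
        probe_path = outdir / "probes.csv"
        pd.DataFrame(
            rows,
            columns=["t_s", "x", "y", "z", "ux", "uy", "uz", "rho", "p_gauge"],
        ).to_csv(probe_path, index=False)
        written.append(probe_path)

        fields_path = outdir / "fields.npz"
        np.savez_compressed(
            fields_path,
            u_mean=result.u_mean,
            u2_mean=result.u2_mean,
            rho_mean=result.rho_mean,
            n_samples=result.n_samples,
        )
        written.append(fields_path)

        rho, u = sim.macroscopic()
        vtk_path = outdir / "snapshot.vtk"
        write_vtk_image(
            vtk_path, lat.dx, ff.origin,
            scalars={"rho": rho}, vectors={"velocity": u * conv_u},
        )
        written.append(vtk_path)

    ckpt = outdir / "checkpoint.npz"
    np.savez_compressed(ckpt, f=sim.f, step=sim.step_count,
                        config=np.array([json.dumps(cfg)]))
    written.append(ckpt)

    man = _manifest_load(outdir)
    man["stages"]["run"] = {
        "seconds": time.time() - t0,
        "steps": n_steps,
        "final_residual": sim.residual_history[-1][1] if sim.residual_history else None,
    }
    _register(man, outdir, *written)
    _manifest_save(outdir, man)
    return outdir


def cmd_characterize(outdir: str | Path) -> Path:
    """Spectra, TKE and microscale report from a run directory."""
    outdir = Path(outdir)
    t0 = time.time()
    man = _manifest_load(outdir)
    cfg = man.get("config", {})
    geom, case, lat, dx, omega, _ = _setup(cfg)
    ff = FlagField.load(outdir / "mesh.npz")
    probes = pd.read_csv(outdir / "probes.csv")
    fields = np.load(outdir / "fields.npz")

    # Welch spectrum of the axial-velocity fluctuation at the probe nearest
    # the expansion plane, on the Strouhal abscissa
    zs = np.sort(probes["z"].unique())
    z_probe = zs[np.argmin(np.abs(zs))]
    series = (
        probes[probes["z"] == z_probe].groupby("t_s")["uz"].mean().sort_index()
    )
    t = series.index.to_numpy()
    fs = 1.0 / np.mean(np.diff(t)) if len(t) > 1 else 1.0
    sig = series.to_numpy()
    sig = sig - sig.mean()
    n_seg = min(8, max(2, len(sig) // 8))
    spec = welch_psd(sig, fs, d=case.throat_diameter,
                     u_mean=case.u_mean_throat, n_segments=n_seg)
    spec_path = outdir / "spectrum.csv"
    pd.DataFrame({"f_hz": spec.f, "st": spec.st, "psd": spec.psd}).to_csv(
        spec_path, index=False
    )

    # microscales from the instantaneous fluctuation field of the checkpoint
    ck = np.load(outdir / "checkpoint.npz")
    from .solver import macroscopic

    f = ck["f"]
    _, u_inst = macroscopic(f)
    uprime = np.nan_to_num(u_inst - fields["u_mean"])
    # nondimensionalize: velocities by the throat mean, lengths by d
    uprime_nd = uprime / lat.u_lattice
    _, S = fluctuating_strain(uprime_nd, dx=1.0 / (geom.throat_diameter / lat.dx))
    _, _, zc = ff.cell_centers()
    nxh, nyh = ff.shape[0] // 2, ff.shape[1] // 2
    S_line = S[nxh - 1: nxh + 1, nyh - 1: nyh + 1, :].mean(axis=(0, 1))
    z_lo_band = max(0.016, float(zc[1]))
    z_hi_band = min(0.08, float(zc[-2]))
    try:
        S_mean = average_strain_over_stations(S_line[None, :], zc, z_lo_band, z_hi_band)
        scales = kolmogorov_scales(S_mean, case.re_throat)
        eta_m, tau_s, ueta = scales.dimensional(case.throat_diameter, case.u_mean_throat)
        lp, tp = resolution_quality(lat.dx, lat.dt, eta_m, tau_s)
        kolmo = {
            "eta_m": eta_m, "tau_s": tau_s, "u_eta_m_s": ueta,
            "l_plus": lp, "t_plus": tp, "S_mean_nondim": S_mean,
        }
    except Exception as exc:  # zero strain on a fully laminar snapshot
        kolmo = {"error": str(exc)}

    # breakdown from the accumulated TKE
    from .solver import RunResult

    rr = RunResult(
        steps=0, probe_steps=np.empty(0), probe_u=np.empty((0, 0, 3)),
        probe_rho=np.empty((0, 0)), u_mean=fields["u_mean"],
        u2_mean=fields["u2_mean"], rho_mean=fields["rho_mean"],
        n_samples=int(fields["n_samples"]),
    )
    tke_line = sim_centerline_tke(ff, rr)
    zb, bracket = jet_breakdown_location(zc, tke_line, lat.u_lattice)

    report = {
        "kolmogorov": kolmo,
        "breakdown_z_m": zb,
        "breakdown_bracket": list(bracket) if bracket else None,
        "spectrum": {"nperseg": spec.nperseg, "n_segments": spec.n_segments,
                     "window": spec.window},
    }
    report_path = outdir / "characterization.json"
    report_path.write_text(json.dumps(report, indent=2))

    man["stages"]["characterize"] = {"seconds": time.time() - t0}
    _register(man, outdir, spec_path, report_path)
    _manifest_save(outdir, man)
    return report_path


def cmd_compare(outdir: str | Path, references: list[str | Path]) -> ComparisonReport:
    """Relative errors of the run's centreline velocity against references."""
    outdir = Path(outdir)
    t0 = time.time()
    man = _manifest_load(outdir)
    cfg = man.get("config", {})
    geom, case, lat, dx, omega, _ = _setup(cfg)
    ff = FlagField.load(outdir / "mesh.npz")
    fields = np.load(outdir / "fields.npz")

    from .comparison import centerline_profile

    _, _, zc = ff.cell_centers()
    conv_u = lat.dx / lat.dt
    z_sim, u_sim = centerline_profile(
        ff, fields["u_mean"] * conv_u, float(zc[1]), float(zc[-2]), n_points=86
    )
    datasets = [read_piv_table(p) for p in references]
    errors = compare_centerline(z_sim, u_sim, datasets)

    rr_tke = 0.5 * np.clip(
        fields["u2_mean"] - fields["u_mean"] ** 2, 0, None
    ).sum(axis=-1)
    nxh, nyh = ff.shape[0] // 2, ff.shape[1] // 2
    tke_line = rr_tke[nxh - 1: nxh + 1, nyh - 1: nyh + 1, :].mean(axis=(0, 1))
    zb, bracket = jet_breakdown_location(zc, tke_line, lat.u_lattice)

    report = ComparisonReport(
        errors=errors,
        breakdown_z=zb,
        breakdown_bracket=bracket,
        provenance={
            "references": [str(p) for p in references],
            "mesh_sha256": man["files"].get("mesh.npz", {}).get("sha256"),
        },
    )
    report.to_csv(outdir / "comparison.csv")
    plot_centerline(z_sim, u_sim, datasets, outdir / "centerline.png")

    man["stages"]["compare"] = {"seconds": time.time() - t0}
    _register(man, outdir, outdir / "comparison.csv", outdir / "centerline.png")
    _manifest_save(outdir, man)
    return report
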