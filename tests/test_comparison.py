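"""Comparison-observable and PIV-dataset tests."""

import numpy as np
import pandas as pd
import pytest

from fdanozzle.comparison import (
    ComparisonError,
    PIVDataset,
    PIVParseError,
    compare_centerline,
    centerline_profile,
    jet_breakdown_location,
    normalized_pressure,
    normalized_shear,
    radial_profile,
    read_piv_table,
    relative_error,
    section_mean,
    write_piv_table,
)
from fdanozzle.geometry import StationSet


def make_dataset(exp="243", with_pressure=True):
    stations = StationSet().z
    rows = [
        {"experiment": exp, "quantity": "u_z_m_s", "z_m": z, "r_m": 0.0,
         "value": 1.0 + 0.1 * i}
        for i, z in enumerate(stations)
    ]
    if with_pressure:
        rows += [
            {"experiment": exp, "quantity": "p_Pa", "z_m": z, "r_m": 0.0,
             "value": 100.0 - i}
            for i, z in enumerate(stations)
        ]
    return PIVDataset(experiment=exp, table=pd.DataFrame(rows))


class TestRelativeError:
    def test_identity_is_zero(self):
        assert relative_error(1.3, 1.3) == 0.0

    @pytest.mark.parametrize("ref,h,expect", [(1.0, 0.9, 10.0), (2.0, 2.5, 25.0)])
    def test_values(self, ref, h, expect):
        assert relative_error(ref, h) == pytest.approx(expect)

    def test_scale_invariance(self, rng):
        a, b = rng.random(20) + 0.1, rng.random(20) + 0.1
        assert relative_error(5.0 * a, 5.0 * b) == pytest.approx(
            relative_error(a, b)
        )

    def test_zero_reference_refused(self):
        with pytest.raises(ComparisonError):
            relative_error(0.0, 1.0)


class TestNormalizedPressure:
    def test_flat_profile_is_zero(self):
        z = np.linspace(-0.08, 0.08, 12)
        p = normalized_pressure(np.full(12, 7.0), z, z0=z[0], rho=1056.0,
                                u_throat=1.657)
        assert np.abs(p.dp_norm).max() == 0.0

    def test_dynamic_pressure_normalization(self):
        z = np.array([0.0, 0.01])
        rho, u = 1056.0, 1.657
        p = normalized_pressure(np.array([0.0, 0.5 * rho * u**2]), z, 0.0, rho, u)
        assert p.dp_norm[1] == pytest.approx(1.0)

    def test_benchmark_arithmetic(self):
        u = 2000.0 * (0.0035 / 1056.0) / 0.004
        z = np.array([0.0, 0.01])
        p = normalized_pressure(np.array([0.0, 1449.3]), z, 0.0, 1056.0, u)
        assert p.dp_norm[1] == pytest.approx(1.0, abs=1e-3)

    def test_invariant_to_constant_offset(self, rng):
        z = np.linspace(-0.05, 0.05, 9)
        p0 = rng.random(9)
        a = normalized_pressure(p0, z, 0.0, 1056.0, 1.0)
        b = normalized_pressure(p0 + 37.0, z, 0.0, 1056.0, 1.0)
        assert a.dp_norm == pytest.approx(b.dp_norm)

    def test_zero_velocity_refused(self):
        with pytest.raises(ComparisonError):
            normalized_pressure(np.zeros(3), np.arange(3.0), 0.0, 1056.0, 0.0)


class TestNormalizedShear:
    def test_constant_profile(self):
        assert normalized_shear(np.full(7, 3.0)) == pytest.approx(np.ones(7))

    def test_scale_invariance(self, rng):
        x = rng.random(30) + 0.1
        assert normalized_shear(4.2 * x) == pytest.approx(normalized_shear(x))

    def test_poiseuille_stress_shape(self):
        r = np.linspace(0.0, 1.0, 2001)
        tau = 0.123 * r                       # linear viscous stress profile
        norm = normalized_shear(tau)
        assert np.abs(norm - 2.0 * r).max() < 0.02

    def test_zero_mean_refused(self):
        with pytest.raises(ComparisonError):
            normalized_shear(np.zeros(5))


class TestJetBreakdown:
    def test_laminar_profile_gives_none(self):
        z = np.linspace(-0.05, 0.1, 200)
        k = np.full(200, 1e-9)
        zb, br = jet_breakdown_location(z, k, u_ref=1.0)
        assert zb is None and br is None

    def test_step_profile_located_within_spacing(self):
        z = np.linspace(-0.05, 0.1, 301)
        zstar = 0.0305
        k = np.where(z >= zstar, 0.02, 1e-8)
        zb, br = jet_breakdown_location(z, k, u_ref=1.0)
        assert abs(zb - zstar) <= z[1] - z[0]
        assert br == (0.024, 0.032)

    def test_bracket_reflects_transition_band(self):
        """TKE rising between the 9th and 10th stations reports that pair."""
        z = np.linspace(0.0, 0.09, 901)
        k = 0.05 / (1.0 + np.exp(-(z - 0.027) / 0.001))
        zb, br = jet_breakdown_location(z, k, u_ref=1.0)
        assert br == (0.024, 0.032)

    def test_threshold_monotonicity(self, rng):
        z = np.linspace(0.0, 0.1, 400)
        k = np.cumsum(rng.random(400))  # nondecreasing
        k = 0.01 * k / k.max()
        last = -np.inf
        for thr in (0.05, 0.1, 0.2, 0.5, 0.9):
            zb, _ = jet_breakdown_location(z, k, u_ref=1.0, threshold=thr)
            assert zb >= last
            last = zb


class TestPIVIO:
    def test_round_trip_bit_identical(self, tmp_path):
        ds = make_dataset()
        p = tmp_path / "piv_243.csv"
        write_piv_table(p, ds, header="synthetic fixture")
        back = read_piv_table(p)
        assert back.experiment == "243"
        pd.testing.assert_frame_equal(
            back.table.reset_index(drop=True),
            ds.table[["experiment", "quantity", "z_m", "r_m", "value"]]
            .astype({"experiment": str})
            .reset_index(drop=True),
            check_dtype=False,
        )

    def test_twelve_stations(self, tmp_path):
        p = tmp_path / "a.csv"
        write_piv_table(p, make_dataset())
        ds = read_piv_table(p)
        assert len(ds.centerline_velocity()) == 12

    def test_missing_pressure_tolerated(self, tmp_path):
        p = tmp_path / "b.csv"
        write_piv_table(p, make_dataset("999", with_pressure=False))
        ds = read_piv_table(p)
        assert not ds.has_pressure
        assert ds.pressure() is None

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "experiment,quantity,z_m,r_m,value\n"
            "243,u_z_m_s,0.0,0.0,1.0\n"
            "243,u_z_m_s,oops,0.0,1.0\n"
        )
        with pytest.raises(PIVParseError, match=":3:"):
            read_piv_table(p)

    def test_unit_mismatch_reported(self, tmp_path):
        p = tmp_path / "units.csv"
        p.write_text(
            "experiment,quantity,z_m,r_m,value\n"
            "243,u_z_cm_s,0.0,0.0,1.0\n"
        )
        with pytest.raises(PIVParseError, match="units"):
            read_piv_table(p)


class TestProfileExtraction:
    def test_centerline_constant_in_developed_pipe(self, open_pipe):
        # the density-weighted velocity is the axially conserved profile;
        # the plain velocity drifts slightly with the compressible pressure
        # drop along the pipe
        ff = open_pipe.sim.ff
        rho, u = open_pipe.sim.macroscopic()
        _, _, zc = ff.cell_centers()
        z, juz = centerline_profile(ff, rho[..., None] * u, float(zc[10]),
                                    float(zc[-10]), n_points=30)
        assert np.abs(juz - juz.mean()).max() / juz.mean() < 0.01

    def test_centerline_station_count(self, open_pipe):
        ff = open_pipe.sim.ff
        _, u = open_pipe.sim.macroscopic()
        _, _, zc = ff.cell_centers()
        z, uz = centerline_profile(ff, u, float(zc[5]), float(zc[-5]), n_points=12)
        assert len(z) == 12 and len(uz) == 12

    def test_radial_profile_poiseuille(self, open_pipe):
        ff = open_pipe.sim.ff
        _, u = open_pipe.sim.macroscopic()
        _, _, zc = ff.cell_centers()
        z_mid = float(zc[ff.shape[2] // 2])
        u_mean = section_mean(ff, u[..., 2], z_mid)
        r, prof = radial_profile(ff, u, z_mid, normalization=u_mean)
        # peak is twice the mean, profile symmetric, wall values near zero
        assert prof.max() == pytest.approx(2.0, rel=0.02)
        assert prof[0] < 0.35 and prof[-1] < 0.35
        assert np.abs(prof - prof[::-1]).max() < 0.02 * prof.max()

    def test_station_in_solid_refused(self, open_pipe):
        ff = open_pipe.sim.ff
        _, u = open_pipe.sim.macroscopic()
        with pytest.raises(Exception):
            radial_profile(ff, u, 1e9)


class TestReportAssembly:
    def test_self_comparison_is_zero_error(self):
        z = np.array(StationSet().z)
        u = 1.0 + np.linspace(0, 1, 12)
        ds = make_dataset()
        ds.table.loc[ds.table["quantity"] == "u_z_m_s", "value"] = u
        errors = compare_centerline(z, u, [ds])
        assert len(errors) == 12
        assert errors["delta_pct"].abs().max() < 1e-10

    def test_section_mean_uniform_field(self, open_pipe):
        ff = open_pipe.sim.ff
        vals = np.full(ff.shape, 3.3)
        _, _, zc = ff.cell_centers()
        assert section_mean(ff, vals, float(zc[4])) == pytest.approx(3.3)
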