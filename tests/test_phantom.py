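import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from synthflow import phantom
from synthflow.phantom import (
    Grid3D,
    GroundTruthField,
    InletSpec,
    StenosisSpec,
    TurbulenceSpec,
    ensemble_covariance,
    hagen_poiseuille_profile,
    load_gridded_fields,
    make_phantom_flow,
    make_stenosis_mask,
    rst6_to_tensor,
    temporal_window_average,
    tensor_to_rst6,
    write_gridded_fields,
)


def _tube_grid(n=(24, 24, 40), spacing=1.0):
    return Grid3D(shape=n, spacing=(spacing,) * 3)


def _spec(**kw):
    base = dict(
        diameter=10.0, throat_position=0.8, downstream_length=2.6, stenosis_length=1.0
    )
    base.update(kw)
    return StenosisSpec(**base)


class TestGrid3D:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Grid3D(shape=(3, 8, 8))
        with pytest.raises(ValueError):
            Grid3D(shape=(8, 8, 8), spacing=(0.0, 1, 1))
        with pytest.raises(ValueError):
            Grid3D(shape=(8, 8, 8), time_axis=(1.0, 1.0))

    def test_voxel_centers(self):
        g = Grid3D(shape=(4, 4, 8), spacing=(0.5, 0.5, 0.5))
        assert g.axis_coords(0)[0] == pytest.approx(0.25)
        assert g.voxel_volume_mm3 == pytest.approx(0.125)


class TestStenosisMask:
    def test_zero_severity_is_uniform_cylinder(self):
        grid = _tube_grid()
        mask = make_stenosis_mask(_spec(severity=0.0, eccentricity=0.0), grid)
        counts = mask.sum(axis=(0, 1))
        assert np.all(counts == counts[0])

    def test_throat_area_matches_severity(self):
        grid = _tube_grid(spacing=0.5, n=(44, 44, 80))
        spec = _spec(severity=0.75, eccentricity=0.0)
        mask = make_stenosis_mask(spec, grid)
        counts = mask.sum(axis=(0, 1))
        inlet_area = counts[0] * 0.25
        throat_area = counts.min() * 0.25
        # one voxel-area worth of discretization slack on each area estimate
        per_voxel = 0.25
        circumference_slack = np.pi * spec.diameter * 0.5  # perimeter * spacing
        assert abs(throat_area - 0.25 * inlet_area) <= circumference_slack
        assert throat_area < 0.35 * inlet_area

    def test_eccentricity_shifts_throat_centroid(self):
        grid = _tube_grid(spacing=0.25, n=(56, 56, 176))
        ecc = _spec(eccentricity=0.05, downstream_length=1.2)
        conc = _spec(eccentricity=0.0, downstream_length=1.2)
        m_e = make_stenosis_mask(ecc, grid)
        m_c = make_stenosis_mask(conc, grid)
        iz = int(np.argmin(m_c.sum(axis=(0, 1))))

        def centroid_x(mask):
            ix, _ = np.nonzero(mask[:, :, iz])
            return (ix + 0.5).mean() * grid.spacing[0]

        shift = centroid_x(m_e) - centroid_x(m_c)
        assert shift == pytest.approx(0.05 * ecc.diameter, abs=0.15)

    def test_mask_simply_connected(self):
        mask = make_stenosis_mask(_spec(), _tube_grid())
        _, n_comp = ndimage.label(mask)
        assert n_comp == 1

    def test_grid_too_short_raises(self):
        with pytest.raises(ValueError, match="mm"):
            make_stenosis_mask(StenosisSpec(), _tube_grid())  # needs 230 mm


class TestHagenPoiseuille:
    def setup_method(self):
        grid = _tube_grid(spacing=0.5, n=(44, 44, 80))
        self.mask = make_stenosis_mask(_spec(severity=0.0), grid)[:, :, 0]
        self.spacing = (0.5, 0.5)

    def test_mean_velocity_matches_reynolds(self):
        inlet = InletSpec(mean_Re=1000.0, peak_Re=1000.0)
        nu = 3.5e-3 / 1060.0
        prof = hagen_poiseuille_profile(
            inlet, self.mask, self.spacing, nu_m2s=nu, diameter_mm=10.0
        )
        u_mean = prof[2][self.mask].mean()
        assert u_mean * 10e-3 / nu == pytest.approx(1000.0, rel=1e-9)

    def test_wall_voxels_zero(self):
        inlet = InletSpec()
        prof = hagen_poiseuille_profile(inlet, self.mask, self.spacing)
        assert np.all(prof[:, ~self.mask] == 0)

    def test_peak_reynolds(self):
        inlet = InletSpec(mean_Re=1000.0, peak_Re=4000.0)
        nu = 3.5e-3 / 1060.0
        t_dense = np.linspace(0, 1000, 2000, endpoint=False)
        re = np.array(
            [
                hagen_poiseuille_profile(
                    inlet,
                    self.mask,
                    self.spacing,
                    frame_time_ms=t,
                    period_ms=1000.0,
                    nu_m2s=nu,
                    diameter_mm=10.0,
                )[2][self.mask].mean()
                * 10e-3
                / nu
                for t in t_dense[::25]
            ]
        )
        assert re.max() == pytest.approx(4000.0, rel=0.01)

    def test_empty_slice_raises(self):
        with pytest.raises(ValueError, match="empty"):
            hagen_poiseuille_profile(
                InletSpec(), np.zeros((8, 8), dtype=bool), (1.0, 1.0)
            )


class TestPhantomFlow:
    def test_zero_tke_gives_laminar_jet(self):
        f = make_phantom_flow(
            _spec(), InletSpec(), _tube_grid(), TurbulenceSpec(tke_peak=0.0)
        )
        assert np.all(f.rst == 0)
        assert np.abs(f.u_mean).max() > 0

    def test_isotropic_peak_tke(self):
        turb = TurbulenceSpec(tke_peak=100.0, anisotropy=1.0, shear_frac=0.0)
        f = make_phantom_flow(_spec(), InletSpec(), _tube_grid(), turb)
        tke = 0.5 * f.rst[0, :3].sum(axis=0)
        assert tke.max() == pytest.approx(100.0, abs=1e-6)

    def test_flow_rate_conserved_along_tube(self):
        grid = Grid3D(shape=(28, 28, 120), spacing=(0.5, 0.5, 0.5))
        spec = StenosisSpec(
            diameter=5.0, throat_position=1.0, downstream_length=10.0,
            stenosis_length=1.0,
        )
        f = make_phantom_flow(spec, InletSpec(), grid, TurbulenceSpec(tke_peak=0.0))
        # brute-force slice integration: inlet vs 10 diameters downstream
        dx, dy = grid.spacing[:2]
        flux = f.u_mean[0, 2].sum(axis=(0, 1)) * dx * dy
        z10 = int((spec.throat_z + 10 * spec.diameter) / grid.spacing[2]) - 1
        assert flux[z10] == pytest.approx(flux[0], rel=0.02)
        # and everywhere in between
        assert np.ptp(flux) <= 0.02 * flux[0]

    def test_turbulence_zero_upstream_positive_downstream(self, jet_field):
        tke = jet_field.tke()[0]
        spec = StenosisSpec(
            diameter=10.0, throat_position=0.8, downstream_length=2.6,
            stenosis_length=1.0,
        )
        iz_throat = int(spec.throat_z / jet_field.grid.spacing[2])
        assert np.all(tke[:, :, : iz_throat + 1] == 0)
        assert tke[:, :, iz_throat + 4 :].max() > 0

    def test_invalid_turb_params_rejected(self):
        with pytest.raises(ValueError):
            TurbulenceSpec(shear_frac=1.0)
        with pytest.raises(ValueError):
            TurbulenceSpec(tke_peak=-1.0)

    def test_bit_reproducible(self):
        a = make_phantom_flow(_spec(), InletSpec(), _tube_grid(), TurbulenceSpec())
        b = make_phantom_flow(_spec(), InletSpec(), _tube_grid(), TurbulenceSpec())
        assert np.array_equal(a.u_mean, b.u_mean)
        assert np.array_equal(a.rst, b.rst)

    def test_field_invariants(self, jet_field):
        jet_field.validate()  # PSD + masking


class TestEnsembleCovariance:
    def test_identical_snapshots_zero(self, rng):
        snap = rng.normal(size=(3, 4, 4, 4))
        _, r6 = ensemble_covariance([snap, snap, snap])
        assert np.allclose(r6, 0)

    def test_two_opposed_snapshots(self):
        a = 0.7
        up = np.zeros((3, 2, 2, 2))
        up[0] = a
        _, r6 = ensemble_covariance([up, -up], rho=1060.0)
        u_mean, _ = ensemble_covariance([up, -up], rho=1060.0)
        assert np.allclose(u_mean, 0)
        assert np.allclose(r6[0], 1060.0 * a**2)
        assert np.allclose(r6[1:], 0)

    def test_monte_carlo_recovers_known_covariance(self, rng):
        sigma2 = 0.04
        n = 100_000
        snaps = rng.normal(0.0, np.sqrt(sigma2), size=(n, 3, 2, 2, 2))
        _, r6 = ensemble_covariance(snaps, rho=1.0)
        se = sigma2 * np.sqrt(2.0 / n)  # MC standard error of a variance
        assert np.all(np.abs(r6[:3] - sigma2) < 3 * se * 3)
        assert np.all(np.abs(r6[3:]) < 3 * sigma2 / np.sqrt(n) * 3)

    def test_requires_two_snapshots(self):
        with pytest.raises(ValueError):
            ensemble_covariance([np.zeros((3, 2, 2, 2))])

    def test_matches_double_loop_oracle(self, rng):
        snaps = rng.normal(size=(6, 3, 2, 2, 3))  # 12 voxels
        u_mean, r6 = ensemble_covariance(snaps, rho=2.5)
        # brute-force per-voxel double loop
        for idx in np.ndindex(2, 2, 3):
            u = snaps[(slice(None), slice(None)) + idx]  # (N, 3)
            ubar = u.mean(axis=0)
            cov = np.zeros((3, 3))
            for n in range(u.shape[0]):
                d = u[n] - ubar
                cov += np.outer(d, d)
            cov /= u.shape[0]
            expect = 2.5 * tensor_to_rst6(cov)
            got = r6[(slice(None),) + idx]
            assert np.allclose(got, expect, rtol=1e-12, atol=1e-12)


class TestTemporalWindow:
    def _series(self, us, rs=None, rho=1060.0):
        nt = len(us)
        grid = Grid3D(
            shape=(4, 4, 4), time_axis=tuple(np.arange(nt, dtype=float) * 10.0)
        )
        u = np.zeros((nt, 3, 4, 4, 4))
        r = np.zeros((nt, 6, 4, 4, 4))
        for i, a in enumerate(us):
            u[i, 0] = a
        if rs is not None:
            for i, b in enumerate(rs):
                r[i, 0] = b
        mask = np.ones((4, 4, 4), dtype=bool)
        return GroundTruthField(grid=grid, u_mean=u, rst=r, mask=mask, rho=rho)

    def test_instantaneous_returns_frame(self):
        s = self._series([0.1, 0.2, 0.3])
        out = temporal_window_average(s, 10.0, 0.0)
        assert np.array_equal(out.u_mean[0], s.u_mean[1])
        assert np.array_equal(out.rst[0], s.rst[1])

    def test_steady_flow_unaffected(self):
        s = self._series([0.25] * 4, rs=[5.0] * 4)
        out = temporal_window_average(s, 15.0, 40.0)
        assert np.allclose(out.u_mean[0], s.u_mean[0])
        assert np.allclose(out.rst[0], s.rst[0])

    def test_idempotent_for_steady_series(self):
        s = self._series([0.25] * 4, rs=[5.0] * 4)
        once = temporal_window_average(s, 15.0, 40.0)
        assert np.allclose(once.u_mean, s.u_mean[:1])

    def test_mean_flow_variation_becomes_apparent_turbulence(self):
        a = 0.3
        s = self._series([a, -a])
        out = temporal_window_average(s, 5.0, 20.0)
        assert np.allclose(out.u_mean[0], 0.0)
        assert np.allclose(out.rst[0, 0], s.rho * a**2)
        assert np.allclose(out.rst[0, 1:], 0.0)

    def test_negative_window_raises(self):
        with pytest.raises(ValueError):
            temporal_window_average(self._series([0.1, 0.2]), 0.0, -1.0)


class TestGriddedIO:
    def test_round_trip_bitwise(self, tiny_field, tmp_path):
        p = tmp_path / "f.h5"
        write_gridded_fields(tiny_field, p)
        back = load_gridded_fields(p)
        assert np.array_equal(back.u_mean, tiny_field.u_mean)
        assert np.array_equal(back.rst, tiny_field.rst)
        assert np.array_equal(back.mask, tiny_field.mask)
        assert back.grid == tiny_field.grid

    def test_variances_only_names_missing_covariances(self, tiny_field, tmp_path):
        import h5py

        p = tmp_path / "bad.h5"
        write_gridded_fields(tiny_field, p)
        with h5py.File(p, "a") as f:
            r = np.asarray(f["rst"])[:, :3]
            del f["rst"]
            f.create_dataset("rst", data=r)
        with pytest.raises(ValueError, match="xy, xz, yz"):
            load_gridded_fields(p)

    def test_asymmetric_full_tensor_rejected(self, tiny_field, tmp_path):
        import h5py

        p = tmp_path / "asym.h5"
        write_gridded_fields(tiny_field, p)
        with h5py.File(p, "a") as f:
            r6 = np.asarray(f["rst"])
            full = np.moveaxis(rst6_to_tensor(np.moveaxis(r6, 1, 0)), (0, 1), (1, 2))
            full[:, 0, 1] += 1.0 + full.max()
            del f["rst"]
            f.create_dataset("rst", data=full)
        with pytest.raises(ValueError, match="asymmetric"):
            load_gridded_fields(p)

    def test_full_tensor_accepted_and_psd_clipped(self, tiny_field, tmp_path):
        import h5py

        p = tmp_path / "full.h5"
        write_gridded_fields(tiny_field, p)
        with h5py.File(p, "a") as f:
            r6 = np.asarray(f["rst"])
            full = np.moveaxis(rst6_to_tensor(np.moveaxis(r6, 1, 0)), (0, 1), (1, 2))
            del f["rst"]
            f.create_dataset("rst", data=full)
        back = load_gridded_fields(p)
        assert np.allclose(back.rst, tiny_field.rst)

    def test_missing_dataset_named(self, tiny_field, tmp_path):
        import h5py

        p = tmp_path / "missing.h5"
        write_gridded_fields(tiny_field, p)
        with h5py.File(p, "a") as f:
            del f["u_mean"]
        with pytest.raises(ValueError, match="u_mean"):
            load_gridded_fields(p)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
        min_size=2,
        max_size=6,
    )
)
def test_window_average_rst_exceeds_mean_of_frames(values):
    """Apparent turbulence from mean-flow variation is always nonnegative."""
    nt = len(values)
    grid = Grid3D(shape=(4, 4, 4), time_axis=tuple(np.arange(nt) * 10.0))
    u = np.zeros((nt, 3, 4, 4, 4))
    for i, a in enumerate(values):
        u[i, 2] = a
    f = GroundTruthField(
        grid=grid,
        u_mean=u,
        rst=np.zeros((nt, 6, 4, 4, 4)),
        mask=np.ones((4, 4, 4), dtype=bool),
    )
    out = temporal_window_average(f, 0.0, 1e9)
    assert np.all(out.rst[0, :3] >= -1e-12)
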