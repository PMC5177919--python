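"""Strain, stress invariants, TKE, turbulence production and TVSS."""

import numpy as np
import pytest

from icosaflow import (max_principal_shear, tke, turbulence_production, tvss,
                       tvss_square_sum, volumetric_sum)
from icosaflow.stress import (laminar_viscous_stress, strain_rate,
                              velocity_gradient)
from icosaflow.tensors import eigvals_sym3, pack

MU = 8.899e-4
RHO = 997.0


def grid_velocity(fn, n=12, spacing=1e-3):
    """Velocity volume u_i = fn(x, y, z) on a cubic grid."""
    c = (np.arange(n) - n / 2) * spacing
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    return np.stack(fn(x, y, z), axis=-1), spacing


class TestVelocityGradient:
    def test_uniform_field_zero_gradient(self):
        v, h = grid_velocity(lambda x, y, z: (np.ones_like(x), 0 * x, 0 * x))
        grad, flagged = velocity_gradient(v, h)
        assert np.abs(grad).max() == 0.0
        assert not flagged.any()

    def test_linear_shear_exact(self):
        k = 100.0
        v, h = grid_velocity(lambda x, y, z: (k * y, 0 * x, 0 * x))
        grad, _ = velocity_gradient(v, h)
        assert np.allclose(grad[..., 0, 1], k, atol=1e-9)
        assert np.abs(grad[..., 0, 0]).max() < 1e-9

    def test_quadratic_fields_differentiated_exactly(self):
        """Second-order stencils (central and one-sided) are exact on
        polynomials up to degree two, including at the grid boundary."""
        v, h = grid_velocity(lambda x, y, z: (x**2, 0 * x, 0 * x), n=10)
        grad, _ = velocity_gradient(v, h)
        c = (np.arange(10) - 5) * h
        assert np.abs(grad[..., 0, 0] - 2 * c[:, None, None]).max() < 1e-12

    def test_cubic_field_second_order_convergence(self):
        """Truncation error on u = x^3 shrinks ~h^2 over a spacing sweep."""
        errs = []
        spacings = (2e-3, 1e-3, 0.5e-3)
        for h in spacings:
            v, _ = grid_velocity(lambda x, y, z: (x**3, 0 * x, 0 * x), n=10,
                                 spacing=h)
            grad, _ = velocity_gradient(v, h)
            c = (np.arange(10) - 5) * h
            errs.append(np.abs(grad[..., 0, 0] - 3 * c[:, None, None] ** 2).max())
        slope = np.polyfit(np.log(spacings), np.log(errs), 1)[0]
        assert slope > 1.8

    def test_mask_excludes_outside_neighbours(self):
        k = 50.0
        v, h = grid_velocity(lambda x, y, z: (k * y, 0 * x, 0 * x))
        mask = np.ones(v.shape[:3], dtype=bool)
        mask[:, :2, :] = False          # wall: gradient must not use it
        v[~mask] = 999.0                # poison outside values
        grad, _ = velocity_gradient(v, h, mask)
        assert np.allclose(grad[mask][:, 0, 1], k, atol=1e-9)

    def test_isolated_voxel_flagged(self):
        v = np.zeros((5, 5, 5, 3))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        _, flagged = velocity_gradient(v, 1e-3, mask)
        assert flagged[2, 2, 2]


class TestLaminarStress:
    def test_simple_shear_off_diagonal(self):
        grad = np.zeros((3, 3))
        grad[0, 1] = 100.0
        tau = laminar_viscous_stress(grad, MU)
        assert tau[..., 3] == pytest.approx(0.08899, rel=1e-12)

    def test_rigid_rotation_gives_zero_stress(self):
        grad = np.array([[0.0, -50.0, 0.0], [50.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert np.abs(laminar_viscous_stress(grad, MU)).max() == 0.0

    def test_uniform_dilation_diagonal(self):
        c = 10.0
        tau = laminar_viscous_stress(c * np.eye(3), MU)
        assert np.allclose(tau[..., :3], 2 * MU * c)

    def test_strain_rate_traceless_for_incompressible_field(self):
        v, h = grid_velocity(lambda x, y, z: (100 * x, -100 * y, 0 * z))
        grad, _ = velocity_gradient(v, h)
        s = strain_rate(grad)
        assert np.abs(s[..., :3].sum(-1)).max() < 1e-8


class TestMaxPrincipalShear:
    def test_isotropic_tensor_gives_zero(self):
        assert max_principal_shear(pack(3.0 * np.eye(3))) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 10.0
        assert max_principal_shear(t) == pytest.approx(10.0, rel=1e-12)

    def test_diagonal_tensor(self):
        assert max_principal_shear(pack(np.diag([5.0, 2.0, -1.0]))) == pytest.approx(3.0)

    def test_matches_eigvalsh_oracle_on_random_tensors(self, rng):
        a = rng.standard_normal((5000, 3, 3))
        a = (a + a.transpose(0, 2, 1)) / 2
        ours = max_principal_shear(pack(a))
        ev = np.linalg.eigvalsh(a)
        assert np.abs(ours - (ev[:, 2] - ev[:, 0]) / 2).max() < 1e-10

    def test_rotation_invariance(self, rng):
        a = rng.standard_normal((3, 3))
        a = (a + a.T) / 2
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert max_principal_shear(pack(q @ a @ q.T)) == pytest.approx(
            max_principal_shear(pack(a)), abs=1e-10)

    def test_asymmetric_input_rejected(self):
        bad = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            max_principal_shear(bad)


class TestTke:
    def test_zero_for_zero_ivsd(self):
        assert tke(0.0, 0.0, 0.0, RHO) == 0.0

    def test_direct_substitution(self):
        assert tke(0.1, 0.1, 0.1, RHO) == pytest.approx(14.955, rel=1e-12)

    def test_negative_ivsd_rejected(self):
        with pytest.raises(ValueError):
            tke(-0.1, 0.1, 0.1, RHO)

    def test_trace_identity_with_tensor_form(self, rng):
        s = rng.random(3) * 0.3
        t = np.diag(s**2)
        from icosaflow.tensors import trace
        assert tke(*s, RHO) == pytest.approx(0.5 * RHO * trace(pack(t)))


class TestProductionAndTvss:
    def test_isotropic_tensor_with_traceless_strain_is_zero(self):
        t = pack(0.02 * np.eye(3))
        s = pack(np.diag([50.0, -20.0, -30.0]))
        assert turbulence_production(t, s, RHO) == pytest.approx(0.0, abs=1e-9)

    def test_hand_contraction_off_diagonal_pair(self):
        # <u'v'> = -0.01, S_xy = 50: P = -rho * 2 * (-0.01) * 50 = 997 W/m^3
        t = np.zeros(6)
        t[3] = -0.01
        s = np.zeros(6)
        s[3] = 50.0
        assert turbulence_production(t, s, RHO) == pytest.approx(997.0, rel=1e-12)

    def test_zero_strain_zero_production(self, rng):
        t = rng.random((4, 6))
        assert np.all(turbulence_production(t, np.zeros((4, 6)), RHO) == 0.0)

    def test_tvss_direct_substitution(self):
        val, defined = tvss(997.0, MU)
        assert defined
        assert val == pytest.approx(np.sqrt(MU * 997.0), rel=1e-12)
        assert val == pytest.approx(0.9419, abs=2e-4)

    def test_tvss_zero_production(self):
        val, defined = tvss(0.0, MU)
        assert val == 0.0 and defined

    def test_negative_production_flagged_undefined(self):
        val, defined = tvss(-10.0, MU)
        assert not defined and np.isnan(val)


class TestSquareSumAndVolumetricSum:
    def test_reduces_to_tvss_square_sum_when_production_nonnegative(self, rng):
        p = rng.random(100) * 1000
        mask = np.ones(100, dtype=bool)
        vv = 1e-9
        signed = tvss_square_sum(p, MU, mask, vv)
        direct = float(np.sum(MU * p) * vv)
        assert signed == pytest.approx(direct, rel=1e-12)

    def test_opposite_productions_cancel(self):
        p = np.array([500.0, -500.0])
        assert tvss_square_sum(p, MU, np.ones(2, bool), 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_signed_sum_unbiased_under_noise_while_flagged_sum_inflates(self, rng):
        """Core noise-robustness property: zero-mean Gaussian noise on the
        production leaves the signed square-sum unbiased (within 3 SE) but
        biases the flagged TVSS sum upward."""
        n = 100_000
        p_true = np.zeros(n)          # quiescent region
        noise = 200.0 * rng.standard_normal(n)
        p = p_true + noise
        vv = 1.0
        mask = np.ones(n, bool)
        signed = tvss_square_sum(p, MU, mask, vv)
        se = MU * noise.std() * np.sqrt(n) * vv
        assert abs(signed - 0.0) < 3 * se
        tvss_map, defined = tvss(p, MU)
        flagged_sum = volumetric_sum(np.nan_to_num(tvss_map), defined, vv)
        assert flagged_sum > 10 * abs(signed)

    def test_volumetric_sum_uniform_and_half_mask(self):
        field = np.full((10, 10), 2.0)
        vv = 1e-9
        full = volumetric_sum(field, np.ones_like(field, bool), vv)
        assert full == pytest.approx(100 * 2.0 * vv)
        half = np.zeros_like(field, bool)
        half[:5] = True
        assert volumetric_sum(field, half, vv) == pytest.approx(full / 2)

    def test_volumetric_sum_matches_loop_oracle(self, rng):
        field = rng.standard_normal((6, 7, 8))
        mask = rng.random((6, 7, 8)) > 0.4
        vv = 2.5e-9
        oracle = sum(field[i, j, k] * vv
                     for i in range(6) for j in range(7) for k in range(8)
                     if mask[i, j, k])
        assert volumetric_sum(field, mask, vv) == pytest.approx(oracle, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            volumetric_sum(np.ones(3), np.zeros(3, bool), 1.0)


class TestEigClosedForm:
    def test_degenerate_spectra_handled(self):
        lam1, lam2, lam3 = eigvals_sym3(pack(2.0 * np.eye(3)))
        assert lam1 == pytest.approx(2.0) and lam3 == pytest.approx(2.0)

    def test_fine_grid_consistency_against_mri_chain(self, small_phantom):
        """At voxel size equal to 4x the phantom grid with no noise, the
        reconstructed stress maps approach a direct fine-grid computation:
        jet-peak TVSS values agree within a factor accounted for by kernel
        smoothing (sanity bound, not equality)."""
        from icosaflow import (AcquisitionSettings, compute_stress_maps,
                               ground_truth_stress_maps, reconstruct,
                               simulate_acquisition, suggest_venc)
        ph = small_phantom
        venc = suggest_venc(ph)
        acq = simulate_acquisition(ph, AcquisitionSettings(voxel_size=1e-3, venc=venc))
        maps = compute_stress_maps(reconstruct(acq))
        truth = ground_truth_stress_maps(ph)
        peak_mri = np.nanmax(maps.tvss)
        peak_cfd = np.nanmax(truth.tvss)
        assert 0.3 * peak_cfd < peak_mri < 3.0 * peak_cfd
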