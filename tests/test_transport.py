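import numpy as np
import pytest

from qdosim import (
    MediumProperties,
    Phantom,
    PhantomSpec,
    build_media,
    build_transport_system,
    flux_to_dose,
    generate_phantom,
    make_ordinates,
    make_source,
    run_monte_carlo,
    solve_classical,
)
from qdosim.transport import estimate_condition_number


def single_voxel_phantom():
    return Phantom(density=np.ones((1, 1, 1)), labels=np.zeros((1, 1, 1), int),
                   spacing=(1.0, 1.0, 1.0))


def absorber_media(shape, mu_t):
    return MediumProperties(mu_t=np.full(shape, mu_t), mu_s=np.zeros(shape),
                            g=np.zeros(shape))


class TestBuildMedia:
    def test_water_constant(self, uniform_phantom_16):
        med = build_media(uniform_phantom_16, {0: (0.02, 0.01, 0.0)})
        assert np.all(med.mu_t == 0.02)
        assert np.all(med.mu_s == 0.01)
        np.testing.assert_allclose(med.mu_a, 0.01)

    def test_density_scales_coefficients(self):
        p = Phantom(density=np.array([[[1.0, 2.0]]]), labels=np.zeros((1, 1, 2), int),
                    spacing=(1, 1, 1))
        med = build_media(p, {0: (0.02, 0.01, 0.0)})
        assert med.mu_t[0, 0, 1] == pytest.approx(2 * med.mu_t[0, 0, 0])

    def test_missing_label_named(self, uniform_phantom_16):
        with pytest.raises(KeyError, match="0"):
            build_media(uniform_phantom_16, {7: (0.02, 0.01, 0.0)})

    def test_scatter_exceeding_total_rejected(self, uniform_phantom_16):
        with pytest.raises(ValueError):
            build_media(uniform_phantom_16, {0: (0.01, 0.02, 0.0)})


class TestOrdinates:
    @pytest.mark.parametrize("n", [1, 2, 6, 8, 26])
    def test_weights_sum_to_4pi_and_unit_directions(self, n):
        dirs, w = make_ordinates(n)
        assert abs(w.sum() - 4 * np.pi) < 1e-9
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            make_ordinates(0)


class TestBuildTransportSystem:
    def test_single_voxel_hand_example(self):
        # Delta=1mm, one ordinate, mu_s=0, mu_t=1/mm, vacuum inflow, S=2:
        # A = [1/Delta + mu_t] = [2], b = [2], f = 1
        p = single_voxel_phantom()
        med = absorber_media(p.shape, 1.0)
        sys_ = build_transport_system(p, med, None, n_ordinates=1,
                                      angular_source=np.full(p.shape, 2.0))
        np.testing.assert_allclose(sys_.A.toarray(), [[2.0]])
        np.testing.assert_allclose(sys_.b, [2.0])
        f = solve_classical(sys_)
        np.testing.assert_allclose(f.values.ravel(), [1.0], atol=1e-12)
        assert sys_.s == 1
        assert sys_.kappa == pytest.approx(1.0)

    def test_no_scatter_decouples_ordinates(self):
        spec = PhantomSpec(shape=(3, 3, 3))
        p = generate_phantom(spec)
        med = absorber_media(p.shape, 0.5)
        sys_ = build_transport_system(p, med, None, n_ordinates=4,
                                      angular_source=np.ones(p.shape))
        A = sys_.A.toarray()
        nvox = 27
        for m in range(4):
            for mp in range(4):
                if m != mp:
                    block = A[m * nvox:(m + 1) * nvox, mp * nvox:(mp + 1) * nvox]
                    assert np.all(block == 0)
        # upwind stencil: diagonal + at most one upstream neighbor per axis
        assert sys_.s <= 4

    def test_reported_sparsity_is_exact(self, uniform_phantom_16):
        med = MediumProperties(mu_t=np.full((16, 16, 16), 0.1),
                               mu_s=np.full((16, 16, 16), 0.05),
                               g=np.zeros((16, 16, 16)))
        sys_ = build_transport_system(uniform_phantom_16, med, None, n_ordinates=2,
                                      angular_source=np.ones((16, 16, 16)),
                                      estimate_kappa=False)
        nnz_per_row = np.diff(sys_.A.tocsr().indptr)
        assert sys_.s == nnz_per_row.max()

    def test_dimension_cap_enforced(self, uniform_phantom_16):
        med = absorber_media((16, 16, 16), 0.1)
        with pytest.raises(ValueError, match="cap"):
            build_transport_system(uniform_phantom_16, med, None, n_ordinates=26,
                                   dim_cap=1000)

    def test_shape_mismatch_rejected(self, uniform_phantom_16):
        med = absorber_media((8, 8, 8), 0.1)
        with pytest.raises(ValueError):
            build_transport_system(uniform_phantom_16, med, None, n_ordinates=1)


class TestConditionNumber:
    def test_matches_dense_svd_above_dense_cutoff(self):
        # 5^3 voxels, 1 ordinate -> 125-dim: exercises the power iteration
        p = Phantom(density=np.ones((5, 5, 5)), labels=np.zeros((5, 5, 5), int),
                    spacing=(2.0, 2.0, 2.0))
        med = absorber_media(p.shape, 0.3)
        sys_ = build_transport_system(p, med, None, n_ordinates=1,
                                      angular_source=np.ones(p.shape))
        exact = np.linalg.cond(sys_.A.toarray())
        assert sys_.kappa == pytest.approx(exact, rel=0.05)

    def test_exact_for_small_systems(self):
        A = np.diag([4.0, 2.0, 1.0])
        import scipy.sparse as sp

        assert estimate_condition_number(sp.csr_matrix(A)) == pytest.approx(4.0)


class TestSolveClassical:
    def test_identity_system(self):
        import scipy.sparse as sp

        from qdosim.transport import TransportSystem

        dirs, w = make_ordinates(1)
        b = np.array([0.3, 0.7, 1.1, 0.1])
        sys_ = TransportSystem(A=sp.identity(4, format="csr"), b=b, ordinates=dirs,
                               weights=w, grid_shape=(4, 1, 1), spacing=(1, 1, 1),
                               s=1, kappa=1.0)
        f = solve_classical(sys_)
        np.testing.assert_allclose(f.values.ravel(), b)
        assert f.residual <= 1e-8

    def test_beer_lambert_slab_64_cells(self):
        # absorption-only slab, unit inflow: flux(z) = exp(-mu_t z) within 2%
        N, mu, depth = 64, 0.1, 10.0
        dz = depth / N
        p = Phantom(density=np.ones((N, 1, 1)), labels=np.zeros((N, 1, 1), int),
                    spacing=(dz, 1.0, 1.0))
        med = absorber_media(p.shape, mu)
        sys_ = build_transport_system(p, med, None, n_ordinates=1,
                                      inflow=np.ones((1, N, 1, 1)),
                                      estimate_kappa=False)
        f = solve_classical(sys_)
        prof = f.values[0, :, 0, 0]
        exact = np.exp(-mu * (np.arange(N) + 0.5) * dz)
        assert np.max(np.abs(prof - exact) / exact) < 0.02

    def test_first_order_grid_convergence(self):
        # refining the grid 2x reduces the slab discretization error
        def slab_error(N):
            mu, depth = 0.2, 10.0
            dz = depth / N
            p = Phantom(density=np.ones((N, 1, 1)), labels=np.zeros((N, 1, 1), int),
                        spacing=(dz, 1.0, 1.0))
            med = absorber_media(p.shape, mu)
            sys_ = build_transport_system(p, med, None, n_ordinates=1,
                                          inflow=np.ones((1, N, 1, 1)),
                                          estimate_kappa=False)
            prof = solve_classical(sys_).values[0, :, 0, 0]
            exact = np.exp(-mu * (np.arange(N) + 0.5) * dz)
            return np.max(np.abs(prof - exact) / exact)

        assert slab_error(32) > slab_error(64) > slab_error(128)

    def test_singular_matrix_reports_kappa(self):
        import scipy.sparse as sp

        from qdosim.transport import TransportSystem

        dirs, w = make_ordinates(1)
        A = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
        sys_ = TransportSystem(A=A, b=np.ones(2), ordinates=dirs, weights=w,
                               grid_shape=(2, 1, 1), spacing=(1, 1, 1), s=1,
                               kappa=float("inf"))
        with pytest.raises(np.linalg.LinAlgError):
            solve_classical(sys_)


class TestMonteCarlo:
    def test_energy_conservation_exact(self, two_tissue_phantom_16, absorber_media_16,
                                       beam_source):
        dose = run_monte_carlo(two_tissue_phantom_16, absorber_media_16, beam_source,
                               n_particles=20_000, seed=5)
        resid = abs(dose.energy_emitted - dose.energy_absorbed - dose.energy_escaped)
        assert resid / dose.energy_emitted < 1e-9

    def test_conservation_with_scattering(self, uniform_phantom_16):
        med = MediumProperties(mu_t=np.full((16, 16, 16), 0.08),
                               mu_s=np.full((16, 16, 16), 0.05),
                               g=np.full((16, 16, 16), 0.4))
        src = make_source({"modality": "brachy_seed", "position_mm": (15.0, 15.0, 15.0)})
        dose = run_monte_carlo(uniform_phantom_16, med, src, n_particles=20_000, seed=8)
        resid = abs(dose.energy_emitted - dose.energy_absorbed - dose.energy_escaped)
        assert resid / dose.energy_emitted < 1e-9

    def test_beer_lambert_transmission(self, uniform_phantom_16, beam_source):
        mu = 0.05
        med = absorber_media((16, 16, 16), mu)
        n = 100_000
        dose = run_monte_carlo(uniform_phantom_16, med, beam_source,
                               n_particles=n, seed=3)
        transmitted = dose.energy_escaped / dose.energy_emitted
        expected = np.exp(-mu * 32.0)  # 16 voxels x 2 mm
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(transmitted - expected) < 3 * sigma

    def test_seed_determinism(self, two_tissue_phantom_16, absorber_media_16, beam_source):
        a = run_monte_carlo(two_tissue_phantom_16, absorber_media_16, beam_source,
                            n_particles=2_000, seed=7)
        b = run_monte_carlo(two_tissue_phantom_16, absorber_media_16, beam_source,
                            n_particles=2_000, seed=7)
        assert np.array_equal(a.dose, b.dose)
        assert np.array_equal(a.stat_uncertainty, b.stat_uncertainty)

    def test_vacuum_internal_source_rejected(self, uniform_phantom_16):
        med = absorber_media((16, 16, 16), 0.0)
        src = make_source({"modality": "brachy_seed", "position_mm": (15.0, 15.0, 15.0)})
        with pytest.raises(ValueError, match="free path"):
            run_monte_carlo(uniform_phantom_16, med, src, n_particles=10, seed=0)


class TestFluxToDose:
    def test_uniform_flux_gives_prescription_everywhere(self):
        from qdosim.transport import FluxField

        shape = (4, 4, 4)
        med = MediumProperties(mu_t=np.full(shape, 0.1), mu_s=np.zeros(shape),
                               g=np.zeros(shape))
        flux = FluxField(values=np.ones((1, *shape)), scalar_flux=np.ones(shape))
        dose = flux_to_dose(flux, med, normalization=2.0)
        np.testing.assert_allclose(dose.dose, 2.0)

    def test_mu_a_proportionality(self):
        from qdosim.transport import FluxField

        shape = (2, 2, 2)
        mu_a = np.full(shape, 0.1)
        mu_a[0, 0, 0] = 0.2  # doubled absorption in one voxel
        med = MediumProperties(mu_t=mu_a, mu_s=np.zeros(shape), g=np.zeros(shape))
        flux = FluxField(values=np.ones((1, *shape)), scalar_flux=np.ones(shape))
        mask = np.zeros(shape, bool)
        mask[1, 1, 1] = True
        dose = flux_to_dose(flux, med, normalization=1.0, reference_mask=mask)
        assert dose.dose[0, 0, 0] == pytest.approx(2 * dose.dose[1, 1, 1])

    def test_zero_flux_rejected(self):
        from qdosim.transport import FluxField

        shape = (2, 2, 2)
        med = MediumProperties(mu_t=np.full(shape, 0.1), mu_s=np.zeros(shape),
                               g=np.zeros(shape))
        flux = FluxField(values=np.zeros((1, *shape)), scalar_flux=np.zeros(shape))
        with pytest.raises(ValueError):
            flux_to_dose(flux, med, normalization=2.0)


class TestMonteCarloVsDeterministic:
    def test_two_tissue_agreement_within_mc_uncertainty(
        self, two_tissue_phantom_16, absorber_media_16, beam_source
    ):
        """Cross-method oracle: voxelwise MC dose matches the deterministic
        solve within 3 sigma of the MC statistical uncertainty for >= 95% of
        in-beam voxels, both normalized on the beam entry layer."""
        p = two_tissue_phantom_16
        mask = np.zeros(p.shape, bool)
        mask[0, 3:13, 3:13] = True
        mc = run_monte_carlo(p, absorber_media_16, beam_source,
                             n_particles=200_000, seed=11, reference_mask=mask)
        sys_ = build_transport_system(p, absorber_media_16, beam_source,
                                      n_ordinates=1, estimate_kappa=False)
        flux = solve_classical(sys_)
        det = flux_to_dose(flux, absorber_media_16, normalization=2.0,
                           density=p.density, spacing=p.spacing, reference_mask=mask)
        beam = det.dose > 0
        diff = np.abs(mc.dose - det.dose)
        sigma = np.maximum(mc.stat_uncertainty, 1e-12)
        assert np.mean(diff[beam] <= 3 * sigma[beam]) >= 0.95
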