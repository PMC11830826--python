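"""Aberration-matrix construction, factorization and gradient integration."""

import itertools

import numpy as np
import pytest

from abermat.aberration import (
    AberrationFunction,
    AberrationMatrix,
    DetectorConfig,
    PhaseDifferenceField,
    align_piston_tilt,
    build_aberration_matrix,
    circular_correlation,
    detect_aberration,
    factorize_projection_power,
    factorize_svd,
    integrate_gradients,
    mask_offdiagonal,
    retrieve_psf,
    threshold_reweight,
    time_reversed_incoming,
    wrap_phase,
)
from abermat.lattice import pupil_mask

from conftest import make_thin_stack, smooth_pupil_phase


def toy_matrix(grid, entries, kin=None):
    """Wrap a small dense matrix into an AberrationMatrix on the grid pupil."""
    mask = pupil_mask(grid, grid.na_det)
    n_rows = int(mask.sum())
    full = np.zeros((n_rows, entries.shape[1]), dtype=complex)
    full[: entries.shape[0]] = entries
    if kin is None:
        kin = np.zeros((entries.shape[1], 2))
    return AberrationMatrix(
        grid=grid, delta_k=np.array([grid.dkx, 0.0]), entries=full,
        row_mask=mask, kin_table=np.asarray(kin, dtype=float),
    )


class TestBuildMatrix:
    def test_aberration_free_arg_is_zero(self, grid96):
        stack, _ = make_thin_stack(grid96, phi_out=None, phi_in=None, seed=2)
        A = build_aberration_matrix(stack, 1)
        mags = np.abs(A.entries)
        strong = mags > np.quantile(mags[mags > 0], 0.5)
        assert np.max(np.abs(np.angle(A.entries[strong]))) < 0.05

    def test_known_screens_give_separable_argument(self, grid96):
        phi_out = smooth_pupil_phase(grid96, "out")
        phi_in = smooth_pupil_phase(grid96, "in")
        stack, _ = make_thin_stack(grid96, phi_out=phi_out, phi_in=phi_in, seed=3)
        mask = pupil_mask(grid96, grid96.na_det)
        for slot, axis in ((1, 1), (2, 0)):
            A = build_aberration_matrix(stack, slot)
            pred_out = np.roll(phi_out, -1, axis=axis) - phi_out
            kin = A.kin_table
            for g in range(min(4, A.n_groups)):
                ix = int(round(kin[g, 0] / grid96.dkx)) + grid96.nx // 2
                iy = int(round(kin[g, 1] / grid96.dky)) + grid96.ny // 2
                if axis == 1:
                    pred_in = phi_in[iy, ix + 1] - phi_in[iy, ix]
                else:
                    pred_in = phi_in[iy + 1, ix] - phi_in[iy, ix]
                col = A.to_grid(A.entries[:, g])
                valid = (
                    mask
                    & np.roll(mask, -1, axis=axis)
                    & (np.abs(col) > np.percentile(np.abs(col[mask]), 70))
                )
                err = wrap_phase(
                    np.angle(col) - (np.roll(phi_out, -1, axis=axis) - phi_out) - pred_in
                )[valid]
                assert np.max(np.abs(err)) < 1e-6

    def test_modulus_approximates_target_spectrum_squared(self, grid96):
        # noise-free thin target: |A| equals |T|^2 within 1e-6 relative
        from abermat.lattice import fft2_centered

        phi_out = smooth_pupil_phase(grid96, "out")
        stack, target = make_thin_stack(grid96, phi_out=phi_out, seed=4)
        A = build_aberration_matrix(stack, 1)
        g = 0
        kin = A.kin_table[g]
        yy, xx = grid96.r_mesh()
        t_spec = fft2_centered(
            target * np.exp(1j * (kin[0] * xx + kin[1] * yy)), grid96
        )
        mask = pupil_mask(grid96, grid96.na_det)
        shifted_mask = mask & np.roll(mask, -1, axis=1)
        col = A.to_grid(A.entries[:, g])
        # for a tilt within the memory effect T(k+dk; k_in+dk) = T(k; k_in),
        # so the raw modulus is |T|^2
        t2 = np.abs(t_spec) ** 2
        sel = shifted_mask & (t2 > 1e-3 * t2.max())
        np.testing.assert_allclose(np.abs(col[sel]), t2[sel], rtol=1e-6)

    def test_subpixel_tilt_accepted(self, grid96):
        # the experimental tilt magnitude (0.0054 / lambda) is sub-pixel here
        delta_u = 0.0054 / grid96.wavelength  # 1/um
        delta_px = 2 * np.pi * delta_u / grid96.dkx
        assert delta_px < 1
        stack, _ = make_thin_stack(grid96, seed=5, delta_k_px=delta_px, n_groups=6)
        A = build_aberration_matrix(stack, 1)
        assert np.all(np.isfinite(A.entries))

    def test_missing_slot_rejected(self, grid96):
        stack, _ = make_thin_stack(grid96, seed=5, n_groups=4)
        with pytest.raises(IndexError):
            build_aberration_matrix(stack, 3)


class TestThresholdReweight:
    def test_zero_threshold_makes_unimodular(self, grid64):
        rng = np.random.default_rng(0)
        entries = rng.normal(size=(20, 4)) + 1j * rng.normal(size=(20, 4))
        A = toy_matrix(grid64, entries)
        out = threshold_reweight(A, 0.0)
        nz = out.entries[np.abs(out.entries) > 0]
        np.testing.assert_allclose(np.abs(nz), 1.0, atol=1e-12)
        assert out.weight_state == "thresholded"

    def test_survivor_count_brute_force(self, grid64):
        moduli = np.array(
            [[3.0, 1.0, 0.2, 0.7], [0.4, 2.0, 0.45, 0.55],
             [0.5, 0.05, 5.0, 0.9], [1.5, 0.3, 0.6, 0.1],
             [0.51, 0.49, 2.5, 0.0], [0.2, 0.8, 0.52, 3.3]]
        )
        rng = np.random.default_rng(1)
        entries = moduli * np.exp(1j * rng.uniform(-np.pi, np.pi, moduli.shape))
        A = toy_matrix(grid64, entries)
        out = threshold_reweight(A, 0.5)
        assert int(np.count_nonzero(out.entries)) == int((moduli > 0.5).sum())

    def test_quantile_spec_keeps_exact_count(self, grid64):
        rng = np.random.default_rng(2)
        entries = rng.normal(size=(25, 4)) + 1j * rng.normal(size=(25, 4))
        A = toy_matrix(grid64, entries)
        out = threshold_reweight(A, "q:0.7")
        n_nonzero = int(np.count_nonzero(entries))
        assert int(np.count_nonzero(out.entries)) == int(np.ceil(0.3 * n_nonzero))

    def test_idempotent(self, grid64):
        rng = np.random.default_rng(3)
        entries = rng.normal(size=(15, 3)) + 1j * rng.normal(size=(15, 3))
        A = threshold_reweight(toy_matrix(grid64, entries), "q:0.6")
        twice = threshold_reweight(A, "q:0.6")
        np.testing.assert_array_equal(A.entries, twice.entries)

    def test_overaggressive_threshold_warns(self, grid64):
        rng = np.random.default_rng(4)
        entries = rng.normal(size=(40, 5)) + 1j * rng.normal(size=(40, 5))
        with pytest.warns(UserWarning, match="99%"):
            threshold_reweight(toy_matrix(grid64, entries), 1e6)


class TestMaskOffdiagonal:
    def test_full_radius_is_noop(self, grid96):
        # |k_out - k_in| is bounded by k_NA,det + k_NA,ill, so a radius that
        # covers that sum leaves every entry untouched
        stack, _ = make_thin_stack(grid96, seed=6, n_groups=6)
        A = build_aberration_matrix(stack, 1)
        out = mask_offdiagonal(A, grid96.na_det + grid96.na_ill)
        np.testing.assert_array_equal(out.entries, A.entries)

    def test_zeroed_set_matches_enumeration(self, grid96):
        stack, _ = make_thin_stack(grid96, seed=7, n_groups=6)
        A = build_aberration_matrix(stack, 1)
        out = mask_offdiagonal(A, 0.35)
        k_rad = 2 * np.pi * 0.35 / grid96.wavelength
        kc = A.row_k_coords()
        for g in range(A.n_groups):
            far = np.hypot(kc[:, 0] - A.kin_table[g, 0],
                           kc[:, 1] - A.kin_table[g, 1]) > k_rad + 1e-12
            assert np.all(out.entries[far, g] == 0)
            np.testing.assert_array_equal(out.entries[~far, g], A.entries[~far, g])


class TestFactorization:
    def _rank1(self, grid64, n_rows=40, n_cols=6, seed=0, sigma=0.0):
        rng = np.random.default_rng(seed)
        pho = rng.uniform(-np.pi, np.pi, n_rows)
        phi = rng.uniform(-np.pi, np.pi, n_cols)
        entries = np.exp(1j * pho)[:, None] * np.exp(1j * phi)[None, :]
        if sigma:
            entries = entries + sigma * (
                rng.normal(size=entries.shape) + 1j * rng.normal(size=entries.shape)
            )
        return toy_matrix(grid64, entries), pho, phi

    def _row_values(self, A, field, n_rows):
        return field.values[A.row_mask][:n_rows]

    @pytest.mark.parametrize("method", [factorize_svd, factorize_projection_power])
    def test_exact_rank1_recovery(self, grid64, method):
        A, pho, phi = self._rank1(grid64)
        At = threshold_reweight(A, 0.0)
        d_out, d_in = method(At)[:2]
        est = self._row_values(At, d_out, 40)
        err = wrap_phase(est - pho)
        err = wrap_phase(err - np.angle(np.mean(np.exp(1j * err))))
        assert np.max(np.abs(err)) < 1e-9
        est_in = d_in.samples[1]
        err_in = wrap_phase(est_in - phi)
        err_in = wrap_phase(err_in - np.angle(np.mean(np.exp(1j * err_in))))
        assert np.max(np.abs(err_in)) < 1e-9

    def test_all_ones_gives_zero_phases(self, grid64):
        A = toy_matrix(grid64, np.ones((30, 5), dtype=complex))
        At = threshold_reweight(A, 0.0)
        d_out, d_in = factorize_svd(At)
        assert np.max(np.abs(self._row_values(At, d_out, 30))) < 1e-12

    def test_noisy_rank1_circular_correlation(self, grid64):
        A, pho, _ = self._rank1(grid64, n_rows=200, n_cols=12, seed=5, sigma=0.1)
        At = threshold_reweight(A, 0.0)
        d_out, _ = factorize_svd(At)
        est = self._row_values(At, d_out, 200)
        err = wrap_phase(est - pho)
        assert np.abs(np.mean(np.exp(1j * err))) > 0.99

    def test_zero_matrix_rejected(self, grid64):
        A = toy_matrix(grid64, np.zeros((10, 3), dtype=complex))
        with pytest.raises(ValueError):
            factorize_svd(A)
        with pytest.raises(ValueError):
            factorize_projection_power(A)

    def test_power_fixed_point_after_one_iteration(self, grid64):
        A, pho, phi = self._rank1(grid64, seed=2)
        At = threshold_reweight(A, 0.0)
        d_out, d_in, obj = factorize_projection_power(At, return_objective=True)
        # exact rank-1: converged in a couple of sweeps, objective flat
        assert len(obj) <= 4
        est = self._row_values(At, d_out, 40)
        err = wrap_phase(est - pho)
        err = wrap_phase(err - np.angle(np.mean(np.exp(1j * err))))
        assert np.max(np.abs(err)) < 1e-12

    def test_objective_nondecreasing_on_noisy_data(self, grid64):
        A, _, _ = self._rank1(grid64, n_rows=100, n_cols=10, seed=9, sigma=0.5)
        At = threshold_reweight(A, 0.0)
        *_, obj = factorize_projection_power(At, return_objective=True)
        assert np.all(np.diff(obj) >= -1e-6 * obj[0])

    def test_power_iteration_dominates_projected_svd(self, grid64):
        """On thresholded speckle-weighted matrices the power iteration is
        the proper UQP solver: its objective always beats the unimodular
        projection of the SVD vector, and its phase error wins the paired
        comparison in the majority of trials."""
        trials = 50
        obj_wins = 0
        err_wins = 0
        for t in range(trials):
            rng = np.random.default_rng(100 + t)
            pho = rng.uniform(-np.pi, np.pi, 60)
            phi = rng.uniform(-np.pi, np.pi, 8)
            amp = rng.rayleigh(1.0, size=(60, 8))
            e = amp * np.exp(1j * pho)[:, None] * np.exp(1j * phi)[None, :]
            e = e + 0.3 * (rng.normal(size=e.shape) + 1j * rng.normal(size=e.shape))
            At = threshold_reweight(toy_matrix(grid64, e), {"q": 0.6})
            M = At.entries.conj().T @ At.entries
            _, _, Vh = np.linalg.svd(At.entries, full_matrices=False)
            v_svd = np.exp(1j * np.angle(Vh[0].conj()))
            obj_svd = float(np.real(v_svd.conj() @ M @ v_svd))
            *_, obj = factorize_projection_power(At, return_objective=True)
            if obj[-1] >= obj_svd * (1 - 1e-12):
                obj_wins += 1

            def err_of(method):
                d_out, *_ = method(At)
                sup = d_out.support[At.row_mask][:60]
                est = self._row_values(At, d_out, 60)
                err = wrap_phase(est - pho)[sup]
                err = wrap_phase(err - np.angle(np.mean(np.exp(1j * err))))
                return np.sqrt(np.mean(err**2))

            if err_of(factorize_projection_power) <= err_of(factorize_svd) + 1e-12:
                err_wins += 1
        assert obj_wins == trials
        assert err_wins > trials // 2

    def test_global_optimum_matches_bruteforce_3x3(self, grid64):
        # exhaustive UQP oracle: discretize each phase over 16 steps
        rng = np.random.default_rng(12)
        entries = np.exp(1j * rng.uniform(-np.pi, np.pi, (3, 3)))
        entries += 0.3 * (rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3)))
        A = toy_matrix(grid64, entries)
        At = threshold_reweight(A, 0.0)
        M = At.entries[:3].conj().T @ At.entries[:3]
        best = -np.inf
        grid_phases = np.linspace(-np.pi, np.pi, 16, endpoint=False)
        for p in itertools.product(grid_phases, repeat=2):
            v = np.exp(1j * np.array([0.0, *p]))  # global phase fixed
            best = max(best, float(np.real(v.conj() @ M @ v)))
        *_, obj = factorize_projection_power(At, return_objective=True)
        step = 2 * np.pi / 16
        # discretization cost of the oracle bounds the allowed shortfall
        assert obj[-1] >= best * (1 - step**2)


class TestIntegrateGradients:
    def _field(self, grid, values, direction, support):
        return PhaseDifferenceField(
            grid=grid, direction=np.asarray(direction), side="outgoing",
            values=values, support=support,
        )

    def test_zero_gradients_give_flat_phase(self, grid64):
        mask = pupil_mask(grid64, grid64.na_det)
        d1 = self._field(grid64, np.zeros(grid64.shape), (grid64.dkx, 0), mask)
        d2 = self._field(grid64, np.zeros(grid64.shape), (0, grid64.dky), mask)
        phi = integrate_gradients(d1, d2)
        assert np.max(np.abs(phi.phase)) < 1e-10

    def test_zernike_round_trip(self, grid96):
        phi_true = smooth_pupil_phase(grid96, "out") * 1.4  # peak ~5 rad
        mask = pupil_mask(grid96, grid96.na_det)
        supp1 = mask & np.roll(mask, -1, axis=1)
        supp2 = mask & np.roll(mask, -1, axis=0)
        d1 = self._field(grid96, np.roll(phi_true, -1, axis=1) - phi_true,
                         (grid96.dkx, 0), supp1)
        d2 = self._field(grid96, np.roll(phi_true, -1, axis=0) - phi_true,
                         (0, grid96.dky), supp2)
        phi = integrate_gradients(d1, d2)
        sup = phi.support
        resid = (phi.phase - phi_true)[sup]
        resid -= resid.mean()
        assert np.max(np.abs(resid)) < 0.02

    def test_linear_ramp_preserved(self, grid64):
        ky, kx = grid64.k_mesh()
        a = 0.15  # rad um
        phi_true = a * kx
        mask = pupil_mask(grid64, grid64.na_det)
        d1 = self._field(grid64, np.full(grid64.shape, a * grid64.dkx),
                         (grid64.dkx, 0), mask)
        d2 = self._field(grid64, np.zeros(grid64.shape), (0, grid64.dky), mask)
        phi = integrate_gradients(d1, d2)
        sup = phi.support
        resid = (phi.phase - phi_true)[sup]
        resid -= resid.mean()
        assert np.max(np.abs(resid)) < 1e-6

    def test_degenerate_directions_rejected(self, grid64):
        mask = pupil_mask(grid64, grid64.na_det)
        d1 = self._field(grid64, np.zeros(grid64.shape), (grid64.dkx, 0), mask)
        d2 = self._field(grid64, np.zeros(grid64.shape), (2 * grid64.dkx, 0), mask)
        with pytest.raises(ValueError, match="linearly"):
            integrate_gradients(d1, d2)


class TestRetrievePsf:
    def test_flat_phase_gives_centered_airy(self, grid64):
        mask = pupil_mask(grid64, grid64.na_det)
        phi = AberrationFunction(grid=grid64, phase=np.zeros(grid64.shape),
                                 support=mask, side="outgoing")
        psf = retrieve_psf(phi)
        assert np.sum(np.abs(psf) ** 2) == pytest.approx(1.0)
        peak = np.unravel_index(np.argmax(np.abs(psf)), psf.shape)
        assert peak == (grid64.ny // 2, grid64.nx // 2)

    def test_linear_ramp_shifts_psf(self, grid64):
        mask = pupil_mask(grid64, grid64.na_det)
        ky, kx = grid64.k_mesh()
        shift_um = 5 * grid64.dx
        phi = AberrationFunction(grid=grid64, phase=np.where(mask, shift_um * kx, 0),
                                 support=mask, side="outgoing")
        psf = retrieve_psf(phi)
        peak = np.unravel_index(np.argmax(np.abs(psf)), psf.shape)
        assert peak[1] - grid64.nx // 2 == pytest.approx(-5, abs=1)

    def test_strehl_matches_marechal_for_weak_screens(self, grid64):
        rng = np.random.default_rng(8)
        mask = pupil_mask(grid64, grid64.na_det)
        flat = AberrationFunction(grid=grid64, phase=np.zeros(grid64.shape),
                                  support=mask, side="outgoing")
        peak0 = np.max(np.abs(retrieve_psf(flat)) ** 2)
        for sigma in (0.2, 0.5):
            noise = rng.normal(scale=sigma, size=grid64.shape)
            noise -= noise[mask].mean()
            phi = AberrationFunction(grid=grid64, phase=np.where(mask, noise, 0),
                                     support=mask, side="outgoing")
            strehl = np.max(np.abs(retrieve_psf(phi)) ** 2) / peak0
            s = np.std(noise[mask])
            assert strehl == pytest.approx(np.exp(-(s**2)), rel=0.2)


class TestEndToEnd:
    @pytest.mark.parametrize("solver", ["power", "svd"])
    def test_recover_known_aberration(self, grid96, solver):
        phi_out = smooth_pupil_phase(grid96, "out")  # ~2 rad RMS
        phi_in = smooth_pupil_phase(grid96, "in")
        stack, _ = make_thin_stack(grid96, phi_out=phi_out, phi_in=phi_in, seed=1)
        phi, info = detect_aberration(stack, DetectorConfig(solver=solver))
        aligned = align_piston_tilt(phi.phase, phi_out, phi.support, grid96)
        assert circular_correlation(aligned, phi_out, phi.support) > 0.99

    def test_factorization_consistency(self, grid96):
        # arg(A) - [dphi_out + dphi_in] has small circular variance
        phi_out = smooth_pupil_phase(grid96, "out")
        stack, _ = make_thin_stack(grid96, phi_out=phi_out, seed=11)
        A = threshold_reweight(build_aberration_matrix(stack, 1), "q:0.6")
        d_out, d_in = factorize_projection_power(A)
        recon = d_out.values[A.row_mask][:, None] + np.asarray(d_in.samples[1])[None, :]
        resid = np.angle(A.entries * np.exp(-1j * recon))
        resid = resid[np.abs(A.entries) > 0]
        mean = np.mean(np.exp(1j * resid))
        assert np.abs(np.angle(mean)) < 0.02
        assert 1 - np.abs(mean) < 0.01  # circular variance

    def test_time_reversal_map(self, grid64):
        mask = pupil_mask(grid64, grid64.na_det)
        ky, kx = grid64.k_mesh()
        phi = AberrationFunction(grid=grid64, phase=np.where(mask, 0.3 * kx + 0.1 * ky**2, 0),
                                 support=mask, side="outgoing")
        rev = time_reversed_incoming(phi)
        # phi_in(k) must equal phi_out(-k) at exact lattice points
        for iy, ix in [(35, 40), (28, 30), (32, 32)]:
            jx = grid64.nx - (ix - grid64.nx // 2) - grid64.nx // 2
            jy = grid64.ny - (iy - grid64.ny // 2) - grid64.ny // 2
            kxv, kyv = kx[iy, ix], ky[iy, ix]
            iyn = grid64.ny // 2 - (iy - grid64.ny // 2)
            ixn = grid64.nx // 2 - (ix - grid64.nx // 2)
            assert rev.phase[iy, ix] == pytest.approx(phi.phase[iyn, ixn])
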