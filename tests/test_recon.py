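"""k-t FOCUSS engine: operators, CG solver, outer loop, KLT, diagnostics."""

import numpy as np
import pytest

import ktfmri as k
from ktfmri.recon import (
    ReconConfig,
    TemporalTransform,
    adjoint_model,
    build_klt,
    cg_solve,
    forward_model,
    ktfocuss,
    reconstruct,
    residual_error,
    select_nfoc_cv,
    stopping_criterion,
)
from ktfmri.recon import _mode_smallest

from _oracles import exhaustive_l1, focuss_toy_reconstruction, sparse_instance


def _random_mask(n_pe, t, rng, frac=0.4):
    lines = rng.random((n_pe, t)) < frac
    lines[n_pe // 2 - 1, :] = True
    return k.SamplingMask("CUSTOM", lines, 1)


class TestOperators:
    def test_forward_of_zero_is_zero(self):
        rng = np.random.default_rng(0)
        mask = _random_mask(8, 6, rng)
        phi = TemporalTransform.fourier(6)
        assert np.all(forward_model(np.zeros((4, 8, 6), complex), mask, phi) == 0)

    def test_adjoint_identity_at_full_sampling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 8, 6)) + 1j * rng.standard_normal((4, 8, 6))
        mask = k.full_mask(8, 6)
        phi = TemporalTransform.fourier(6)
        back = adjoint_model(forward_model(x, mask, phi), mask, phi)
        np.testing.assert_allclose(back, x, atol=1e-10)

    def test_adjoint_inner_product_identity(self):
        rng = np.random.default_rng(2)
        mask = _random_mask(8, 6, rng)
        phi = TemporalTransform.fourier(6)
        x = rng.standard_normal((4, 8, 6)) + 1j * rng.standard_normal((4, 8, 6))
        y = rng.standard_normal((4, 8, 6)) + 1j * rng.standard_normal((4, 8, 6))
        lhs = np.vdot(y.ravel(), forward_model(x, mask, phi).ravel())
        rhs = np.vdot(adjoint_model(y, mask, phi).ravel(), x.ravel())
        assert abs(lhs - rhs) < 1e-8 * max(abs(lhs), 1.0)

    def test_non_unitary_transform_rejected(self):
        with pytest.raises(ValueError, match="unitary"):
            TemporalTransform(np.ones((4, 4)), kind="FT")


class TestCgSolve:
    def test_identity_weights_full_mask_recovers_transform(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((4, 8, 6)) + 1j * rng.standard_normal((4, 8, 6))
        mask = k.full_mask(8, 6)
        phi = TemporalTransform.fourier(6)
        w = np.ones((4, 8, 6))
        q, _ = cg_solve(mask, phi, w, y, lam=0.0, n_cg=30)
        np.testing.assert_allclose(w * q, adjoint_model(y, mask, phi), atol=1e-6)

    def test_huge_lambda_bounds_solution_norm(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((4, 8, 6)) + 1j * rng.standard_normal((4, 8, 6))
        mask = _random_mask(8, 6, rng)
        phi = TemporalTransform.fourier(6)
        w = rng.uniform(0.5, 2.0, (4, 8, 6))
        lam = 1e6
        q, _ = cg_solve(mask, phi, w, y, lam=lam, n_cg=30)
        b = w * adjoint_model(y, mask, phi)
        assert np.linalg.norm(q) <= np.linalg.norm(b) / lam * (1 + 1e-6)

    def test_matches_dense_normal_equation_solve(self):
        """Small system: CG agrees with a dense linear-algebra oracle."""
        rng = np.random.default_rng(5)
        n_pe, t = 4, 2
        mask = _random_mask(n_pe, t, rng, frac=0.5)
        phi = TemporalTransform.fourier(t)
        w = rng.uniform(0.2, 1.5, (1, n_pe, t))
        y = rng.standard_normal((1, n_pe, t)) + 1j * rng.standard_normal((1, n_pe, t))
        lam = 0.3
        dim = n_pe * t
        dense = np.zeros((dim, dim), complex)
        for j in range(dim):
            e = np.zeros(dim, complex)
            e[j] = 1.0
            ej = e.reshape(1, n_pe, t)
            dense[:, j] = (
                w * adjoint_model(forward_model(w * ej, mask, phi), mask, phi) + lam * ej
            ).ravel()
        b = (w * adjoint_model(y, mask, phi)).ravel()
        expected = np.linalg.solve(dense, b)
        q, _ = cg_solve(mask, phi, w, y, lam=lam, n_cg=200)
        np.testing.assert_allclose(q.ravel(), expected, atol=1e-6 * np.abs(expected).max())


class TestKtFocuss:
    def test_requires_mask(self, clean_series):
        ks = k.KSpaceSeries(k.image_to_kspace(clean_series.frames))
        with pytest.raises(ValueError, match="mask"):
            ktfocuss(ks, ReconConfig.ft())

    def test_full_sampling_identity(self, noisy_kspace):
        images = k.kspace_to_image(noisy_kspace.data)
        res = ktfocuss(noisy_kspace, ReconConfig.ft(lam=0.0))
        rel = np.linalg.norm(res.series.frames - images) / np.linalg.norm(images)
        assert rel < 1e-6
        assert res.series.provenance == "reconstruction"

    def test_deterministic(self, grc1_kspace):
        a = ktfocuss(grc1_kspace, ReconConfig.ft(n_foc=2))
        b = ktfocuss(grc1_kspace, ReconConfig.ft(n_foc=2))
        np.testing.assert_array_equal(a.series.frames, b.series.frames)

    def test_auto_stops_and_reports_count(self, grc1_kspace):
        res = ktfocuss(grc1_kspace, ReconConfig.ft())
        assert res.converged and 1 <= res.n_foc_used <= 20
        assert len(res.residual_trace) == res.n_foc_used

    def test_residual_nonincreasing_within_inner_solves(self, grc1_kspace):
        res = ktfocuss(grc1_kspace, ReconConfig.ft(n_foc=3))
        for trace in res.residual_trace:
            slack = 1e-8 * trace[0]
            assert np.all(np.diff(trace) <= slack)

    def test_mean_subtract_roundtrip_at_full_sampling(self, noisy_kspace):
        images = k.kspace_to_image(noisy_kspace.data)
        res = ktfocuss(noisy_kspace, ReconConfig.ft(lam=0.0, mean_subtract=True))
        rel = np.linalg.norm(res.series.frames - images) / np.linalg.norm(images)
        assert rel < 1e-6

    def test_sparse_recovery_matches_l1_oracle_at_convergence(self):
        """FOCUSS with p = 0.5, run to convergence, lands on the minimum-l1
        solution of 1D partial-Fourier toys (support and values)."""
        ok_support = ok_value = 0
        for seed in range(20):
            coef, samples, y = sparse_instance(seed)
            oracle = exhaustive_l1(samples, y)
            recovered = focuss_toy_reconstruction(samples, y, n_foc=16)
            sup_f = np.abs(recovered) > 1e-2 * np.abs(recovered).max()
            sup_o = np.abs(oracle) > 1e-2 * np.abs(oracle).max()
            ok_support += np.array_equal(sup_f, sup_o)
            ok_value += np.abs(recovered - oracle).max() < 1e-3
        assert ok_support >= 19
        assert ok_value >= 19


class TestStoppingCriterion:
    def test_identical_iterates_stop(self):
        u = np.ones((2, 2, 2))
        assert stopping_criterion(u, u, 0.1) is True

    def test_zero_previous_iterate_continues(self):
        u = np.ones((2, 2, 2))
        assert stopping_criterion(u, np.zeros_like(u), 0.1) is False

    def test_hand_computed_ratio(self):
        # ||[0, 0.4]|| / ||[3, 4]|| = 0.08 < 0.1
        assert stopping_criterion(np.array([3.0, 4.0]), np.array([3.0, 3.6]), 0.1) is True

    def test_zero_norm_current_raises(self):
        with pytest.raises(ValueError, match="zero norm"):
            stopping_criterion(np.zeros(3), np.ones(3), 0.1)


class TestResidualError:
    def test_exact_match_and_zero_reconstruction(self, grc1_kspace):
        assert residual_error(grc1_kspace, grc1_kspace) == 0.0
        zero = k.KSpaceSeries(
            np.zeros_like(grc1_kspace.data), mask=grc1_kspace.mask, paradigm=grc1_kspace.paradigm
        )
        expected = float(np.sum(np.abs(grc1_kspace.data) ** 2))
        assert residual_error(grc1_kspace, zero) == pytest.approx(expected)

    def test_three_entry_toy(self):
        lines = np.ones((3, 1), bool)
        mask = k.SamplingMask("CUSTOM", lines, 1)
        y = k.KSpaceSeries(np.array([1 + 0j, 0 + 1j, 2 + 0j]).reshape(1, 3, 1), mask=mask)
        zero = k.KSpaceSeries(np.zeros((1, 3, 1), complex), mask=mask)
        assert residual_error(y, zero) == pytest.approx(6.0)

    def test_mask_mismatch_raises(self, grc1_kspace, noisy_kspace):
        with pytest.raises(ValueError, match="mask"):
            residual_error(grc1_kspace, noisy_kspace)


class TestBuildKlt:
    def test_rank_one_series_concentrates_trace(self):
        rng = np.random.default_rng(6)
        spatial = rng.standard_normal((5, 4))
        course = rng.standard_normal(8)
        frames = spatial[:, :, None] * course[None, None, :]
        phi = build_klt(k.ImageSeries(frames))
        assert phi.eigenvalues[0] / phi.eigenvalues.sum() > 0.999

    def test_transform_is_unitary(self, grc1_kspace):
        prelim = ktfocuss(grc1_kspace, ReconConfig.ft(n_foc=2))
        phi = build_klt(prelim)
        gram = phi.matrix @ phi.matrix.conj().T
        assert np.abs(gram - np.eye(phi.n_frames)).max() < 1e-10

    def test_matches_dense_eigen_oracle_on_4x4(self):
        rng = np.random.default_rng(7)
        frames = rng.standard_normal((3, 3, 4)) + 1j * rng.standard_normal((3, 3, 4))
        phi = build_klt(k.ImageSeries(frames))
        u = frames.reshape(-1, 4)
        cov = u.conj().T @ u
        evals, evecs = np.linalg.eigh(0.5 * (cov + cov.conj().T))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(phi.eigenvalues, evals, atol=1e-8 * evals[0])
        # rows of Phi match eigenvectors up to phase
        overlap = np.abs(np.diag(phi.matrix @ evecs))
        np.testing.assert_allclose(overlap, 1.0, atol=1e-8)

    def test_all_zero_preliminary_raises(self):
        with pytest.raises(ValueError, match="zero"):
            build_klt(k.ImageSeries(np.zeros((2, 2, 3), complex)))


class TestTransformInvariance:
    def test_ft_and_klt_agree_at_full_sampling(self, noisy_kspace):
        ft = ktfocuss(noisy_kspace, ReconConfig.ft(lam=0.0))
        klt = reconstruct(noisy_kspace, ReconConfig.klt(lam=0.0))
        rel = np.linalg.norm(ft.series.frames - klt.series.frames) / np.linalg.norm(
            ft.series.frames
        )
        assert rel < 1e-6


class TestSelectNfoc:
    def test_mode_prefers_smaller_on_ties(self):
        assert _mode_smallest([3, 3, 4]) == 3
        assert _mode_smallest([5, 5, 5]) == 5
        assert _mode_smallest([2, 3]) == 2

    def test_requires_two_datasets(self, noisy_kspace):
        with pytest.raises(ValueError, match="2 datasets"):
            select_nfoc_cv([noisy_kspace], "GRC1", ReconConfig.ft())

    def test_klt_needs_at_least_as_many_outer_steps(self, paradigm, acq):
        """Cross-validated outer-iteration counts on a 3-subject synthetic
        GRC1 run: the KLT variant stops no earlier than temporal FT."""
        datasets = []
        for s in range(3):
            ph = k.make_phantom((64, 48), seed=100 + s)
            series = k.simulate_timeseries(ph, paradigm, acq)
            sd = k.noise_sd_for_snr(series, 20.0)
            datasets.append(k.to_kspace(series, noise_sd=sd, seed=200 + s))
        ft = select_nfoc_cv(datasets, "GRC1", ReconConfig.ft(), base_seed=1)
        klt = select_nfoc_cv(datasets, "GRC1", ReconConfig.klt(), base_seed=1)
        assert len(ft.per_holdout) == 3
        assert klt.value >= ft.value
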