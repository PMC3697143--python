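"""HTF estimation, complex Wilks U, Rao's F and the voxelwise driver."""

import numpy as np
import pytest
from scipy import stats

from spectralglm import (
    Contrast,
    MultiRunSeries,
    cross_spectra_from_data,
    estimate_htf,
    error_spectral_matrix,
    hypothesis_matrices,
    make_band_partition,
    pvalue,
    rao_f,
    run_voxelwise_tests,
    standard_contrasts,
    wilks_u,
)
from spectralglm.cglm import SingularResidualError, evaluate_contrast
from spectralglm.spectral import ConfigurationError, SpectraBundle, estimate_cross_spectra


def random_bundle(rng, T=60, m=2, R=2, S=3, V=4):
    part = make_band_partition(T, m)
    K = T // 2 + 1
    stim_dft = rng.standard_normal((K, R)) + 1j * rng.standard_normal((K, R))
    bold_dft = rng.standard_normal((V, S, K)) + 1j * rng.standard_normal((V, S, K))
    return estimate_cross_spectra(stim_dft, bold_dft, part), stim_dft, bold_dft


class TestEstimateHtf:
    def test_identity_frr_returns_f_rs(self, rng):
        bundle, _, _ = random_bundle(rng)
        nb = bundle.f_rr.shape[0]
        eye = np.broadcast_to(np.eye(2), (nb, 2, 2)).copy()
        synthetic = SpectraBundle(
            f_rr=eye, f_rs=bundle.f_rs, f_ss=bundle.f_ss, partition=bundle.partition
        )
        est = estimate_htf(synthetic)
        assert np.allclose(est.A_hat, bundle.f_rs, atol=1e-12)

    def test_zero_f_rs_gives_zero_htf(self, rng):
        bundle, _, _ = random_bundle(rng)
        synthetic = SpectraBundle(
            f_rr=bundle.f_rr,
            f_rs=np.zeros_like(bundle.f_rs),
            f_ss=bundle.f_ss,
            partition=bundle.partition,
        )
        assert np.all(estimate_htf(synthetic).A_hat == 0)

    def test_equals_stacked_least_squares_solution(self, rng):
        """A_hat solves the complex LS problem over the band's frequencies."""
        bundle, stim_dft, bold_dft = random_bundle(rng)
        est = estimate_htf(bundle)
        part = bundle.partition
        for j in range(part.n_bands):
            X = stim_dft[part.members(j)]  # (w, R)
            for v in range(bundle.n_voxels):
                Y = bold_dft[v, :, part.members(j)]  # (w, S)
                A_ls = np.linalg.lstsq(X, Y, rcond=None)[0]
                rel = np.linalg.norm(est.A_hat[j, v] - A_ls) / np.linalg.norm(A_ls)
                assert rel < 1e-8

    def test_ill_conditioned_design_raises_naming_band(self, rng):
        bundle, _, _ = random_bundle(rng)
        bad_rr = bundle.f_rr.copy()
        bad_rr[1] = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank deficient
        broken = SpectraBundle(
            f_rr=bad_rr, f_rs=bundle.f_rs, f_ss=bundle.f_ss, partition=bundle.partition
        )
        with pytest.raises(ValueError, match="band.*1"):
            estimate_htf(broken)


class TestErrorSpectralMatrix:
    def test_hermitian_to_tolerance(self, rng):
        bundle, _, _ = random_bundle(rng)
        G = error_spectral_matrix(bundle)
        assert np.allclose(G, np.conj(np.swapaxes(G, -1, -2)), atol=1e-12)

    def test_perfect_fit_leaves_zero_residual(self, rng):
        """If s~ = r~ A exactly at all in-band frequencies, G vanishes."""
        part = make_band_partition(60, 2)
        K = 31
        stim_dft = rng.standard_normal((K, 2)) + 1j * rng.standard_normal((K, 2))
        A0 = rng.standard_normal((2, 3)) + 1j * rng.standard_normal((2, 3))
        bold_dft = np.einsum("kr,rs->sk", stim_dft, A0)[None]
        bundle = estimate_cross_spectra(stim_dft, bold_dft, part)
        G = error_spectral_matrix(bundle)
        assert np.allclose(G, 0, atol=1e-10)
        eig = np.linalg.eigvalsh(G)
        assert eig.min() > -1e-10

    def test_matches_direct_formula_evaluation(self, rng):
        bundle, _, _ = random_bundle(rng)
        G = error_spectral_matrix(bundle)
        w = bundle.partition.width
        for j in range(bundle.f_rr.shape[0]):
            inv = np.linalg.inv(bundle.f_rr[j])
            for v in range(bundle.n_voxels):
                f_rs = bundle.f_rs[j, v]
                direct = w * (bundle.f_ss[j, v] - f_rs.conj().T @ inv @ f_rs)
                direct = 0.5 * (direct + direct.conj().T)
                assert np.allclose(G[j, v], direct, atol=1e-10)


class TestHypothesisMatrices:
    def test_identity_contrasts_recover_a_hat_and_g(self, rng):
        bundle, _, _ = random_bundle(rng)
        est = estimate_htf(bundle)
        mats = hypothesis_matrices(est, bundle, Contrast(np.eye(2), np.eye(3), "omni"))
        assert np.allclose(mats.E, est.A_hat, atol=1e-12)
        assert np.allclose(mats.G_c, error_spectral_matrix(bundle), atol=1e-10)

    def test_zero_htf_gives_zero_hypothesis_matrix(self, rng):
        bundle, _, _ = random_bundle(rng)
        synthetic = SpectraBundle(
            f_rr=bundle.f_rr,
            f_rs=np.zeros_like(bundle.f_rs),
            f_ss=bundle.f_ss,
            partition=bundle.partition,
        )
        est = estimate_htf(synthetic)
        mats = hypothesis_matrices(
            est, synthetic, Contrast([[1, -1]], [[1, -1, 0], [0, 1, -1]], "inter")
        )
        assert np.allclose(mats.H, 0, atol=1e-12)

    def test_matches_direct_matrix_arithmetic(self, rng):
        bundle, _, _ = random_bundle(rng)
        est = estimate_htf(bundle)
        B = np.array([[1.0, -1.0]])
        C = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        mats = hypothesis_matrices(est, bundle, Contrast(B, C, "inter"))
        w = bundle.partition.width
        for j in range(bundle.f_rr.shape[0]):
            V = B @ np.linalg.inv(bundle.f_rr[j]) @ B.T
            for v in range(bundle.n_voxels):
                E = B @ est.A_hat[j, v] @ C.T
                H = w * (E.conj().T @ np.linalg.inv(V) @ E)
                assert np.allclose(mats.H[j, v], H, atol=1e-10)
                assert np.allclose(mats.E[j, v], E, atol=1e-12)


class TestWilksU:
    def test_zero_hypothesis_matrix_gives_one(self):
        G_c = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert wilks_u(G_c, np.zeros((2, 2))) == pytest.approx(1.0)

    def test_scalar_case(self):
        assert wilks_u(np.array([[2.0]]), np.array([[6.0]])) == pytest.approx(0.25)

    def test_matches_eigenvalue_product_evaluation(self, rng):
        M = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        G_c = M @ M.conj().T + 0.5 * np.eye(3)
        N = rng.standard_normal((3, 2)) + 1j * rng.standard_normal((3, 2))
        H = N @ N.conj().T
        expect = np.prod(np.linalg.eigvalsh(G_c)) / np.prod(np.linalg.eigvalsh(G_c + H))
        assert wilks_u(G_c, H) == pytest.approx(expect, rel=1e-10)

    def test_singular_residual_raises(self):
        with pytest.raises(SingularResidualError):
            wilks_u(np.zeros((2, 2)), np.eye(2))


class TestRaoF:
    @pytest.mark.parametrize(
        "b, c, df1, df2, d, h",
        [
            (1, 2, 4, 20.0, 1.0, 10.0),  # multivariate state effect
            (1, 1, 2, 22.0, 1.0, 11.0),  # univariate-style tests
            (2, 3, 12, 36.0, 2.0, 18.0),  # omnibus
        ],
    )
    def test_degrees_of_freedom_for_study_design(self, b, c, df1, df2, d, h):
        F, got_df1, got_df2, got_d, got_h = rao_f(0.5, b=b, c=c, m=6, R=2)
        assert (got_df1, got_df2) == (df1, df2)
        assert (got_d, got_h) == (d, h)

    def test_d_unity_branch_triggers_at_b2c2_five(self):
        # b=1, c=2 -> b^2+c^2 = 5 exactly
        assert rao_f(0.3, 1, 2, 6, 2)[3] == 1.0

    def test_u_of_one_gives_zero_f(self):
        for b, c in [(1, 1), (1, 2), (2, 3)]:
            assert rao_f(1.0, b, c, 6, 2)[0] == pytest.approx(0.0)

    def test_f_identity_with_u(self):
        F, df1, df2, d, h = rao_f(0.37, 2, 3, 6, 2)
        b, c = 2, 3
        assert F == pytest.approx((h / (b * c)) * (1 - 0.37 ** (1 / d)) / 0.37 ** (1 / d))

    def test_negative_h_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            rao_f(0.5, b=1, c=3, m=1, R=3)


class TestPvalue:
    def test_zero_f_gives_one(self):
        assert pvalue(0.0, 4, 20) == pytest.approx(1.0)

    def test_median_maps_to_half(self):
        med = stats.f.ppf(0.5, 4, 20)
        assert pvalue(med, 4, 20) == pytest.approx(0.5, abs=1e-12)

    def test_huge_f_is_deep_in_the_tail(self):
        assert pvalue(1e6, 4, 20) < 1e-10

    def test_invalid_df_raises(self):
        with pytest.raises(ConfigurationError):
            pvalue(1.0, 0, 20)


class TestStandardContrasts:
    def test_study_library_has_22_named_tests(self):
        lib = standard_contrasts(2, 3)
        assert len(lib) == 22

    @pytest.mark.parametrize(
        "name, B, C",
        [
            ("omnibus", np.eye(2), np.eye(3)),
            ("interaction", [[1, -1]], [[1, -1, 0], [0, 1, -1]]),
            ("state-effect", [[1, 1]], [[1, -1, 0], [0, 1, -1]]),
            ("stimulus-effect", [[1, -1]], [[1, 1, 1]]),
            ("state-effect-cog-vs-pas", [[1, 1]], [[1, 0, -1]]),
            ("stimulus-effect-emo", [[1, -1]], [[0, 1, 0]]),
            ("neg-emo", [[0, 1]], [[0, 1, 0]]),
            ("pos-emo", [[1, 0]], [[0, 1, 0]]),
        ],
    )
    def test_printed_matrices(self, name, B, C):
        ct = standard_contrasts(2, 3)[name]
        assert np.array_equal(ct.B, np.atleast_2d(B))
        assert np.array_equal(ct.C, np.atleast_2d(C))

    def test_generic_builders_for_other_designs(self):
        lib = standard_contrasts(3, 2)
        omni = lib["omnibus"]
        assert omni.B.shape == (3, 3) and omni.C.shape == (2, 2)
        assert "simple-s2-r1" in lib and "runs-0-vs-1" in lib

    def test_dimension_mismatch_is_configuration_error(self, rng):
        bundle, _, _ = random_bundle(rng)  # R=2, S=3
        est = estimate_htf(bundle)
        bad = standard_contrasts(3, 2)["omnibus"]
        with pytest.raises(ConfigurationError):
            hypothesis_matrices(est, bundle, bad)

    def test_rank_deficient_contrast_rejected(self):
        with pytest.raises(ConfigurationError):
            Contrast([[1, -1], [2, -2]], [[1, 0, 0]], "bad")


def _series(vals, TR=2.0):
    grid = (vals.shape[0], 1, 1)
    labels = tuple(f"r{s}" for s in range(vals.shape[1]))
    return MultiRunSeries(vals, labels, grid, np.ones(grid, bool), TR)


class TestInvariances:
    def test_univariate_reduction_to_variance_ratio(self, rng):
        """For R = S = 1 the machinery collapses to explained/unexplained."""
        from spectralglm import StimulusSet, generate_stimulus_train

        ind = generate_stimulus_train(120, 2.0, 2.0, (0.0, 6.0), seed=3)
        stimuli = StimulusSet(ind, ("stim",), 2.0)
        series = _series(100 + rng.standard_normal((3, 1, 120))
                         + 2.0 * ind.T[None].repeat(3, axis=0)[:, :1])
        res = run_voxelwise_tests(series, stimuli, [Contrast([[1]], [[1]], "uni")], m=4)
        bundle = cross_spectra_from_data(stimuli, series, m=4)
        _, _, _, _, h = rao_f(0.5, 1, 1, 4, 1)
        for j in range(bundle.partition.n_bands):
            for v in range(series.n_voxels):
                frr = bundle.f_rr[j, 0, 0].real
                frs = bundle.f_rs[j, v, 0, 0]
                fss = bundle.f_ss[j, v, 0, 0].real
                direct = h * np.abs(frs) ** 2 / (frr * fss - np.abs(frs) ** 2)
                assert res["uni"].F[j, v] == pytest.approx(direct, rel=1e-10)

    def test_global_rescaling_and_offsets_leave_statistics_unchanged(
        self, rng, study_stimuli
    ):
        vals = 100 + rng.standard_normal((5, 3, 156))
        contrasts = [standard_contrasts(2, 3)["omnibus"],
                     standard_contrasts(2, 3)["state-effect"]]
        base = run_voxelwise_tests(_series(vals), study_stimuli, contrasts, m=6)
        tweaked = 7.3 * vals + np.array([4.0, -1.0, 9.0])[None, :, None]
        alt = run_voxelwise_tests(_series(tweaked), study_stimuli, contrasts, m=6)
        for name in ("omnibus", "state-effect"):
            assert np.allclose(base[name].U, alt[name].U, atol=1e-10)
            assert np.allclose(base[name].F, alt[name].F, rtol=1e-10)
            assert np.allclose(base[name].p, alt[name].p, atol=1e-10)

    def test_contrast_row_mixing_invariance(self, rng, study_stimuli):
        vals = 100 + rng.standard_normal((5, 3, 156))
        B = np.array([[1.0, -1.0]])
        C = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        M = np.array([[2.5]])
        N = np.array([[1.0, 0.5], [-0.3, 2.0]])
        res = run_voxelwise_tests(
            _series(vals), study_stimuli,
            [Contrast(B, C, "orig"), Contrast(M @ B, N @ C, "mixed")], m=6,
        )
        assert np.allclose(res["orig"].U, res["mixed"].U, atol=1e-9)
        assert np.allclose(res["orig"].F, res["mixed"].F, rtol=1e-9)
        assert np.allclose(res["orig"].p, res["mixed"].p, atol=1e-9)

    def test_all_zero_data_is_flagged_never_a_silent_pvalue(self, study_stimuli):
        series = _series(np.zeros((3, 3, 156)))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = run_voxelwise_tests(
                series, study_stimuli, [standard_contrasts(2, 3)["omnibus"]], m=6
            )
        omni = res["omnibus"]
        assert omni.degenerate.all()
        assert np.isnan(omni.p).all()
        assert np.isnan(omni.F).all()

    def test_estimability_guard_rejects_narrow_bands(self, rng, study_stimuli):
        vals = 100 + rng.standard_normal((2, 3, 156))
        with pytest.raises(ConfigurationError, match="band width"):
            run_voxelwise_tests(
                _series(vals), study_stimuli,
                [standard_contrasts(2, 3)["omnibus"]], m=2,
            )

    def test_result_accessor_returns_consistent_record(self, rng, study_stimuli):
        vals = 100 + rng.standard_normal((2, 3, 156))
        res = run_voxelwise_tests(
            _series(vals), study_stimuli, [standard_contrasts(2, 3)["omnibus"]], m=6
        )["omnibus"]
        rec = res.at(band=2, voxel=1)
        assert rec.df == (12, 36.0)
        assert rec.F == pytest.approx(
            (rec.h / 6) * (rec.U ** (-1 / rec.d) - 1), rel=1e-12
        )
        assert 0 < rec.U <= 1 and rec.F >= 0 and 0 <= rec.p <= 1
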