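import dataclasses

import numpy as np
import pytest

from plscorr import (
    AnalysisConfig,
    SyntheticSpec,
    bootstrap_analysis,
    cross_correlation,
    cross_validate,
    decompose,
    fit_preprocess,
    generate_dataset,
    generate_null_dataset,
    permutation_test,
    procrustes_align,
    run_inference,
)
from plscorr.inference import (
    _resample_indices,
    aligned_singular_values,
    signed_permutation,
)


def _random_orthonormal(rng, n, k):
    Q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return Q


def _decomposed(ds):
    Zx, Zy, _ = fit_preprocess(ds)
    return decompose(cross_correlation(Zx, Zy), Zx, Zy)


class TestProcrustes:
    def test_sign_flips_recovered(self, rng):
        ref = _random_orthonormal(rng, 8, 3)
        new = ref * np.array([1.0, -1.0, -1.0])
        np.testing.assert_allclose(procrustes_align(ref, new), ref, atol=1e-10)

    def test_column_swap_recovered(self, rng):
        ref = _random_orthonormal(rng, 8, 3)
        new = ref[:, [1, 0, 2]]
        np.testing.assert_allclose(procrustes_align(ref, new), ref, atol=1e-10)

    def test_never_increases_distance(self, rng):
        for _ in range(20):
            ref = _random_orthonormal(rng, 6, 3)
            new = _random_orthonormal(rng, 6, 3)
            before = np.linalg.norm(new - ref)
            after = np.linalg.norm(procrustes_align(ref, new) - ref)
            assert after <= before + 1e-12

    def test_shape_mismatch_error(self, rng):
        with pytest.raises(ValueError):
            procrustes_align(_random_orthonormal(rng, 6, 3), _random_orthonormal(rng, 6, 2))

    def test_signed_permutation_exact(self, rng):
        ref = _random_orthonormal(rng, 9, 4)
        new = ref[:, [2, 0, 3, 1]] * np.array([-1.0, 1.0, -1.0, 1.0])
        Q = signed_permutation(ref, new)
        np.testing.assert_allclose(new @ Q, ref, atol=1e-10)
        # Q is orthogonal
        np.testing.assert_allclose(Q.T @ Q, np.eye(4), atol=1e-12)

    def test_aligned_singular_values_identity_case(self, rng):
        # aligning a decomposition to itself returns its own singular values
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 5))
        R = cross_correlation(X, Y).R
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        np.testing.assert_allclose(aligned_singular_values(Vt.T, U, S, Vt.T), S, atol=1e-10)


class TestPermutationTest:
    def test_strong_signal_minimal_p(self):
        spec = SyntheticSpec(
            n_edr=30, n_edbp=15, n_hc=4, p=6, q=5, n_latent=1,
            effect_brain=(4.0,), effect_behavior=(4.0,), noise_sd=0.3,
            brain_support=6, behavior_support=5, subtype_shift=0.0, seed=1,
        )
        ds, _ = generate_dataset(spec)
        cfg = AnalysisConfig(n_permutations=99, seed=4)
        res = permutation_test(ds.ed_subset(), cfg)
        assert res.pvalues[0] == pytest.approx(1 / 100)

    def test_pvalues_never_zero(self, small_dataset, fast_config):
        ds, _ = small_dataset
        res = permutation_test(ds.ed_subset(), fast_config)
        assert np.all(res.pvalues > 0)
        assert np.all(res.pvalues <= 1)

    def test_too_few_subjects_error(self, small_dataset, fast_config):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            permutation_test(ds.subset(np.arange(2)), fast_config)

    def test_determinism(self, small_dataset, fast_config):
        ds, _ = small_dataset
        a = permutation_test(ds.ed_subset(), fast_config)
        b = permutation_test(ds.ed_subset(), fast_config)
        np.testing.assert_array_equal(a.null_S, b.null_S)

    def test_rotated_variant_runs(self, small_dataset, fast_config):
        ds, _ = small_dataset
        cfg = dataclasses.replace(fast_config, rotate_permutation=True)
        res = permutation_test(ds.ed_subset(), cfg)
        assert res.pvalues.shape == (5,)


class TestBootstrap:
    def test_degenerate_noise_limit(self):
        spec = SyntheticSpec(
            n_edr=30, n_edbp=15, n_hc=4, p=6, q=5, n_latent=1,
            effect_brain=(2.0,), effect_behavior=(2.0,), noise_sd=1e-3,
            brain_support=6, behavior_support=5, subtype_shift=0.0, seed=9,
        )
        ds, gt = generate_dataset(spec)
        ed = ds.ed_subset()
        dec = _decomposed(ed)
        cfg = AnalysisConfig(n_bootstraps=60, seed=2)
        boot = bootstrap_analysis(ed, dec, cfg)
        assert np.all(boot.se_brain_weights[:, 0] < 0.01)
        assert np.all(np.abs(boot.bootstrap_ratios_brain[:, 0]) > 1.96)

    def test_bsr_matches_two_pass_oracle(self, small_dataset):
        ds, _ = small_dataset
        ed = ds.ed_subset()
        dec = _decomposed(ed)
        cfg = AnalysisConfig(n_bootstraps=50, seed=3)
        boot = bootstrap_analysis(ed, dec, cfg, store_draws=True)
        draws = boot.brain_weight_draws
        # independent two-pass variance over the stored draws
        mean = draws.sum(axis=0) / draws.shape[0]
        ss = ((draws - mean) ** 2).sum(axis=0)
        se = np.sqrt(ss / (draws.shape[0] - 1))
        np.testing.assert_allclose(boot.se_brain_weights, se, atol=1e-12)
        np.testing.assert_allclose(boot.bootstrap_ratios_brain, dec.U / se, atol=1e-10)

    def test_null_feature_ci_crosses_zero(self):
        crossings = 0
        n_rep = 25
        for seed in range(n_rep):
            spec = SyntheticSpec(
                n_edr=40, n_edbp=20, n_hc=4, p=10, q=8, n_latent=1,
                effect_brain=(2.0,), effect_behavior=(2.0,),
                brain_support=5, behavior_support=4, subtype_shift=0.0, seed=seed,
            )
            ds, gt = generate_dataset(spec)
            ed = ds.ed_subset()
            dec = _decomposed(ed)
            cfg = AnalysisConfig(n_bootstraps=120, seed=seed)
            boot = bootstrap_analysis(ed, dec, cfg)
            null_col = np.setdiff1d(np.arange(8), gt.behavior_support[0])[0]
            lv = int(np.argmax(np.abs(gt.v[:, 0] @ dec.V)))
            if boot.behavior_loading_lower[null_col, lv] < 0 < boot.behavior_loading_upper[null_col, lv]:
                crossings += 1
        assert crossings >= 0.8 * n_rep

    def test_zero_variance_resample_exhaustion(self, small_dataset):
        ds, _ = small_dataset
        ds.brain[:, 0] = 1.0  # constant -> every resample invalid
        with pytest.raises(RuntimeError, match="no valid bootstrap resample"):
            _resample_indices(np.random.default_rng(0), ds)

    def test_determinism(self, small_dataset, fast_config):
        ds, _ = small_dataset
        ed = ds.ed_subset()
        dec = _decomposed(ed)
        a = bootstrap_analysis(ed, dec, fast_config)
        b = bootstrap_analysis(ed, dec, fast_config)
        np.testing.assert_array_equal(a.bootstrap_ratios_brain, b.bootstrap_ratios_brain)


class TestCrossValidate:
    def test_noiseless_rank_one_all_splits_perfect(self):
        spec = SyntheticSpec(
            n_edr=30, n_edbp=15, n_hc=4, p=6, q=5, n_latent=1,
            effect_brain=(1.0,), effect_behavior=(1.0,), noise_sd=0.0,
            brain_support=6, behavior_support=5, subtype_shift=0.0, age_slope_scale=0.0, seed=6,
        )
        ds, _ = generate_dataset(spec)
        cfg = AnalysisConfig(n_cv_splits=20, n_cv_null=0, seed=1, age_correct=False)
        cv = cross_validate(ds.ed_subset(), cfg, lv=0)
        np.testing.assert_allclose(cv.split_rs, 1.0, atol=1e-8)
        assert cv.mean_r == pytest.approx(1.0, abs=1e-8)

    def test_too_small_split_error(self, small_dataset):
        ds, _ = small_dataset
        cfg = AnalysisConfig(n_cv_splits=2, train_fraction=0.9, n_cv_null=0, seed=0)
        with pytest.raises(ValueError, match="need >= 3"):
            cross_validate(ds.subset(np.arange(8)), cfg, lv=0)

    def test_stratification_balances_subtypes(self):
        spec = SyntheticSpec(seed=0)
        ds, _ = generate_dataset(spec)
        ed = ds.ed_subset()
        from plscorr.inference import _split_indices

        rng = np.random.default_rng(0)
        for _ in range(5):
            train, test = _split_indices(rng, ed, 0.75, stratify=True)
            frac_train = np.mean(ed.subtype[train] == "EDbp")
            frac_all = np.mean(ed.subtype == "EDbp")
            assert abs(frac_train - frac_all) < 0.05

    def test_shrinkage_vs_in_sample(self):
        """Out-of-sample mean r <= in-sample r on noisy planted data."""
        worse = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n_edr=40, n_edbp=20, n_hc=4, p=8, q=6, n_latent=1,
                effect_brain=(1.5,), effect_behavior=(1.5,),
                brain_support=4, behavior_support=3, subtype_shift=0.0, seed=seed,
            )
            ds, _ = generate_dataset(spec)
            ed = ds.ed_subset()
            dec = _decomposed(ed)
            in_r = np.corrcoef(dec.brain_scores[:, 0], dec.behavior_scores[:, 0])[0, 1]
            cfg = AnalysisConfig(n_cv_splits=10, n_cv_null=0, seed=seed)
            cv = cross_validate(ed, cfg, lv=0)
            worse += cv.mean_r <= in_r
        assert worse == 20

    def test_cv_pvalue_small_for_strong_signal(self):
        spec = SyntheticSpec(
            n_edr=30, n_edbp=15, n_hc=4, p=6, q=5, n_latent=1,
            effect_brain=(3.0,), effect_behavior=(3.0,), noise_sd=0.3,
            brain_support=6, behavior_support=5, subtype_shift=0.0, seed=3,
        )
        ds, _ = generate_dataset(spec)
        cfg = AnalysisConfig(n_cv_splits=8, n_cv_null=19, seed=2)
        cv = cross_validate(ds.ed_subset(), cfg, lv=0)
        assert cv.pvalue == pytest.approx(1 / 20)


class TestRunInference:
    def test_determinism_and_fields(self, small_dataset, fast_config):
        ds, _ = small_dataset
        ed = ds.ed_subset()
        dec = _decomposed(ed)
        a = run_inference(ed, dec, fast_config)
        b = run_inference(ed, dec, fast_config)
        np.testing.assert_array_equal(a.perm_pvalues, b.perm_pvalues)
        np.testing.assert_array_equal(a.bootstrap_ratios_brain, b.bootstrap_ratios_brain)
        np.testing.assert_array_equal(a.cv_split_rs, b.cv_split_rs)
        assert a.cv_split_rs.shape[0] == fast_config.n_cv_splits
        assert np.all(a.perm_pvalues > 0) and np.all(a.perm_pvalues <= 1)
        finite = a.bootstrap_se_brain > 0
        assert np.all(np.isfinite(a.bootstrap_ratios_brain[finite]))
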