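import numpy as np
import pytest
from scipy import stats

from plscorr import (
    AnalysisConfig,
    SyntheticSpec,
    chi_square_independence,
    compare_subtypes,
    cross_correlation,
    decompose,
    fit_preprocess,
    generate_dataset,
    group_descriptives,
    prospective_association,
    welch_t,
    welch_t_from_samples,
)
from plscorr.clinical import partial_correlation


def _decomposed(ds):
    Zx, Zy, _ = fit_preprocess(ds)
    return decompose(cross_correlation(Zx, Zy), Zx, Zy)


class TestWelchT:
    # printed cohort summaries (ED n=91 vs HC n=48) and their printed t values
    @pytest.mark.parametrize(
        "ed,hc,expected",
        [
            ((25.04, 6.29), (14.04, 7.55), 8.64),  # harm avoidance
            ((22.13, 8.00), (33.19, 7.65), -7.98),  # self directedness
            ((114.65, 24.97), (63.17, 14.05), 15.55),  # emotion dysregulation total
            ((25.12, 2.87), (19.98, 3.16), 9.41),  # behavioral inhibition
            ((57.70, 11.66), (44.17, 10.14), 7.10),  # alexithymia total
            ((11.18, 6.13), (2.56, 2.77), 11.39),  # restricting
        ],
    )
    def test_cohort_table_values(self, ed, hc, expected):
        res = welch_t(ed[0], ed[1], 91, hc[0], hc[1], 48)
        assert round(res.t, 2) == pytest.approx(expected, abs=0.02)
        assert res.df > 0

    def test_identical_groups_zero(self):
        assert welch_t(5.0, 2.0, 10, 5.0, 2.0, 10).t == 0.0

    def test_matches_scipy_on_vectors(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(loc=0.5, size=8)
        res = welch_t_from_samples(x, y)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert abs(res.t - t_ref) < 1e-12
        assert abs(res.p - p_ref) < 1e-12

    def test_formula_oracle(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = welch_t_from_samples(x, y)
        v1, v2 = x.var(ddof=1) / 8, y.var(ddof=1) / 8
        t_hand = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
        df_hand = (v1 + v2) ** 2 / (v1**2 / 7 + v2**2 / 7)
        assert abs(res.t - t_hand) < 1e-12
        assert abs(res.df - df_hand) < 1e-12

    def test_antisymmetric(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=12)
        assert welch_t_from_samples(x, y).t == pytest.approx(-welch_t_from_samples(y, x).t)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            welch_t(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestChiSquare:
    def test_uniform_table_zero(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.df == 1

    def test_cohort_ethnicity_counts(self):
        # Hispanic / non-Hispanic by group: ED 9/82, HC 7/41
        res = chi_square_independence([[9, 82], [7, 41]])
        assert res.chi2 == pytest.approx(0.68, abs=0.02)

    def test_brute_force_oracle(self, rng):
        table = rng.integers(1, 30, size=(3, 3))
        res = chi_square_independence(table)
        total = table.sum()
        chi2 = 0.0
        for i in range(3):
            for j in range(3):
                e = table[i].sum() * table[:, j].sum() / total
                chi2 += (table[i, j] - e) ** 2 / e
        assert abs(res.chi2 - chi2) < 1e-12
        assert res.df == 4

    def test_zero_margin_error(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 20, size=(3, 4))
        base = chi_square_independence(table).chi2
        assert chi_square_independence(table[::-1]).chi2 == pytest.approx(base)
        assert chi_square_independence(table[:, ::-1]).chi2 == pytest.approx(base)


class TestCompareSubtypes:
    def test_output_shape_two_lvs(self, small_dataset):
        ds, _ = small_dataset
        ed = ds.ed_subset()
        comp = compare_subtypes(ed, _decomposed(ed), lvs=(0, 1))
        assert len(comp.table) == 4  # 2 score types x 2 LVs
        assert comp.n_edr + comp.n_edbp == ed.n

    def test_missing_subtype_error(self, small_dataset):
        ds, _ = small_dataset
        edr_only = ds.subset(ds.subtype == "EDr")
        with pytest.raises(ValueError, match="EDbp"):
            compare_subtypes(edr_only, _decomposed(edr_only))

    def test_null_shift_calibrated(self):
        quiet = 0
        n_rep = 50
        for seed in range(n_rep):
            spec = SyntheticSpec(
                n_edr=40, n_edbp=20, n_hc=4, p=8, q=6, n_latent=1,
                effect_brain=(2.0,), effect_behavior=(2.0,),
                brain_support=4, behavior_support=3, subtype_shift=0.0, seed=seed,
            )
            ds, _ = generate_dataset(spec)
            ed = ds.ed_subset()
            comp = compare_subtypes(ed, _decomposed(ed), lvs=(0,))
            if (comp.table["p"] > 0.05).all():
                quiet += 1
        assert quiet >= 0.9 * n_rep

    def test_planted_shift_detected(self):
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            spec = SyntheticSpec(
                n_latent=1, effect_brain=(2.0,), effect_behavior=(2.0,),
                brain_support=10, behavior_support=8, subtype_shift=1.0, seed=seed,
            )
            ds, _ = generate_dataset(spec)
            ed = ds.ed_subset()  # 61 EDr / 30 EDbp
            comp = compare_subtypes(ed, _decomposed(ed), lvs=(0,))
            if (comp.table["p"] < 0.05).any():
                hits += 1
        assert hits >= 0.8 * n_rep


class TestProspective:
    def test_orthogonal_covariate_equals_simple_r(self):
        # covariate exactly orthogonal (after centering) to both variables
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([1.0, -1.0, 0.0, 0.0, -1.0, 1.0])
        assert abs((x - x.mean()) @ z) < 1e-12 and abs((y - y.mean()) @ z) < 1e-12
        simple = np.corrcoef(x, y)[0, 1]
        res = partial_correlation(x, y, z)
        assert abs(res.r - simple) < 1e-10

    def test_constant_covariate_equals_simple_r(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = partial_correlation(x, y, np.full(12, 3.0))
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_residual_oracle_small_example(self):
        x = np.array([0.2, 1.1, -0.4, 2.2, 0.9, -1.3])
        y = np.array([1.0, 0.3, -0.2, 1.8, 0.4, -0.9])
        z = np.array([0.5, 0.1, -0.3, 1.2, 0.7, -0.8])
        res = partial_correlation(x, y, z)
        # two-regression residual oracle via lstsq
        A = np.column_stack([np.ones(6), z])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert abs(res.r - np.corrcoef(rx, ry)[0, 1]) < 1e-12

    def test_bounds(self, rng):
        for _ in range(10):
            res = partial_correlation(rng.normal(size=15), rng.normal(size=15), rng.normal(size=15))
            assert -1.0 <= res.r <= 1.0

    def test_null_coupling_centered_at_zero(self):
        rs = []
        for seed in range(50):
            spec = SyntheticSpec(
                n_edr=40, n_edbp=20, n_hc=4, p=8, q=6, n_latent=1,
                effect_brain=(2.0,), effect_behavior=(2.0,),
                brain_support=4, behavior_support=3, subtype_shift=0.0,
                followup_coupling=0.0, seed=seed,
            )
            ds, _ = generate_dataset(spec)
            ed = ds.ed_subset()
            rs.append(prospective_association(ed, _decomposed(ed), lv=0).r)
        assert abs(np.mean(rs)) < 0.05

    def test_insufficient_followup_error(self, small_dataset):
        ds, _ = small_dataset
        ds.followup_severity[:] = np.nan
        ds.followup_severity[0] = 1.0
        with pytest.raises(ValueError, match="insufficient follow-up"):
            prospective_association(ds.ed_subset(), _decomposed(ds.ed_subset()), lv=0)


class TestGroupDescriptives:
    def test_row_count_and_welch(self, small_dataset):
        ds, _ = small_dataset
        table = group_descriptives(ds, ds.behavior_names + ["age"]).table
        assert len(table) == ds.q + 1
        # cross-check one row against the direct test
        var = ds.behavior_names[0]
        j = ds.behavior_names.index(var)
        expected = welch_t_from_samples(
            ds.behavior[ds.group == "ED", j], ds.behavior[ds.group == "HC", j]
        )
        assert table.loc[var, "statistic"] == pytest.approx(expected.t, abs=1e-12)

    def test_all_missing_group_flagged(self, small_dataset):
        ds, _ = small_dataset
        ds.behavior[ds.group == "HC", 0] = np.nan
        table = group_descriptives(ds, [ds.behavior_names[0]]).table
        row = table.iloc[0]
        assert "no test" in row["note"]
        assert np.isnan(row["p"])

    def test_unknown_variable_error(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(KeyError, match="bogus"):
            group_descriptives(ds, ["bogus"])

    def test_bh_column_monotone(self, small_dataset):
        ds, _ = small_dataset
        table = group_descriptives(ds, ds.behavior_names).table
        ok = table["p"].notna()
        assert np.all(table.loc[ok, "p_bh"] >= table.loc[ok, "p"] - 1e-12)
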