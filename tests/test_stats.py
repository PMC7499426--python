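"""Mixed-model genotype tests, Meff correction and transforms."""

import numpy as np
import pandas as pd
import pytest

from larvaswim import (CohortConfig, ComparisonError, adjust_pvalues,
                       choose_transform, compare_groups, compute_meff,
                       fit_genotype_model, generate_cohort,
                       latents_to_summaries)

# permutations of 0..7 with exact Spearman rank correlations vs identity
# (frozen from an exhaustive search over sum of squared rank differences:
# rho = 1 - 6*sum(d^2)/(n(n^2-1)), n=8)
PERM_RHO_HALF = [0, 1, 3, 5, 6, 7, 4, 2]   # sum(d^2) = 42 -> rho = 0.5
PERM_RHO_ZERO = [0, 3, 5, 6, 7, 4, 2, 1]   # sum(d^2) = 84 -> rho = 0.0


def null_cohort(seed, n_per_clutch=5):
    """Cohort with zero injected genotype effect and honest sampling."""
    from larvaswim import SLOW_DEFAULTS, ESCAPE_DEFAULTS
    cfg = CohortConfig(
        seed=seed, fish_per_clutch_per_genotype=n_per_clutch,
        centering="none",
        slow={"wt": SLOW_DEFAULTS["wt"], "mut": SLOW_DEFAULTS["wt"]},
        escape={"wt": ESCAPE_DEFAULTS["wt"], "mut": ESCAPE_DEFAULTS["wt"]},
    )
    return latents_to_summaries(generate_cohort(cfg))


class TestMeff:
    def test_perfect_correlation_limit_is_one(self):
        base = np.arange(40, dtype=float)
        df = pd.DataFrame({f"p{i}": base * (i + 1) + i for i in range(8)})
        res = compute_meff(df)
        assert res.k == 8
        assert res.vcorr == pytest.approx(8.0)
        assert res.meff == pytest.approx(1.0)
        assert res.eigenvalues.sum() == pytest.approx(8.0)

    def test_independent_pair_is_two(self):
        df = pd.DataFrame({"a": range(8), "b": PERM_RHO_ZERO})
        res = compute_meff(df)
        assert res.vcorr == pytest.approx(0.0, abs=1e-12)
        assert res.meff == pytest.approx(2.0)

    def test_two_by_two_analytic_case(self):
        # Spearman rho = 0.5 -> eigenvalues {1.5, 0.5} -> vcorr = 0.5
        # -> Meff = 1 + (2-1)(1 - 0.5/2) = 1.75
        df = pd.DataFrame({"a": range(8), "b": PERM_RHO_HALF})
        res = compute_meff(df)
        assert sorted(res.eigenvalues) == pytest.approx([0.5, 1.5])
        assert res.vcorr == pytest.approx(0.5)
        assert res.meff == pytest.approx(1.75)

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for k in (2, 4, 6, 8):
            for _ in range(5):
                base = rng.normal(size=(30, k))
                mix = base @ rng.normal(size=(k, k))
                res = compute_meff(pd.DataFrame(mix))
                assert 1.0 <= res.meff <= k
                assert res.eigenvalues.sum() == pytest.approx(k)
                assert res.vcorr >= 0.0

    def test_monotone_decrease_in_exchangeable_family(self):
        rng = np.random.default_rng(1)
        meffs = []
        for rho in (0.0, 0.25, 0.5, 0.75, 0.99):
            cov = np.full((6, 6), rho) + np.eye(6) * (1 - rho)
            x = rng.multivariate_normal(np.zeros(6), cov, size=3000)
            meffs.append(compute_meff(pd.DataFrame(x)).meff)
        assert all(a > b for a, b in zip(meffs, meffs[1:]))

    def test_constant_column_raises_naming_it(self):
        df = pd.DataFrame({"good": range(10), "flat": [1.0] * 10})
        with pytest.raises(ComparisonError, match="flat"):
            compute_meff(df)

    def test_too_few_rows_raises(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(4, 6)))
        with pytest.raises(ComparisonError):
            compute_meff(df)


class TestAdjustPvalues:
    def test_printed_scale_arithmetic(self):
        assert adjust_pvalues(0.007, 4.003) == pytest.approx(0.028, abs=5e-4)

    def test_cap_at_one(self):
        assert adjust_pvalues(0.5, 7.230) == 1.0

    def test_meff_one_is_identity(self):
        p = np.array([0.01, 0.5, 0.999])
        assert np.allclose(adjust_pvalues(p, 1.0), p)

    def test_never_decreases_and_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        for meff in (1.0, 2.5, 7.23):
            adj = adjust_pvalues(p, meff)
            assert (adj >= p - 1e-15).all()
            assert (adj <= 1.0).all()

    def test_invalid_meff_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(0.5, 0.5)


class TestChooseTransform:
    def test_gaussian_needs_no_transform(self):
        rng = np.random.default_rng(4)
        g = np.repeat(["a", "b"], 150)
        assert choose_transform(rng.normal(10, 1, 300), g) == "none"

    def test_lognormal_prefers_log(self):
        rng = np.random.default_rng(5)
        g = np.repeat(["a", "b"], 150)
        assert choose_transform(np.exp(rng.normal(0, 1, 300)), g) == "log"

    def test_zero_values_exclude_log(self):
        rng = np.random.default_rng(6)
        g = np.repeat(["a", "b"], 150)
        v = np.exp(rng.normal(0, 1, 300))
        v[0] = 0.0
        assert choose_transform(v, g) != "log"


class TestGenotypeModel:
    def test_label_symmetry(self):
        summ = null_cohort(seed=10)
        chi1, p1 = fit_genotype_model(summ, "fwd_speed_mm_s")
        swapped = summ.copy()
        swapped["genotype"] = swapped["genotype"].map(
            {"wt": "mut", "mut": "wt"})
        chi2, p2 = fit_genotype_model(swapped, "fwd_speed_mm_s")
        assert chi1 == pytest.approx(chi2, rel=1e-6)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_zero_clutch_variance_matches_marginal_model(self):
        import statsmodels.api as sm
        cfg = CohortConfig(seed=12, clutch_sd_scale=0.0, centering="none",
                           fish_per_clutch_per_genotype=10)
        summ = latents_to_summaries(generate_cohort(cfg))
        chi_mixed, _ = fit_genotype_model(summ, "fwd_distance_mm")
        y = summ["fwd_distance_mm"].to_numpy()
        x = (summ["genotype"] == summ["genotype"].unique()[1]).astype(float)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        chi_ols = float((ols.params.iloc[1] / ols.bse.iloc[1]) ** 2)
        assert chi_mixed == pytest.approx(chi_ols, rel=0.05)

    def test_single_genotype_rejected(self):
        summ = null_cohort(seed=13)
        with pytest.raises(ComparisonError):
            fit_genotype_model(summ[summ.genotype == "wt"], "fwd_speed_mm_s")

    def test_null_pvalues_uniform(self):
        """Raw Wald p-values are uniform under the null generator
        (Kolmogorov-Smirnov at alpha = 0.01 over 1,000 replicates)."""
        from scipy.stats import kstest
        ps = np.array([
            fit_genotype_model(null_cohort(seed=2000 + s),
                               "fwd_speed_mm_s")[1]
            for s in range(1000)
        ])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestCompareGroups:
    def test_single_parameter_family_uses_meff_one(self):
        summ = null_cohort(seed=20)
        [res] = compare_groups(summ, "boutrate")
        assert res.meff == 1.0
        assert res.p_adj == res.p_raw

    def test_results_carry_group_means_on_original_scale(self):
        summ = null_cohort(seed=21)
        results = compare_groups(summ, "forward")
        assert len(results) == 6
        meffs = {r.meff for r in results}
        assert len(meffs) == 1  # shared within the family
        for r in results:
            assert set(r.group_means) == {"wt", "mut"}
            assert r.p_adj >= r.p_raw
            mean_wt = r.group_means["wt"][0]
            col = summ[summ.genotype == "wt"][r.parameter]
            assert mean_wt == pytest.approx(col.mean())

    def test_unknown_analysis_rejected(self):
        with pytest.raises(ComparisonError):
            compare_groups(null_cohort(seed=22), "nonsense")
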