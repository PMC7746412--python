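import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrsoc import (
    SimConfig, simulate_cohort, compute_prs, fit_tsls,
    per_snp_assoc, select_gws, wald_ratios, ivw, egger, weighted_median,
    mode_estimators,
)
from mrsoc.summarymr import read_summary_stats, write_summary_stats
from conftest import oracle_weights


def stats_frame(bx, by, se_out, se_exp=0.0, n=10_000):
    k = len(bx)
    return pd.DataFrame({
        "snp": [f"snp{j}" for j in range(k)],
        "beta_exp": np.asarray(bx, float),
        "se_exp": se_exp if np.ndim(se_exp) else np.full(k, se_exp),
        "pval_exp": np.full(k, 1e-9),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(se_out, float) if np.ndim(se_out)
        else np.full(k, float(se_out)),
        "n": n,
    })


class TestPerSnpAssoc:
    def test_exact_linear_relation_recovered(self, small_cohort):
        _, genotypes, _, _, _ = small_cohort
        trait = 2.0 * genotypes.dosages[:, 0]
        res = per_snp_assoc(genotypes, trait)
        assert res.loc[0, "beta"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc[0, "pval"] < 1e-100

    def test_single_snp_equals_covariance_slope(self, small_cohort):
        _, genotypes, cohort, _, _ = small_cohort
        t = cohort["exposure"].to_numpy()
        res = per_snp_assoc(genotypes, t)
        g = genotypes.dosages[:, 3]
        slope = np.cov(g, t)[0, 1] / np.var(g, ddof=1)
        assert res.loc[3, "beta"] == pytest.approx(slope, abs=1e-10)

    def test_adjusted_betas_match_per_snp_ols(self, small_cohort):
        import statsmodels.api as sm

        _, genotypes, cohort, _, cov = small_cohort
        t = cohort["outcome"].to_numpy()
        res = per_snp_assoc(genotypes, t, covariates=cov)
        for j in (0, 5, 11):
            X = sm.add_constant(
                np.column_stack([cov.to_numpy(float), genotypes.dosages[:, j]])
            )
            ref = sm.OLS(t, X).fit()
            assert res.loc[j, "beta"] == pytest.approx(ref.params[-1], abs=1e-8)
            assert res.loc[j, "se"] == pytest.approx(ref.bse[-1], rel=1e-6)

    def test_null_trait_pvalues_uniform(self):
        cfg = SimConfig(seed=99, n_individuals=2000, n_snps=1000,
                        snp_effect_scale=0.0, causal_effect=0.0)
        genotypes, _, _ = simulate_cohort(cfg)
        trait = np.random.default_rng(1).standard_normal(2000)
        res = per_snp_assoc(genotypes, trait)
        ks = stats.kstest(res["pval"].dropna(), "uniform")
        assert ks.pvalue > 0.001

    def test_monomorphic_variant_flagged(self):
        from test_prs import make_panel

        dos = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        panel = make_panel(dos, snps=["rs1", "rs2"], counted=["A", "C"],
                           other=["G", "T"])
        res = per_snp_assoc(panel, [0.1, 0.5, -0.2, 0.4])
        assert not res.loc[0, "monomorphic"]
        assert res.loc[1, "monomorphic"] and np.isnan(res.loc[1, "beta"])

    def test_constant_trait_rejected(self, small_cohort):
        _, genotypes, _, _, _ = small_cohort
        with pytest.raises(ValueError, match="constant"):
            per_snp_assoc(genotypes, np.ones(genotypes.n_individuals))


class TestSelectGws:
    def test_threshold_filters(self):
        df = stats_frame([0.1, 0.2], [0.1, 0.2], 0.05)
        df["pval_exp"] = [1e-9, 1e-7]
        assert len(select_gws(df, 5e-8)) == 1

    def test_threshold_one_is_identity(self):
        df = stats_frame([0.1, 0.2], [0.1, 0.2], 0.05)
        assert len(select_gws(df, 1.0)) == 2

    def test_empty_selection_allowed(self):
        df = stats_frame([0.1], [0.1], 0.05)
        df["pval_exp"] = [0.5]
        out = select_gws(df, 5e-8)
        assert len(out) == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_gws(stats_frame([0.1], [0.1], 0.05), 0.0)


class TestWaldRatios:
    def test_formula(self):
        df = stats_frame([2.0, 2.0], [1.0, 0.0], [0.4, 0.4])
        out = wald_ratios(df)
        assert out["ratio"].tolist() == pytest.approx([0.5, 0.0])
        assert out["se"].tolist() == pytest.approx([0.2, 0.2])

    def test_zero_exposure_beta_excluded_with_warning(self):
        df = stats_frame([1.0, 0.0], [1.0, 1.0], 0.1)
        with pytest.warns(UserWarning, match="zero exposure"):
            out = wald_ratios(df)
        assert len(out) == 1


class TestIvw:
    def test_closed_form_two_variants(self):
        est, q = ivw(stats_frame([1.0, 1.0], [1.0, 3.0], 1.0))
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(2))
        assert q.q == pytest.approx(2.0)
        assert q.df == 1

    def test_identical_ratios_give_zero_q(self):
        est, q = ivw(stats_frame([0.5, 1.0, 2.0], [0.15, 0.3, 0.6], 0.05))
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert q.q == pytest.approx(0.0, abs=1e-12)

    def test_q_invariant_to_outcome_units(self):
        df = stats_frame([0.5, 1.0, 1.5], [0.2, 0.7, 0.4], [0.1, 0.2, 0.15])
        est1, q1 = ivw(df)
        df2 = df.assign(beta_out=df.beta_out * 7.0, se_out=df.se_out * 7.0)
        est2, q2 = ivw(df2)
        assert q2.q == pytest.approx(q1.q, rel=1e-12)
        assert est2.beta == pytest.approx(7.0 * est1.beta, rel=1e-12)

    def test_pleiotropy_inflates_q(self):
        from mrsoc import simulate_summary_stats

        qs_null, qs_pleio = [], []
        for rep in range(30):
            s0 = simulate_summary_stats(seed=500 + rep, causal_effect=0.3)
            s1 = simulate_summary_stats(seed=500 + rep, causal_effect=0.3,
                                        pleiotropy_mode="balanced",
                                        pleiotropy_scale=0.1)
            qs_null.append(ivw(s0)[1].q)
            qs_pleio.append(ivw(s1)[1].q)
        assert np.mean(qs_pleio) > 2.0 * np.mean(qs_null)

    def test_too_few_variants(self):
        with pytest.raises(ValueError, match="2 variants"):
            ivw(stats_frame([1.0], [1.0], 0.1))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.2, 0.5, 0.8, 1.1])
        by = 0.07 + 0.6 * bx
        res = egger(stats_frame(bx, by, [0.1, 0.2, 0.15, 0.12]))
        assert res.slope.beta == pytest.approx(0.6, abs=1e-10)
        assert res.intercept == pytest.approx(0.07, abs=1e-10)

    def test_orientation_flips_negative_exposure_betas(self):
        bx = np.array([0.2, 0.5, 0.8, 1.1])
        by = 0.07 + 0.6 * bx
        df = stats_frame(bx, by, [0.1, 0.2, 0.15, 0.12])
        df.loc[1, ["beta_exp", "beta_out"]] *= -1  # same variant, other allele
        res = egger(df)
        assert res.slope.beta == pytest.approx(0.6, abs=1e-10)
        assert res.intercept == pytest.approx(0.07, abs=1e-10)

    def test_too_few_variants(self):
        with pytest.raises(ValueError, match="3"):
            egger(stats_frame([1.0, 2.0], [1.0, 2.0], 0.1))


class TestMedianAndModes:
    def test_equal_weights_odd_k_is_plain_median(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        est = weighted_median(stats_frame(bx, by, 1.0), n_boot=50, seed=3)
        assert est.beta == pytest.approx(np.median(by))

    def test_identical_ratios_returned_exactly(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        df = stats_frame(bx, 0.3 * bx, 0.05)
        wm = weighted_median(df, n_boot=50, seed=1)
        sm_, wmo = mode_estimators(df, n_boot=50, seed=1)
        assert wm.beta == pytest.approx(0.3, abs=1e-12)
        assert sm_.beta == pytest.approx(0.3, abs=1e-12)
        assert wmo.beta == pytest.approx(0.3, abs=1e-12)

    def test_bootstrap_reproducible_under_seed(self):
        df = stats_frame([0.4, 0.8, 1.2, 1.6], [0.1, 0.5, 0.3, 0.8], 0.1,
                         se_exp=0.02)
        a = weighted_median(df, n_boot=200, seed=11)
        b = weighted_median(df, n_boot=200, seed=11)
        c = weighted_median(df, n_boot=200, seed=12)
        assert a.se == b.se
        assert a.se != c.se

    def test_bandwidth_change_is_continuous(self):
        df = stats_frame([0.4, 0.8, 1.2, 1.6, 2.0],
                         [0.1, 0.5, 0.3, 0.8, 0.9], 0.1)
        s1, w1 = mode_estimators(df, bandwidth_factor=1.0, n_boot=50, seed=2)
        s2, w2 = mode_estimators(df, bandwidth_factor=2.0, n_boot=50, seed=2)
        for est in (s1, s2, w1, w2):
            assert np.isfinite(est.beta) and est.se > 0
        assert abs(s1.beta - s2.beta) < 1.0

    def test_seed_required(self):
        df = stats_frame([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], 0.1)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(df, n_boot=10)
        with pytest.raises(ValueError, match="seed"):
            mode_estimators(df, n_boot=10)


def test_ivw_consistent_with_tsls_on_one_sample_data():
    """On a large simulated cohort with independent SNPs, the IVW slope
    built from in-sample per-SNP associations agrees with the 2SLS fit."""
    cfg = SimConfig(seed=314, n_individuals=50_000, n_snps=30)
    genotypes, cohort, truth = simulate_cohort(cfg)
    gx = per_snp_assoc(genotypes, cohort["exposure"])
    gy = per_snp_assoc(genotypes, cohort["outcome"])
    s = pd.DataFrame({
        "snp": gx["snp"], "beta_exp": gx["beta"], "se_exp": gx["se"],
        "pval_exp": gx["pval"], "beta_out": gy["beta"], "se_out": gy["se"],
        "n": cfg.n_individuals,
    })
    est_ivw, _ = ivw(s)
    prs = compute_prs(genotypes, oracle_weights(genotypes, truth))
    est_tsls = fit_tsls(cohort["exposure"], cohort["outcome"], prs)
    tol = 2.0 * np.sqrt(est_ivw.se ** 2 + est_tsls.se ** 2)
    assert abs(est_ivw.beta - est_tsls.beta) <= tol


def test_summary_stats_roundtrip(tmp_path):
    df = stats_frame([0.1, 0.2], [0.3, 0.4], 0.05, se_exp=0.01)
    path = tmp_path / "stats.tsv"
    write_summary_stats(df, path)
    back = read_summary_stats(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)
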