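"""Stage-1 scan: OLS correctness, skip/degenerate policy, BH screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sseqtl.containers import Cohort
from sseqtl.simulate import SimulationConfig, simulate_cohort
from sseqtl.stage1 import (
    INTERACTION_COL,
    bh_threshold,
    fit_interaction_model,
    run_stage1,
)
from sseqtl.experiments import truth_pairs


def normal_equations_fit(y, snp, sex, pcs):
    """Independent textbook oracle: solve (X'X) b = X'y explicitly."""
    cols = [np.ones_like(snp), snp, sex, sex * snp]
    if pcs is not None and pcs.size:
        cols.extend(np.atleast_2d(pcs.T))
    X = np.column_stack(cols)
    XtX = X.T @ X
    beta = np.linalg.inv(XtX) @ (X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(XtX)))
    t = beta[INTERACTION_COL] / se[INTERACTION_COL]
    return beta, se, 2 * stats.t.sf(abs(t), n - p)


class TestFitInteractionModel:
    def test_exact_fit_recovers_slopes_and_flags_degenerate(self):
        """Noise-free sex-specific slopes 1 (M) and 2 (F): beta = (0,1,0,1)."""
        snp = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        sex = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 1, 1, 0, 0, 2, 2], dtype=float)
        fit = fit_interaction_model(y, snp, sex)
        assert fit["status"] == "degenerate_fit"
        assert np.allclose(fit["beta"], [0, 1, 0, 1], atol=1e-10)
        assert np.isnan(fit["p_interaction"])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(30, 80)
            snp = rng.binomial(2, 0.3, n).astype(float)
            sex = (rng.random(n) < 0.5).astype(float)
            pcs = rng.normal(size=(n, 2))
            y = rng.normal(size=n) + 0.3 * snp * sex
            if np.ptp(snp) == 0 or np.unique(sex).size < 2:
                continue
            fit = fit_interaction_model(y, snp, sex, pcs)
            beta_o, se_o, p_o = normal_equations_fit(y, snp, sex, pcs)
            assert np.allclose(fit["beta"], beta_o, rtol=1e-8)
            assert np.allclose(fit["se"], se_o, rtol=1e-8)
            assert fit["p_interaction"] == pytest.approx(p_o, rel=1e-8)

    @pytest.mark.parametrize(
        "sex,snp,expected",
        [
            (np.zeros(40), None, "single_sex"),
            (None, np.ones(40), "constant_snp"),
        ],
    )
    def test_skip_reason_codes(self, sex, snp, expected):
        rng = np.random.default_rng(1)
        n = 40
        sex = rng.integers(0, 2, n).astype(float) if sex is None else sex
        snp = rng.binomial(2, 0.4, n).astype(float) if snp is None else snp
        fit = fit_interaction_model(rng.normal(size=n), snp, sex)
        assert fit["status"] == expected
        assert np.isnan(fit["p_interaction"])

    def test_insufficient_complete_cases(self):
        fit = fit_interaction_model(
            np.zeros(4), np.array([0.0, 1, 2, 1]), np.array([0.0, 1, 0, 1])
        )
        assert fit["status"] == "insufficient_n"

    def test_missing_dosage_dropped_per_test(self):
        rng = np.random.default_rng(4)
        n = 60
        snp = rng.binomial(2, 0.4, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        snp_miss = snp.copy()
        snp_miss[:5] = np.nan
        fit = fit_interaction_model(y, snp_miss, sex)
        ref = fit_interaction_model(y[5:], snp[5:], sex[5:])
        assert fit["n_used"] == n - 5
        assert np.allclose(fit["beta"], ref["beta"])

    def test_p_invariant_to_affine_rescaling_of_y(self):
        rng = np.random.default_rng(6)
        n = 80
        snp = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        a = fit_interaction_model(y, snp, sex)
        b = fit_interaction_model(3.7 * y - 11.0, snp, sex)
        assert a["p_interaction"] == pytest.approx(b["p_interaction"], rel=1e-10)

    def test_p_invariant_to_sex_label_swap(self):
        rng = np.random.default_rng(7)
        n = 80
        snp = rng.binomial(2, 0.3, n).astype(float)
        sex = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n) + 0.4 * sex * snp
        a = fit_interaction_model(y, snp, sex)
        b = fit_interaction_model(y, snp, 1.0 - sex)
        assert a["p_interaction"] == pytest.approx(b["p_interaction"], rel=1e-8)
        assert b["beta"][INTERACTION_COL] == pytest.approx(
            -a["beta"][INTERACTION_COL], rel=1e-8
        )


class TestBhThreshold:
    @pytest.mark.parametrize(
        "pvals,q,n_rej,thr",
        [
            ([0.001, 0.01, 0.02, 0.04, 0.9], 0.05, 4, 0.04),
            ([1.0, 1.0, 1.0], 0.05, 0, np.nan),
            ([0.04], 0.05, 1, 0.04),
            ([0.05, 0.05], 0.05, 2, 0.05),  # tie at the step-up boundary
            ([0.5], 0.05, 0, np.nan),
        ],
    )
    def test_step_up_examples(self, pvals, q, n_rej, thr):
        screen = bh_threshold(pvals, q=q)
        assert screen.n_rejected == n_rej
        if np.isnan(thr):
            assert np.isnan(screen.p_threshold)
        else:
            assert screen.p_threshold == pytest.approx(thr)

    def test_nan_excluded_from_test_count(self):
        screen = bh_threshold([0.01, np.nan, 0.5, np.nan], q=0.05)
        assert screen.m == 2
        assert screen.n_excluded == 2
        assert screen.n_rejected == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            bh_threshold([], q=0.05)

    def test_matches_statsmodels_fdr_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(50):
            m = rng.integers(1, 60)
            p = np.round(rng.random(m), rng.integers(1, 4))  # rounding makes ties
            screen = bh_threshold(p, q=0.05)
            expected, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.array_equal(screen.rejected, expected)


class TestRunStage1:
    def test_batched_and_scalar_paths_agree(self, null_cohort):
        pairs = truth_pairs(null_cohort)
        res, _ = run_stage1(null_cohort, pairs)
        for _, row in res.iterrows():
            fit = fit_interaction_model(
                null_cohort.expression.row(row["feature_id"]),
                null_cohort.genotypes.row(row["variant_id"]),
                null_cohort.samples.sex,
                null_cohort.samples.pcs,
            )
            assert row["status"] == fit["status"] == "ok"
            assert row["p_interaction"] == pytest.approx(fit["p_interaction"], rel=1e-9)
            assert row["beta_interaction"] == pytest.approx(
                fit["beta"][INTERACTION_COL], rel=1e-9
            )

    def test_missing_dosages_fall_back_to_complete_case(self, null_cohort):
        dosage = null_cohort.genotypes.dosage.copy()
        dosage[0, :7] = np.nan
        geno = null_cohort.genotypes
        holey = Cohort(
            genotypes=type(geno)(
                variants=geno.variants.copy(), dosage=dosage, samples=list(geno.samples)
            ),
            samples=null_cohort.samples,
            expression=null_cohort.expression,
        )
        pairs = pd.DataFrame({"variant_id": ["var00000"], "feature_id": ["feat00000"]})
        res, _ = run_stage1(holey, pairs)
        assert res.loc[0, "n_used"] == holey.n_samples - 7
        assert res.loc[0, "status"] == "ok"

    def test_interaction_pvalues_uniform_under_null(self):
        """2000 independent null fits at n = 334: KS does not reject at 0.01."""
        cohort = simulate_cohort(
            SimulationConfig(n_male=174, n_female=160, n_variants=2000,
                             n_features=2000, seed=71)
        )
        res, screen = run_stage1(cohort, truth_pairs(cohort))
        p = res["p_interaction"].to_numpy()
        assert stats.kstest(p[np.isfinite(p)], "uniform").pvalue > 0.01
        assert screen.m == 2000

    def test_empty_pairs_raise(self, null_cohort):
        with pytest.raises(ValueError):
            run_stage1(null_cohort, pd.DataFrame(columns=["variant_id", "feature_id"]))
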