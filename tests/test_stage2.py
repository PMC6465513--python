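"""Robust stage: block QC, Huber IWLS, robust Wald test, OR-logic calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sseqtl.containers import Cohort, ExpressionMatrix, GenotypeMatrix, SampleTable
from sseqtl.simulate import (
    NoiseModel,
    PlantedEffect,
    SimulationConfig,
    simulate_cohort,
)
from sseqtl.stage2 import (
    RobustFit,
    fit_rlm_huber,
    huber_loss,
    qc_block_filter,
    robust_wald_test,
    run_stage2,
)
from sseqtl.experiments import truth_pairs


def blocks_to_vectors(male_counts, female_counts):
    """Expand per-genotype block counts into aligned dosage/sex vectors."""
    dos, sex = [], []
    for s, counts in ((0, male_counts), (1, female_counts)):
        for g, c in zip((0.0, 1.0, 2.0), counts):
            dos.extend([g] * c)
            sex.extend([s] * c)
    return np.array(dos), np.array(sex)


class TestQcBlockFilter:
    def test_low_count_block_named(self):
        dos, sex = blocks_to_vectors((5, 5, 5), (5, 5, 4))
        ok, reason = qc_block_filter(dos, sex)
        assert not ok
        assert reason == "F genotype 2 count 4 < 5"

    def test_all_blocks_adequate(self):
        dos, sex = blocks_to_vectors((10, 10, 10), (5, 5, 5))
        ok, reason = qc_block_filter(dos, sex)
        assert ok and reason == ""

    def test_absent_genotype_named(self):
        dos, sex = blocks_to_vectors((6, 0, 6), (6, 6, 6))
        ok, reason = qc_block_filter(dos, sex)
        assert not ok
        assert reason == "genotype 1 absent in males"

    def test_x_mode_skips_male_het_block(self):
        # hemizygous males never carry genotype 1; only {0,2} are required
        dos = np.array([0.0] * 6 + [2.0] * 6 + [0.0] * 5 + [1.0] * 5 + [2.0] * 5)
        sex = np.array([0] * 12 + [1] * 15)
        ok, _ = qc_block_filter(dos, sex, is_x=True)
        assert ok
        ok_auto, reason = qc_block_filter(dos, sex, is_x=False)
        assert not ok_auto and "absent in males" in reason

    def test_missing_dosages_do_not_count(self):
        dos, sex = blocks_to_vectors((5, 5, 5), (5, 5, 5))
        dos = dos.astype(float)
        dos[0] = np.nan  # male genotype-0 block drops to 4
        ok, reason = qc_block_filter(dos, sex)
        assert not ok and reason == "M genotype 0 count 4 < 5"


class TestFitRlmHuber:
    def test_exact_linear_data_degenerate_scale(self):
        snp = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        y = 2.0 * snp
        fit = fit_rlm_huber(y, np.column_stack([np.ones(8), snp]))
        assert fit.degenerate_scale
        assert fit.beta[1] == pytest.approx(2.0)
        assert np.isnan(fit.robust_se).all()

    def test_equals_ols_when_no_residual_is_downweighted(self):
        """Bounded noise below k*scale: every Huber weight is 1, so RLM = OLS."""
        rng = np.random.default_rng(9)
        n = 100
        snp = rng.binomial(2, 0.4, n).astype(float)
        e = 0.5 * np.sign(rng.normal(size=n))  # |r| identical => MAD scale ~ 0.74
        y = 1.0 + 0.3 * snp + e
        X = np.column_stack([np.ones(n), snp])
        fit = fit_rlm_huber(y, X, keep_trace=True)
        resid = y - X @ fit.beta
        assert np.all(np.abs(resid) <= 1.345 * fit.scale)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-8)

    def test_close_to_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(10)
        n = 200
        snp = rng.binomial(2, 0.3, n).astype(float)
        y = 1.0 + 0.5 * snp + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), snp])
        fit = fit_rlm_huber(y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.converged
        assert abs(fit.beta[1] - ols[1]) < 0.1

    def test_matches_statsmodels_rlm(self):
        """Independent cross-check: MASS-style Huber defaults in statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        for _ in range(5):
            n = 150
            snp = rng.binomial(2, 0.3, n).astype(float)
            pcs = rng.normal(size=(n, 2))
            e = rng.normal(0, 1, n)
            e[rng.random(n) < 0.05] = rng.normal(0, 8)
            y = 1.0 + 0.5 * snp + e
            X = np.column_stack([np.ones(n), snp, pcs])
            ours = fit_rlm_huber(y, X)
            ref = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
            assert np.allclose(ours.beta, ref.params, atol=1e-4)
            assert np.allclose(ours.robust_se, ref.bse, rtol=1e-3)

    def test_iwls_objective_nonincreasing(self):
        """Huber loss at the final scale decreases along the IWLS iterates."""
        rng = np.random.default_rng(15)
        for _ in range(20):
            n = 80
            snp = rng.binomial(2, 0.3, n).astype(float)
            e = rng.normal(0, 1, n)
            e[rng.random(n) < 0.1] = rng.normal(0, 10)
            y = 0.5 * snp + e
            X = np.column_stack([np.ones(n), snp])
            fit = fit_rlm_huber(y, X, keep_trace=True)
            losses = [huber_loss(y - X @ b, fit.scale) for b in fit.trace]
            assert all(b <= a + 1e-7 for a, b in zip(losses, losses[1:]))

    def test_downweights_gross_outliers(self):
        """One 10-sigma point drags OLS but barely moves the Huber fit."""
        rng = np.random.default_rng(16)
        n = 100
        snp = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * snp + rng.normal(0, 1, n)
        y_dirty = y.copy()
        y_dirty[np.argmax(snp)] += 30.0
        X = np.column_stack([np.ones(n), snp])
        ols_shift = abs(
            np.linalg.lstsq(X, y_dirty, rcond=None)[0][1]
            - np.linalg.lstsq(X, y, rcond=None)[0][1]
        )
        rlm_shift = abs(fit_rlm_huber(y_dirty, X).beta[1] - fit_rlm_huber(y, X).beta[1])
        assert rlm_shift < ols_shift / 3

    def test_too_few_cases_raise(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_rlm_huber(np.zeros(3), np.column_stack([np.ones(3), np.arange(3.0)]))


class TestRobustWald:
    def _fit(self, beta1, se=0.1, n=100, p=2):
        return RobustFit(
            beta=np.array([0.0, beta1]), robust_se=np.array([0.1, se]),
            scale=1.0, n_used=n, iterations=3, converged=True,
        )

    def test_zero_coefficient_gives_p_one(self):
        assert robust_wald_test(self._fit(0.0)) == pytest.approx(1.0)

    def test_p_monotone_in_statistic(self):
        ps = [robust_wald_test(self._fit(b)) for b in (0.05, 0.2, 0.8, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-10

    def test_degenerate_fit_refused(self):
        fit = self._fit(1.0)
        fit.degenerate_scale = True
        with pytest.raises(ValueError, match="degenerate"):
            robust_wald_test(fit)

    def test_nonconverged_fit_refused(self):
        fit = self._fit(1.0)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            robust_wald_test(fit)

    def test_type_i_error_calibrated(self):
        """Null slope, n = 170: rejection rate at 0.05 lands in [0.03, 0.07]."""
        rng = np.random.default_rng(18)
        n, reps = 170, 2000
        hits = 0
        for _ in range(reps):
            snp = rng.binomial(2, 0.3, n).astype(float)
            y = rng.normal(0, 1, n)
            fit = fit_rlm_huber(y, np.column_stack([np.ones(n), snp]))
            if robust_wald_test(fit) < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_agrees_with_ols_t_test_without_outliers(self):
        """No downweighted residuals at n = 1000: robust and OLS p agree.

        Bounded noise keeps every residual inside k * scale so the Huber
        estimate coincides with OLS; the two p-values then differ only by
        the robust-variance correction factors, which vanish here.
        """
        rng = np.random.default_rng(19)
        n = 1000
        snp = rng.binomial(2, 0.3, n).astype(float)
        e = rng.uniform(-0.5, 0.5, n)  # max |e| well below k * MAD-scale
        y = 0.08 * snp + e
        X = np.column_stack([np.ones(n), snp])
        p_rlm = robust_wald_test(fit_rlm_huber(y, X))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p_ols = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
        assert abs(p_rlm - p_ols) < 0.02


def _interaction_cohort(seed=25, beta3=1.2):
    return simulate_cohort(
        SimulationConfig(
            n_male=174, n_female=160, n_variants=30, n_features=30,
            maf_range=(0.25, 0.5),
            effects=(PlantedEffect(feature=0, variant=0, beta3=beta3),),
            seed=seed,
        )
    )


class TestRunStage2:
    def test_empty_candidates_empty_calls(self, null_cohort):
        strata, calls, screen = run_stage2(
            pd.DataFrame(columns=["variant_id", "feature_id"]), null_cohort
        )
        assert calls.empty and screen is None

    def test_qc_failure_excluded_before_fitting(self):
        cohort = _interaction_cohort()
        # a rare variant cannot fill the hom-alt blocks
        cohort.genotypes.dosage[5] = 0.0
        cohort.genotypes.dosage[5, :3] = 1.0
        cand = pd.DataFrame(
            {"variant_id": ["var00005"], "feature_id": ["feat00005"]}
        )
        strata, calls, _ = run_stage2(cand, cohort)
        assert (~strata["qc_pass"]).all()
        assert strata["p_beta1"].isna().all()
        assert "count" in strata["qc_reason"].iloc[0] or "absent" in strata["qc_reason"].iloc[0]
        assert calls.empty

    def test_or_logic_single_stratum_call(self):
        """A female-only association passes via the OR rule."""
        cohort = _interaction_cohort(seed=26, beta3=1.5)
        cand = truth_pairs(cohort).iloc[[0]]
        strata, calls, _ = run_stage2(cand, cohort)
        female = strata[strata["sex_stratum"] == "female"].iloc[0]
        assert female["p_beta1"] < 0.01
        assert len(calls) == 1
        assert calls.iloc[0]["which_stratum"] in ("female", "both")

    def test_calls_invariant_under_sample_permutation(self):
        cohort = _interaction_cohort(seed=27, beta3=1.5)
        cand = truth_pairs(cohort)
        _, calls_a, _ = run_stage2(cand, cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_samples)
        ids = [cohort.samples.sample_ids[i] for i in perm]
        permuted = Cohort(
            genotypes=cohort.genotypes.subset_samples(ids),
            samples=cohort.samples.reorder(ids),
            expression=cohort.expression.reorder_samples(ids),
        )
        _, calls_b, _ = run_stage2(cand, permuted)
        pd.testing.assert_frame_equal(calls_a, calls_b)

    def test_pooled_screen_counts_both_strata(self):
        cohort = _interaction_cohort(seed=28, beta3=1.5)
        cand = truth_pairs(cohort).iloc[:4]
        strata, _, screen = run_stage2(cand, cohort)
        assert screen.m == int(strata["p_beta1"].notna().sum())
        assert len(strata) == 8  # two strata per candidate
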