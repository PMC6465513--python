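"""Analytic power calculations for the two regression stages.

``anova_interaction_power`` treats the interaction screen as an omnibus
fixed-effects one-way ANOVA over the sex-by-genotype cells (6 groups by
default): with Cohen's effect size f and total sample size N, the test
statistic is noncentral F with df1 = groups - 1, df2 = N - groups and
noncentrality lambda = f^2 * N, and power is the probability it exceeds the
central-F critical value at level alpha.

``eqtl_power`` gives the power of the per-stratum eQTL test: a two-sided
level-alpha t-test of the slope in a simple regression of expression on
dosage.  Under Hardy-Weinberg the genotype variance is 2*maf*(1-maf), so the
noncentrality of the t statistic is slope * sqrt(n * 2*maf*(1-maf)) / sigma
with n - 2 degrees of freedom.  The noncentral-t formulation (rather than a
normal approximation) matters at per-sex sample sizes of ~160-176.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["anova_interaction_power", "eqtl_power"]


def anova_interaction_power(
    effect_size_f: float,
    n_total: int,
    n_groups: int = 6,
    alpha: float = 0.05,
) -> float:
    """Power of the omnibus fixed-effects ANOVA at Cohen's f.

    Parameters
    ----------
    effect_size_f
        Cohen's f (between-group SD / within-group SD); >= 0.
    n_total
        Total sample size across all groups.
    n_groups
        Number of cells; 6 = 2 sexes x 3 genotypes.
    alpha
        Test level.
    """
    if effect_size_f < 0:
        raise ValueError("effect_size_f must be >= 0")
    if n_total <= n_groups:
        raise ValueError("n_total must exceed n_groups")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df1 = n_groups - 1
    df2 = n_total - n_groups
    lam = effect_size_f**2 * n_total
    f_crit = stats.f.ppf(1.0 - alpha, df1, df2)
    if lam == 0:
        return float(alpha)  # central F: power equals the level exactly
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def eqtl_power(
    maf: float,
    n: int,
    slope: float,
    sigma: float,
    alpha: float = 0.05,
) -> float:
    """Power to detect a single eQTL by a two-sided slope t-test.

    Parameters
    ----------
    maf
        Minor allele frequency in (0, 0.5]; genotype variance under HWE is
        ``2 * maf * (1 - maf)``.
    n
        Sample size of the analysis (e.g. one sex stratum).
    slope
        Expression change per alternate allele.
    sigma
        Residual SD of expression.
    alpha
        Test level.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n < 3:
        raise ValueError("n must be >= 3 for a slope t-test")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 2
    delta = slope * np.sqrt(n * 2.0 * maf * (1.0 - maf)) / sigma
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    if delta == 0:
        return float(alpha)
    return float(stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta))
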