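"""Stage 2: sex-stratified robust validation of stage-1 candidates.

Each candidate pair is refitted separately in males and in females with

    y = b0 + b1*SNP + b2*PC1 + b3*PC2 + b4*PC3 + e

using a Huber M-estimator solved by iteratively reweighted least squares
(IWLS): residuals are computed at the current coefficients, the scale is
re-estimated as the median absolute residual / 0.6745 (the normal-consistent
MAD), Huber weights w_i = min(1, k*s/|r_i|) are formed with tuning constant
k = 1.345 (95% efficiency at the Gaussian), and a weighted least-squares
solve updates the coefficients.  The genotype coefficient b1 is tested with
a robust Wald statistic t = b1 / robust_se(b1) against t(n - p).

The robust covariance is the classical Huber proposal used by standard
M-estimation summaries:

    cov(beta) = kappa^2 * [s^2 * sum(psi(u)^2) / (n - p)] / mean(psi'(u))^2
                * (X'X)^{-1}

with u = r/s, psi the Huber psi-function, and kappa the small-sample
correction 1 + p/n * var(psi') / mean(psi')^2.  (A full sandwich estimator
can be substituted via ``cov="sandwich"``.)

Before fitting, a block QC filter requires every genotype-by-sex block to
hold at least ``min_count`` samples with all genotypes present — 0/1/2 in
each sex on autosomes; on the X chromosome the realizable blocks are {0, 2}
for hemizygous males and {0, 1, 2} for females.  The stage-2 BH screen runs
over the pooled male and female p-values of all candidates, and a candidate
is called significant when either stratum (or both) passes — the OR rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sseqtl.containers import Cohort
from sseqtl.stage1 import FdrScreen, bh_threshold

__all__ = [
    "RobustFit",
    "qc_block_filter",
    "fit_rlm_huber",
    "robust_wald_test",
    "run_stage2",
]

HUBER_K = 1.345
MAD_CONST = 0.6745  # median(|N(0,1)|): makes MAD consistent for sigma


@dataclass
class RobustFit:
    """One Huber IWLS fit: coefficients, robust SEs and diagnostics."""

    beta: np.ndarray
    robust_se: np.ndarray
    scale: float
    n_used: int
    iterations: int
    converged: bool
    degenerate_scale: bool = False
    trace: list | None = None  # per-iteration beta vectors when requested


def qc_block_filter(
    dosages: np.ndarray,
    sex: np.ndarray,
    min_count: int = 5,
    is_x: bool = False,
) -> tuple[bool, str]:
    """Check genotype-by-sex block occupancy for one variant.

    Every realizable block must contain at least ``min_count`` samples and
    every realizable genotype must be present in each sex.  Missing dosages
    do not count toward any block.  Returns (pass, reason); the reason names
    the first failing block.
    """
    d = np.asarray(dosages, dtype=float)
    sex = np.asarray(sex)
    male_levels = (0.0, 2.0) if is_x else (0.0, 1.0, 2.0)
    female_levels = (0.0, 1.0, 2.0)
    for sx, label, levels in ((0, "males", male_levels), (1, "females", female_levels)):
        sub = d[(sex == sx) & np.isfinite(d)]
        for g in levels:
            count = int((sub == g).sum())
            if count == 0:
                return False, f"genotype {g:g} absent in {label}"
            if count < min_count:
                return False, f"{label[0].upper()} genotype {g:g} count {count} < {min_count}"
    return True, ""


def _huber_weights(resid: np.ndarray, scale: float, k: float) -> np.ndarray:
    a = np.abs(resid)
    with np.errstate(divide="ignore"):
        return np.minimum(1.0, k * scale / np.where(a > 0, a, np.inf))


def huber_loss(resid: np.ndarray, scale: float, k: float = HUBER_K) -> float:
    """Huber objective at a fixed scale (used to verify IWLS descent)."""
    u = np.abs(resid) / scale
    quad = 0.5 * u**2
    lin = k * u - 0.5 * k**2
    return float(np.where(u <= k, quad, lin).sum())


def fit_rlm_huber(
    y: np.ndarray,
    X: np.ndarray,
    tuning_k: float = HUBER_K,
    max_iter: int = 50,
    tol: float = 1e-8,
    cov: str = "huber",
    keep_trace: bool = False,
) -> RobustFit:
    """Huber M-estimate of ``y = X beta + e`` by IWLS with MAD scale.

    Starts from OLS; stops when ``max|delta beta| < tol * (1 + max|beta|)``
    or after ``max_iter`` sweeps.  A (near-)exact fit collapses the MAD
    scale; the fit is then returned with ``degenerate_scale`` set and no
    usable standard errors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {n}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design")

    yscale = max(float(np.median(np.abs(y - np.median(y)))), 1.0)
    trace = [beta.copy()] if keep_trace else None
    converged = False
    scale = np.nan
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid))) / MAD_CONST
        if scale < 1e-10 * yscale:
            return RobustFit(
                beta=beta, robust_se=np.full(p, np.nan), scale=scale,
                n_used=n, iterations=it, converged=True, degenerate_scale=True,
                trace=trace,
            )
        w = _huber_weights(resid, scale, tuning_k)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if keep_trace:
            trace.append(beta.copy())
        if step < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    resid = y - X @ beta
    scale = float(np.median(np.abs(resid))) / MAD_CONST
    if scale < 1e-10 * yscale:
        return RobustFit(
            beta=beta, robust_se=np.full(p, np.nan), scale=scale,
            n_used=n, iterations=it, converged=converged, degenerate_scale=True,
            trace=trace,
        )
    u = resid / scale
    psi = np.clip(u, -tuning_k, tuning_k)
    psi_prime = (np.abs(u) <= tuning_k).astype(float)
    mbar = psi_prime.mean()
    if cov == "huber":
        kappa = 1.0 + p / n * psi_prime.var() / mbar**2
        num = scale**2 * (psi**2).sum() / (n - p)
        cov_beta = kappa**2 * num / mbar**2 * np.linalg.inv(X.T @ X)
    elif cov == "sandwich":
        bread = np.linalg.inv(X.T @ (psi_prime[:, None] * X))
        meat = scale**2 * (X * psi[:, None]).T @ (X * psi[:, None]) * n / (n - p)
        cov_beta = bread @ meat @ bread
    else:
        raise ValueError(f"unknown cov estimator {cov!r}")
    return RobustFit(
        beta=beta,
        robust_se=np.sqrt(np.diag(cov_beta)),
        scale=scale,
        n_used=n,
        iterations=it,
        converged=converged,
        trace=trace,
    )


def robust_wald_test(fit: RobustFit, coef_index: int = 1) -> float:
    """Two-sided robust Wald p-value for one coefficient of a Huber fit.

    ``t = beta / robust_se`` referred to t with ``n_used - p`` df.  Raises
    on a non-converged fit or a degenerate scale (no valid inference).
    """
    if not fit.converged:
        raise ValueError("robust fit did not converge; no Wald test available")
    if fit.degenerate_scale or not np.isfinite(fit.robust_se[coef_index]):
        raise ValueError("degenerate robust scale; no Wald test available")
    df = fit.n_used - fit.beta.size
    t = fit.beta[coef_index] / fit.robust_se[coef_index]
    return float(2.0 * stats.t.sf(abs(t), df=df))


def _stratum_fit(
    y: np.ndarray, snp: np.ndarray, pcs: np.ndarray, **rlm_kwargs
) -> tuple[RobustFit | None, float, str]:
    """Fit one sex stratum; returns (fit, p, reason) with NaN p on failure."""
    ok = np.isfinite(y) & np.isfinite(snp)
    if pcs.size:
        ok &= np.isfinite(pcs).all(axis=1)
    y, snp, pcs = y[ok], snp[ok], pcs[ok]
    p_cols = 2 + pcs.shape[1]
    if y.size < p_cols + 2:
        return None, np.nan, "insufficient_n"
    if np.ptp(snp) == 0:
        return None, np.nan, "constant_snp"
    X = np.column_stack([np.ones_like(snp), snp] + list(pcs.T))
    try:
        fit = fit_rlm_huber(y, X, **rlm_kwargs)
    except ValueError as exc:
        return None, np.nan, str(exc)
    if not fit.converged:
        return fit, np.nan, "not_converged"
    if fit.degenerate_scale:
        return fit, np.nan, "degenerate_scale"
    return fit, robust_wald_test(fit, coef_index=1), ""


def run_stage2(
    candidates: pd.DataFrame,
    cohort: Cohort,
    q: float = 0.05,
    min_count: int = 5,
    pool: str = "pooled",
    **rlm_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, FdrScreen | None]:
    """Validate stage-1 candidates with sex-stratified robust fits.

    ``candidates`` needs columns ``variant_id, feature_id`` (typically the
    stage-1 rejections).  Per candidate: block QC, then a male-only and a
    female-only Huber fit with robust Wald p for the genotype coefficient.
    BH at level ``q`` runs over the pooled male+female p-values
    (``pool="pooled"``, the default) or separately per stratum
    (``pool="per-stratum"``); the final ss-eQTL call is the OR rule over
    strata.  Candidates failing QC or with non-convergent fits are excluded
    from the screen with their reason recorded.

    Returns (per-stratum result table, calls table, screen).  The calls
    table is ordered by chromosome, position, feature.
    """
    if pool not in ("pooled", "per-stratum"):
        raise ValueError(f"unknown pooling mode {pool!r}")
    empty_calls = pd.DataFrame(
        columns=["variant_id", "feature_id", "chrom", "pos", "significant", "which_stratum"]
    )
    if candidates.empty:
        return pd.DataFrame(), empty_calls, None

    sex = cohort.samples.sex
    pcs = cohort.samples.pcs
    vmeta = cohort.genotypes.variants.set_index("variant_id")

    rows = []
    for _, cand in candidates.iterrows():
        vid, fid = cand["variant_id"], cand["feature_id"]
        d = cohort.genotypes.row(vid)
        y = cohort.expression.row(fid)
        is_x = bool(vmeta.loc[vid, "is_x"])
        usable = np.isfinite(d) & np.isfinite(y)
        qc_pass, qc_reason = qc_block_filter(
            np.where(usable, d, np.nan), sex, min_count=min_count, is_x=is_x
        )
        for sx, label in ((0, "male"), (1, "female")):
            row = {
                "variant_id": vid, "feature_id": fid, "sex_stratum": label,
                "chrom": vmeta.loc[vid, "chrom"], "pos": int(vmeta.loc[vid, "pos"]),
                "qc_pass": qc_pass, "qc_reason": qc_reason,
                "beta_snp": np.nan, "se_snp": np.nan, "scale": np.nan,
                "n_used": 0, "iterations": 0, "converged": False,
                "p_beta1": np.nan, "fit_reason": "",
            }
            if qc_pass:
                mask = sex == sx
                fit, pval, reason = _stratum_fit(
                    y[mask], d[mask], pcs[mask], **rlm_kwargs
                )
                if fit is not None:
                    row.update(
                        beta_snp=fit.beta[1], se_snp=fit.robust_se[1],
                        scale=fit.scale, n_used=fit.n_used,
                        iterations=fit.iterations, converged=fit.converged,
                    )
                row.update(p_beta1=pval, fit_reason=reason)
            rows.append(row)
    stratum = pd.DataFrame(rows)

    if pool == "pooled":
        screen = bh_threshold(stratum["p_beta1"].to_numpy(), q=q)
        stratum["stage2_rejected"] = screen.rejected
    else:
        stratum["stage2_rejected"] = False
        screen = None
        for label in ("male", "female"):
            mask = (stratum["sex_stratum"] == label).to_numpy()
            sub = bh_threshold(stratum.loc[mask, "p_beta1"].to_numpy(), q=q)
            stratum.loc[mask, "stage2_rejected"] = sub.rejected
            screen = sub if screen is None else screen  # report male screen first

    by_pair = stratum.pivot_table(
        index=["variant_id", "feature_id", "chrom", "pos"],
        columns="sex_stratum",
        values="stage2_rejected",
        aggfunc="first",
    ).rename_axis(columns=None).reset_index()
    for col in ("male", "female"):
        if col not in by_pair.columns:
            by_pair[col] = False
        by_pair[col] = by_pair[col].fillna(False).astype(bool)
    by_pair["significant"] = by_pair["male"] | by_pair["female"]
    by_pair["which_stratum"] = np.select(
        [by_pair["male"] & by_pair["female"], by_pair["male"], by_pair["female"]],
        ["both", "male", "female"],
        default="",
    )
    calls = (
        by_pair.loc[by_pair["significant"]]
        .sort_values(["chrom", "pos", "feature_id"], kind="mergesort")
        .reset_index(drop=True)
        [["variant_id", "feature_id", "chrom", "pos", "significant", "which_stratum"]]
    )
    return stratum, calls, screen
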