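"""Stage 1: genome-wide OLS interaction scan with BH-FDR screening.

For every cis variant-feature pair the model

    y = b0 + b1*SNP + b2*sex + b3*sex*SNP + b4*PC1 + ... + e

is fitted by ordinary least squares and the sex-by-genotype interaction b3
is tested two-sided against t with n - p degrees of freedom.  The
Benjamini-Hochberg step-up procedure at level q (default 0.05) screens the
interaction p-values; the screen reports the equivalent p-value threshold
(the largest rejected p).  Pairs that cannot be tested — constant genotype,
a single sex among complete cases, a rank-deficient design or zero residual
variance — are flagged with a reason code and excluded from the BH test
count.

Design-matrix column order is fixed as
``(intercept, snp, sex, sex*snp, PC1..PCk)``; the interaction coefficient
is always column 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sseqtl.containers import Cohort

__all__ = [
    "FdrScreen",
    "bh_threshold",
    "fit_interaction_model",
    "run_stage1",
    "INTERACTION_COL",
]

#: index of the sex*snp column in the stage-1 design matrix
INTERACTION_COL = 3

STATUS_OK = "ok"
STATUS_CONSTANT_SNP = "constant_snp"
STATUS_SINGLE_SEX = "single_sex"
STATUS_INSUFFICIENT_N = "insufficient_n"
STATUS_COLLINEAR = "collinear"
STATUS_DEGENERATE = "degenerate_fit"

_COND_MAX = 1e10  # condition-number cutoff for a usable design
_RSS_REL_MIN = 1e-12  # residual variance below this fraction of TSS is degenerate


@dataclass
class FdrScreen:
    """Outcome of one Benjamini-Hochberg step-up screen.

    ``p_threshold`` is the largest rejected p-value (the screen's equivalent
    p-value cutoff) and is NaN when nothing is rejected.  ``n_excluded``
    counts NaN/flagged inputs that were kept out of the test count ``m``.
    """

    q: float
    m: int
    n_rejected: int
    p_threshold: float
    rejected: np.ndarray  # boolean mask over the input p-value vector
    n_excluded: int = 0


def bh_threshold(pvalues, q: float = 0.05) -> FdrScreen:
    """Standard BH step-up over a p-value vector.

    NaN entries (untestable pairs) are excluded from ``m`` with a count.
    Ties at the threshold are rejected together, as the step-up rule
    implies.  Raises on an empty vector.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_threshold requires at least one p-value")
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = int(valid.sum())
    rejected = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return FdrScreen(q=q, m=0, n_rejected=0, p_threshold=np.nan,
                         rejected=rejected, n_excluded=int(p.size))
    ps = np.sort(p[valid])
    passing = np.nonzero(ps <= np.arange(1, m + 1) * q / m)[0]
    if passing.size == 0:
        thr = np.nan
    else:
        thr = ps[passing[-1]]
        rejected[valid] = p[valid] <= thr
    return FdrScreen(
        q=q,
        m=m,
        n_rejected=int(rejected.sum()),
        p_threshold=float(thr) if np.isfinite(thr) else np.nan,
        rejected=rejected,
        n_excluded=int(p.size - m),
    )


def _design(snp: np.ndarray, sex: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(snp), snp, sex, sex * snp]
    if pcs.size:
        cols.extend(pcs.T)
    return np.column_stack(cols)


def fit_interaction_model(
    y: np.ndarray,
    snp_dosage: np.ndarray,
    sex: np.ndarray,
    pcs: np.ndarray | None = None,
) -> dict:
    """OLS fit of the interaction model for one pair.

    Complete-case over ``y``/``snp``/PCs (missing dosages drop the sample
    for this pair only).  Returns a dict with ``beta``, ``se``,
    ``p_interaction``, ``n_used`` and a ``status`` reason code; a flagged
    fit carries NaN p so it can never silently enter the screen.
    """
    y = np.asarray(y, dtype=float)
    snp = np.asarray(snp_dosage, dtype=float)
    sex = np.asarray(sex, dtype=float)
    pcs = np.empty((y.size, 0)) if pcs is None else np.asarray(pcs, dtype=float)
    if pcs.ndim == 1:
        pcs = pcs[:, None]

    ok = np.isfinite(y) & np.isfinite(snp) & np.isfinite(pcs).all(axis=1)
    y, snp, sex, pcs = y[ok], snp[ok], sex[ok], pcs[ok]
    n = y.size
    p = 4 + pcs.shape[1]

    def _flagged(status: str) -> dict:
        return {
            "beta": np.full(p, np.nan), "se": np.full(p, np.nan),
            "p_interaction": np.nan, "n_used": int(n), "status": status,
        }

    if n < p + 2:
        return _flagged(STATUS_INSUFFICIENT_N)
    if np.unique(sex).size < 2:
        return _flagged(STATUS_SINGLE_SEX)
    if np.ptp(snp) == 0:
        return _flagged(STATUS_CONSTANT_SNP)

    X = _design(snp, sex, pcs)
    beta, rss_arr, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or sv[0] / sv[-1] > _COND_MAX:
        return _flagged(STATUS_COLLINEAR)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= _RSS_REL_MIN * max(tss, 1.0):
        out = _flagged(STATUS_DEGENERATE)
        out["beta"] = beta  # coefficients are still exact; only inference is void
        return out
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t3 = beta[INTERACTION_COL] / se[INTERACTION_COL]
    p_int = 2.0 * stats.t.sf(abs(t3), df=n - p)
    return {
        "beta": beta,
        "se": se,
        "p_interaction": float(p_int),
        "n_used": int(n),
        "status": STATUS_OK,
    }


def _scan_batched(
    D: np.ndarray,  # (m, n) complete dosage rows
    Y: np.ndarray,  # (m, n) matching expression rows
    sex: np.ndarray,
    pcs: np.ndarray,
    chunk: int = 1024,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS over many pairs with a shared complete sample set.

    Returns (beta, se, p_interaction, status_ok mask) with the same pair
    semantics as :func:`fit_interaction_model`; pairs flagged here get NaN
    p-values and are refitted by the scalar path for a reason code.
    """
    m, n = D.shape
    p = 4 + pcs.shape[1]
    beta_out = np.full((m, p), np.nan)
    se_out = np.full((m, p), np.nan)
    p_out = np.full(m, np.nan)
    ok_out = np.zeros(m, dtype=bool)
    both_sexes = np.unique(sex).size == 2
    if n < p + 2 or not both_sexes:
        return beta_out, se_out, p_out, ok_out

    base = [np.ones(n), None, sex.astype(float), None]
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Dc, Yc = D[lo:hi], Y[lo:hi]
        mb = hi - lo
        X = np.empty((mb, n, p))
        X[:, :, 0] = 1.0
        X[:, :, 1] = Dc
        X[:, :, 2] = sex
        X[:, :, 3] = Dc * sex
        if pcs.shape[1]:
            X[:, :, 4:] = pcs[None, :, :]
        G = np.einsum("bnp,bnq->bpq", X, X)
        Xty = np.einsum("bnp,bn->bp", X, Yc)
        nonconst = np.ptp(Dc, axis=1) > 0
        ev = np.linalg.eigvalsh(G)
        usable = nonconst & (ev[:, 0] > 0) & (ev[:, -1] / np.maximum(ev[:, 0], 1e-300) < _COND_MAX**2)
        if not usable.any():
            continue
        Ginv = np.full_like(G, np.nan)
        Ginv[usable] = np.linalg.inv(G[usable])
        b = np.einsum("bpq,bq->bp", Ginv, Xty)
        yty = np.einsum("bn,bn->b", Yc, Yc)
        rss = yty - np.einsum("bp,bp->b", b, Xty)
        rss = np.maximum(rss, 0.0)
        tss = yty - n * Yc.mean(axis=1) ** 2
        nondegen = rss > _RSS_REL_MIN * np.maximum(tss, 1.0)
        sigma2 = rss / (n - p)
        se = np.sqrt(sigma2[:, None] * np.einsum("bpp->bp", Ginv))
        with np.errstate(invalid="ignore", divide="ignore"):
            t3 = b[:, INTERACTION_COL] / se[:, INTERACTION_COL]
        pv = 2.0 * stats.t.sf(np.abs(t3), df=n - p)
        good = usable & nondegen
        beta_out[lo:hi][usable] = b[usable]
        se_out[lo:hi][good] = se[good]
        p_out[lo:hi][good] = pv[good]
        ok_out[lo:hi] = good
    return beta_out, se_out, p_out, ok_out


def run_stage1(
    cohort: Cohort,
    pairs: pd.DataFrame,
    q: float = 0.05,
) -> tuple[pd.DataFrame, FdrScreen]:
    """Scan every cis pair and apply the stage-1 BH screen.

    ``pairs`` is the table from :func:`sseqtl.io.enumerate_cis_pairs`
    (columns ``variant_id, feature_id``).  Pairs whose variant has no
    missing dosage go through a vectorized path; pairs with missing data or
    flagged by the fast path are fitted one by one for an exact reason code.
    The screen is applied to this scan alone (separate analyses — e.g. mRNA
    vs miRNA — are screened separately by construction).

    Returns the per-pair result table and the :class:`FdrScreen` (whose
    ``p_threshold`` is the scan's equivalent p-value cutoff).
    """
    if pairs.empty:
        raise ValueError("no testable cis pairs")
    sex = cohort.samples.sex.astype(float)
    pcs = cohort.samples.pcs
    n_pcs = pcs.shape[1]
    p = 4 + n_pcs

    vidx = {v: i for i, v in enumerate(cohort.genotypes.variants["variant_id"])}
    fidx = {f: i for i, f in enumerate(cohort.expression.values.index)}
    vi = pairs["variant_id"].map(vidx)
    fi = pairs["feature_id"].map(fidx)
    if vi.isna().any() or fi.isna().any():
        missing = pairs.loc[vi.isna(), "variant_id"].tolist()[:5]
        missing += pairs.loc[fi.isna(), "feature_id"].tolist()[:5]
        raise KeyError(f"pairs reference unknown ids, e.g. {missing}")
    vi = vi.to_numpy(dtype=int)
    fi = fi.to_numpy(dtype=int)

    D = cohort.genotypes.dosage[vi]
    Y = cohort.expression.values.to_numpy(dtype=float)[fi]
    complete = np.isfinite(D).all(axis=1) & np.isfinite(Y).all(axis=1)

    beta = np.full((len(pairs), p), np.nan)
    se = np.full((len(pairs), p), np.nan)
    pint = np.full(len(pairs), np.nan)
    n_used = np.full(len(pairs), 0, dtype=int)
    status = np.array([""] * len(pairs), dtype=object)

    if complete.any():
        b, s, pv, ok = _scan_batched(D[complete], Y[complete], sex, pcs)
        idx = np.nonzero(complete)[0]
        beta[idx], se[idx], pint[idx] = b, s, pv
        n_used[idx] = D.shape[1]
        status[idx] = np.where(ok, STATUS_OK, "")

    slow = np.nonzero(status == "")[0]
    for k in slow:
        fit = fit_interaction_model(Y[k], D[k], sex, pcs)
        beta[k], se[k] = fit["beta"], fit["se"]
        pint[k], n_used[k], status[k] = fit["p_interaction"], fit["n_used"], fit["status"]

    col_names = ["intercept", "snp", "sex", "interaction"] + [f"PC{i+1}" for i in range(n_pcs)]
    result = pairs[["variant_id", "feature_id"]].copy()
    for j, name in enumerate(col_names):
        result[f"beta_{name}"] = beta[:, j]
    for j, name in enumerate(col_names):
        result[f"se_{name}"] = se[:, j]
    result["p_interaction"] = pint
    result["n_used"] = n_used
    result["status"] = status

    screen = bh_threshold(result["p_interaction"].to_numpy(), q=q)
    result["stage1_rejected"] = screen.rejected
    return result, screen
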