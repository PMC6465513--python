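"""LD-based annotation of ss-eQTL calls against a trait-association catalog.

LD is computed as the squared Pearson correlation of unphased dosages
(composite LD), which is the natural estimator when haplotype phase is
unavailable.  A call is annotated with every catalog SNP within the search
window that is in high LD (r^2 strictly greater than ``r2_min``, default
0.8) and carries a nominal trait association (p strictly below ``p_max``,
default 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sseqtl.containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["ld_r2", "annotate_with_catalog"]


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (complete-case)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete dosage pairs")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def annotate_with_catalog(
    calls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    catalog: pd.DataFrame,
    r2_min: float = 0.8,
    p_max: float = 0.05,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Co-localize ss-eQTL calls with catalog associations via LD.

    ``calls`` needs a ``variant_id`` column (one row per called SNP is
    enough; duplicates are collapsed).  ``catalog`` has columns
    ``snp_id, trait, p[, source]``; catalog SNPs absent from the genotype
    matrix are skipped with a logged count, as are those farther than
    ``window`` bp from the call.  Both thresholds are strict (r^2 > r2_min,
    p < p_max).  Output is deterministically ordered by call SNP, catalog
    p-value, catalog SNP and trait.
    """
    cols = ["call_snp", "catalog_snp", "r2", "trait", "catalog_p", "source"]
    if calls.empty or catalog.empty:
        return pd.DataFrame(columns=cols)
    vmeta = genotypes.variants.set_index("variant_id")
    known = set(vmeta.index)
    absent = sorted(set(catalog["snp_id"]) - known)
    if absent:
        logger.info("skipping %d catalog SNPs absent from genotypes", len(absent))
    cat = catalog[catalog["snp_id"].isin(known)]

    out = []
    for call_snp in pd.unique(calls["variant_id"]):
        if call_snp not in known:
            logger.warning("call SNP %s absent from genotypes; skipped", call_snp)
            continue
        chrom, pos = vmeta.loc[call_snp, "chrom"], vmeta.loc[call_snp, "pos"]
        d_call = genotypes.row(call_snp)
        for rec in cat.itertuples(index=False):
            if rec.p >= p_max:
                continue
            rchrom = vmeta.loc[rec.snp_id, "chrom"]
            rpos = vmeta.loc[rec.snp_id, "pos"]
            if rchrom != chrom or abs(int(rpos) - int(pos)) > window:
                continue
            try:
                r2 = ld_r2(d_call, genotypes.row(rec.snp_id))
            except ValueError:
                continue
            if r2 > r2_min:
                out.append(
                    {
                        "call_snp": call_snp,
                        "catalog_snp": rec.snp_id,
                        "r2": r2,
                        "trait": rec.trait,
                        "catalog_p": rec.p,
                        "source": getattr(rec, "source", ""),
                    }
                )
    result = pd.DataFrame(out, columns=cols)
    return result.sort_values(
        ["call_snp", "catalog_p", "catalog_snp", "trait"], kind="mergesort"
    ).reset_index(drop=True)
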