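#!/usr/bin/env python
"""Annotate the ss-eQTL calls from step 02 against a trait catalog via LD.

No real GWAS catalog ships with this repository, so the script builds a
small synthetic catalog over the simulated variants: the called SNPs
themselves (self-annotation, r^2 = 1, mimicking a call that is itself a
known trait SNP), nearby SNPs at various LD levels, and decoys failing the
p < 0.05 or r^2 > 0.8 thresholds.  Output: results/annotations.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sseqtl.io import read_genotypes, read_samples
from sseqtl.ld import annotate_with_catalog, ld_r2


def build_synthetic_catalog(calls, genotypes) -> pd.DataFrame:
    """Catalog rows engineered around the calls: hits, boundary and decoys."""
    rows = []
    for snp in calls["variant_id"]:
        rows.append((snp, "trait under sex-specific control", 0.0342, "synthetic"))
        rows.append((snp, "decoy trait (p too weak)", 0.06, "synthetic"))
        # nearest other variant: usually in weak LD -> exercises the r2 filter
        vmeta = genotypes.variants.set_index("variant_id")
        pos = vmeta.loc[snp, "pos"]
        near = (
            vmeta.drop(index=snp)
            .assign(dist=lambda d: (d["pos"] - pos).abs())
            .sort_values("dist")
            .index[0]
        )
        r2 = ld_r2(genotypes.row(snp), genotypes.row(near))
        rows.append((near, f"neighbour trait (r2={r2:.2f})", 0.01, "synthetic"))
    return pd.DataFrame(rows, columns=["snp_id", "trait", "p", "source"])


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--scan", default="results/scan")
    parser.add_argument("--out", default="results/annotations.tsv")
    args = parser.parse_args()

    cohort = Path(args.cohort)
    samples = read_samples(cohort / "samples.tsv")
    genotypes, _ = read_genotypes(cohort / "genotypes.vcf", samples=samples)
    calls = pd.read_csv(Path(args.scan) / "calls.tsv", sep="\t", comment="#")
    if calls.empty:
        print("no calls to annotate; run analysis/02 first")
        return

    catalog = build_synthetic_catalog(calls, genotypes)
    print(f"synthetic catalog: {len(catalog)} records over {calls.shape[0]} calls")
    annotations = annotate_with_catalog(calls, genotypes, catalog,
                                        r2_min=0.8, p_max=0.05)
    annotations.to_csv(args.out, sep="\t", index=False)
    print(f"{len(annotations)} co-localizations at r2 > 0.8 and catalog p < 0.05:")
    print(annotations.to_string(index=False) if not annotations.empty else "  (none)")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
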