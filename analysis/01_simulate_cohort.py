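#!/usr/bin/env python
"""Simulate the study-style cohort and write it to results/cohort/.

174 males and 160 females, 400 cis SNPs and 40 expression features on one
10 Mb chromosome, three population PCs, unit gaussian noise.  Three
sex-by-genotype interactions are planted (one also visible in both sexes,
one female-specific, one weak) so the downstream scan has structure to find;
everything else is null.  The cohort is written as VCF + TSVs so the later
steps exercise the same file readers a real analysis would.
"""

import argparse

from sseqtl.io import save_cohort
from sseqtl.simulate import PlantedEffect, SimulationConfig, simulate_cohort

PLANTED = (
    PlantedEffect(feature=0, variant=0, beta1=0.3, beta3=1.0),   # shifted in both sexes
    PlantedEffect(feature=1, variant=40, beta3=1.2),             # female-specific slope
    PlantedEffect(feature=2, variant=80, beta3=0.35),            # likely below stage-1 power
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results/cohort")
    args = parser.parse_args()

    config = SimulationConfig(
        n_male=174, n_female=160,
        n_variants=400, n_features=40,
        maf_range=(0.25, 0.5),
        effects=PLANTED,
        seed=args.seed,
    )
    cohort = simulate_cohort(config)
    paths = save_cohort(cohort, args.out)

    print(f"cohort: {cohort.n_samples} samples "
          f"({(cohort.samples.sex == 0).sum()} M / {(cohort.samples.sex == 1).sum()} F), "
          f"{cohort.genotypes.n_variants} variants, "
          f"{len(cohort.expression.feature_ids)} features")
    print("planted interactions (feature, variant, beta3):")
    for row in cohort.truth.itertuples():
        if row.beta3 != 0:
            print(f"  {row.feature_id}  {row.variant_id}  beta3={row.beta3}")
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
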