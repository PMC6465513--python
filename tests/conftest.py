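import numpy as np
import pandas as pd
import pytest

from sseqtl.containers import ExpressionMatrix, GenotypeMatrix, SampleTable
from sseqtl.simulate import PlantedEffect, SimulationConfig, simulate_cohort


def make_genotypes(dosage, chrom="1", pos=None, is_x=False, samples=None):
    """Build a GenotypeMatrix from a raw dosage array (variants x samples)."""
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    n_var, n_samp = dosage.shape
    if pos is None:
        pos = np.arange(1, n_var + 1) * 1000
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n_samp)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "is_x": is_x,
        }
    )
    return GenotypeMatrix(variants=variants, dosage=dosage, samples=list(samples))


def make_samples(sex, pcs=None):
    sex = np.asarray(sex, dtype=int)
    data = {"sample_id": [f"S{i:03d}" for i in range(sex.size)], "sex": sex}
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        for k in range(pcs.shape[1]):
            data[f"PC{k + 1}"] = pcs[:, k]
    return SampleTable(pd.DataFrame(data))


def make_expression(values, feature_chrom="1", anchors=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_feat, n_samp = values.shape
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n_samp)]
    if anchors is None:
        anchors = np.arange(1, n_feat + 1) * 1000
    feature_ids = [f"f{i}" for i in range(n_feat)]
    features = pd.DataFrame(
        {"feature_id": feature_ids, "chrom": feature_chrom, "anchor": anchors, "strand": "+"}
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        features=features,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Small complete-null cohort (no genetic effects, gaussian noise)."""
    return simulate_cohort(
        SimulationConfig(n_male=60, n_female=60, n_variants=40, n_features=8, seed=11)
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one strong sex-by-genotype interaction planted."""
    return simulate_cohort(
        SimulationConfig(
            n_male=174,
            n_female=160,
            n_variants=120,
            n_features=12,
            maf_range=(0.2, 0.5),
            effects=(PlantedEffect(feature=0, variant=0, beta3=1.2),),
            seed=13,
        )
    )
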