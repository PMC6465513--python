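"""In-memory containers shared by every pipeline stage.

Dosages are stored as a dense float matrix (variants x samples) with NaN for
missing calls; alternate-allele counts 0/1/2 on autosomes, 0/2 for hemizygous
males on the X chromosome after encoding.  Sample order is the single source
of alignment: :class:`Cohort` validates that genotypes, sample metadata and
expression share one identically ordered sample list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_MALE = 0
SEX_FEMALE = 1

#: variant metadata columns required by :class:`GenotypeMatrix`
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "is_x")

#: feature annotation columns (anchor = TSS for genes, locus for miRNAs)
FEATURE_COLUMNS = ("feature_id", "chrom", "anchor", "strand")


class AlignmentError(ValueError):
    """Sample sets of two pipeline inputs do not match."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages with per-variant metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``variant_id, chrom, pos, ref, alt, is_x``
        (``pos`` 1-based).  One row per retained variant.
    dosage
        Float array of shape ``(n_variants, n_samples)``; NaN marks a
        missing call.
    samples
        Sample identifiers, one per dosage column.
    """

    variants: pd.DataFrame
    dosage: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        idx = self._index().get(variant_id)
        if idx is None:
            raise KeyError(f"unknown variant id: {variant_id}")
        return self.dosage[idx]

    def _index(self) -> dict[str, int]:
        cached = getattr(self, "_id_to_row", None)
        if cached is None or len(cached) != self.n_variants:
            cached = {v: i for i, v in enumerate(self.variants["variant_id"])}
            object.__setattr__(self, "_id_to_row", cached)
        return cached

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosage=self.dosage[mask],
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        absent = [s for s in sample_ids if s not in pos]
        if absent:
            raise AlignmentError(f"samples absent from genotypes: {absent}")
        cols = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            variants=self.variants.copy(),
            dosage=self.dosage[:, cols],
            samples=list(sample_ids),
        )


@dataclass
class SampleTable:
    """Sample metadata: sex coded 0 = male / 1 = female, plus population PCs."""

    table: pd.DataFrame  # columns: sample_id, sex, PC1..PCk

    def __post_init__(self) -> None:
        for col in ("sample_id", "sex"):
            if col not in self.table.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        bad = set(self.table["sex"].unique()) - {SEX_MALE, SEX_FEMALE}
        if bad:
            raise ValueError(f"sex column must be 0 (male) / 1 (female); got {bad}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy(dtype=int)

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("PC")]

    @property
    def pcs(self) -> np.ndarray:
        """Population-PC matrix of shape (n_samples, n_pcs); may have 0 columns."""
        cols = self.pc_columns
        if not cols:
            return np.empty((len(self.table), 0))
        return self.table[cols].to_numpy(dtype=float)

    def reorder(self, sample_ids: list[str]) -> "SampleTable":
        pos = {s: i for i, s in enumerate(self.table["sample_id"])}
        absent = [s for s in sample_ids if s not in pos]
        if absent:
            raise AlignmentError(f"samples absent from sample table: {absent}")
        return SampleTable(self.table.iloc[[pos[s] for s in sample_ids]])


@dataclass
class ExpressionMatrix:
    """Normalized expression values (features x samples) with genomic anchors.

    ``features`` carries the annotation used for cis-pairing: chromosome and
    a 1-based anchor position (gene TSS or miRNA locus).
    """

    values: pd.DataFrame  # index feature_id, columns sample ids
    features: pd.DataFrame  # feature_id, chrom, anchor, strand

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if (self.features["anchor"] < 1).any():
            raise ValueError("feature anchors must be 1-based positive positions")
        unannotated = set(self.values.index) - set(self.features["feature_id"])
        if unannotated:
            raise ValueError(f"features without annotation: {sorted(unannotated)[:5]}")
        self.features = self.features.reset_index(drop=True)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def reorder_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        absent = [s for s in sample_ids if s not in self.values.columns]
        if absent:
            raise AlignmentError(f"samples absent from expression: {absent}")
        return ExpressionMatrix(self.values[sample_ids], self.features.copy())


@dataclass
class Cohort:
    """Aligned genotype + sample + expression bundle for one analysis run."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    expression: ExpressionMatrix
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        ids = self.samples.sample_ids
        if self.genotypes.samples != ids or self.expression.samples != ids:
            raise AlignmentError(
                "genotypes, samples and expression must share one identically "
                "ordered sample list; use align() to intersect and reorder"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples.sample_ids)


def align(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    expression: ExpressionMatrix,
) -> Cohort:
    """Intersect the three sample sets and return an aligned :class:`Cohort`.

    The intersection preserves the sample-table order.  Raises
    :class:`AlignmentError` when the intersection is empty.
    """
    geno = set(genotypes.samples)
    expr = set(expression.samples)
    shared = [s for s in samples.sample_ids if s in geno and s in expr]
    if not shared:
        raise AlignmentError("no samples shared by genotypes, metadata and expression")
    return Cohort(
        genotypes=genotypes.subset_samples(shared),
        samples=samples.reorder(shared),
        expression=expression.reorder_samples(shared),
    )
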