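"""Reading, writing and filtering of genotypes, expression and annotation.

Conventions
-----------
* VCF and GFF3 coordinates are 1-based inclusive; BED is half-open 0-based
  and converted on read.
* Dosage = count of alternate alleles.  On the X chromosome males are
  hemizygous and recoded 0/2 (one allele counted twice, reflecting X
  inactivation in females); male heterozygous X calls are genotyping
  artifacts and are set missing with a logged count.
* Variant filters follow the study design: biallelic SNPs only, minor
  allele frequency >= 1% computed on the analysis samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sseqtl.containers import (
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleTable,
)

logger = logging.getLogger(__name__)

X_CHROM_NAMES = frozenset({"X", "chrX", "x", "chrx", "23"})

__all__ = [
    "FilterLog",
    "VcfParseError",
    "read_genotypes",
    "write_vcf",
    "compute_maf",
    "encode_x_dosage",
    "filter_by_maf",
    "enumerate_cis_pairs",
    "read_samples",
    "write_samples",
    "read_expression",
    "write_expression",
    "read_features",
    "write_features",
    "read_catalog",
    "save_cohort",
    "load_cohort",
]


class VcfParseError(ValueError):
    """VCF could not be parsed."""


@dataclass
class FilterLog:
    """Attrition counts from genotype reading and variant filtering."""

    n_records: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_male_het_x: int = 0
    n_maf_failed: int = 0
    n_all_missing: int = 0
    n_kept: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_multiallelic": self.n_multiallelic,
            "n_non_snp": self.n_non_snp,
            "n_male_het_x": self.n_male_het_x,
            "n_maf_failed": self.n_maf_failed,
            "n_all_missing": self.n_all_missing,
            "n_kept": self.n_kept,
        }


def encode_x_dosage(raw_alt_count: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Recode hemizygous male X genotypes 0/1 -> 0/2; females unchanged.

    ``raw_alt_count`` holds per-sample alternate-allele counts with males
    haploid (0 or 1) and females diploid (0, 1 or 2); NaN is missing.
    """
    raw = np.asarray(raw_alt_count, dtype=float)
    sex = np.asarray(sex)
    male = sex == 0
    bad = male & np.isfinite(raw) & ~np.isin(raw, (0.0, 1.0))
    if bad.any():
        raise ValueError("male raw X allele counts must be 0 or 1 (haploid)")
    out = raw.copy()
    out[male] = 2.0 * raw[male]
    return out


def read_genotypes(
    vcf_path: str | Path,
    samples: SampleTable | None = None,
    sample_subset: list[str] | None = None,
    x_chroms: frozenset[str] = X_CHROM_NAMES,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Read biallelic SNP dosages from a VCF.

    Multi-allelic and non-SNP records are dropped and counted.  When the file
    contains X-chromosome records a :class:`SampleTable` with sex codes is
    required so male dosages can be encoded 0/2 (male heterozygous diploid
    calls are set missing and counted as artifacts).

    Returns the genotype matrix (sample order = ``sample_subset`` if given,
    else the sample-table order, else the VCF order) and a :class:`FilterLog`.
    """
    from cyvcf2 import VCF

    path = str(vcf_path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare Exceptions
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    wanted = sample_subset if sample_subset is not None else (
        samples.sample_ids if samples is not None else vcf_samples
    )
    absent = [s for s in wanted if s not in set(vcf_samples)]
    if absent:
        raise ValueError(f"samples absent from VCF: {absent}")
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    cols = np.array([col_of[s] for s in wanted])

    sex = None
    if samples is not None:
        sex = samples.reorder(wanted).sex

    log = FilterLog()
    rows, meta = [], []
    try:
        for rec_no, v in enumerate(vcf, start=1):
            log.n_records += 1
            if len(v.ALT) != 1:
                log.n_multiallelic += 1
                continue
            if len(v.REF) != 1 or len(v.ALT[0]) != 1 or not v.ALT[0].isalpha():
                log.n_non_snp += 1
                continue
            is_x = v.CHROM in x_chroms
            raw = np.full(len(vcf_samples), np.nan)
            ploidy = np.ones(len(vcf_samples), dtype=int)
            for i, call in enumerate(v.genotypes):
                alleles = [a for a in call[:-1] if a is not None]
                ploidy[i] = len(alleles)
                if any(a < 0 for a in alleles) or not alleles:
                    continue
                raw[i] = float(sum(a == 1 for a in alleles))
            raw = raw[cols]
            ploidy = ploidy[cols]
            if is_x:
                if sex is None:
                    raise ValueError(
                        f"X-chromosome record {v.CHROM}:{v.POS} requires a sample "
                        "table with sex codes for dosage encoding"
                    )
                raw = _encode_x_record(raw, ploidy, sex, log)
            rows.append(raw)
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
            meta.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0], is_x))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path!r} near record {log.n_records + 1}: {exc}") from exc

    log.n_kept = len(rows)
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt", "is_x"]
    )
    dosage = np.vstack(rows) if rows else np.empty((0, len(wanted)))
    return GenotypeMatrix(variants=variants, dosage=dosage, samples=list(wanted)), log


def _encode_x_record(
    raw: np.ndarray, ploidy: np.ndarray, sex: np.ndarray, log: FilterLog
) -> np.ndarray:
    """Turn per-call alt counts into 0/2 male, 0/1/2 female dosages."""
    out = raw.copy()
    male = sex == 0
    # diploid-coded males: hom calls halve to a haploid count, het is artifact
    dip = male & (ploidy == 2) & np.isfinite(raw)
    het = dip & (raw == 1.0)
    if het.any():
        log.n_male_het_x += int(het.sum())
        out[het] = np.nan
    out[dip & (raw == 2.0)] = 1.0
    fin = male & np.isfinite(out)
    out[fin] = 2.0 * out[fin]
    return out


def compute_maf(
    dosages: np.ndarray,
    sex: np.ndarray | None = None,
    is_x: bool = False,
) -> float:
    """Folded minor-allele frequency of one variant's dosage vector.

    Autosomes: alt frequency = sum(dosage) / (2 * n_nonmissing), folded to
    <= 0.5.  X: males contribute one allele (dosage/2 after 0/2 encoding)
    and females two, so the allele total is n_male + 2 * n_female.
    """
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(d)
    if not ok.any():
        raise ValueError("MAF undefined: all dosages missing")
    if is_x:
        if sex is None:
            raise ValueError("X-chromosome MAF requires sex codes")
        sex = np.asarray(sex)
        male = ok & (sex == 0)
        female = ok & (sex == 1)
        alt = d[male].sum() / 2.0 + d[female].sum()
        total = male.sum() + 2 * female.sum()
    else:
        alt = d[ok].sum()
        total = 2 * ok.sum()
    freq = alt / total
    return float(min(freq, 1.0 - freq))


def filter_by_maf(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    maf_min: float = 0.01,
    log: FilterLog | None = None,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Drop variants below the MAF threshold (computed on analysis samples)."""
    log = log if log is not None else FilterLog()
    sex = samples.reorder(genotypes.samples).sex
    keep = np.zeros(genotypes.n_variants, dtype=bool)
    is_x = genotypes.variants["is_x"].to_numpy()
    for i in range(genotypes.n_variants):
        row = genotypes.dosage[i]
        if not np.isfinite(row).any():
            log.n_all_missing += 1
            continue
        maf = compute_maf(row, sex=sex, is_x=bool(is_x[i]))
        if maf >= maf_min:
            keep[i] = True
        else:
            log.n_maf_failed += 1
    out = genotypes.subset_variants(keep)
    log.n_kept = out.n_variants
    return out, log


def enumerate_cis_pairs(
    variants: pd.DataFrame,
    features: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All variant-feature pairs on the same chromosome within the cis window.

    The window is inclusive: |pos - anchor| <= window.  Raises when the two
    tables share no chromosome name (e.g. ``chr1`` vs ``1``) to avoid a
    silent zero-pair result.
    """
    if variants.empty or features.empty:
        raise ValueError("variant and feature tables must be non-empty")
    vchroms = set(variants["chrom"].astype(str))
    fchroms = set(features["chrom"].astype(str))
    if not vchroms & fchroms:
        norm = lambda s: {c.removeprefix("chr") for c in s}
        hint = (
            " (names differ only by a 'chr' prefix)"
            if norm(vchroms) & norm(fchroms)
            else ""
        )
        raise ValueError(
            f"no shared chromosome names between variants {sorted(vchroms)} "
            f"and features {sorted(fchroms)}{hint}"
        )
    vtab = variants[["variant_id", "chrom", "pos"]].assign(chrom=variants["chrom"].astype(str))
    ftab = features[["feature_id", "chrom", "anchor"]].assign(chrom=features["chrom"].astype(str))
    merged = vtab.merge(ftab, on="chrom")
    merged["distance"] = (merged["pos"] - merged["anchor"]).abs()
    pairs = (
        merged.loc[merged["distance"] <= window, ["variant_id", "feature_id", "distance"]]
        .sort_values(["feature_id", "variant_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    logger.info("cis pairing: %d pairs within +/-%d bp", len(pairs), window)
    return pairs


# ---------------------------------------------------------------------------
# tabular readers / writers


def read_samples(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", comment="#"))


def write_samples(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_expression(values_path: str | Path, features_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    values.index.name = None
    features = read_features(features_path)
    return ExpressionMatrix(values=values, features=features)


def write_expression(expr: ExpressionMatrix, values_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="feature_id")


def read_features(path: str | Path) -> pd.DataFrame:
    """Feature anchors from TSV, BED or GFF3.

    TSV needs columns ``feature_id, chrom, anchor, strand``.  For BED and
    GFF3 the anchor is the transcription start: the start coordinate on the
    + strand, the end coordinate on the - strand; unknown strand falls back
    to the start with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _features_from_gff3(path)
    if suffix == ".bed":
        return _features_from_bed(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"feature_id", "chrom", "anchor"}
    if not required <= set(df.columns):
        raise ValueError(f"feature TSV must have columns {sorted(required)}")
    if "strand" not in df.columns:
        df["strand"] = "unknown"
    return df[["feature_id", "chrom", "anchor", "strand"]]


def _features_from_bed(path: Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("BED feature file needs >= 4 columns (chrom start end name)")
    bed = bed.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "feature_id"})
    strand = bed[5] if bed.shape[1] > 5 else pd.Series("unknown", index=bed.index)
    return _anchored(bed["feature_id"], bed["chrom"], bed["start"] + 1, bed["end"], strand)


def _features_from_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    rows = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        fid = feat.attributes.get("ID", feat.attributes.get("Name", [None]))[0]
        if fid is None:
            raise ValueError(f"GFF3 record without ID/Name at {feat.seqid}:{feat.start}")
        rows.append((fid, feat.seqid, feat.start, feat.end, feat.strand or "unknown"))
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "strand"])
    return _anchored(df["feature_id"], df["chrom"], df["start"], df["end"], df["strand"])


def _anchored(fid, chrom, start, end, strand) -> pd.DataFrame:
    strand = strand.where(strand.isin(["+", "-"]), "unknown")
    if (strand == "unknown").any():
        logger.warning(
            "%d features with unknown strand: using start coordinate as anchor",
            int((strand == "unknown").sum()),
        )
    anchor = end.where(strand == "-", start)
    return pd.DataFrame(
        {"feature_id": fid, "chrom": chrom, "anchor": anchor, "strand": strand}
    ).reset_index(drop=True)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Trait-association catalog: columns snp_id, trait, p[, source]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "trait", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = ""
    if not ((df["p"] > 0) & (df["p"] <= 1)).all():
        raise ValueError("catalog p-values must lie in (0, 1]")
    return df[["snp_id", "trait", "p", "source"]]


# ---------------------------------------------------------------------------
# VCF writer (fixture factory for the synthetic generator)


def write_vcf(genotypes: GenotypeMatrix, samples: SampleTable, path: str | Path) -> None:
    """Write dosages as a plain-text VCF 4.2 with GT calls.

    Autosomal dosages map to 0/0, 0/1, 1/1; on the X chromosome males are
    written haploid (``0`` / ``1``).  Missing calls become ``./.`` (``.``
    for haploid males).
    """
    sex = samples.reorder(genotypes.samples).sex
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in pd.unique(genotypes.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples))
    dip_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    hap_gt = {0.0: "0", 2.0: "1"}
    order = genotypes.variants.sort_values(["chrom", "pos"], kind="mergesort").index
    for i in order:
        v = genotypes.variants.loc[i]
        row = genotypes.dosage[i]
        calls = []
        for j, d in enumerate(row):
            if v["is_x"] and sex[j] == 0:
                calls.append("." if not np.isfinite(d) else hap_gt[float(d)])
            else:
                calls.append("./." if not np.isfinite(d) else dip_gt[float(d)])
        lines.append(
            f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
            f"\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# whole-cohort round trip


def save_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as VCF + TSVs; returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "expression": out / "expression.tsv",
        "features": out / "features.tsv",
    }
    write_vcf(cohort.genotypes, cohort.samples, paths["genotypes"])
    write_samples(cohort.samples, paths["samples"])
    write_expression(cohort.expression, paths["expression"])
    cohort.expression.features.to_csv(paths["features"], sep="\t", index=False)
    if cohort.truth is not None:
        paths["truth"] = out / "truth.tsv"
        cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def load_cohort(in_dir: str | Path) -> tuple[Cohort, FilterLog]:
    """Read back a cohort written by :func:`save_cohort`."""
    d = Path(in_dir)
    samples = read_samples(d / "samples.tsv")
    genotypes, log = read_genotypes(d / "genotypes.vcf", samples=samples)
    expr = read_expression(d / "expression.tsv", d / "features.tsv")
    truth_path = d / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    cohort = Cohort(genotypes=genotypes, samples=samples, expression=expr, truth=truth)
    return cohort, log
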