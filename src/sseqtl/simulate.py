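"""Synthetic cohort generator matching the pipeline's assumed generative model.

Expression is generated directly on the normalized scale analysed by the
interaction model

    y = b0 + b1*SNP + b2*sex + b3*sex*SNP + sum_k bPCk*PCk + e

with genotype dosages drawn under Hardy-Weinberg equilibrium, sex coded
0 = male / 1 = female, and population PCs standard normal (optionally given
a sex-correlated component to let tests probe confounding).  The error term
is Gaussian or a Tukey gross-error mixture (a fraction of residuals drawn at
an inflated scale) so the robust second stage can be exercised against
heavy-tailed contamination.

Each feature is tied to exactly one causal variant (possibly with an all-zero
coefficient vector, i.e. a null pair); the generative coefficients of every
feature-variant pair are recorded in a truth table.  A single master seed
deterministically derives one substream per variant and per feature, so any
subset of the simulated data is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sseqtl.containers import (
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleTable,
)

__all__ = [
    "NoiseModel",
    "PlantedEffect",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_samples",
    "simulate_expression",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class NoiseModel:
    """Residual distribution: gaussian, or contaminated gaussian mixture.

    ``contaminated`` draws each residual from N(0, sigma^2) with probability
    ``1 - outlier_fraction`` and from N(0, (outlier_scale * sigma)^2)
    otherwise.
    """

    kind: str = "gaussian"  # "gaussian" | "contaminated"
    sigma: float = 1.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("gaussian", "contaminated"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be > 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ConfigurationError("outlier_fraction must lie in [0, 1)")
        if self.kind == "contaminated" and self.outlier_scale <= 0:
            raise ConfigurationError("outlier_scale must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        e = rng.normal(0.0, self.sigma, n)
        if self.kind == "contaminated" and self.outlier_fraction > 0:
            hit = rng.random(n) < self.outlier_fraction
            e[hit] = rng.normal(0.0, self.outlier_scale * self.sigma, int(hit.sum()))
        return e


@dataclass(frozen=True)
class PlantedEffect:
    """Generative coefficients for one feature / causal-variant pair."""

    feature: int  # feature index
    variant: int  # causal variant index
    beta0: float = 0.0
    beta1: float = 0.0  # genotype main effect
    beta2: float = 0.0  # sex main effect
    beta3: float = 0.0  # sex x genotype interaction
    beta_pc: tuple[float, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the study design the pipeline targets: 174 males and 160
    females, three population PCs, MAF >= 1%, unit-variance gaussian noise.
    """

    n_male: int = 174
    n_female: int = 160
    n_variants: int = 100
    n_features: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_pcs: int = 3
    chrom_type: str = "autosome"  # "autosome" | "X"
    chrom_length: int = 10_000_000
    effects: tuple[PlantedEffect, ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    pc_sex_corr: float = 0.0  # correlation of each PC with the sex indicator
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_male + self.n_female

    @property
    def chrom(self) -> str:
        return "X" if self.chrom_type == "X" else "1"

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must be a nonempty interval within (0, 0.5]; got {self.maf_range}"
            )
        if min(self.n_male, self.n_female, self.n_variants, self.n_features) < 1:
            raise ConfigurationError("all counts must be positive")
        if self.n_pcs < 0:
            raise ConfigurationError("n_pcs must be >= 0")
        if self.chrom_type not in ("autosome", "X"):
            raise ConfigurationError(f"unknown chrom_type {self.chrom_type!r}")
        if self.n_samples < 2 * self.n_pcs + 6:
            raise ConfigurationError(
                "n_male + n_female must be >= 2*n_pcs + 6 for residual df"
            )
        if not -1.0 < self.pc_sex_corr < 1.0:
            raise ConfigurationError("pc_sex_corr must lie in (-1, 1)")
        self.noise.validate()
        for eff in self.effects:
            if not 0 <= eff.feature < self.n_features:
                raise ConfigurationError(f"effect feature index {eff.feature} out of range")
            if not 0 <= eff.variant < self.n_variants:
                raise ConfigurationError(f"effect variant index {eff.variant} out of range")
            if len(eff.beta_pc) not in (0, self.n_pcs):
                raise ConfigurationError("beta_pc length must be 0 or n_pcs")
        if len({e.feature for e in self.effects}) != len(self.effects):
            raise ConfigurationError("at most one planted effect per feature")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _resolved_effects(config: SimulationConfig) -> list[PlantedEffect]:
    """One effect per feature: planted where specified, null otherwise.

    Unlisted features are paired with variant ``feature_index % n_variants``
    with all-zero coefficients, so the truth table has exactly one row per
    simulated feature-variant pair.
    """
    by_feature = {e.feature: e for e in config.effects}
    out = []
    for j in range(config.n_features):
        eff = by_feature.get(j, PlantedEffect(feature=j, variant=j % config.n_variants))
        if len(eff.beta_pc) == 0 and config.n_pcs:
            eff = replace(eff, beta_pc=(0.0,) * config.n_pcs)
        out.append(eff)
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE dosages for every variant.

    Autosomes: dosage ~ Binomial(2, p) for every sample.  X chromosome:
    males ~ Binomial(1, p) recoded 0/2 (hemizygous dosage convention),
    females ~ Binomial(2, p).  Allele frequency p is uniform on
    ``maf_range`` per variant; positions are uniform over the chromosome so
    cis-window pairing is nontrivial.
    """
    config.validate()
    n = config.n_samples
    is_x = config.chrom_type == "X"
    sex = _sex_vector(config)

    layout = _rng(config.seed, 3)
    pos = np.sort(layout.choice(config.chrom_length, size=config.n_variants, replace=False)) + 1

    dosage = np.empty((config.n_variants, n))
    freqs = np.empty(config.n_variants)
    lo, hi = config.maf_range
    for i in range(config.n_variants):
        rng = _rng(config.seed, 0, i)
        p = rng.uniform(lo, hi)
        freqs[i] = p
        if is_x:
            d = np.empty(n)
            male = sex == 0
            d[male] = 2.0 * rng.binomial(1, p, int(male.sum()))
            d[~male] = rng.binomial(2, p, int((~male).sum()))
            dosage[i] = d
        else:
            dosage[i] = rng.binomial(2, p, n)

    variants = pd.DataFrame(
        {
            "variant_id": [f"var{i:05d}" for i in range(config.n_variants)],
            "chrom": config.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "is_x": is_x,
            "true_af": freqs,
        }
    )
    return GenotypeMatrix(variants=variants, dosage=dosage, samples=_sample_ids(config))


def _sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(config.n_samples)]


def _sex_vector(config: SimulationConfig) -> np.ndarray:
    # males first, then females; sample order is shared by all components
    return np.concatenate(
        [np.zeros(config.n_male, dtype=int), np.ones(config.n_female, dtype=int)]
    )


def simulate_samples(config: SimulationConfig) -> SampleTable:
    """Sample metadata: sex 0/1 and ``n_pcs`` standard-normal PCs.

    With ``pc_sex_corr`` nonzero each PC is a mixture
    ``c * z_sex + sqrt(1 - c^2) * N(0,1)`` where ``z_sex`` is the
    standardized sex indicator, giving corr(PC, sex) = c.
    """
    config.validate()
    sex = _sex_vector(config)
    rng = _rng(config.seed, 1)
    data = {"sample_id": _sample_ids(config), "sex": sex}
    if config.n_pcs:
        z = rng.normal(size=(config.n_samples, config.n_pcs))
        c = config.pc_sex_corr
        if c != 0.0:
            zsex = (sex - sex.mean()) / sex.std()
            z = c * zsex[:, None] + np.sqrt(1 - c * c) * z
        for k in range(config.n_pcs):
            data[f"PC{k + 1}"] = z[:, k]
    return SampleTable(pd.DataFrame(data))


def simulate_expression(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate expression from the interaction model; return values + truth.

    Every feature's value vector is ``b0 + b1*g + b2*sex + b3*sex*g +
    PCs @ beta_pc + e`` for its causal variant's dosage ``g``.  Each
    feature's anchor (its TSS stand-in) is placed uniformly within +/-500 kb
    of its causal variant, so the truth pair is always cis while the rest of
    the cis pairing stays nontrivial.
    """
    config.validate()
    if genotypes.samples != samples.sample_ids:
        raise ValueError("genotype and sample tables are not aligned")
    sex = samples.sex.astype(float)
    pcs = samples.pcs
    effects = _resolved_effects(config)

    anchors_rng = _rng(config.seed, 4)
    causal_pos = genotypes.variants["pos"].to_numpy()[[e.variant for e in effects]]
    offsets = anchors_rng.integers(-500_000, 500_001, size=config.n_features)
    anchors = np.clip(causal_pos + offsets, 1, config.chrom_length)

    values = np.empty((config.n_features, config.n_samples))
    truth_rows = []
    for eff in effects:
        g = genotypes.dosage[eff.variant]
        rng = _rng(config.seed, 2, eff.feature)
        e = config.noise.draw(rng, config.n_samples)
        y = eff.beta0 + eff.beta1 * g + eff.beta2 * sex + eff.beta3 * sex * g + e
        if config.n_pcs:
            y = y + pcs @ np.asarray(eff.beta_pc)
        values[eff.feature] = y
        row = {
            "feature_id": f"feat{eff.feature:05d}",
            "variant_id": genotypes.variants["variant_id"].iloc[eff.variant],
            "beta0": eff.beta0,
            "beta1": eff.beta1,
            "beta2": eff.beta2,
            "beta3": eff.beta3,
        }
        for k in range(config.n_pcs):
            row[f"beta_PC{k + 1}"] = eff.beta_pc[k]
        truth_rows.append(row)

    feature_ids = [f"feat{j:05d}" for j in range(config.n_features)]
    features = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "chrom": config.chrom,
            "anchor": anchors,
            "strand": "+",
        }
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples.sample_ids),
        features=features,
    )
    return expr, pd.DataFrame(truth_rows)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full synthetic cohort: genotypes, sample metadata, expression, truth."""
    genotypes = simulate_genotypes(config)
    samples = simulate_samples(config)
    expression, truth = simulate_expression(genotypes, samples, config)
    return Cohort(genotypes=genotypes, samples=samples, expression=expression, truth=truth)
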