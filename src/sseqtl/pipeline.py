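"""End-to-end orchestration: load or simulate, pair, scan, validate, annotate.

``run_pipeline`` drives the full two-stage analysis and writes deterministic
tabular outputs plus a machine-readable manifest:

* ``stage1_results.tsv``  — per-pair interaction fits and the BH screen flag
* ``stage2_strata.tsv``   — per-candidate per-sex robust fits and Wald p's
* ``calls.tsv``           — final ss-eQTL calls (OR rule over strata)
* ``annotations.tsv``     — LD/trait-catalog co-localizations (if a catalog
  is supplied)
* ``screens.json``        — both FDR screens with their equivalent p-value
  thresholds
* ``attrition.tsv``       — variant/pair counts surviving each filter
* ``manifest.json``       — config, seed, package/library versions, config
  hash

Every TSV carries a header comment naming the pipeline version and config
hash so a results directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import sseqtl
from sseqtl import io as sio
from sseqtl.containers import Cohort, align
from sseqtl.ld import annotate_with_catalog
from sseqtl.simulate import NoiseModel, PlantedEffect, SimulationConfig, simulate_cohort
from sseqtl.stage1 import run_stage1
from sseqtl.stage2 import run_stage2

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either the four input paths (``vcf``, ``samples``, ``expression``,
    ``features``) or a ``simulate`` spec must be provided.  Thresholds
    default to the study design: +/-1 Mb cis window, MAF >= 1%, FDR 0.05 at
    both stages, >= 5 samples per genotype-by-sex block.
    """

    vcf: str | None = None
    samples: str | None = None
    expression: str | None = None
    features: str | None = None
    catalog: str | None = None
    simulate: dict | None = None
    window: int = 1_000_000
    maf_min: float = 0.01
    q_stage1: float = 0.05
    q_stage2: float = 0.05
    min_block: int = 5
    stage2_pool: str = "pooled"
    r2_min: float = 0.8
    catalog_p_max: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, val in (("q_stage1", self.q_stage1), ("q_stage2", self.q_stage2),
                          ("maf_min", self.maf_min), ("catalog_p_max", self.catalog_p_max)):
            if not 0 < val < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {val}")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_block < 1:
            raise ValueError("min_block must be >= 1")
        has_files = all(x is not None for x in (self.vcf, self.samples, self.expression, self.features))
        if not has_files and self.simulate is None:
            raise ValueError("provide input paths or a simulate spec")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are kept under ``extra``."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)} - {"extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Fingerprint of the analytic configuration (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _simulation_config(spec: dict, seed: int) -> SimulationConfig:
    spec = dict(spec)
    noise = spec.pop("noise", None)
    effects = spec.pop("effects", ())
    kwargs = dict(spec)
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    if noise is not None:
        kwargs["noise"] = NoiseModel(**noise)
    kwargs["effects"] = tuple(
        PlantedEffect(**{**e, "beta_pc": tuple(e.get("beta_pc", ()))}) for e in effects
    )
    kwargs.setdefault("seed", seed)
    return SimulationConfig(**kwargs)


def _load_inputs(config: PipelineConfig) -> tuple[Cohort, sio.FilterLog]:
    if config.simulate is not None:
        sim = _simulation_config(config.simulate, config.seed)
        cohort = simulate_cohort(sim)
        return cohort, sio.FilterLog(n_records=cohort.genotypes.n_variants,
                                     n_kept=cohort.genotypes.n_variants)
    samples = sio.read_samples(config.samples)
    genotypes, log = sio.read_genotypes(config.vcf, samples=samples)
    features = sio.read_features(config.features)
    values = pd.read_csv(config.expression, sep="\t", index_col=0, comment="#")
    values.index.name = None
    expr = sio.ExpressionMatrix(values=values, features=features)
    return align(genotypes, samples, expr), log


def _write_tsv(df: pd.DataFrame, path: Path, version: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sseqtl {version} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-stage analysis; returns a run report dict.

    The report holds the output paths, the two FDR screens (with equivalent
    p-value thresholds), the attrition table and headline counts.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    version = sseqtl.__version__
    attrition: list[dict] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    cohort, read_log = _stage("load", _load_inputs, config)
    attrition.append({"step": "read", **read_log.as_dict()})

    def _maf(cohort):
        geno, log = sio.filter_by_maf(cohort.genotypes, cohort.samples, config.maf_min)
        return Cohort(genotypes=geno, samples=cohort.samples,
                      expression=cohort.expression, truth=cohort.truth), log

    cohort, maf_log = _stage("maf_filter", _maf, cohort)
    attrition.append({"step": "maf_filter", **maf_log.as_dict()})

    pairs = _stage(
        "cis_pairing", sio.enumerate_cis_pairs,
        cohort.genotypes.variants, cohort.expression.features, config.window,
    )
    attrition.append({"step": "cis_pairing", "n_kept": len(pairs)})

    stage1, screen1 = _stage("stage1", run_stage1, cohort, pairs, q=config.q_stage1)
    candidates = stage1.loc[stage1["stage1_rejected"], ["variant_id", "feature_id"]]
    attrition.append({
        "step": "stage1",
        "n_records": len(stage1),
        "n_untestable": int((stage1["status"] != "ok").sum()),
        "n_kept": len(candidates),
    })

    strata, calls, screen2 = _stage(
        "stage2", run_stage2, candidates, cohort,
        q=config.q_stage2, min_count=config.min_block, pool=config.stage2_pool,
    )
    n_qc_failed = 0 if strata.empty else int(
        strata.loc[~strata["qc_pass"], ["variant_id", "feature_id"]]
        .drop_duplicates().shape[0]
    )
    attrition.append({
        "step": "stage2",
        "n_records": len(candidates),
        "n_qc_failed": n_qc_failed,
        "n_kept": len(calls),
    })

    annotations = pd.DataFrame()
    if config.catalog is not None:
        catalog = _stage("annotation", sio.read_catalog, config.catalog)
        annotations = _stage(
            "annotation", annotate_with_catalog, calls, cohort.genotypes, catalog,
            config.r2_min, config.catalog_p_max, config.window,
        )

    paths = {
        "stage1_results": out / "stage1_results.tsv",
        "stage2_strata": out / "stage2_strata.tsv",
        "calls": out / "calls.tsv",
        "attrition": out / "attrition.tsv",
        "screens": out / "screens.json",
        "manifest": out / "manifest.json",
    }
    _write_tsv(stage1, paths["stage1_results"], version, cfg_hash)
    _write_tsv(strata if not strata.empty else pd.DataFrame(columns=["variant_id"]),
               paths["stage2_strata"], version, cfg_hash)
    _write_tsv(calls, paths["calls"], version, cfg_hash)
    _write_tsv(pd.DataFrame(attrition), paths["attrition"], version, cfg_hash)
    if config.catalog is not None:
        paths["annotations"] = out / "annotations.tsv"
        _write_tsv(annotations, paths["annotations"], version, cfg_hash)

    def _screen_dict(s):
        if s is None:
            return None
        return {"q": s.q, "m": s.m, "n_rejected": s.n_rejected,
                "p_threshold": None if not np.isfinite(s.p_threshold) else s.p_threshold,
                "n_excluded": s.n_excluded}

    screens = {"stage1": _screen_dict(screen1), "stage2": _screen_dict(screen2)}
    paths["screens"].write_text(json.dumps(screens, indent=2))

    manifest = {
        "package": "sseqtl",
        "version": version,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_calls": len(calls),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))

    logger.info(
        "pipeline done: %d pairs, %d stage-1 candidates, %d calls",
        len(pairs), len(candidates), len(calls),
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "screens": screens,
        "attrition": attrition,
        "n_pairs": len(pairs),
        "n_candidates": len(candidates),
        "n_calls": len(calls),
        "calls": calls,
        "annotations": annotations,
    }
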