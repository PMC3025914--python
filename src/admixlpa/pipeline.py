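"""End-to-end pipeline driver.

A single declarative YAML config runs: simulate -> QC -> global and
local ancestry -> cases-only admixture scan -> SNP association ->
variance partitioning -> Cox power -> (optional) TF-occupancy scan,
writing a machine-readable JSON report plus per-stage TSVs.  One
global seed fans out to per-stage derived seeds so any stage can be
re-run in isolation and the whole run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import estimate_global_ancestry, local_ancestry_posteriors
from .association import adjust_trait, ancestry_effect, snp_association
from .cohort import (
    CohortConfig,
    TraitModel,
    percent_to_beta,
    sample_unrelated,
    simulate_cohort,
)
from .panel import simulate_aim_panel
from .partition import cv_variance_explained, pi_statistic
from .power import PowerConfig, simulate_power
from .scan import cases_only_lod, credible_interval, define_case_control
from . import io as aio

log = logging.getLogger("admixlpa")

__all__ = ["PipelineConfig", "run_pipeline"]


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from the global seed."""
    import zlib

    mix = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(mix.generate_state(1, dtype=np.uint32)[0] % 2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    # simulation block (the pipeline is self-contained by default)
    n_individuals: int = 2000
    n_chrom: int = 10
    markers_per_chrom: int = 60
    mean_african: float = 0.83
    generations: float = 6.0
    trait_snp: str = "aim6_30"
    trait_snp_effect_pct: float = 25.4
    global_ancestry_effect_pct_per_10: float = 9.9
    residual_sd: float = 0.8
    # analysis blocks
    case_quantile: float = 0.2
    n_unrelated_groups: int = 5
    power: Optional[dict] = field(
        default_factory=lambda: {
            "n": 3225, "n_events": 389, "allele_freq": 0.19,
            "hr_mean": 1.067, "hr_cv": 0.01, "alpha": 0.05, "n_iter": 200,
        }
    )
    phenotype_path: Optional[str] = None  # external phenotypes instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.phenotype_path is not None and not Path(cfg.phenotype_path).exists():
            raise FileNotFoundError(f"phenotype file not found: {cfg.phenotype_path}")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
    }

    log.info("stage simulate: n=%d", config.n_individuals)
    panel = simulate_aim_panel(
        n_chrom=config.n_chrom,
        markers_per_chrom=config.markers_per_chrom,
        seed=_stage_seed(config.seed, "panel"),
    )
    tm = TraitModel(
        global_ancestry_effect=percent_to_beta(config.global_ancestry_effect_pct_per_10) / 0.10,
        snp_effects={config.trait_snp: percent_to_beta(config.trait_snp_effect_pct)},
        residual_sd=config.residual_sd,
    )
    cc = CohortConfig(
        n_individuals=config.n_individuals,
        mean_african=config.mean_african,
        generations=config.generations,
        family_sizes=(0.7, 0.2, 0.1),
        seed=_stage_seed(config.seed, "cohort"),
    )
    cohort = simulate_cohort(cc, panel, tm)
    aio.write_genotypes_tsv(cohort, out / "genotypes.tsv")
    aio.write_phenotypes(cohort, out / "phenotypes.tsv")
    panel.to_tsv(out / "panel.tsv")
    report["simulate"] = {
        "n_individuals": int(cohort.n_individuals),
        "n_markers": int(panel.n_markers),
        "mean_theta_true": float(cohort.theta_true.mean()),
    }

    log.info("stage ancestry")
    theta_hat, _flat = estimate_global_ancestry(cohort.genotypes, panel)
    post = local_ancestry_posteriors(cohort.genotypes, panel, theta_hat)
    pd.DataFrame(
        {"sample_id": cohort.sample_id, "theta_hat": theta_hat}
    ).to_csv(out / "global_ancestry.tsv", sep="\t", index=False)
    report["ancestry"] = {
        "mean_theta_hat": float(theta_hat.mean()),
        "rmse_theta": float(np.sqrt(np.mean((theta_hat - cohort.theta_true) ** 2))),
    }

    log.info("stage scan")
    design = define_case_control(cohort.trait, cohort.sex, config.case_quantile)
    scan = cases_only_lod(post, design)
    scan.to_frame().to_csv(out / "scan.tsv", sep="\t", index=False)
    peak_chrom = scan.chrom[scan.max_locus]
    ci = credible_interval(scan, peak_chrom)
    aio.write_credible_bed({peak_chrom: ci}, out / "credible.bed")
    report["scan"] = {
        "max_lod": float(scan.max_lod),
        "peak_chrom": str(peak_chrom),
        "peak_marker": str(scan.chrom[scan.max_locus]) + ":" + str(int(scan.pos_bp[scan.max_locus])),
        "credible_interval_bp": [int(ci[0]), int(ci[1])],
        "significant": bool(scan.max_lod > 5.0),
    }

    log.info("stage association")
    resid = adjust_trait(cohort.trait, cohort.sex)
    glob = ancestry_effect(resid, theta_hat)
    j = panel.index_of(config.trait_snp)
    local = post.mean_dosage()[:, j]
    loc = ancestry_effect(resid, local / 2.0)
    snp = snp_association(resid, cohort.genotype_of(config.trait_snp), theta_hat, local)
    report["association"] = {
        "global_pct_per_10pct": glob.effect_percent,
        "local_pct_per_10pct": loc.effect_percent,
        "snp_pct_per_allele": snp.effect_percent,
        "snp_p": snp.p,
    }

    log.info("stage partition")
    groups = sample_unrelated(
        cohort, n_groups=config.n_unrelated_groups, seed=_stage_seed(config.seed, "groups")
    )
    pi = pi_statistic(resid, local, cohort.genotype_of(config.trait_snp))
    cv = cv_variance_explained(
        resid,
        pd.DataFrame({config.trait_snp: cohort.genotype_of(config.trait_snp)}),
        groups,
        candidate_snps=[config.trait_snp],
        scheme="two_fold",
        seed=_stage_seed(config.seed, "cv"),
    )
    report["partition"] = {
        "pi": pi.pi,
        "r2_base": pi.r2_base,
        "cv_variance_pct_mean": cv.mean,
        "cv_variance_pct_sd": cv.sd,
    }

    if config.power is not None:
        log.info("stage power")
        pres = simulate_power(
            PowerConfig(seed=_stage_seed(config.seed, "power"), **config.power)
        )
        report["power"] = {"power": pres.power, "mc_se": pres.mc_se}

    def _clean(x):
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        if isinstance(x, float) and not np.isfinite(x):
            return None  # keep the report strict JSON
        return x

    report = _clean(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
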