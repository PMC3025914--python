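#!/usr/bin/env python
"""Simulate the demonstration admixed cohort used by the later steps.

Generates 4464 individuals on a 10-chromosome panel of 600
ancestry-informative markers with the study conditions baked into the
generator defaults: mean African ancestry 0.83 (sd 0.09), a log-normal
trait whose African-ancestry association is carried almost entirely by
a cluster of three frequency-differentiated SNPs at one locus (25.4%
per allele each, the lead SNP "aim6_30"), plus a small residual direct
global-ancestry term.  Writes genotypes (VCF + TSV), phenotypes and
the panel under scratch/cohort/ (bulky raw data; later steps read it
from there and publish only small summary tables under results/).
"""

from pathlib import Path

import numpy as np

from admixlpa import (
    CohortConfig,
    TraitModel,
    percent_to_beta,
    simulate_cohort,
    simulate_aim_panel,
)
from admixlpa import io as aio

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 20110124
LOCUS_SNPS = ("aim6_29", "aim6_30", "aim6_31")
TRAIT_SNP = "aim6_30"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = simulate_aim_panel(n_chrom=10, markers_per_chrom=60, seed=SEED)
    # count the African-enriched allele at every locus SNP
    for snp in LOCUS_SNPS:
        j = panel.index_of(snp)
        if panel.f_afr[j] < panel.f_eur[j]:
            panel.f_afr[j], panel.f_eur[j] = panel.f_eur[j], panel.f_afr[j]
    tm = TraitModel(
        global_ancestry_effect=percent_to_beta(2.0) / 0.10,
        snp_effects={s: percent_to_beta(25.4) for s in LOCUS_SNPS},
        residual_sd=0.8,
    )
    cfg = CohortConfig(
        n_individuals=4464, family_sizes=(0.7, 0.2, 0.1), seed=SEED
    )
    cohort = simulate_cohort(cfg, panel, tm)

    aio.write_genotypes_vcf(cohort, OUT / "genotypes.vcf")
    aio.write_genotypes_tsv(cohort, OUT / "genotypes.tsv")
    aio.write_phenotypes(cohort, OUT / "phenotypes.tsv")
    panel.to_tsv(OUT / "panel.tsv")
    np.savetxt(OUT / "theta_true.tsv", cohort.theta_true, fmt="%.6f")

    print(f"cohort: n={cohort.n_individuals}, markers={panel.n_markers}")
    print(f"mean true African ancestry: {cohort.theta_true.mean():.3f}"
          f" (sd {cohort.theta_true.std():.3f})")
    for snp in LOCUS_SNPS:
        j = panel.index_of(snp)
        print(f"locus SNP {snp}: f_afr={panel.f_afr[j]:.2f}, f_eur={panel.f_eur[j]:.2f}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
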