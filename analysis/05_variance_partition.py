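#!/usr/bin/env python
"""How much of the ancestry-trait association do the locus SNPs explain?

Computes the mediation statistic pi = 1 - R2_geno/R2 at the trait
locus, then cross-validates: two-fold CV for the single-SNP percent of
trait variance explained, and five-fold CV (discovery / model-building
/ held-out evaluation over resampled unrelated groups) for the percent
of the local-ancestry association mediated by genotype.  Writes a JSON
summary under results/partition/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from admixlpa import (
    adjust_trait,
    cv_ancestry_explained,
    cv_variance_explained,
    pi_statistic,
)
from admixlpa import io as aio

BASE = Path(__file__).resolve().parent.parent / "scratch"
OUT = Path(__file__).resolve().parent.parent / "results" / "partition"
TRAIT_SNP = "aim6_30"
LOCUS_SNPS = ["aim6_29", "aim6_30", "aim6_31"]
SEED = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = aio.read_genotypes_tsv(BASE / "cohort" / "genotypes.tsv")
    pheno = aio.read_phenotypes(BASE / "cohort" / "phenotypes.tsv")
    dose = pd.read_csv(BASE / "ancestry" / "local_dosage.tsv", sep="\t", index_col=0)

    resid = adjust_trait(pheno["trait"].to_numpy(), pheno["sex"].to_numpy(dtype=object))
    local = dose[TRAIT_SNP].to_numpy()
    geno = g[[TRAIT_SNP]]

    pi = pi_statistic(resid, local, geno)  # lead SNP alone
    print(f"R2(ancestry) {pi.r2_base:.4f} -> after genotype adjustment "
          f"{pi.r2_geno:.4f}; pi = {pi.pi:.2f}")

    # one unrelated member per family, resampled
    rng = np.random.default_rng(SEED)
    fam = pheno["family_id"].to_numpy()
    groups = []
    for k in range(10):
        pick = (
            pd.Series(np.arange(len(fam)))
            .groupby(fam)
            .apply(lambda s: s.sample(1, random_state=int(rng.integers(2**31))).iloc[0])
        )
        groups.append(np.sort(pick.to_numpy()))

    cv_var = cv_variance_explained(
        resid, geno, groups, candidate_snps=[TRAIT_SNP], scheme="two_fold", seed=SEED
    )
    cv_anc = cv_ancestry_explained(
        resid, g[LOCUS_SNPS], local, groups, candidate_snps=LOCUS_SNPS, seed=SEED
    )
    print(f"single-SNP variance explained (two-fold CV): "
          f"{cv_var.mean:.1f}±{cv_var.sd:.1f}%")
    print(f"ancestry association explained (five-fold CV): "
          f"{cv_anc.mean:.0f}±{cv_anc.sd:.0f}%")

    with open(OUT / "partition.json", "w") as fh:
        json.dump(
            {
                "pi": pi.pi, "r2_base": pi.r2_base, "r2_geno": pi.r2_geno,
                "cv_variance_pct": {"mean": cv_var.mean, "sd": cv_var.sd},
                "cv_ancestry_pct": {"mean": cv_anc.mean, "sd": cv_anc.sd},
            },
            fh, indent=2,
        )
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
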