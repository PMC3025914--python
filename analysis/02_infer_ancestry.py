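#!/usr/bin/env python
"""Estimate global and local ancestry for the simulated cohort.

Reads scratch/cohort/, runs the grid maximum-likelihood global
estimate and the diploid forward-backward HMM, reports accuracy
against the generator's ground truth, and writes theta-hat plus the
posterior-mean local African dosage under scratch/ancestry/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from admixlpa import estimate_global_ancestry, local_ancestry_posteriors
from admixlpa.panel import MarkerPanel
from admixlpa import io as aio

BASE = Path(__file__).resolve().parent.parent / "scratch"
OUT = BASE / "ancestry"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = MarkerPanel.from_tsv(BASE / "cohort" / "panel.tsv")
    g = aio.read_genotypes_tsv(BASE / "cohort" / "genotypes.tsv")
    geno = np.where(np.isnan(g.to_numpy()), -1, g.to_numpy()).astype(np.int8)
    theta_true = np.loadtxt(BASE / "cohort" / "theta_true.tsv")

    theta, flat = estimate_global_ancestry(geno, panel)
    post = local_ancestry_posteriors(geno, panel, theta)

    pd.DataFrame({"sample_id": g.index, "theta_hat": theta, "flat": flat}).to_csv(
        OUT / "global_ancestry.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        post.mean_dosage(), index=g.index, columns=panel.marker_id
    ).to_csv(OUT / "local_dosage.tsv", sep="\t", index_label="sample_id")

    rmse = float(np.sqrt(np.mean((theta - theta_true) ** 2)))
    print(f"global ancestry: mean theta-hat {theta.mean():.3f}, RMSE vs truth {rmse:.3f}")
    print(f"genome-wide posterior dosage/2 vs theta-hat: "
          f"mean |diff| {np.abs(post.mean_dosage().mean(1)/2 - theta).mean():.4f}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
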