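"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (diploid GT fields, one sample column per
individual; read through pysam) or as a plain TSV dosage matrix;
phenotypes, panels and posteriors as TSV.  Coordinates are 1-based
inclusive everywhere except BED output (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort
from .panel import MarkerPanel

__all__ = [
    "read_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_credible_bed",
]


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read additive dosages from a VCF.

    Returns ``(genotypes, meta)``: a samples x markers DataFrame with
    NaN for missing calls, and per-marker metadata (chrom, pos, id,
    ref, alt).  Multi-allelic records are rejected.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, meta = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"{path}: record {rec.id or rec.pos} is not biallelic; "
                "split multi-allelic sites first"
            )
        doses = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                doses.append(np.nan)
            else:
                doses.append(float(sum(gt)))
        rows.append(doses)
        meta.append(
            {
                "marker_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos_bp": rec.pos,  # pysam reports 1-based position
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
        )
    meta_df = pd.DataFrame(meta)
    g = pd.DataFrame(
        np.array(rows).T, index=samples, columns=meta_df["marker_id"].tolist()
    )
    return g, meta_df


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Samples x markers dosage matrix; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~(df.isna() | df.isin([0, 1, 2]))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: invalid dosage at sample {df.index[r]!r}, marker {df.columns[c]!r}"
        )
    return df.astype(float)


def write_genotypes_tsv(cohort: Cohort, path) -> None:
    g = cohort.genotypes.astype(float)
    g[g == MISSING] = np.nan
    pd.DataFrame(
        g, index=cohort.sample_id, columns=cohort.panel.marker_id
    ).to_csv(path, sep="\t", index_label="sample_id", float_format="%.0f")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(cohort: Cohort, path) -> None:
    """Minimal VCF 4.2 with GT fields (alleles coded A=ref, B=alt)."""
    panel = cohort.panel
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_id)
            + "\n"
        )
        for j in range(panel.n_markers):
            gts = "\t".join(_GT[int(g)] for g in cohort.genotypes[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos_bp[j]}\t{panel.marker_id[j]}"
                f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phenotypes(cohort: Cohort, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": cohort.sample_id,
            "sex": cohort.sex,
            "family_id": cohort.family_id,
            "trait": cohort.trait,
        }
    )
    if cohort.survival_time is not None:
        df["time"] = cohort.survival_time
        df["event"] = cohort.event_flag.astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"phenotype file not found: {p}")
    return pd.read_csv(p, sep="\t")


def write_credible_bed(intervals: dict, path) -> None:
    """BED (0-based half-open) of per-chromosome credible intervals."""
    with open(path, "w") as fh:
        for chrom, (lo, hi) in intervals.items():
            fh.write(f"{chrom}\t{lo - 1}\t{hi}\tcredible_interval\n")
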