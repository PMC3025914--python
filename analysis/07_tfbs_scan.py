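#!/usr/bin/env python
"""Allele-aware occupancy scan of synthetic SNP flanks.

Builds a small synthetic motif library (GATA-, Forkhead- and YY1-like
frequency matrices written in JASPAR pfm format) and synthetic 41-base
allele flank pairs, one of which places a motif across the variant so
the alternate allele disrupts it.  Scans every SNP x motif pair with
the binding-isotherm occupancy model (thresholds p>0.20, delta>0.20),
applies a liver-expression style allow-list, and writes the hit table
under results/tfbs/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from admixlpa import filter_by_tf_allowlist, read_pwm_file, read_snp_contexts_fasta, scan_snp

OUT = Path(__file__).resolve().parent.parent / "results" / "tfbs"

# synthetic motifs: consensus and per-position count of the consensus base
MOTIFS = {
    ("SYN0001", "GATA1"): ("AGATAA", [90, 88, 88, 92, 85, 80]),
    ("SYN0002", "FOXA2"): ("TGTTTA", [85, 80, 82, 78, 75, 70]),
    ("SYN0003", "YY1"): ("CCATNT", [70, 75, 80, 60, 25, 65]),
}


def _write_jaspar(path: Path) -> None:
    """Emit synthetic JASPAR pfm count matrices."""
    lines = []
    rng = np.random.default_rng(7)
    for (mid, tf), (consensus, strong) in MOTIFS.items():
        counts = {b: [] for b in "ACGT"}
        for j, base in enumerate(consensus):
            rest = [b for b in "ACGT" if b != base]
            spread = rng.multinomial(100 - strong[j], [1 / 3] * 3)
            if base == "N":
                for b in "ACGT":
                    counts[b].append(25)
                continue
            counts[base].append(strong[j])
            for b, c in zip(rest, spread):
                counts[b].append(int(c))
        lines.append(f">{mid} {tf}")
        for b in "ACGT":
            lines.append(f"{b} [ " + " ".join(f"{c:3d}" for c in counts[b]) + " ]")
    path.write_text("\n".join(lines) + "\n")


def _write_contexts(path: Path) -> None:
    """Synthetic flank pairs; rs_hit embeds AGATAA across the center."""
    rng = np.random.default_rng(8)
    bg = lambda k: "".join(rng.choice(list("ACGT"), k))
    records = []
    # GATA consensus AGATAA spans positions 16-21; the SNP at 20 is its
    # fifth base (ref A); the alternate C destroys the match
    left = bg(16) + "AGAT"
    right = "A" + bg(19)
    records += [f">rs_hit|ref|A\n{left}A{right}", f">rs_hit|alt|C\n{left}C{right}"]
    l2, r2 = bg(20), bg(20)
    records += [f">rs_null|ref|G\n{l2}G{r2}", f">rs_null|alt|T\n{l2}T{r2}"]
    path.write_text("\n".join(records) + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pwm_path = OUT / "synthetic_motifs.jaspar"
    ctx_path = OUT / "synthetic_contexts.fa"
    _write_jaspar(pwm_path)
    _write_contexts(ctx_path)

    pwms = read_pwm_file(pwm_path, "jaspar")
    contexts = read_snp_contexts_fasta(ctx_path)
    hits = []
    for ctx in contexts:
        for pwm in pwms:
            h = scan_snp(pwm, ctx, p_min=0.20, delta_min=0.20)
            if h:
                hits.append(h)
    liver_tfs = {"GATA1", "FOXA2", "YY1"}
    hits = filter_by_tf_allowlist(hits, liver_tfs)

    df = pd.DataFrame([vars(h) for h in hits])
    df.to_csv(OUT / "hits.tsv", sep="\t", index=False)
    print(f"scanned {len(contexts)} SNPs x {len(pwms)} motifs -> {len(hits)} hits")
    if not df.empty:
        print(df.to_string(index=False))
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
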