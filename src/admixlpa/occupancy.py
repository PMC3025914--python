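"""Allele-aware transcription-factor occupancy scanning.

Binding of a factor X to a candidate site is modeled with the simple
binding isotherm ``p = [X] / ([X] + Kd)``.  The sequence-dependent
dissociation constant comes from a position-frequency-matrix energy:
a window's score is ``s = sum_j ln(f'_{b_j, j} / p_{b_j})`` (observed
base frequency over background, with a background-proportional
pseudocount), and ``Kd`` is proportional to ``exp(-s)``.  The free
concentration [X] is anchored at the dissociation constant of the
motif's optimal site, which makes the occupancy of a consensus window
exactly 50% and gives ``p = 1 / (1 + exp(s_max - s))`` elsewhere.

For a SNP, the 41-base flank of each allele is scanned with sliding
windows on both strands; an allele-specific hit is reported when the
occupancy clears ``p_min`` and the two alleles differ by more than
``delta_min`` (defaults 0.20/0.20; results should be robust across
0.10-0.30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "PWM",
    "SNPContext",
    "OccupancyHit",
    "site_score",
    "occupancy_probability",
    "scan_snp",
    "filter_by_tf_allowlist",
    "read_pwm_file",
    "read_snp_contexts_fasta",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position frequency matrix with background model.

    ``freq`` is L x 4 (columns A, C, G, T); rows are regularized with a
    background-proportional pseudocount so zero counts never produce
    infinite energies.
    """

    motif_id: str
    tf_name: str
    freq: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("freq must be an L x 4 matrix")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not np.allclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        rows = self.freq.sum(axis=1, keepdims=True)
        if np.any(rows <= 0):
            raise ValueError("each PWM row needs positive mass")
        self.freq = self.freq / rows
        # background-proportional regularization
        reg = (self.freq + self.pseudocount * self.background[None, :]) / (
            1.0 + self.pseudocount
        )
        self._log_odds = np.log(reg) - np.log(self.background[None, :])

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def max_score(self) -> float:
        """Score of the optimal (consensus) window."""
        return float(self._log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self._log_odds.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            tf_name=self.tf_name,
            freq=self.freq[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    @classmethod
    def from_counts(cls, motif_id, tf_name, counts, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id=motif_id, tf_name=tf_name, freq=counts, **kw)


@dataclass
class SNPContext:
    """A SNP and its two 41-base allele flanks (20 up + allele + 20 down)."""

    snp_id: str
    ref_allele: str
    alt_allele: str
    flank_ref: str
    flank_alt: str

    def __post_init__(self) -> None:
        self.flank_ref = self.flank_ref.upper()
        self.flank_alt = self.flank_alt.upper()
        for seq, allele in ((self.flank_ref, self.ref_allele), (self.flank_alt, self.alt_allele)):
            if len(seq) != 41:
                raise ValueError(f"{self.snp_id}: flank must be 41 bases, got {len(seq)}")
            if seq[20] != allele.upper():
                raise ValueError(f"{self.snp_id}: center base does not match the allele")
        diff = [i for i in range(41) if self.flank_ref[i] != self.flank_alt[i]]
        if diff != [20]:
            raise ValueError(
                f"{self.snp_id}: allele flanks must differ at exactly the center base"
            )

    @property
    def center(self) -> int:
        return 20


@dataclass
class OccupancyHit:
    snp_id: str
    motif_id: str
    tf_name: str
    strand: str
    offset: int  # window start within the 41-base flank (0-based)
    p_occ_ref: float
    p_occ_alt: float
    delta: float


def site_score(pwm: PWM, window: str) -> float:
    """Log-odds energy score of one window; N contributes 0."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    s = 0.0
    for j, b in enumerate(window.upper()):
        if b == "N":
            continue
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid base {b!r} at window position {j}")
        s += pwm._log_odds[j, _BASE_INDEX[b]]
    return float(s)


def occupancy_probability(pwm: PWM, window: str) -> float:
    """Binding-isotherm occupancy with [X] anchored at the optimal Kd."""
    s = site_score(pwm, window)
    return float(1.0 / (1.0 + np.exp(pwm.max_score - s)))


def _best_occupancy(pwm: PWM, seq: str, center: Optional[int] = None):
    """Max occupancy over sliding windows (both strands).

    When ``center`` is given only windows covering that position are
    scanned.  Returns ``(p, offset, strand)``.
    """
    L = pwm.length
    rc_pwm = pwm.reverse_complement()
    best = (-1.0, -1, "+")
    for start in range(0, len(seq) - L + 1):
        if center is not None and not (start <= center < start + L):
            continue
        window = seq[start : start + L]
        for strand, mat in (("+", pwm), ("-", rc_pwm)):
            p = occupancy_probability(mat, window)
            if p > best[0]:
                best = (p, start, strand)
    return best


def scan_snp(
    pwm: PWM,
    context: SNPContext,
    p_min: float = 0.20,
    delta_min: float = 0.20,
) -> Optional[OccupancyHit]:
    """Allele-aware occupancy scan of one SNP with one motif.

    The allele-difference ``delta`` compares only windows overlapping
    the variant base (other windows are identical between alleles);
    the ``p_min`` filter uses the per-allele maximum over all windows.
    """
    if pwm.length > 41:
        raise ValueError("motif longer than the 41-base flank")
    c = context.center
    p_ref_c, off_ref, strand_ref = _best_occupancy(pwm, context.flank_ref, center=c)
    p_alt_c, off_alt, strand_alt = _best_occupancy(pwm, context.flank_alt, center=c)
    p_ref_all, _, _ = _best_occupancy(pwm, context.flank_ref)
    p_alt_all, _, _ = _best_occupancy(pwm, context.flank_alt)
    delta = abs(p_ref_c - p_alt_c)
    if max(p_ref_all, p_alt_all) > p_min and delta > delta_min:
        if p_ref_c >= p_alt_c:
            offset, strand = off_ref, strand_ref
        else:
            offset, strand = off_alt, strand_alt
        return OccupancyHit(
            snp_id=context.snp_id,
            motif_id=pwm.motif_id,
            tf_name=pwm.tf_name,
            strand=strand,
            offset=offset,
            p_occ_ref=p_ref_c,
            p_occ_alt=p_alt_c,
            delta=delta,
        )
    return None


def filter_by_tf_allowlist(
    hits: Iterable[OccupancyHit], allowlist: set
) -> list[OccupancyHit]:
    """Keep hits whose factor is on the (e.g. liver-expressed) allow-list.

    An empty allow-list passes everything through with a warning, since
    it usually means the curation step was skipped.
    """
    hits = list(hits)
    if not allowlist:
        import warnings

        warnings.warn("empty TF allow-list: no expression filter applied")
        return hits
    return [h for h in hits if h.tf_name in allowlist]


def read_pwm_file(path, fmt: str, pseudocount: float = 0.01,
                  background: Optional[np.ndarray] = None) -> list[PWM]:
    """Read PWMs from a JASPAR pfm or TRANSFAC matrix file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    fmt = fmt.lower()
    if fmt not in ("jaspar", "pfm", "transfac"):
        raise ValueError(f"unsupported PWM format {fmt!r}")
    with open(path) as fh:
        records = bio_motifs.parse(fh, "pfm-four-columns" if fmt == "pfm" else fmt)
        out = []
        for m in records:
            counts = np.column_stack([m.counts[b] for b in BASES])
            name = m.name or getattr(m, "matrix_id", None) or "motif"
            motif_id = getattr(m, "matrix_id", None) or m.name or "motif"
            kw = {"pseudocount": pseudocount}
            if background is not None:
                kw["background"] = np.asarray(background, dtype=float)
            out.append(PWM.from_counts(str(motif_id), str(name), counts, **kw))
    return out


def read_snp_contexts_fasta(path) -> list[SNPContext]:
    """Read allele flank pairs from FASTA.

    Records are paired by SNP id with headers ``>snpid|ref|A`` and
    ``>snpid|alt|C`` (id, role, allele separated by '|').
    """
    from Bio import SeqIO

    by_snp: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3 or parts[1] not in ("ref", "alt"):
            raise ValueError(f"malformed context header {rec.id!r}")
        snp_id, role, allele = parts
        by_snp.setdefault(snp_id, {})[role] = (allele, str(rec.seq))
    out = []
    for snp_id, d in by_snp.items():
        if set(d) != {"ref", "alt"}:
            raise ValueError(f"{snp_id}: need both ref and alt records")
        out.append(
            SNPContext(
                snp_id=snp_id,
                ref_allele=d["ref"][0],
                alt_allele=d["alt"][0],
                flank_ref=d["ref"][1],
                flank_alt=d["alt"][1],
            )
        )
    return out
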