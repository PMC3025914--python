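"""Ancestry-informative marker panels.

A panel records, for each biallelic marker, its genomic position (base
pairs and Morgans) and the frequency of the counted allele in the two
ancestral populations (West African and European).  Markers with a large
``|f_afr - f_eur|`` are ancestry-informative markers (AIMs); panels of a
few hundred to a few thousand such markers are what admixture-mapping
studies of African-American cohorts genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerPanel", "simulate_aim_panel"]


@dataclass
class MarkerPanel:
    """Per-marker metadata: positions and ancestral allele frequencies.

    Parameters
    ----------
    marker_id
        Unique marker names (e.g. rs identifiers).
    chrom
        Chromosome label per marker.  Markers must be grouped by
        chromosome and sorted by genetic-map position within it.
    pos_bp
        1-based physical position.
    pos_morgan
        Genetic-map position in Morgans, non-decreasing within a
        chromosome.
    f_afr, f_eur
        Frequency of the counted allele in the African and European
        ancestral populations, each in [0, 1].
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_morgan: np.ndarray
    f_afr: np.ndarray
    f_eur: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_morgan = np.asarray(self.pos_morgan, dtype=float)
        self.f_afr = np.asarray(self.f_afr, dtype=float)
        self.f_eur = np.asarray(self.f_eur, dtype=float)
        n = len(self.marker_id)
        for name in ("chrom", "pos_bp", "pos_morgan", "f_afr", "f_eur"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} has wrong length")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker_ids are not unique")
        for name in ("f_afr", "f_eur"):
            f = getattr(self, name)
            if np.any((f < 0) | (f > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.pos_morgan < 0):
            raise ValueError("pos_morgan must be non-negative")
        for c in self.chromosomes:
            pm = self.pos_morgan[self.chrom == c]
            if np.any(np.diff(pm) < 0):
                raise ValueError(f"pos_morgan not non-decreasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def index_of(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_id == marker_id)
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(idx[0])

    def chrom_slices(self) -> dict:
        """Map chromosome label -> index array of its markers (panel order)."""
        return {c: np.flatnonzero(self.chrom == c) for c in self.chromosomes}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "pos_morgan": self.pos_morgan,
                "f_afr": self.f_afr,
                "f_eur": self.f_eur,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        return cls(
            marker_id=df["marker_id"].to_numpy(dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            pos_bp=df["pos_bp"].to_numpy(),
            pos_morgan=df["pos_morgan"].to_numpy(dtype=float),
            f_afr=df["f_afr"].to_numpy(dtype=float),
            f_eur=df["f_eur"].to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        # chromosome labels are names, not numbers
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def simulate_aim_panel(
    n_chrom: int = 10,
    markers_per_chrom: int = 60,
    spacing_morgan: float = 0.025,
    freq_separation: float = 0.6,
    seed: int = 0,
) -> MarkerPanel:
    """Draw a synthetic panel of ancestry-informative markers.

    Each marker gets ancestral frequencies separated by roughly
    ``freq_separation`` (beta-distributed about 0.2 / 0.8 by default),
    mimicking the highly differentiated SNPs genotyped on admixture
    panels.  Markers are equally spaced in Morgans.
    """
    rng = np.random.default_rng(seed)
    mids, chroms, bp, cm, fa, fe = [], [], [], [], [], []
    lo = (1.0 - freq_separation) / 2.0
    hi = 1.0 - lo
    for c in range(1, n_chrom + 1):
        for m in range(markers_per_chrom):
            mids.append(f"aim{c}_{m}")
            chroms.append(str(c))
            cm.append(m * spacing_morgan)
            bp.append(int(1e6 * (1 + m)))
            # jitter the two frequencies about the separated centres,
            # randomly swapping which population carries the high allele
            a = float(np.clip(rng.normal(hi, 0.08), 0.0, 1.0))
            e = float(np.clip(rng.normal(lo, 0.08), 0.0, 1.0))
            if rng.random() < 0.5:
                a, e = e, a
            fa.append(a)
            fe.append(e)
    return MarkerPanel(
        marker_id=np.array(mids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(bp),
        pos_morgan=np.array(cm),
        f_afr=np.array(fa),
        f_eur=np.array(fe),
    )
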