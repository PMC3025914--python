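"""Cases-only admixture scan with LOD scores and credible intervals.

Cases are individuals in the top quantile of the sex-adjusted log
trait.  At each locus the scan asks whether the cases' local African
ancestry deviates from their genome-wide expectation: a Bayes factor
averages, over a grid of ancestry risk ratios psi, the likelihood of
each case's local-ancestry data when the Hardy-Weinberg prior implied
by that case's global ancestry is tilted by psi per African allele,
relative to psi = 1.  LOD = log10 of that averaged Bayes factor.
Peaks above LOD 5 are declared significant, controls are checked for
an opposite-direction shift, and a Bayesian 95% credible interval is
read off the normalized 10^LOD profile of the peak chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ancestry import LocalAncestryPosterior, stationary_prior
from .association import adjust_trait

__all__ = [
    "CaseControlDesign",
    "ScanResult",
    "default_psi_grid",
    "define_case_control",
    "cases_only_lod",
    "credible_interval",
    "compare_case_control_ancestry",
]

LOD_SIGNIFICANCE = 5.0  # genome-wide significance threshold for admixture peaks


@dataclass
class CaseControlDesign:
    case_ids: np.ndarray
    control_ids: np.ndarray
    basis: str = "sex-adjusted trait quantiles"

    def __post_init__(self) -> None:
        if np.intersect1d(self.case_ids, self.control_ids).size:
            raise ValueError("case and control sets overlap")


@dataclass
class ScanResult:
    chrom: np.ndarray  # (m,)
    pos_bp: np.ndarray  # (m,)
    lod: np.ndarray  # (m,)
    case_mean_afr: np.ndarray  # (m,) mean African fraction among cases
    control_mean_afr: np.ndarray  # (m,)
    max_lod: float
    max_locus: int  # index into the marker arrays

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "lod": self.lod,
                "case_mean_afr": self.case_mean_afr,
                "control_mean_afr": self.control_mean_afr,
            }
        )


def default_psi_grid() -> np.ndarray:
    """Risk-ratio grid 0.3, 0.4, ..., 3.0 with the null point removed."""
    g = np.round(np.arange(0.3, 3.01, 0.1), 10)
    return g[~np.isclose(g, 1.0)]


def define_case_control(
    trait: np.ndarray, sex: np.ndarray, quantile: float = 0.2
) -> CaseControlDesign:
    """Top/bottom quantiles of the sex-adjusted log trait.

    The top ``ceil(q*n)`` individuals are cases, the bottom
    ``ceil(q*n)`` controls; ties break by stable sample order.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n < 10:
        raise ValueError("need at least 10 individuals to form quantile groups")
    resid = adjust_trait(trait, sex)
    k = int(np.ceil(quantile * n))
    order = np.argsort(resid, kind="stable")
    return CaseControlDesign(
        case_ids=np.sort(order[-k:]), control_ids=np.sort(order[:k])
    )


def cases_only_lod(
    posterior: LocalAncestryPosterior,
    design: CaseControlDesign,
    psi_grid: Optional[Sequence[float]] = None,
) -> ScanResult:
    """Genome-wide cases-only LOD profile.

    ``psi_grid`` is the set of ancestry risk ratios averaged over with
    a uniform prior; any grid point equal to 1 is dropped with a
    warning since it is the null model.
    """
    if psi_grid is None:
        grid = default_psi_grid()
    else:
        grid = np.asarray(psi_grid, dtype=float)
        if np.any(np.isclose(grid, 1.0)):
            import warnings

            warnings.warn("psi grid contains the null value 1; removing it")
            grid = grid[~np.isclose(grid, 1.0)]
    if design.case_ids.size == 0:
        raise ValueError("empty case set")

    cases = np.asarray(design.case_ids)
    probs = posterior.probs[cases]  # (k, m, 3)
    prior = stationary_prior(posterior.theta_hat[cases])  # (k, 3)

    a = np.array([0.0, 1.0, 2.0])
    psi_pow = grid[:, None] ** a[None, :]  # (P, 3)
    num = np.einsum("pa,kma->pkm", psi_pow, probs)
    den = np.einsum("pa,ka->pk", psi_pow, prior)
    log_bf = np.sum(np.log(num) - np.log(den)[:, :, None], axis=1)  # (P, m)
    from scipy.special import logsumexp

    lod = (logsumexp(log_bf, axis=0) - np.log(grid.size)) / np.log(10.0)

    dose = posterior.mean_dosage()
    case_mean = dose[cases].mean(axis=0) / 2.0
    ctrl = np.asarray(design.control_ids)
    control_mean = (
        dose[ctrl].mean(axis=0) / 2.0 if ctrl.size else np.full(lod.size, np.nan)
    )
    imax = int(np.argmax(lod))
    return ScanResult(
        chrom=posterior.panel.chrom,
        pos_bp=posterior.panel.pos_bp,
        lod=lod,
        case_mean_afr=case_mean,
        control_mean_afr=control_mean,
        max_lod=float(lod[imax]),
        max_locus=imax,
    )


def credible_interval(
    scan: ScanResult, chrom: str, mass: float = 0.95
) -> tuple[int, int]:
    """Bayesian credible interval (bp range) for a chromosome's peak.

    10^LOD is normalized over loci with positive LOD on the chromosome
    and the smallest contiguous run of loci around the argmax
    accumulating at least ``mass`` of that area is returned, grown one
    locus at a time toward whichever side adds more area.
    """
    on = np.flatnonzero(scan.chrom == chrom)
    if on.size == 0:
        raise ValueError(f"no loci on chromosome {chrom!r}")
    lod = scan.lod[on]
    pos = scan.pos_bp[on]
    w = np.where(lod > 0, 10.0**lod, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"no positive LOD on chromosome {chrom!r}; interval undefined")
    w = w / total
    i = int(np.argmax(lod))
    lo = hi = i
    acc = w[i]
    while acc < mass and (lo > 0 or hi < w.size - 1):
        left = w[lo - 1] if lo > 0 else -1.0
        right = w[hi + 1] if hi < w.size - 1 else -1.0
        if left >= right:
            lo -= 1
            acc += w[lo]
        else:
            hi += 1
            acc += w[hi]
    return int(pos[lo]), int(pos[hi])


def compare_case_control_ancestry(
    posterior: LocalAncestryPosterior,
    design: CaseControlDesign,
    marker_id: str,
) -> tuple[float, float, float]:
    """Case vs control mean African ancestry (%) at a locus, Welch p.

    Returns ``(case_mean_pct, control_mean_pct, p)``.
    """
    frac = posterior.dosage_at(marker_id) / 2.0
    x = frac[np.asarray(design.case_ids)]
    y = frac[np.asarray(design.control_ids)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two individuals per group")
    if np.std(x) == 0 and np.std(y) == 0:
        p = 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return float(100 * x.mean()), float(100 * y.mean()), p
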