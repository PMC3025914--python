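"""Local-ancestry inference from ancestry-informative markers.

Global ancestry is estimated per individual by maximizing the
marker-independent genotype likelihood on a theta grid (refined by a
bounded local search).  Local ancestry — the African-allele count
a in {0,1,2} at each marker — is then obtained by a forward-backward
pass of a diploid hidden Markov model: the two chromosome copies carry
independent two-state ancestry chains (random mating), each switching
along the genetic map at rate ``lambda_switch`` per Morgan with new
ancestry redrawn from Bernoulli(theta_hat), and the genotype emission
is the convolution of Bernoulli(f_afr) draws over African copies and
Bernoulli(f_eur) draws over European copies, contaminated by a small
genotype-error rate.

This is a deterministic plug-in substitute for MCMC samplers of the
same model: frequencies and theta are fixed at their point estimates
rather than integrated over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort import MISSING
from .panel import MarkerPanel

__all__ = [
    "HMMParams",
    "LocalAncestryPosterior",
    "estimate_global_ancestry",
    "local_ancestry_posteriors",
    "classify_locus_strata",
]


@dataclass
class HMMParams:
    lambda_switch: float = 6.0
    genotype_error: float = 0.01
    theta_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.01, 0.995, 0.01)
    )

    def __post_init__(self) -> None:
        if self.lambda_switch <= 0:
            raise ValueError("lambda_switch must be positive")
        if not (0.0 <= self.genotype_error < 0.5):
            raise ValueError("genotype_error must be in [0, 0.5)")
        g = np.asarray(self.theta_grid, dtype=float)
        if np.any(np.diff(g) <= 0) or np.any((g <= 0) | (g >= 1)):
            raise ValueError("theta_grid must be strictly increasing within (0, 1)")
        self.theta_grid = g


@dataclass
class LocalAncestryPosterior:
    """Per individual x marker posterior over the African-allele count."""

    panel: MarkerPanel
    probs: np.ndarray  # (n, m, 3); [..., a] = P(count == a | data)
    theta_hat: np.ndarray  # (n,)
    flat_likelihood: np.ndarray | None = None  # (n,) bool

    def __post_init__(self) -> None:
        if np.any(np.abs(self.probs.sum(axis=2) - 1.0) > 1e-9):
            raise ValueError("posterior probabilities must sum to 1 at every marker")

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    def mean_dosage(self) -> np.ndarray:
        """Posterior-mean African-allele count, (n, m)."""
        return self.probs @ np.array([0.0, 1.0, 2.0])

    def dosage_at(self, marker_id: str) -> np.ndarray:
        return self.mean_dosage()[:, self.panel.index_of(marker_id)]

    def probs_at(self, marker_id: str) -> np.ndarray:
        return self.probs[:, self.panel.index_of(marker_id), :]


def _genotype_loglik_grid(
    genotypes: np.ndarray, panel: MarkerPanel, grid: np.ndarray
) -> np.ndarray:
    """Log-likelihood of each individual's genotypes at each grid theta, (n, T)."""
    n, m = genotypes.shape
    T = grid.size
    # allele frequency under theta: theta*f_afr + (1-theta)*f_eur, (T, m)
    p = np.clip(np.outer(grid, panel.f_afr) + np.outer(1.0 - grid, panel.f_eur), 1e-12, 1 - 1e-12)
    logp = {
        0: 2 * np.log1p(-p),
        1: np.log(2.0) + np.log(p) + np.log1p(-p),
        2: 2 * np.log(p),
    }
    ll = np.zeros((n, T))
    for g, lp in logp.items():
        mask = (genotypes == g).astype(float)  # (n, m)
        ll += mask @ lp.T
    return ll


def estimate_global_ancestry(
    genotypes: np.ndarray, panel: MarkerPanel, params: HMMParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood global African proportion per individual.

    Returns ``(theta_hat, flat)``.  ``flat`` flags individuals whose
    likelihood carries no information (all genotypes missing or all
    markers uninformative); their theta_hat is the grid midpoint.
    """
    if params is None:
        params = HMMParams()
    grid = params.theta_grid
    genotypes = np.asarray(genotypes)
    ll = _genotype_loglik_grid(genotypes, panel, grid)
    spread = ll.max(axis=1) - ll.min(axis=1)
    flat = spread < 1e-9
    best = grid[np.argmax(ll, axis=1)]
    midpoint = 0.5 * (grid[0] + grid[-1])

    theta = np.empty(genotypes.shape[0])
    step = np.median(np.diff(grid))
    for i in range(genotypes.shape[0]):
        if flat[i]:
            theta[i] = midpoint
            continue
        g_i = genotypes[i]
        obs = g_i != MISSING

        def negll(t: float) -> float:
            p = np.clip(
                t * panel.f_afr[obs] + (1.0 - t) * panel.f_eur[obs], 1e-12, 1 - 1e-12
            )
            g = g_i[obs]
            return -float(
                np.sum(
                    np.where(g == 1, np.log(2 * p * (1 - p)), 0.0)
                    + np.where(g == 2, 2 * np.log(p), 0.0)
                    + np.where(g == 0, 2 * np.log1p(-p), 0.0)
                )
            )

        lo = max(1e-6, best[i] - 2 * step)
        hi = min(1 - 1e-6, best[i] + 2 * step)
        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
        theta[i] = float(res.x)
    return theta, flat


def _emission_table(f_afr: float, f_eur: float, err: float) -> np.ndarray:
    """P(observed genotype g | African-copy count a), 3x3 [a, g].

    Convolution of one Bernoulli(f_afr) per African copy with one
    Bernoulli(f_eur) per European copy; with probability ``err`` the
    observed genotype is uniform on {0,1,2}.
    """
    out = np.zeros((3, 3))
    for a in range(3):
        e = 2 - a
        for g in range(3):
            p = 0.0
            for k in range(0, a + 1):
                j = g - k
                if 0 <= j <= e:
                    p += (
                        comb(a, k) * f_afr**k * (1 - f_afr) ** (a - k)
                        * comb(e, j) * f_eur**j * (1 - f_eur) ** (e - j)
                    )
            out[a, g] = p
    return (1.0 - err) * out + err / 3.0


def _transition_tensor(theta: np.ndarray, d: float, lam: float) -> np.ndarray:
    """Per-individual 3x3 transition of the African-copy count, (n, 3, 3).

    Built from two independent per-copy chains: over a gap of d Morgans
    a copy keeps its ancestry with probability exp(-lam*d) and
    otherwise redraws it from Bernoulli(theta).
    """
    stay = np.exp(-lam * d)
    pAA = stay + (1 - stay) * theta  # African copy stays African
    pEA = (1 - stay) * theta  # European copy becomes African
    n = theta.shape[0]
    T = np.zeros((n, 3, 3))
    # state a = number of African copies; copies transition independently
    # a=0: two European copies
    T[:, 0, 0] = (1 - pEA) ** 2
    T[:, 0, 1] = 2 * pEA * (1 - pEA)
    T[:, 0, 2] = pEA**2
    # a=1: one of each
    T[:, 1, 0] = (1 - pAA) * (1 - pEA)
    T[:, 1, 1] = pAA * (1 - pEA) + (1 - pAA) * pEA
    T[:, 1, 2] = pAA * pEA
    # a=2: two African copies
    T[:, 2, 0] = (1 - pAA) ** 2
    T[:, 2, 1] = 2 * pAA * (1 - pAA)
    T[:, 2, 2] = pAA**2
    return T


def stationary_prior(theta: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg prior over the African-copy count, (n, 3)."""
    theta = np.asarray(theta, dtype=float)
    return np.stack(
        [(1 - theta) ** 2, 2 * theta * (1 - theta), theta**2], axis=-1
    )


def local_ancestry_posteriors(
    genotypes: np.ndarray,
    panel: MarkerPanel,
    theta_hat: np.ndarray,
    params: HMMParams | None = None,
) -> LocalAncestryPosterior:
    """Forward-backward posteriors of the African-allele count.

    Chromosomes are independent; within a chromosome markers must be
    sorted by map position (enforced by :class:`MarkerPanel`).
    Missing genotypes emit likelihood 1.
    """
    if params is None:
        params = HMMParams()
    genotypes = np.asarray(genotypes)
    theta_hat = np.asarray(theta_hat, dtype=float)
    n, m = genotypes.shape
    probs = np.empty((n, m, 3))
    prior = stationary_prior(theta_hat)  # (n, 3)

    for idx in panel.chrom_slices().values():
        pm = panel.pos_morgan[idx]
        L = idx.size
        # emission likelihoods per marker: (n, L, 3) indexed [i, j, a]
        emit = np.ones((n, L, 3))
        for jj, j in enumerate(idx):
            tab = _emission_table(panel.f_afr[j], panel.f_eur[j], params.genotype_error)
            g = genotypes[:, j]
            obs = g != MISSING
            emit[obs, jj, :] = tab[:, g[obs]].T

        alpha = np.empty((n, L, 3))
        scale = np.empty((n, L))
        a0 = prior * emit[:, 0, :]
        scale[:, 0] = a0.sum(axis=1)
        alpha[:, 0, :] = a0 / scale[:, 0, None]
        trans = []
        for jj in range(1, L):
            T = _transition_tensor(theta_hat, pm[jj] - pm[jj - 1], params.lambda_switch)
            trans.append(T)
            a = np.einsum("ns,nst->nt", alpha[:, jj - 1, :], T) * emit[:, jj, :]
            scale[:, jj] = a.sum(axis=1)
            alpha[:, jj, :] = a / scale[:, jj, None]

        beta = np.empty((n, L, 3))
        beta[:, L - 1, :] = 1.0
        for jj in range(L - 2, -1, -1):
            T = trans[jj]
            b = np.einsum(
                "nst,nt->ns", T, emit[:, jj + 1, :] * beta[:, jj + 1, :]
            )
            beta[:, jj, :] = b / scale[:, jj + 1, None]

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        probs[:, idx, :] = post

    return LocalAncestryPosterior(panel=panel, probs=probs, theta_hat=theta_hat)


def classify_locus_strata(
    posterior: LocalAncestryPosterior, marker_id: str, p_threshold: float = 0.95
):
    """Assign local-ancestry strata at one locus.

    Returns a dict of boolean arrays: ``afr2`` (two African copies with
    posterior above threshold), ``eur12`` (at least one European copy),
    ``eur2`` (two European copies; a subset of ``eur12``), and
    ``unassigned``.
    """
    p = posterior.probs_at(marker_id)
    afr2 = p[:, 2] > p_threshold
    eur12 = (p[:, 0] + p[:, 1]) > p_threshold
    eur2 = p[:, 0] > p_threshold
    return {
        "afr2": afr2,
        "eur12": eur12,
        "eur2": eur2,
        "unassigned": ~(afr2 | eur12),
    }
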