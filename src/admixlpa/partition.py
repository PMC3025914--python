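"""Ancestry-mediation variance partitioning.

The mediation statistic compares two adjusted R-squareds for the
regression linking local ancestry and the sex-adjusted log trait:

* ``r2_base`` — trait explained by the local African-allele dosage;
* ``r2_geno`` — the same after the trait has additionally been
  residualized on one or more SNP genotypes.

``pi = 1 - r2_geno / r2_base`` is then the fraction of the
ancestry-specific trait variation that the genotypes account for: 0
when the SNPs are irrelevant to the ancestry association, 1 when they
mediate it entirely.  (The equivalent quantity is sometimes printed
with the ratio inverted, which flips its sign; the ``orientation``
flag exposes both forms.)

Multi-SNP models are built by stepwise forward selection with
nested-model ANOVA, averaging each candidate's p-value over resampled
unrelated groups, and variance explained is estimated out-of-sample by
five-fold (multi-SNP) or two-fold (single-SNP) cross-validation so
that SNP discovery, model building and variance evaluation never share
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PiResult",
    "CVEstimate",
    "StepwiseModel",
    "pi_statistic",
    "stepwise_build",
    "cv_variance_explained",
    "cv_ancestry_explained",
]


@dataclass
class PiResult:
    r2_base: float
    r2_geno: float
    pi: float  # NaN when r2_base <= 0
    orientation: str = "mediation"
    diagnostic: str = ""


@dataclass
class CVEstimate:
    mean: float  # percent of variance
    sd: float
    n_groups: int
    scheme: str  # "five_fold" | "two_fold"


@dataclass
class StepwiseModel:
    markers: list = field(default_factory=list)  # order of entry
    entry_p: list = field(default_factory=list)  # averaged p at entry
    coef: dict = field(default_factory=dict)  # marker -> fitted coefficient
    intercept: float = 0.0

    def predict(self, genotypes: pd.DataFrame) -> np.ndarray:
        """Fitted genotype contribution (includes the intercept)."""
        yhat = np.full(len(genotypes), self.intercept)
        for m in self.markers:
            yhat = yhat + self.coef[m] * genotypes[m].to_numpy(dtype=float)
        return yhat


def _adj_r2(y: np.ndarray, x: np.ndarray) -> float:
    keep = ~np.isnan(y) & ~np.isnan(x)
    fit = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
    return float(fit.rsquared_adj)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of y on [1, X], propagating NaN rows."""
    out = np.full(y.shape, np.nan)
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    fit = sm.OLS(y[keep], sm.add_constant(X[keep])).fit()
    out[keep] = fit.resid
    return out


def pi_statistic(
    residual: np.ndarray,
    local_dosage: np.ndarray,
    genotypes,
    orientation: str = "mediation",
) -> PiResult:
    """Fraction of the ancestry-trait association mediated by genotype.

    ``genotypes`` may be a single dosage vector or a samples x SNPs
    DataFrame/2-D array (the multi-SNP adjustment).
    """
    y = np.asarray(residual, dtype=float)
    d = np.asarray(local_dosage, dtype=float)
    G = genotypes.to_numpy(dtype=float) if hasattr(genotypes, "to_numpy") else np.asarray(
        genotypes, dtype=float
    )
    if G.ndim == 1:
        G = G[:, None]
    r2_base = _adj_r2(y, d)
    y_geno = _residualize(y, G)
    r2_geno = _adj_r2(y_geno, d)
    if r2_base <= 0:
        return PiResult(
            r2_base=r2_base, r2_geno=r2_geno, pi=float("nan"),
            orientation=orientation,
            diagnostic="base ancestry R^2 is not positive; mediation fraction undefined",
        )
    pi = 1.0 - r2_geno / r2_base
    if orientation == "printed":
        pi = 1.0 - r2_base / r2_geno if r2_geno != 0 else float("nan")
    return PiResult(r2_base=r2_base, r2_geno=r2_geno, pi=float(pi), orientation=orientation)


def _group_anova_p(
    y: np.ndarray,
    G: pd.DataFrame,
    in_model: list,
    candidate: str,
    groups: Sequence[np.ndarray],
    covariates: Optional[np.ndarray],
) -> float:
    """Averaged nested-ANOVA p-value for adding one SNP, over groups."""
    ps = []
    for idx in groups:
        yy = y[idx]
        cols = [G[m].to_numpy(dtype=float)[idx] for m in in_model]
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)[idx]
            if cov.ndim == 1:
                cols.append(cov)
            else:
                cols.extend(cov[:, k] for k in range(cov.shape[1]))
        g = G[candidate].to_numpy(dtype=float)[idx]
        keep = ~np.isnan(yy) & ~np.isnan(g)
        for c in cols:
            keep &= ~np.isnan(c)
        if keep.sum() < len(cols) + 3 or np.std(g[keep]) == 0:
            ps.append(1.0)
            continue
        X0 = (
            sm.add_constant(np.column_stack([c[keep] for c in cols]))
            if cols
            else np.ones((int(keep.sum()), 1))
        )
        X1 = np.column_stack([X0, g[keep]])
        if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
            ps.append(1.0)
            continue
        f1 = sm.OLS(yy[keep], X1).fit()
        f0 = sm.OLS(yy[keep], X0).fit()
        ps.append(float(f1.compare_f_test(f0)[1]))
    return float(np.mean(ps))


def stepwise_build(
    residual: np.ndarray,
    genotypes: pd.DataFrame,
    groups: Sequence[np.ndarray],
    candidate_snps: Optional[Sequence[str]] = None,
    covariates: Optional[np.ndarray] = None,
    p_enter: float = 0.05,
) -> StepwiseModel:
    """Forward stepwise SNP selection by group-averaged nested ANOVA.

    At each step every remaining candidate is tested (model with vs
    without it) in each unrelated group; the candidate with the
    smallest group-averaged p enters if that p is below ``p_enter``
    (ties break by marker order).  Coefficients are then fit on the
    union of the group memberships.
    """
    if len(groups) == 0:
        raise ValueError("need at least one group")
    y = np.asarray(residual, dtype=float)
    cands = list(candidate_snps) if candidate_snps is not None else list(genotypes.columns)
    model = StepwiseModel()
    while cands:
        avg = [
            _group_anova_p(y, genotypes, model.markers, c, groups, covariates)
            for c in cands
        ]
        k = int(np.argmin(avg))  # argmin is stable: first of tied minima
        if avg[k] >= p_enter:
            break
        model.markers.append(cands.pop(k))
        model.entry_p.append(float(avg[k]))

    pool = np.unique(np.concatenate(list(groups)))
    if model.markers:
        X = np.column_stack(
            [genotypes[m].to_numpy(dtype=float)[pool] for m in model.markers]
        )
        yy = y[pool]
        keep = ~np.isnan(yy) & ~np.isnan(X).any(axis=1)
        fit = sm.OLS(yy[keep], sm.add_constant(X[keep])).fit()
        model.intercept = float(fit.params[0])
        model.coef = {m: float(b) for m, b in zip(model.markers, fit.params[1:])}
    return model


def _oos_r2(y_test: np.ndarray, yhat: np.ndarray) -> float:
    keep = ~np.isnan(y_test) & ~np.isnan(yhat)
    y, f = y_test[keep], yhat[keep]
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 0.0
    return float(1.0 - np.sum((y - f) ** 2) / sst)


def _fit_fixed_set(
    y: np.ndarray, G: pd.DataFrame, markers: Sequence[str], idx: np.ndarray
) -> StepwiseModel:
    m = StepwiseModel(markers=list(markers))
    X = np.column_stack([G[s].to_numpy(dtype=float)[idx] for s in markers])
    yy = y[idx]
    keep = ~np.isnan(yy) & ~np.isnan(X).any(axis=1)
    fit = sm.OLS(yy[keep], sm.add_constant(X[keep])).fit()
    m.intercept = float(fit.params[0])
    m.coef = {s: float(b) for s, b in zip(markers, fit.params[1:])}
    return m


def _marginal_discovery(
    y: np.ndarray,
    G: pd.DataFrame,
    cands: Sequence[str],
    idx: np.ndarray,
    ancestry: Optional[np.ndarray],
    p_disc: float,
) -> list:
    """SNPs with (optionally ancestry-adjusted) association p below p_disc."""
    found = []
    yy = y[idx]
    if ancestry is not None:
        yy = _residualize(yy, np.asarray(ancestry, dtype=float)[idx][:, None])
    for c in cands:
        g = G[c].to_numpy(dtype=float)[idx]
        keep = ~np.isnan(yy) & ~np.isnan(g)
        if keep.sum() < 5 or np.std(g[keep]) == 0:
            continue
        fit = sm.OLS(yy[keep], sm.add_constant(g[keep])).fit()
        if fit.pvalues[1] < p_disc:
            found.append(c)
    return found


def cv_variance_explained(
    residual: np.ndarray,
    genotypes: pd.DataFrame,
    groups: Sequence[np.ndarray],
    candidate_snps: Optional[Sequence[str]] = None,
    scheme: str = "five_fold",
    ancestry: Optional[np.ndarray] = None,
    p_discovery: float = 0.05,
    seed: int = 0,
) -> CVEstimate:
    """Cross-validated percent of trait variance explained by SNPs.

    five_fold: each group is split into 5 sets; per rotation 3 sets
    discover candidate SNPs (p < 0.05, ancestry-adjusted when an
    ancestry vector is supplied), one builds a stepwise model with
    coefficients, and the held-out fifth supplies the out-of-sample
    R-squared.  A rotation whose discovery set finds nothing
    contributes 0%.

    two_fold: the fixed ``candidate_snps`` (typically a single SNP)
    are fit on one half and evaluated on the other, both rotations.
    """
    y = np.asarray(residual, dtype=float)
    rng = np.random.default_rng(seed)
    estimates = []
    for idx in groups:
        idx = np.asarray(idx)
        perm = rng.permutation(idx)
        if scheme == "two_fold":
            if not candidate_snps:
                raise ValueError("two_fold scheme needs an explicit SNP set")
            folds = np.array_split(perm, 2)
            for t in range(2):
                train, test = folds[1 - t], folds[t]
                model = _fit_fixed_set(y, genotypes, candidate_snps, train)
                yhat = model.predict(genotypes.iloc[test])
                estimates.append(100.0 * _oos_r2(y[test], yhat))
        elif scheme == "five_fold":
            folds = np.array_split(perm, 5)
            cands = (
                list(candidate_snps)
                if candidate_snps is not None
                else list(genotypes.columns)
            )
            for r in range(5):
                test = folds[r]
                build = folds[(r + 1) % 5]
                disc = np.concatenate([folds[(r + k) % 5] for k in (2, 3, 4)])
                found = _marginal_discovery(y, genotypes, cands, disc, ancestry, p_discovery)
                if not found:
                    estimates.append(0.0)
                    continue
                model = stepwise_build(y, genotypes, [build], candidate_snps=found)
                if not model.markers:
                    estimates.append(0.0)
                    continue
                yhat = model.predict(genotypes.iloc[test])
                estimates.append(100.0 * _oos_r2(y[test], yhat))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    est = np.asarray(estimates)
    return CVEstimate(
        mean=float(est.mean()), sd=float(est.std(ddof=1)) if est.size > 1 else 0.0,
        n_groups=len(groups), scheme=scheme,
    )


def cv_ancestry_explained(
    residual: np.ndarray,
    genotypes: pd.DataFrame,
    local_dosage: np.ndarray,
    groups: Sequence[np.ndarray],
    candidate_snps: Optional[Sequence[str]] = None,
    p_discovery: float = 0.05,
    adjust_discovery: bool = True,
    seed: int = 0,
) -> CVEstimate:
    """Cross-validated percent of the ancestry association mediated by SNPs.

    Five-fold scheme as in :func:`cv_variance_explained`, but the
    held-out set evaluates the mediation fraction: the trained model's
    genotype prediction is subtracted from the held-out trait and pi is
    computed there.  Rotations with an undefined pi (no positive base
    ancestry R-squared) are skipped; rotations discovering no SNPs
    contribute 0%.
    """
    y = np.asarray(residual, dtype=float)
    d = np.asarray(local_dosage, dtype=float)
    rng = np.random.default_rng(seed)
    estimates = []
    for idx in groups:
        perm = rng.permutation(np.asarray(idx))
        folds = np.array_split(perm, 5)
        cands = (
            list(candidate_snps) if candidate_snps is not None else list(genotypes.columns)
        )
        for r in range(5):
            test = folds[r]
            build = folds[(r + 1) % 5]
            disc = np.concatenate([folds[(r + k) % 5] for k in (2, 3, 4)])
            found = _marginal_discovery(
                y, genotypes, cands, disc, d if adjust_discovery else None, p_discovery
            )
            if not found:
                estimates.append(0.0)
                continue
            model = stepwise_build(y, genotypes, [build], candidate_snps=found)
            if not model.markers:
                estimates.append(0.0)
                continue
            y_test = y[test]
            y_geno = y_test - model.predict(genotypes.iloc[test])
            r2_base = _adj_r2(y_test, d[test])
            r2_geno = _adj_r2(y_geno, d[test])
            if r2_base <= 0:
                continue
            estimates.append(100.0 * (1.0 - r2_geno / r2_base))
    est = np.asarray(estimates)
    return CVEstimate(
        mean=float(est.mean()), sd=float(est.std(ddof=1)) if est.size > 1 else 0.0,
        n_groups=len(groups), scheme="five_fold",
    )
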