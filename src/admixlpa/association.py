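"""Trait-ancestry and trait-genotype regression.

All models run on the natural-log trait.  The phenotype used
throughout is the residual of log trait on sex ("sex-adjusted"); SNP
tests compare nested OLS models (ancestry covariates vs covariates +
genotype) by F-test, assuming additive inheritance, and effect sizes
are reported as the percent change in the trait per unit of the
predictor: ``effect% = 100*(exp(beta*delta) - 1)`` with the standard
error propagated by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "InteractionResult",
    "BONFERRONI_P",
    "adjust_trait",
    "ancestry_effect",
    "snp_association",
    "interaction_test",
    "ld_r2",
    "qc_filter",
    "hwe_test",
]

# 0.05 Bonferroni-corrected for a 59-SNP fine-mapping panel
BONFERRONI_P = 0.05 / 59


@dataclass
class RegressionResult:
    beta: float  # log-trait units per unit predictor
    se: float
    p: float
    effect_percent: float  # % trait change per `delta` units
    effect_percent_se: float
    delta: float
    n_used: int


@dataclass
class InteractionResult:
    p_int: float
    beta_int: float = float("nan")
    collinear: bool = False


def _percent(beta: float, se: float, delta: float) -> tuple[float, float]:
    eff = 100.0 * np.expm1(beta * delta)
    return float(eff), float(100.0 * np.exp(beta * delta) * se * delta)


def adjust_trait(trait: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Residual of the natural-log trait on an intercept + male indicator."""
    trait = np.asarray(trait, dtype=float)
    bad = np.flatnonzero(~(trait > 0))
    if bad.size:
        raise ValueError(f"nonpositive trait values at sample indices {bad.tolist()[:20]}")
    y = np.log(trait)
    male = (np.asarray(sex) == "male").astype(float)
    if male.std() == 0:
        return y - y.mean()
    X = sm.add_constant(male)
    return np.asarray(sm.OLS(y, X).fit().resid)


def ancestry_effect(
    residual: np.ndarray,
    predictor: np.ndarray,
    per_unit: float = 0.10,
    covariates: Optional[np.ndarray] = None,
) -> RegressionResult:
    """OLS of sex-adjusted log trait on an ancestry fraction.

    ``predictor`` is a fraction in [0, 1] (global theta, or local
    dosage / 2); ``per_unit`` is the change the percent effect is
    quoted for (default 0.10, i.e. per 10% increase in African
    ancestry).  ``covariates`` are added to the model if given.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(residual, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if np.ptp(x) == 0:
        raise ValueError("constant ancestry predictor")
    cols = [x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[keep]
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    eff, eff_se = _percent(beta, se, per_unit)
    return RegressionResult(
        beta=float(beta), se=float(se), p=float(p),
        effect_percent=eff, effect_percent_se=eff_se,
        delta=per_unit, n_used=int(y.size),
    )


def _nested_f(y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> float:
    """p-value of the F-test comparing OLS fits on X0 (reduced) vs X1 (full)."""
    f0 = sm.OLS(y, X0).fit()
    f1 = sm.OLS(y, X1).fit()
    return float(f1.compare_f_test(f0)[1])


def snp_association(
    residual: np.ndarray,
    genotype: np.ndarray,
    theta_hat: Optional[np.ndarray] = None,
    local_dosage: Optional[np.ndarray] = None,
) -> RegressionResult:
    """Additive SNP test by nested-model ANOVA.

    The reduced model carries the ancestry covariates (global theta
    and/or local dosage, whichever are supplied); the full model adds
    the genotype.  ``p`` is the nested F-test p-value; ``beta`` and the
    percent effect per allele come from the full model.  Missing
    genotypes are dropped listwise.
    """
    y = np.asarray(residual, dtype=float)
    g = np.asarray(genotype, dtype=float)
    covs = []
    if theta_hat is not None:
        covs.append(np.asarray(theta_hat, dtype=float))
    if local_dosage is not None:
        covs.append(np.asarray(local_dosage, dtype=float))
    keep = ~np.isnan(g) & ~np.isnan(y)
    for c in covs:
        keep &= ~np.isnan(c)
    y, g = y[keep], g[keep]
    covs = [c[keep] for c in covs]
    if np.ptp(g) == 0:
        return RegressionResult(
            beta=float("nan"), se=float("nan"), p=float("nan"),
            effect_percent=float("nan"), effect_percent_se=float("nan"),
            delta=1.0, n_used=int(y.size),
        )
    X0 = sm.add_constant(np.column_stack(covs)) if covs else np.ones((y.size, 1))
    X1 = np.column_stack([X0, g])
    p = _nested_f(y, X0, X1)
    fit = sm.OLS(y, X1).fit()
    beta, se = fit.params[-1], fit.bse[-1]
    eff, eff_se = _percent(beta, se, 1.0)
    return RegressionResult(
        beta=float(beta), se=float(se), p=p,
        effect_percent=eff, effect_percent_se=eff_se,
        delta=1.0, n_used=int(y.size),
    )


def interaction_test(
    residual: np.ndarray,
    genotype: np.ndarray,
    local_dosage: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> InteractionResult:
    """F-test of the genotype x local-ancestry product term.

    The product multiplies the genotype (0..2) by the local African
    fraction (dosage/2), so the interaction covariate ranges over
    [0, 2].
    """
    y = np.asarray(residual, dtype=float)
    g = np.asarray(genotype, dtype=float)
    d = np.asarray(local_dosage, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(y) & ~np.isnan(d)
    cols = [d[keep], g[keep]]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[keep]
        cols.append(cov if cov.ndim == 2 else cov[:, None])
    y = y[keep]
    inter = g[keep] * (d[keep] / 2.0)
    X0 = sm.add_constant(np.column_stack(cols))
    X1 = np.column_stack([X0, inter])
    if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
        return InteractionResult(p_int=float("nan"), collinear=True)
    p = _nested_f(y, X0, X1)
    beta = float(sm.OLS(y, X1).fit().params[-1])
    return InteractionResult(p_int=p, beta_int=beta)


def ld_r2(genotype_a: np.ndarray, genotype_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages."""
    a = np.asarray(genotype_a, dtype=float)
    b = np.asarray(genotype_b, dtype=float)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic genotype; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def qc_filter(
    genotypes: pd.DataFrame,
    snp_call_rate: float = 0.90,
    sample_call_rate: float = 0.85,
) -> tuple[pd.DataFrame, dict]:
    """Call-rate QC: drop SNPs below 90%, then individuals below 85%.

    ``genotypes`` is samples x markers with NaN for missing calls.
    Returns the filtered frame and a report of the counts dropped.
    """
    snp_rate = genotypes.notna().mean(axis=0)
    keep_snps = snp_rate >= snp_call_rate
    g = genotypes.loc[:, keep_snps]
    sample_rate = g.notna().mean(axis=1) if g.shape[1] else pd.Series(1.0, index=g.index)
    keep_samples = sample_rate >= sample_call_rate
    out = g.loc[keep_samples]
    report = {
        "n_snps_dropped": int((~keep_snps).sum()),
        "n_samples_dropped": int((~keep_samples).sum()),
        "snps_dropped": list(genotypes.columns[~keep_snps]),
        "samples_dropped": list(g.index[~keep_samples]),
    }
    return out, report


def hwe_test(genotype: np.ndarray) -> float:
    """Hardy-Weinberg chi-square goodness-of-fit p-value (1 df)."""
    g = np.asarray(genotype, dtype=float)
    g = g[~np.isnan(g)]
    n = g.size
    obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], dtype=float)
    p = (2 * obs[2] + obs[1]) / (2 * n)
    if p in (0.0, 1.0):
        raise ValueError("monomorphic genotype; HWE test undefined")
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))
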