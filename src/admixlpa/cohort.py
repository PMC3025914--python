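"""Synthetic admixed cohorts with known ground truth.

The simulator emulates a recently admixed African-American cohort: each
individual draws a global African ancestry proportion theta from a Beta
distribution (mean ~0.83, sd ~0.09 as observed in large community
cohorts), each chromosome copy follows a Markov ancestry process along
the genetic map (exponential switch distances, rate ``lambda`` per
Morgan, new ancestry redrawn from Bernoulli(theta)), and alleles are
drawn from the ancestral frequency of whichever population the copy
descends from at that marker.  The quantitative trait is log-normal
with additive sex, global-ancestry and per-allele SNP effects; percent
effects convert to natural-log slopes via ``beta = ln(1 + pct/100)``.

Every draw is controlled by a single integer seed, so cohorts are
byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .panel import MarkerPanel

__all__ = [
    "TraitModel",
    "CohortConfig",
    "Cohort",
    "percent_to_beta",
    "beta_to_percent",
    "simulate_cohort",
    "simulate_survival",
    "sample_unrelated",
]

MISSING = -1  # sentinel for a missing genotype in integer matrices


def percent_to_beta(effect_percent: float) -> float:
    """Per-unit natural-log slope implied by a percent change per unit."""
    return float(np.log1p(effect_percent / 100.0))


def beta_to_percent(beta: float, delta: float = 1.0) -> float:
    """Percent trait change for a ``delta``-unit change of the predictor."""
    return float(100.0 * np.expm1(beta * delta))


@dataclass
class TraitModel:
    """Additive model for the natural-log trait.

    ``snp_effects`` maps marker ids to per-allele log effects; use
    :func:`percent_to_beta` to convert from percent-per-allele.
    """

    intercept: float = 3.5
    sex_effect: float = -0.2
    global_ancestry_effect: float = 0.0
    snp_effects: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 0.9

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass
class CohortConfig:
    """Knobs of the cohort generator.

    ``admix_dispersion`` is the Beta concentration (a+b); the default
    reproduces a mean 0.83, sd 0.09 African-ancestry distribution.
    ``generations`` is the ancestry-switch rate per Morgan (roughly the
    number of generations since admixture).
    """

    n_individuals: int = 1000
    mean_african: float = 0.83
    admix_dispersion: float = 0.83 * 0.17 / 0.09**2 - 1.0  # mean .83, sd .09
    generations: float = 6.0
    male_fraction: float = 0.368
    family_sizes: Sequence[float] = (1.0,)  # P(family size = 1, 2, ...)
    dropout: float = 0.0  # uniform genotype missingness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not (0.0 < self.mean_african < 1.0):
            raise ValueError("mean_african must be in (0, 1)")
        if self.admix_dispersion <= 0 or self.generations <= 0:
            raise ValueError("admix_dispersion and generations must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        p = np.asarray(self.family_sizes, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("family_sizes must be a probability vector over sizes 1..k")


@dataclass
class Cohort:
    """A simulated cohort with full ground truth.

    ``genotypes`` holds additive dosages in {0,1,2} with ``MISSING``
    (-1) for dropped calls; ``local_true`` is the true African-allele
    count per individual and marker; ``theta_true`` the true global
    African proportion.  ``trait`` is on the positive (mg/dL-like)
    scale; the generative model is log-normal.
    """

    panel: MarkerPanel
    genotypes: np.ndarray  # (n, m) int8
    sex: np.ndarray  # (n,) "male"/"female"
    family_id: np.ndarray  # (n,) str
    theta_true: np.ndarray  # (n,) float
    local_true: np.ndarray  # (n, m) int8
    trait: np.ndarray  # (n,) float, positive
    survival_time: Optional[np.ndarray] = None
    event_flag: Optional[np.ndarray] = None
    sample_id: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_id is None:
            self.sample_id = np.array(
                [f"ind{i:05d}" for i in range(self.n_individuals)], dtype=object
            )
        if np.any(self.trait <= 0):
            raise ValueError("trait must be positive")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == "male"

    def log_trait(self) -> np.ndarray:
        return np.log(self.trait)

    def genotype_of(self, marker_id: str) -> np.ndarray:
        """Dosage vector for one marker, missing as NaN."""
        g = self.genotypes[:, self.panel.index_of(marker_id)].astype(float)
        g[g == MISSING] = np.nan
        return g

    def replace(self, **kw) -> "Cohort":
        return dataclasses.replace(self, **kw)


def _draw_family_ids(n: int, size_probs: Sequence[float], rng: np.random.Generator):
    sizes = []
    total = 0
    k = len(size_probs)
    while total < n:
        s = int(rng.choice(np.arange(1, k + 1), p=np.asarray(size_probs, dtype=float)))
        s = min(s, n - total)
        sizes.append(s)
        total += s
    fam = np.empty(n, dtype=object)
    i = 0
    for f, s in enumerate(sizes):
        fam[i : i + s] = f"fam{f:05d}"
        i += s
    return fam


def _simulate_copy_ancestry(
    theta: np.ndarray, pos_morgan: np.ndarray, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """One chromosome copy's ancestry (1=African) at each marker, all individuals.

    Markov process along the map: over a gap of d Morgans the ancestry
    is kept with probability exp(-lam*d), otherwise redrawn from
    Bernoulli(theta_i).
    """
    n = theta.shape[0]
    m = pos_morgan.shape[0]
    anc = np.empty((n, m), dtype=np.int8)
    state = (rng.random(n) < theta).astype(np.int8)
    anc[:, 0] = state
    gaps = np.diff(pos_morgan)
    for j, d in enumerate(gaps, start=1):
        switch = rng.random(n) >= np.exp(-lam * d)
        redraw = (rng.random(n) < theta).astype(np.int8)
        state = np.where(switch, redraw, state)
        anc[:, j] = state
    return anc


def simulate_cohort(
    config: CohortConfig, panel: MarkerPanel, trait_model: TraitModel
) -> Cohort:
    """Generate a cohort under the admixture + log-normal trait model.

    Raises
    ------
    ValueError
        If ``trait_model.snp_effects`` names a marker absent from the
        panel.
    """
    unknown = set(trait_model.snp_effects) - set(panel.marker_id)
    if unknown:
        raise ValueError(f"snp_effects reference markers not in panel: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, panel.n_markers

    conc = config.admix_dispersion
    a = config.mean_african * conc
    b = (1.0 - config.mean_african) * conc
    theta = rng.beta(a, b, size=n)

    local = np.zeros((n, m), dtype=np.int8)
    geno = np.zeros((n, m), dtype=np.int8)
    for idx in panel.chrom_slices().values():
        pm = panel.pos_morgan[idx]
        for _copy in range(2):
            anc = _simulate_copy_ancestry(theta, pm, config.generations, rng)
            freq = np.where(anc == 1, panel.f_afr[idx], panel.f_eur[idx])
            allele = (rng.random((n, idx.size)) < freq).astype(np.int8)
            local[:, idx] += anc
            geno[:, idx] += allele

    if config.dropout > 0:
        geno = geno.copy()
        geno[rng.random((n, m)) < config.dropout] = MISSING

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female").astype(object)
    fam = _draw_family_ids(n, config.family_sizes, rng)

    log_trait = (
        trait_model.intercept
        + trait_model.sex_effect * (sex == "male")
        + trait_model.global_ancestry_effect * theta
        + rng.normal(0.0, trait_model.residual_sd, size=n)
    )
    for marker_id, beta in trait_model.snp_effects.items():
        log_trait = log_trait + beta * _true_dosage(geno, panel.index_of(marker_id))

    trait = np.exp(log_trait)
    return Cohort(
        panel=panel,
        genotypes=geno,
        sex=sex,
        family_id=fam,
        theta_true=theta,
        local_true=local,
        trait=trait,
    )


def _true_dosage(geno: np.ndarray, j: int) -> np.ndarray:
    # Dropped calls contribute 0 to the trait; dropout defaults to 0 and
    # trait effects at dropped-out markers are not part of any contract.
    g = geno[:, j].astype(float)
    g[g == MISSING] = 0.0
    return g


def simulate_survival(
    cohort: Cohort,
    marker_id: str,
    hr_per_allele: float,
    hr_cv: float = 0.0,
    n_events: int = 100,
    seed: int = 0,
) -> Cohort:
    """Attach exponential survival outcomes driven by one SNP.

    Survival times are exponential with rate proportional to
    ``HR**genotype``; the realized HR is drawn once per call from
    Normal(hr_per_allele, hr_cv * hr_per_allele) truncated positive.
    The censoring threshold is placed at the ``n_events``-th smallest
    time so exactly ``n_events`` individuals experience the event.
    """
    n = cohort.n_individuals
    if not (0 < n_events <= n):
        raise ValueError(f"n_events must be in 1..{n}")
    if hr_per_allele <= 0:
        raise ValueError("hr_per_allele must be positive")
    j = cohort.panel.index_of(marker_id)
    rng = np.random.default_rng(seed)
    hr = rng.normal(hr_per_allele, hr_cv * hr_per_allele) if hr_cv > 0 else hr_per_allele
    while hr <= 0:
        hr = rng.normal(hr_per_allele, hr_cv * hr_per_allele)
    g = cohort.genotypes[:, j].astype(float)
    g[g == MISSING] = 0.0
    rate = hr**g
    times = rng.exponential(1.0 / rate)
    order = np.sort(times)
    threshold = order[n_events - 1]
    event = times <= threshold
    observed = np.minimum(times, threshold)
    return cohort.replace(survival_time=observed, event_flag=event)


def sample_unrelated(
    cohort: Cohort,
    n_groups: int = 100,
    group_size: Optional[int] = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Overlapping groups of mutually unrelated individuals.

    Each group takes one uniformly chosen member per family; if
    ``group_size`` is given, that many families are subsampled without
    replacement per group.  Mirrors the resampling scheme used when a
    family-aware regression is unavailable.
    """
    fam = cohort.family_id
    families: dict = {}
    for i, f in enumerate(fam):
        families.setdefault(f, []).append(i)
    fam_members = [np.asarray(v) for v in families.values()]
    n_fam = len(fam_members)
    if group_size is not None and group_size > n_fam:
        raise ValueError(f"requested group size {group_size} exceeds {n_fam} families")
    rng = np.random.default_rng(seed)
    groups = []
    for _ in range(n_groups):
        if group_size is None:
            chosen = fam_members
        else:
            sel = rng.choice(n_fam, size=group_size, replace=False)
            chosen = [fam_members[k] for k in sel]
        idx = np.array([members[rng.integers(len(members))] for members in chosen])
        groups.append(np.sort(idx))
    return groups
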