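import numpy as np
import pytest

from admixlpa import (
    CohortConfig,
    MarkerPanel,
    TraitModel,
    simulate_aim_panel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    """Two-chromosome AIM panel, 30 markers each, well differentiated."""
    return simulate_aim_panel(n_chrom=2, markers_per_chrom=30, seed=11)


@pytest.fixture(scope="session")
def trait_snp(small_panel) -> str:
    """A chromosome-1 marker whose counted allele is much commoner in Africans."""
    diff = small_panel.f_afr - small_panel.f_eur
    on1 = np.flatnonzero((small_panel.chrom == "1") & (diff > 0.5))
    return str(small_panel.marker_id[on1[len(on1) // 2]])


@pytest.fixture(scope="session")
def small_cohort(small_panel, trait_snp):
    tm = TraitModel(
        global_ancestry_effect=0.9,
        snp_effects={trait_snp: np.log(1.254)},
        residual_sd=0.6,
    )
    cfg = CohortConfig(n_individuals=400, seed=7, family_sizes=(0.6, 0.3, 0.1))
    return simulate_cohort(cfg, small_panel, tm)


def tiny_panel(freqs, spacing=0.05, chrom="1"):
    """Panel on one chromosome from a list of (f_afr, f_eur) pairs."""
    m = len(freqs)
    return MarkerPanel(
        marker_id=np.array([f"m{j}" for j in range(m)], dtype=object),
        chrom=np.array([chrom] * m, dtype=object),
        pos_bp=np.arange(1, m + 1) * 1000,
        pos_morgan=np.arange(m) * spacing,
        f_afr=np.array([f[0] for f in freqs]),
        f_eur=np.array([f[1] for f in freqs]),
    )
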