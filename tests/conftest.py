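import itertools
import math

import numpy as np
import pandas as pd
import pytest

from grstrata.panel import SnpPanel, SnpWeight


@pytest.fixture
def tiny_panel() -> SnpPanel:
    """Three hand-written SNPs with easy ORs/frequencies."""
    return SnpPanel(
        name="tiny-3",
        snps=(
            SnpWeight("rs1", "1", 100, "A", "G", 1.5, 0.3),
            SnpWeight("rs2", "2", 200, "C", "T", 1.2, 0.5),
            SnpWeight("rs3", "3", 300, "G", "T", 2.0, 0.1),
        ),
    )


@pytest.fixture
def one_snp_panel() -> SnpPanel:
    return SnpPanel(
        name="one", snps=(SnpWeight("rs1", "1", 100, "A", "G", 1.5, 0.3),)
    )


def brute_force_grs(panel: SnpPanel, counts: dict[str, int]) -> float:
    """Independent scalar GRS oracle: plain-float product of per-genotype
    risks standardized by the HWE population mean, no shared code paths."""
    total = 1.0
    for snp in panel:
        p = snp.risk_allele_freq
        freqs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        mean = sum(snp.allelic_or**g * f for g, f in zip(range(3), freqs))
        total *= snp.allelic_or ** counts[snp.rsid] / mean
    return total


def all_genotype_matrix(panel: SnpPanel) -> pd.DataFrame:
    """One subject per possible genotype combination (3^k subjects)."""
    combos = list(itertools.product(range(3), repeat=len(panel)))
    data = np.array(combos, dtype=float).T
    return pd.DataFrame(
        data,
        index=pd.Index(panel.rsids, name="rsid"),
        columns=[f"G{i}" for i in range(len(combos))],
    )


def logistic_cohort(
    rng: np.random.Generator,
    n: int,
    beta_bmi: dict[str, float],
    intercept_by_stratum: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Minimal cohort for fit tests: stratum labels assigned directly (not
    via a GRS), outcome logistic in BMI with stratum-specific slope."""
    strata = rng.choice(list(beta_bmi), size=n)
    bmi = rng.normal(24, 3, n)
    icpt = intercept_by_stratum or {s: -24 * b for s, b in beta_bmi.items()}
    lp = np.array([icpt[s] + beta_bmi[s] * x for s, x in zip(strata, bmi)])
    y = rng.random(n) < 1 / (1 + np.exp(-lp))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "bmi": bmi,
            "stratum": pd.Categorical(
                strata, categories=["low", "intermediate", "high"], ordered=True
            ),
            "pca": y,
        }
    )
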