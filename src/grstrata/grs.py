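"""Population-standardized multiplicative genetic risk score (GRS).

For each panel SNP with allelic odds ratio OR and risk-allele frequency p:

1. the genotypic ORs under a multiplicative (log-additive) model are
   ``(1, OR, OR^2)`` for 0, 1, 2 risk alleles;
2. genotype frequencies follow Hardy–Weinberg equilibrium,
   ``((1-p)^2, 2p(1-p), p^2)``;
3. the population-mean risk is ``m = sum_g OR_g * f_g`` and each genotype's
   risk *relative to the population average* is ``OR_g / m`` — by
   construction the population expectation of this relative risk is exactly 1;
4. a subject's GRS is the product of per-SNP relative risks across the panel.

A GRS of 1 therefore means population-average genetic risk; the score is
cohort-independent because standardization uses the panel's stated
frequencies, not the observed sample.  Products are accumulated in log space
so large panels cannot underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GrstrataError
from .panel import SnpPanel, SnpWeight

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("neutral", "drop_subject")


def genotypic_or(allelic_or: float) -> tuple[float, float, float]:
    """Genotypic odds ratios (1, OR, OR²) under the multiplicative model."""
    if not allelic_or > 0:
        raise ValueError(f"allelic OR must be > 0, got {allelic_or}")
    return (1.0, float(allelic_or), float(allelic_or) ** 2)


def hwe_genotype_freqs(risk_allele_freq: float) -> tuple[float, float, float]:
    """Hardy–Weinberg genotype frequencies ((1−p)², 2p(1−p), p²).

    Indexed by risk-allele count 0, 1, 2; sums to 1 exactly up to rounding.
    """
    p = float(risk_allele_freq)
    if not 0.0 < p < 1.0:
        raise ValueError(f"risk allele frequency must be in (0,1), got {p}")
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


@dataclass(frozen=True)
class SnpRiskProfile:
    """Per-genotype risk of one SNP relative to the population average."""

    rsid: str
    genotypic_or: tuple[float, float, float]
    genotype_freq: tuple[float, float, float]
    mean_risk: float
    relative_risk: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.genotype_freq) - 1.0) > 1e-12:
            raise GrstrataError(f"{self.rsid}: genotype frequencies do not sum to 1")
        expected = sum(r * f for r, f in zip(self.relative_risk, self.genotype_freq))
        if abs(expected - 1.0) > 1e-12:
            raise GrstrataError(
                f"{self.rsid}: population-expected relative risk is {expected}, not 1"
            )


def snp_risk_profile(snp: SnpWeight) -> SnpRiskProfile:
    """Standardize one SNP: relative risk per genotype, population mean 1."""
    g_or = genotypic_or(snp.allelic_or)
    freqs = hwe_genotype_freqs(snp.risk_allele_freq)
    mean_risk = sum(o * f for o, f in zip(g_or, freqs))
    rel = tuple(o / mean_risk for o in g_or)
    return SnpRiskProfile(
        rsid=snp.rsid,
        genotypic_or=g_or,
        genotype_freq=freqs,
        mean_risk=mean_risk,
        relative_risk=rel,  # type: ignore[arg-type]
    )


def _log_relative_risk_table(panel: SnpPanel) -> np.ndarray:
    """(n_snps, 3) array of log relative risks, rows in panel order."""
    return np.log(
        [snp_risk_profile(s).relative_risk for s in panel], dtype=float
    )


def compute_grs(
    genotypes: pd.DataFrame,
    panel: SnpPanel,
    missing_policy: str = "neutral",
) -> pd.DataFrame:
    """Compute each subject's GRS over a panel.

    Parameters
    ----------
    genotypes
        Risk-allele count matrix: index = rsid, columns = subject IDs,
        values in {0, 1, 2} or NaN for missing.  Must cover every panel rsid.
    panel
        The SNP panel supplying ORs and population frequencies.
    missing_policy
        ``"neutral"`` (default): a missing genotype contributes a factor of 1,
        i.e. population-average risk.  ``"drop_subject"``: any missingness
        excludes the subject (logged).

    Returns
    -------
    DataFrame with columns ``subject_id, grs, n_snps_used, n_snps_missing``;
    subjects excluded by policy (or with every genotype missing) are absent.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {MISSING_POLICIES}, got {missing_policy!r}"
        )
    absent = [r for r in panel.rsids if r not in genotypes.index]
    if absent:
        raise GrstrataError(f"genotype matrix lacks panel rsids: {absent}")

    counts = genotypes.loc[panel.rsids].to_numpy(dtype=float)  # (snps, subjects)
    bad = counts[~np.isnan(counts)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise GrstrataError("genotype matrix contains counts outside {0,1,2}")

    log_rel = _log_relative_risk_table(panel)  # (snps, 3)
    missing = np.isnan(counts)
    idx = np.where(missing, 0, counts).astype(int)
    per_snp_log = np.take_along_axis(log_rel, idx, axis=1)
    per_snp_log = np.where(missing, 0.0, per_snp_log)  # neutral factor 1

    log_grs = per_snp_log.sum(axis=0)
    n_missing = missing.sum(axis=0)
    n_used = len(panel) - n_missing

    subjects = list(genotypes.columns)
    rows = []
    for j, sid in enumerate(subjects):
        if n_used[j] == 0:
            logger.warning("subject %s: all panel genotypes missing; excluded", sid)
            continue
        if missing_policy == "drop_subject" and n_missing[j] > 0:
            logger.info(
                "subject %s: %d missing genotype(s); excluded under drop_subject",
                sid,
                n_missing[j],
            )
            continue
        rows.append(
            {
                "subject_id": str(sid),
                "grs": float(np.exp(log_grs[j])),
                "n_snps_used": int(n_used[j]),
                "n_snps_missing": int(n_missing[j]),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "grs", "n_snps_used", "n_snps_missing"])


def log_grs(results: pd.DataFrame) -> pd.Series:
    """Natural log of the multiplicative GRS (used for diagnostics)."""
    return np.log(results["grs"]).rename("log_grs")
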