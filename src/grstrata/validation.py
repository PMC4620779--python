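"""Monte-Carlo validation studies of the interaction estimator.

Two repeated-simulation studies characterize the BMI × GRS-stratum
interaction test end-to-end (simulate → score → stratify → fit):

* **type-I calibration** — with identical BMI slopes in every stratum the
  high-vs-low interaction test should reject at its nominal level;
* **parameter recovery** — with a known high-vs-low slope ratio built into
  the generator, the estimate should be unbiased and its Wald 95% CI should
  cover the truth at the nominal rate.

Replicate seeds are spawned from a single master seed, so each study is
fully reproducible from one integer.
"""

from __future__ import annotations

import logging

import numpy as np

from .analysis import fit_interaction, build_cohort
from .errors import GrstrataError
from .grs import compute_grs
from .panel import SnpPanel, synthetic_panel
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds below 2**31 so they stay plain C ints everywhere
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _high_vs_low_fit(
    rep_seed: int,
    n_subjects: int,
    beta_bmi_by_stratum: tuple[float, float, float],
    panel: SnpPanel,
):
    cfg = SimConfig(
        seed=rep_seed,
        n_subjects=n_subjects,
        panel=panel,
        beta_bmi_by_stratum=beta_bmi_by_stratum,
    )
    genotypes, phenotypes = simulate_cohort(cfg)
    cohort = build_cohort(phenotypes, compute_grs(genotypes, panel))
    fits = fit_interaction(cohort, outcome="pca")
    return next(f for f in fits if f.contrast == "high")


def interaction_null_rejection_rate(
    seed: int,
    n_replicates: int = 500,
    n_subjects: int = 2000,
    alpha: float = 0.05,
    panel: SnpPanel | None = None,
    beta_bmi: float = 0.07,
) -> dict:
    """Rejection rate of the high-vs-low interaction test under the null.

    Every stratum gets the same per-unit-BMI slope, so the true interaction
    OR is 1 and the test should reject at rate ``alpha``.  Returns the
    observed rate, the replicate counts, and the binomial SE of the rate.
    """
    panel = panel or synthetic_panel()
    rejections = 0
    completed = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        try:
            fit = _high_vs_low_fit(
                rep_seed, n_subjects, (beta_bmi,) * 3, panel
            )
        except GrstrataError as exc:  # rare degenerate replicate
            logger.warning("replicate (seed %d) skipped: %s", rep_seed, exc)
            continue
        completed += 1
        if fit.p_interaction < alpha:
            rejections += 1
    rate = rejections / completed
    return {
        "rate": rate,
        "alpha": alpha,
        "n_replicates": completed,
        "n_failed": n_replicates - completed,
        "se": float(np.sqrt(alpha * (1 - alpha) / completed)),
    }


def interaction_recovery_study(
    seed: int,
    true_or: float = 1.2,
    n_replicates: int = 200,
    n_subjects: int = 5000,
    panel: SnpPanel | None = None,
    beta_bmi_low: float = 0.0,
) -> dict:
    """Recovery of a known high-vs-low interaction OR.

    The generator gives the high stratum a per-unit-BMI log-odds slope
    ``beta_bmi_low + log(true_or)``, so the true high-vs-low interaction OR
    is ``true_or``.  Returns the mean estimate, the 95% Wald CI coverage of
    the truth, and the replicate counts.
    """
    panel = panel or synthetic_panel()
    beta = (beta_bmi_low, beta_bmi_low, beta_bmi_low + float(np.log(true_or)))
    estimates = []
    covered = 0
    completed = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        try:
            fit = _high_vs_low_fit(rep_seed, n_subjects, beta, panel)
        except GrstrataError as exc:
            logger.warning("replicate (seed %d) skipped: %s", rep_seed, exc)
            continue
        completed += 1
        estimates.append(fit.or_interaction)
        if fit.ci_low <= true_or <= fit.ci_high:
            covered += 1
    return {
        "true_or": true_or,
        "mean_or": float(np.mean(estimates)),
        "ci_coverage": covered / completed,
        "n_replicates": completed,
        "n_failed": n_replicates - completed,
    }
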