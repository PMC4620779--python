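"""GRS-stratified analysis of biopsy outcome.

Subjects are stratified into low / intermediate / high genetic risk by the
empirical tertiles of their GRS.  Within each stratum an unconditional
logistic regression of the biopsy outcome on BMI plus adjustment covariates
yields the per-stratum BMI odds ratio.  Effect modification is tested in a
single pooled model with BMI, stratum dummies (low = reference) and
BMI × stratum product terms: the exponentiated product-term coefficient is
the interaction OR — the ratio of per-unit-BMI odds ratios between that
stratum and the low-GRS reference — and its Wald p-value is the interaction
test.

Default adjustment set: age, log-PSA, prostate volume, DRE finding and
family history (the covariates associated with outcome in this cohort
design).  CIs and p-values are Wald-based.  No multiplicity correction is
applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateOutcomeError, FitError, InsufficientDataError

logger = logging.getLogger(__name__)

STRATA = ("low", "intermediate", "high")
DEFAULT_COVARIATES = ("age", "log_psa", "prostate_volume", "dre_abnormal", "family_history")

CONTINUOUS_BASELINE_VARS = ("age", "bmi", "psa", "prostate_volume", "grs")
CATEGORICAL_BASELINE_VARS = (
    "dre_abnormal",
    "family_history",
    "smoking",
    "drinking",
    "hypertension",
    "diabetes",
    "pca",
    "high_grade",
)


@dataclass(frozen=True)
class StratumFit:
    """Adjusted per-unit-BMI odds ratio within one GRS stratum."""

    stratum: str
    bmi_or: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "bmi_or": self.bmi_or,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "coefficients": dict(sorted(self.coefficients.items())),
        }


@dataclass(frozen=True)
class InteractionFit:
    """BMI × stratum interaction contrast against the low-GRS reference."""

    reference: str
    contrast: str
    or_interaction: float
    ci_low: float
    ci_high: float
    p_interaction: float
    n: int
    covariate_estimates: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "contrast": self.contrast,
            "or_interaction": self.or_interaction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_interaction": self.p_interaction,
            "n": self.n,
            "covariate_estimates": dict(sorted(self.covariate_estimates.items())),
        }


def assign_tertiles(grs_values) -> pd.Categorical:
    """Assign low/intermediate/high by the empirical 1/3 and 2/3 quantiles.

    Values strictly below the first tertile cut are ``low``, values in
    [q1/3, q2/3) are ``intermediate``, values ≥ q2/3 are ``high``; tied
    values therefore share a stratum.  Fewer than three non-missing values
    raise :class:`~grstrata.errors.InsufficientDataError`.
    """
    values = np.asarray(pd.Series(grs_values), dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 3:
        raise InsufficientDataError(
            f"tertile assignment needs >= 3 non-missing GRS values, got {finite.size}"
        )
    q1, q2 = np.quantile(finite, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(values < q1, "low", np.where(values < q2, "intermediate", "high"))
    labels = labels.astype(object)
    labels[np.isnan(values)] = None
    cat = pd.Categorical(labels, categories=list(STRATA), ordered=True)
    present = set(cat.dropna())
    if len(present) < 3:
        warnings.warn(
            "degenerate GRS distribution: tertile cuts produced strata "
            f"{sorted(present, key=STRATA.index)} only",
            stacklevel=2,
        )
    return cat


def build_cohort(phenotypes: pd.DataFrame, grs_results: pd.DataFrame) -> pd.DataFrame:
    """Merge phenotypes with GRS results; add log-PSA and the GRS stratum."""
    merged = phenotypes.merge(
        grs_results[["subject_id", "grs"]], on="subject_id", how="inner"
    )
    dropped = len(phenotypes) - len(merged)
    if dropped:
        logger.warning("%d subject(s) without a GRS dropped from the cohort", dropped)
    merged["log_psa"] = np.log(merged["psa"])
    merged["stratum"] = assign_tertiles(merged["grs"])
    return merged


def _outcome_vector(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "pca":
        return cohort["pca"].astype(bool).to_numpy().astype(float)
    if outcome == "high_grade":
        # high-grade disease vs everything else (incl. negative biopsies)
        return cohort["high_grade"].fillna(False).astype(bool).to_numpy().astype(float)
    raise ValueError(f"outcome must be 'pca' or 'high_grade', got {outcome!r}")


def _design(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    for col in columns:
        if col not in cohort.columns:
            raise ValueError(f"covariate {col!r} not in cohort table")
        X[col] = cohort[col].astype(float)
    return X


def _drop_constant_covariates(X: pd.DataFrame, context: str) -> pd.DataFrame:
    """Drop zero-variance adjustment covariates (a rare covariate can be
    constant within a small stratum, which would make the design singular).
    BMI itself being constant is unrecoverable and raises."""
    for col in list(X.columns):
        if col == "const":
            continue
        if X[col].nunique() <= 1:
            if col == "bmi" or col.startswith(("bmi_x_", "stratum_")):
                raise FitError(f"{context}: design column {col!r} is constant")
            logger.warning("%s: covariate %r is constant; dropped from the fit", context, col)
            X = X.drop(columns=[col])
    return X


def _drop_separating_covariates(X: pd.DataFrame, y: np.ndarray, context: str) -> pd.DataFrame:
    """Drop binary adjustment covariates that are quasi-completely separated
    from the outcome (a zero cell in their 2×2 table), which would send the
    MLE to infinity.  Only adjustment covariates are droppable; separation
    involving BMI or the stratum terms still raises downstream."""
    for col in list(X.columns):
        if col in ("const", "bmi") or col.startswith(("bmi_x_", "stratum_")):
            continue
        x = X[col].to_numpy()
        if len(np.unique(x)) != 2:
            continue
        hi = x == x.max()
        cells = [y[hi].sum(), (1 - y[hi]).sum(), y[~hi].sum(), (1 - y[~hi]).sum()]
        if 0 in cells:
            logger.warning(
                "%s: covariate %r quasi-separates the outcome; dropped from the fit",
                context,
                col,
            )
            X = X.drop(columns=[col])
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame, context: str):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise FitError(f"{context}: logistic fit failed ({exc})") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"{context}: logistic fit did not converge")
    if np.any(~np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
        raise FitError(f"{context}: quasi-separation (unbounded coefficients)")
    return res


def fit_stratum_bmi_or(
    cohort: pd.DataFrame,
    stratum: str,
    outcome: str = "pca",
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> StratumFit:
    """Adjusted BMI odds ratio for the outcome within one GRS stratum.

    Maximum-likelihood logistic fit of the outcome on BMI + covariates among
    subjects of the stratum; returns OR = exp(BMI coefficient) with Wald 95%
    CI and p-value.
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}, got {stratum!r}")
    sub = cohort.loc[cohort["stratum"] == stratum]
    y = _outcome_vector(sub, outcome)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(
            f"stratum {stratum!r}: outcome {outcome!r} has a single class (n={len(y)})"
        )
    X = _drop_constant_covariates(_design(sub, ["bmi", *covariates]), f"stratum {stratum!r}")
    X = _drop_separating_covariates(X, y, f"stratum {stratum!r}")
    res = _fit_logit(y, X, f"stratum {stratum!r}")
    ci = res.conf_int().loc["bmi"]
    return StratumFit(
        stratum=stratum,
        bmi_or=float(np.exp(res.params["bmi"])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(res.pvalues["bmi"]),
        n=int(len(sub)),
        coefficients={k: float(v) for k, v in res.params.items()},
    )


def fit_interaction(
    cohort: pd.DataFrame,
    outcome: str = "pca",
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> list[InteractionFit]:
    """BMI × GRS-stratum interaction on the outcome, low stratum as reference.

    Fits one pooled logistic model with BMI, intermediate/high stratum
    dummies, BMI × stratum product terms and the covariates.  Returns an
    :class:`InteractionFit` per non-reference stratum whose
    ``or_interaction`` is the exponentiated product-term coefficient.
    """
    cohort = cohort.loc[cohort["stratum"].notna()].copy()
    for s in STRATA:
        ys = _outcome_vector(cohort.loc[cohort["stratum"] == s], outcome)
        if len(ys) == 0 or len(np.unique(ys)) < 2:
            raise DegenerateOutcomeError(
                f"stratum {s!r}: outcome {outcome!r} lacks both classes"
            )
    y = _outcome_vector(cohort, outcome)
    X = _design(cohort, ["bmi", *covariates])
    for s in ("intermediate", "high"):
        dummy = (cohort["stratum"] == s).astype(float)
        X[f"stratum_{s}"] = dummy
        X[f"bmi_x_{s}"] = dummy * cohort["bmi"].astype(float)
    X = _drop_constant_covariates(X, "interaction model")
    X = _drop_separating_covariates(X, y, "interaction model")
    res = _fit_logit(y, X, "interaction model")
    fits = []
    for s in ("intermediate", "high"):
        term = f"bmi_x_{s}"
        ci = res.conf_int().loc[term]
        fits.append(
            InteractionFit(
                reference="low",
                contrast=s,
                or_interaction=float(np.exp(res.params[term])),
                ci_low=float(np.exp(ci[0])),
                ci_high=float(np.exp(ci[1])),
                p_interaction=float(res.pvalues[term]),
                n=int(len(cohort)),
                covariate_estimates={k: float(v) for k, v in res.params.items()},
            )
        )
    return fits


def fit_interaction_continuous(
    cohort: pd.DataFrame,
    outcome: str = "pca",
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> InteractionFit:
    """Sensitivity variant: continuous BMI × log-GRS product term.

    Keeps the full GRS information instead of tertile dummies; the returned
    ``or_interaction`` is per (BMI unit × log-GRS unit) and is not directly
    comparable to the tertile-contrast ORs.
    """
    cohort = cohort.loc[cohort["grs"].notna()].copy()
    y = _outcome_vector(cohort, outcome)
    X = _design(cohort, ["bmi", *covariates])
    X["log_grs"] = np.log(cohort["grs"].astype(float))
    X["bmi_x_log_grs"] = X["bmi"] * X["log_grs"]
    X = _drop_separating_covariates(_drop_constant_covariates(X, "continuous interaction"), y, "continuous interaction")
    res = _fit_logit(y, X, "continuous interaction model")
    ci = res.conf_int().loc["bmi_x_log_grs"]
    return InteractionFit(
        reference="log_grs=0 (population-average risk)",
        contrast="bmi_x_log_grs",
        or_interaction=float(np.exp(res.params["bmi_x_log_grs"])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_interaction=float(res.pvalues["bmi_x_log_grs"]),
        n=int(len(cohort)),
        covariate_estimates={k: float(v) for k, v in res.params.items()},
    )


def baseline_table(cohort: pd.DataFrame, group_by: str = "stratum") -> pd.DataFrame:
    """Baseline characteristics by GRS stratum (or by biopsy outcome).

    Continuous variables are summarized as median (IQR) and compared with
    the Kruskal–Wallis rank test; categorical variables as count (%) with a
    chi-squared test.  Constant variables get p = NA with a warning.
    """
    if group_by == "stratum":
        groups = [(s, cohort.loc[cohort["stratum"] == s]) for s in STRATA]
        groups = [(k, g) for k, g in groups if len(g)]
    elif group_by == "outcome":
        groups = [
            ("negative", cohort.loc[~cohort["pca"].astype(bool)]),
            ("pca", cohort.loc[cohort["pca"].astype(bool)]),
        ]
    else:
        raise ValueError(f"group_by must be 'stratum' or 'outcome', got {group_by!r}")
    if len(groups) < 2:
        raise InsufficientDataError("baseline table needs >= 2 groups")

    rows = []
    for var in CONTINUOUS_BASELINE_VARS:
        if var not in cohort.columns:
            continue
        row: dict[str, object] = {"variable": var, "type": "continuous"}
        samples = []
        for key, g in groups:
            x = g[var].astype(float).dropna()
            q1, med, q3 = np.percentile(x, [25, 50, 75]) if len(x) else (np.nan,) * 3
            row[str(key)] = f"{med:.2f} ({q1:.2f}-{q3:.2f})"
            samples.append(x.to_numpy())
        if np.ptp(np.concatenate(samples)) == 0:
            warnings.warn(f"baseline variable {var!r} is constant; p set to NA", stacklevel=2)
            row["p_value"] = np.nan
        else:
            _, p = stats.kruskal(*samples)
            row["p_value"] = float(p) if np.isfinite(p) else np.nan
        rows.append(row)

    for var in CATEGORICAL_BASELINE_VARS:
        if var not in cohort.columns:
            continue
        if group_by == "outcome" and var in ("pca", "high_grade"):
            continue
        row = {"variable": var, "type": "categorical"}
        table = []
        for key, g in groups:
            x = g[var]
            if str(x.dtype) == "boolean":
                x = x.fillna(False)
            x = x.astype(bool)
            n_true = int(x.sum())
            pct = 100.0 * n_true / len(x) if len(x) else np.nan
            row[str(key)] = f"{n_true} ({pct:.1f}%)"
            table.append([n_true, len(x) - n_true])
        table_arr = np.asarray(table)
        if (table_arr.sum(axis=0) == 0).any():
            warnings.warn(f"baseline variable {var!r} is constant; p set to NA", stacklevel=2)
            row["p_value"] = np.nan
        else:
            _, p, _, _ = stats.chi2_contingency(table_arr, correction=False)
            row["p_value"] = float(p)
        rows.append(row)

    cols = ["variable", "type"] + [str(k) for k, _ in groups] + ["p_value"]
    return pd.DataFrame(rows, columns=cols)
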