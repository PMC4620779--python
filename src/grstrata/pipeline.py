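"""End-to-end run: score → stratify → analyze → report.

A run takes one or more SNP panels, a genotype source (VCF or CSV matrix)
and a phenotype table, and emits per panel: the GRS table, the stratified
cohort, per-stratum BMI odds ratios, the interaction fits, a baseline
characteristics table, and a compact markdown summary shaped like a
per-stratum OR / interaction-test table.  results.json is serialized with
sorted keys so identical configs reproduce it byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import (
    DEFAULT_COVARIATES,
    STRATA,
    baseline_table,
    build_cohort,
    fit_interaction,
    fit_stratum_bmi_or,
)
from .errors import GrstrataError
from .grs import compute_grs
from .io import read_genotypes_csv, read_genotypes_vcf, read_phenotypes
from .panel import read_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and analysis options for one pipeline run."""

    panels: dict[str, str]  # name -> panel CSV path
    genotypes: str  # .vcf or .csv
    phenotypes: str
    out_dir: str
    outcome: str = "pca"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    missing_policy: str = "neutral"

    def __post_init__(self) -> None:
        if self.outcome not in ("pca", "high_grade"):
            raise ValueError(f"outcome must be 'pca' or 'high_grade', got {self.outcome!r}")
        if not self.panels:
            raise ValueError("at least one panel is required")
        for label, p in {**self.panels, "genotypes": self.genotypes, "phenotypes": self.phenotypes}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{label}: path does not exist: {p}")

    def hash(self) -> str:
        blob = json.dumps(
            {
                "panels": dict(sorted(self.panels.items())),
                "genotypes": self.genotypes,
                "phenotypes": self.phenotypes,
                "outcome": self.outcome,
                "covariates": list(self.covariates),
                "missing_policy": self.missing_policy,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _render_report(panel_results: dict, outcome: str) -> str:
    """Markdown summary: per-stratum adjusted BMI ORs and interaction tests."""
    lines = [f"# Adjusted BMI odds ratios for {outcome} by GRS stratum", ""]
    for name, res in panel_results.items():
        lines += [f"## Panel: {name}", ""]
        lines.append("| GRS stratum | n | BMI OR (95% CI) | p |")
        lines.append("|---|---|---|---|")
        for s in res["strata"]:
            lines.append(
                f"| {s['stratum']} | {s['n']} | "
                f"{s['bmi_or']:.3f} ({s['ci_low']:.3f}-{s['ci_high']:.3f}) | "
                f"{s['p_value']:.3g} |"
            )
        lines.append("")
        lines.append("| Interaction (vs low) | OR (95% CI) | p |")
        lines.append("|---|---|---|")
        for i in res["interactions"]:
            lines.append(
                f"| {i['contrast']} | {i['or_interaction']:.3f} "
                f"({i['ci_low']:.3f}-{i['ci_high']:.3f}) | {i['p_interaction']:.3g} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; write the report bundle; return the results dict.

    Emits, under ``config.out_dir``: ``grs_<panel>.csv``, ``cohort_<panel>.csv``,
    ``baseline_table_<panel>.csv``, ``results.json``, ``report.md`` and
    ``run.log``.  Any stage failure aborts with the stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"grstrata {__version__} (python {platform.python_version()})",
        f"config hash: {config.hash()}",
    ]

    try:
        phenotypes = read_phenotypes(config.phenotypes)
    except GrstrataError as exc:
        raise GrstrataError(f"stage panel_io (phenotypes): {exc}") from exc

    panel_results: dict[str, dict] = {}
    for name, panel_path in config.panels.items():
        try:
            panel = read_panel(panel_path, name=name)
            if config.genotypes.endswith(".vcf"):
                genotypes = read_genotypes_vcf(config.genotypes, panel)
            else:
                genotypes = read_genotypes_csv(config.genotypes).reindex(panel.rsids)
        except GrstrataError as exc:
            raise GrstrataError(f"stage panel_io (panel {name!r}): {exc}") from exc

        try:
            grs_results = compute_grs(genotypes, panel, config.missing_policy)
        except GrstrataError as exc:
            raise GrstrataError(f"stage grs_engine (panel {name!r}): {exc}") from exc
        grs_results.to_csv(out_dir / f"grs_{name}.csv", index=False)

        try:
            cohort = build_cohort(phenotypes, grs_results)
            strata_fits = [
                fit_stratum_bmi_or(cohort, s, config.outcome, config.covariates)
                for s in STRATA
            ]
            interactions = fit_interaction(cohort, config.outcome, config.covariates)
            baseline = baseline_table(cohort, group_by="stratum")
        except GrstrataError as exc:
            raise GrstrataError(f"stage cohort_analysis (panel {name!r}): {exc}") from exc

        cohort.to_csv(out_dir / f"cohort_{name}.csv", index=False)
        baseline.to_csv(out_dir / f"baseline_table_{name}.csv", index=False)
        panel_results[name] = {
            "n_subjects": int(len(cohort)),
            "outcome": config.outcome,
            "covariates": list(config.covariates),
            "strata": [f.to_dict() for f in strata_fits],
            "interactions": [f.to_dict() for f in interactions],
        }
        log_lines.append(f"panel {name}: {len(panel)} SNPs, {len(cohort)} subjects analyzed")

    results = {"config_hash": config.hash(), "panels": panel_results}
    (out_dir / "results.json").write_text(
        json.dumps(results, sort_keys=True, indent=2) + "\n"
    )
    (out_dir / "report.md").write_text(_render_report(panel_results, config.outcome))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
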