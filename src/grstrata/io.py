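"""Genotype and phenotype IO.

Genotypes travel either as a plain rsID × subject CSV matrix of risk-allele
counts (0/1/2, empty cell = missing) or as VCF 4.x with GT fields.  When
reading VCF, panel sites are located by ID and then by chrom+pos; if the
panel's risk allele is the REF allele the ALT dosage is complemented
(2 − dosage).  A risk allele matching neither REF nor ALT is an error —
strand flips are deliberately never inferred, because silent flipping of
ambiguous SNPs is a classic polygenic-score failure mode.

Phenotypes are a per-subject CSV with the biopsy-cohort covariates (age,
BMI, PSA, prostate volume, DRE finding, family history, smoking, drinking,
hypertension, diabetes) and outcomes (pca, high_grade).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import AlleleMismatchError, PanelFormatError, PhenotypeValidationError
from .panel import SnpPanel

logger = logging.getLogger(__name__)

PHENOTYPE_BOOL_COLUMNS = [
    "dre_abnormal",
    "family_history",
    "smoking",
    "drinking",
    "hypertension",
    "diabetes",
    "pca",
    "high_grade",
]
PHENOTYPE_NUMERIC_COLUMNS = ["age", "bmi", "psa", "prostate_volume"]
PHENOTYPE_COLUMNS = ["subject_id"] + PHENOTYPE_NUMERIC_COLUMNS + PHENOTYPE_BOOL_COLUMNS

_TRUTHY = {"1", "yes", "true"}
_FALSY = {"0", "no", "false"}


def read_genotypes_csv(path: str | Path) -> pd.DataFrame:
    """Read an rsID × subject risk-allele-count matrix.

    First column = rsid, remaining columns = subject IDs; empty cells are
    missing.  Returns a float DataFrame (NaN = missing) indexed by rsid.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "rsid":
        raise PanelFormatError(f"{path}: first column must be 'rsid', got {df.columns[0]!r}")
    df = df.set_index("rsid")
    mat = df.astype(float)
    vals = mat.to_numpy()
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        bad_rows = mat.index[(~ok).any(axis=1)].tolist()
        raise PanelFormatError(f"{path}: counts outside {{0,1,2}} at rsids {bad_rows}")
    mat.columns = mat.columns.astype(str)
    return mat


def write_genotypes_csv(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write the count matrix; missing entries become empty cells."""
    out = genotypes.copy()
    out.index.name = "rsid"
    # render 0/1/2 without a trailing .0, missing as empty
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> pd.DataFrame:
    """Extract panel risk-allele counts from a VCF.

    Sites are matched by rsID (the VCF ID column), falling back to
    chrom+pos.  Panel SNPs absent from the VCF are missing for all subjects
    (with a warning).  Multi-allelic records are skipped with a warning.

    Raises
    ------
    AlleleMismatchError
        If the risk allele matches neither REF nor ALT at a located site.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    subjects = [str(s) for s in vcf.samples]
    by_rsid = {s.rsid: s for s in panel}
    by_locus = {(s.chrom, s.pos): s for s in panel}

    counts = pd.DataFrame(
        np.nan, index=pd.Index(panel.rsids, name="rsid"), columns=subjects
    )
    seen: set[str] = set()
    for var in vcf:
        snp = by_rsid.get(var.ID) or by_locus.get((str(var.CHROM), int(var.POS)))
        if snp is None or snp.rsid in seen:
            continue
        if len(var.ALT) != 1:
            logger.warning(
                "%s: site for %s is multi-allelic; treated as missing", path, snp.rsid
            )
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if {ref, alt} != {snp.risk_allele, snp.other_allele}:
            raise AlleleMismatchError(
                f"{snp.rsid}: risk/other alleles {snp.risk_allele}/{snp.other_allele} "
                f"do not match VCF REF/ALT {ref}/{alt} (strand flips are not auto-resolved)"
            )
        seen.add(snp.rsid)
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        dosage = np.asarray(var.gt_types, dtype=float)
        dosage[dosage == 3] = np.nan
        if snp.risk_allele == ref:
            dosage = 2.0 - dosage
        counts.loc[snp.rsid, :] = dosage
    absent = [r for r in panel.rsids if r not in seen]
    if absent:
        logger.warning("%s: panel rsids absent from VCF: %s", path, absent)
    return counts


def write_genotypes_vcf(
    genotypes: pd.DataFrame, panel: SnpPanel, path: str | Path
) -> None:
    """Write counts as a minimal VCF 4.2 (GT only).

    REF = other allele, ALT = risk allele, so the ALT dosage equals the
    risk-allele count; missing counts become ``./.``.
    """
    subjects = [str(c) for c in genotypes.columns]
    chroms = list(dict.fromkeys(s.chrom for s in panel))
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for snp in panel:
        row = genotypes.loc[snp.rsid]
        gts = [
            "./." if pd.isna(v) else gt_strings[int(v)] for v in row.to_numpy()
        ]
        lines.append(
            "\t".join(
                [
                    snp.chrom,
                    str(snp.pos),
                    snp.rsid,
                    snp.other_allele,
                    snp.risk_allele,
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_bool(series: pd.Series, column: str, path: str) -> pd.Series:
    def conv(v: object) -> object:
        if pd.isna(v) or (isinstance(v, str) and v.strip() == ""):
            return pd.NA
        s = str(v).strip().lower()
        if s.endswith(".0"):
            s = s[:-2]
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise PhenotypeValidationError(
            f"{path}: column {column!r} has unparseable boolean value {v!r}"
        )

    return series.map(conv).astype("boolean")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-subject phenotype/covariate table.

    Boolean columns accept 0/1/yes/no/true/false case-insensitively;
    ``high_grade`` may be empty for subjects without prostate cancer.

    Raises
    ------
    PhenotypeValidationError
        For BMI ≤ 0 or PSA ≤ 0 (naming the subject), a high-grade flag on a
        negative biopsy, or duplicate subject IDs.
    """
    path = str(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise PhenotypeValidationError(f"{path}: duplicate subject IDs {dups}")
    for col in PHENOTYPE_NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col])
    for col in PHENOTYPE_BOOL_COLUMNS:
        df[col] = _parse_bool(df[col], col, path)

    for col, label in (("bmi", "BMI"), ("psa", "PSA")):
        bad = df.loc[df[col] <= 0, "subject_id"].tolist()
        if bad:
            raise PhenotypeValidationError(
                f"{path}: {label} must be > 0; violated by subjects {bad}"
            )
    bad = df.loc[
        (df["high_grade"] == True) & (df["pca"] == False), "subject_id"  # noqa: E712
    ].tolist()
    if bad:
        raise PhenotypeValidationError(
            f"{path}: high_grade set while pca is false for subjects {bad}"
        )
    return df.reset_index(drop=True)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    """Write the phenotype table; booleans as 1/0, NA as empty."""
    out = phenotypes.copy()
    for col in PHENOTYPE_BOOL_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else int(v))
    out.to_csv(path, index=False)
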