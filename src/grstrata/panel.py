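"""SNP risk panels: the per-SNP weights a genetic risk score is built from.

A panel row carries the rsID, genomic position, risk/other allele, the
allelic odds ratio taken from an external association study, and the risk
allele frequency in the reference population.  Panels are stored as plain
CSV with the fixed schema::

    rsid,chrom,pos,risk_allele,other_allele,allelic_or,risk_allele_freq

The published 24-SNP prostate cancer panel lives in an external supplement,
so the package bundles a synthetic stand-in panel with the same shape (24
SNPs, plus a 7-SNP subset mirroring the overall / East-Asian panel pair).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import PanelFormatError, PanelValidationError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "risk_allele",
    "other_allele",
    "allelic_or",
    "risk_allele_freq",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpWeight:
    """One panel SNP: identity, alleles, allelic OR and population frequency."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    allelic_or: float
    risk_allele_freq: float

    def __post_init__(self) -> None:
        if self.risk_allele not in _NUCLEOTIDES:
            raise PanelValidationError(
                f"{self.rsid}: risk_allele {self.risk_allele!r} is not a single nucleotide"
            )
        if self.other_allele not in _NUCLEOTIDES:
            raise PanelValidationError(
                f"{self.rsid}: other_allele {self.other_allele!r} is not a single nucleotide"
            )
        if self.risk_allele == self.other_allele:
            raise PanelValidationError(
                f"{self.rsid}: risk and other allele are identical ({self.risk_allele})"
            )
        if not self.allelic_or > 0:
            raise PanelValidationError(
                f"{self.rsid}: allelic_or must be > 0, got {self.allelic_or}"
            )
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise PanelValidationError(
                f"{self.rsid}: risk_allele_freq must be in (0,1), got {self.risk_allele_freq}"
            )
        if self.pos < 1:
            raise PanelValidationError(f"{self.rsid}: pos must be >= 1 (1-based)")

    @property
    def strand_ambiguous(self) -> bool:
        """A/T or C/G SNPs cannot be strand-verified against a VCF."""
        return _COMPLEMENT[self.risk_allele] == self.other_allele


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, rsID-unique collection of :class:`SnpWeight`."""

    name: str
    snps: tuple[SnpWeight, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.snps) == 0:
            raise PanelValidationError(f"panel {self.name!r} is empty")
        seen: set[str] = set()
        for snp in self.snps:
            if snp.rsid in seen:
                raise PanelValidationError(
                    f"panel {self.name!r}: duplicate rsid {snp.rsid}"
                )
            seen.add(snp.rsid)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpWeight]:
        return iter(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def subset(self, rsids: list[str], name: str) -> "SnpPanel":
        by_id = {s.rsid: s for s in self.snps}
        missing = [r for r in rsids if r not in by_id]
        if missing:
            raise PanelValidationError(f"panel {self.name!r} lacks rsids: {missing}")
        return SnpPanel(name=name, snps=tuple(by_id[r] for r in rsids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": s.rsid,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "risk_allele": s.risk_allele,
                    "other_allele": s.other_allele,
                    "allelic_or": s.allelic_or,
                    "risk_allele_freq": s.risk_allele_freq,
                }
                for s in self.snps
            ],
            columns=PANEL_COLUMNS,
        )


def read_panel(path: str | Path, name: str | None = None) -> SnpPanel:
    """Read a panel CSV, validating every row.

    Rows violating a SnpWeight invariant raise
    :class:`~grstrata.errors.PanelValidationError` naming the rsID; a missing
    column raises :class:`~grstrata.errors.PanelFormatError` naming the
    column.  Strand-ambiguous (A/T, C/G) SNPs are accepted with a warning
    because their orientation cannot be verified against genotype data.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"chrom": str, "risk_allele": str, "other_allele": str})
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing required column {col!r}")
    snps = []
    for row in df.itertuples(index=False):
        snps.append(
            SnpWeight(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                risk_allele=str(row.risk_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                allelic_or=float(row.allelic_or),
                risk_allele_freq=float(row.risk_allele_freq),
            )
        )
    panel = SnpPanel(name=name or path.stem, snps=tuple(snps))
    ambiguous = [s.rsid for s in panel if s.strand_ambiguous]
    if ambiguous:
        warnings.warn(
            f"panel {panel.name!r}: strand-ambiguous (A/T or C/G) SNPs "
            f"{ambiguous}; orientation cannot be verified and will never be "
            "auto-flipped",
            stacklevel=2,
        )
    return panel


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel as CSV; ``read_panel`` round-trips it field-for-field."""
    panel.to_frame().to_csv(path, index=False)


def synthetic_panel(
    n_snps: int = 24, seed: int = 2012, name: str = "synthetic-24"
) -> SnpPanel:
    """Deterministically generate a synthetic stand-in risk panel.

    Allelic ORs are log-uniform in [1.05, 1.45] and risk-allele frequencies
    uniform in [0.1, 0.9] — the effect-size/frequency range typical of
    GWAS-derived prostate cancer panels.  Alleles are drawn to avoid
    strand-ambiguous pairs.  This is synthetic data, not the published panel.
    """
    rng = np.random.default_rng(seed)
    ors = np.exp(rng.uniform(np.log(1.05), np.log(1.45), size=n_snps))
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    # unambiguous allele pairs only (no A/T, no C/G)
    pairs = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
    snps = []
    for i in range(n_snps):
        risk, other = pairs[rng.integers(len(pairs))]
        if rng.random() < 0.5:
            risk, other = other, risk
        snps.append(
            SnpWeight(
                rsid=f"rs{9000000 + i}",
                chrom=str(1 + i % 22),
                pos=1_000_000 + 50_000 * i,
                risk_allele=risk,
                other_allele=other,
                allelic_or=round(float(ors[i]), 4),
                risk_allele_freq=round(float(freqs[i]), 4),
            )
        )
    return SnpPanel(name=name, snps=tuple(snps))


def bundled_panel(which: str = "overall") -> SnpPanel:
    """Load a bundled synthetic panel.

    ``which='overall'`` gives the 24-SNP stand-in, ``which='east-asian'``
    the 7-SNP subset mirroring the overall / East-Asian-specific panel pair.
    """
    ref = resources.files("grstrata").joinpath("data/synthetic_panel_24.csv")
    with resources.as_file(ref) as p:
        panel = read_panel(p, name="synthetic-24")
    if which == "overall":
        return panel
    if which == "east-asian":
        return panel.subset(panel.rsids[:7], name="synthetic-east-asian-7")
    raise ValueError(f"unknown bundled panel {which!r}")
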