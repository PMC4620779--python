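"""Exception hierarchy for the grstrata pipeline.

Every stage raises a subclass of :class:`GrstrataError` so the CLI can abort
with the offending stage, subject or SNP named.
"""


class GrstrataError(Exception):
    """Base class for all grstrata errors."""


class PanelFormatError(GrstrataError):
    """A panel/genotype/phenotype file is structurally malformed (e.g. a
    required column is absent)."""


class PanelValidationError(GrstrataError):
    """A row violates a domain invariant (OR <= 0, frequency outside (0,1),
    duplicate rsID, ...)."""


class AlleleMismatchError(GrstrataError):
    """The panel's risk allele matches neither REF nor ALT at a located VCF
    site.  Strand flips are never auto-resolved."""


class PhenotypeValidationError(GrstrataError):
    """A phenotype row violates an invariant (BMI <= 0, PSA <= 0, or a
    high-grade flag on a negative biopsy)."""


class InsufficientDataError(GrstrataError):
    """Too few observations for the requested operation (e.g. tertiles on
    fewer than three values)."""


class DegenerateOutcomeError(GrstrataError):
    """A stratum contains a single outcome class, so no odds ratio exists."""


class FitError(GrstrataError):
    """Logistic maximum likelihood failed: non-convergence or (quasi-)
    separation."""
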