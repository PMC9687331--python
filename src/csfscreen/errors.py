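"""Exception hierarchy for csfscreen.

All package-specific failures derive from :class:`CsfScreenError` so callers
can catch one base class; validation-type errors additionally derive from
``ValueError`` to behave well in generic code.
"""


class CsfScreenError(Exception):
    """Base class for all csfscreen errors."""


class InvalidConcentrationError(CsfScreenError, ValueError):
    """A concentration is missing, non-positive, or otherwise unusable."""


class UnsupportedAnalyteError(CsfScreenError, ValueError):
    """Operation requested for an analyte it is not defined for (e.g. a
    hyperbolic discrimination limit for albumin, which is the x-axis)."""


class UndefinedFractionError(CsfScreenError, ValueError):
    """Intrathecal fraction requested for a non-positive quotient; this is
    distinct from "no intrathecal synthesis" (a negative fraction)."""


class IncompleteSampleError(CsfScreenError, ValueError):
    """A sample lacks a CSF/serum pair required to build a quotient profile."""

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = missing


class BelowQuantificationError(CsfScreenError, ValueError):
    """CSF FLC-kappa below the assay's lower limit of quantification while
    the hard-reject policy is active."""


class IndeterminateReferenceStandardError(CsfScreenError):
    """Neither oligoclonal-band status nor any immunoglobulin pair is
    available, so the composite reference standard cannot be evaluated."""


class CannotScreenError(CsfScreenError):
    """FLC-kappa data required by the screening algorithm are missing; the
    sample needs the full conventional workup."""


class DuplicateSampleIdError(CsfScreenError, ValueError):
    """A cohort contains repeated sample identifiers."""


class EmptyCohortError(CsfScreenError, ValueError):
    """An operation that needs at least one sample received none."""


class UndefinedMetricError(CsfScreenError):
    """An accuracy metric has a zero denominator."""


class SchemaError(CsfScreenError, ValueError):
    """An input table is missing required columns."""


class GenerationError(CsfScreenError, ValueError):
    """A synthetic-cohort specification is infeasible."""


class NothingToPlotError(CsfScreenError, ValueError):
    """No profile carries the analyte requested for plotting."""
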