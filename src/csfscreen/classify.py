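"""Case definitions for intrathecal humoral immune responses.

A sample shows an *intrathecal humoral immune response* (the composite
reference standard) when it carries CSF-specific oligoclonal bands (OCB)
and/or a positive intrathecal fraction of IgG, IgA or IgM — unless the
quantitative Ig pattern is attributable to artificial blood contamination
from a traumatic puncture.

Blood admixture inflates the Ig quotients in proportion to serum gradient
and molecular size, producing an IgM-dominant pseudo-synthesis pattern.  The
contamination rule requires an erythrocyte count above 500/µL together with
a positive IgM fraction dominating whichever of IgA/IgG are also positive
(IF IgM > IF IgA > IF IgG over the participating analytes).  Contamination
discounts only the quantitative quotient-diagram flags: CSF-specific OCB are
not produced by serum admixture and still count toward the reference
standard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .errors import IndeterminateReferenceStandardError
from .reiber import (
    Analyte,
    IG_ANALYTES,
    OCBStatus,
    QuotientProfile,
    SampleRecord,
)

#: Erythrocyte count threshold (per µL) above which blood admixture can
#: mimic quantitative Ig synthesis.
ERYTHROCYTE_THRESHOLD_PER_UL = 500


@dataclass(frozen=True)
class SerumReferenceRange:
    """Serum FLCκ reference interval in mg/L (manufacturer specification)."""

    lower: float = 6.7
    upper: float = 22.4

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"reference range lower bound must be below upper bound, "
                f"got ({self.lower}, {self.upper})"
            )

    def exceeds(self, value: float) -> bool:
        return value > self.upper

    def below(self, value: float) -> bool:
        return value < self.lower


class ResponsePattern(str, enum.Enum):
    """Quantitative Ig synthesis pattern (OCB excluded), the one/two/
    three-class taxonomy of clinical cohort tables."""

    NONE = "none"
    IGG = "IgG"
    IGA = "IgA"
    IGM = "IgM"
    IGG_M = "IgG/M"
    IGA_M = "IgA/M"
    IGG_A = "IgG/A"
    IGG_A_M = "IgG/A/M"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_PATTERN_BY_FLAGS: dict[frozenset[Analyte], ResponsePattern] = {
    frozenset(): ResponsePattern.NONE,
    frozenset({Analyte.IGG}): ResponsePattern.IGG,
    frozenset({Analyte.IGA}): ResponsePattern.IGA,
    frozenset({Analyte.IGM}): ResponsePattern.IGM,
    frozenset({Analyte.IGG, Analyte.IGM}): ResponsePattern.IGG_M,
    frozenset({Analyte.IGA, Analyte.IGM}): ResponsePattern.IGA_M,
    frozenset({Analyte.IGG, Analyte.IGA}): ResponsePattern.IGG_A,
    frozenset({Analyte.IGG, Analyte.IGA, Analyte.IGM}): ResponsePattern.IGG_A_M,
}


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the case definitions for one sample.

    ``synthesis_flags`` records IF > 0 per measured analyte (FLCκ included).
    ``immune_response`` is the composite reference standard; when
    ``blood_contamination`` is true the quantitative Ig flags are discounted
    from it (OCB positivity still counts).  ``rationale`` lists the rule
    firings in evaluation order.
    """

    sample_id: str
    synthesis_flags: Mapping[Analyte, bool]
    ocb_positive: bool
    blood_contamination: bool
    immune_response: bool
    serum_flck_elevated: bool
    rationale: tuple[str, ...] = field(default_factory=tuple)

    @property
    def flck_synthesis(self) -> bool:
        """Index-test positivity: FLCκ intrathecal fraction > 0."""
        return bool(self.synthesis_flags.get(Analyte.FLCK, False))


def assess_blood_contamination(
    sample: SampleRecord, profile: QuotientProfile
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the blood-admixture rule, returning (verdict, notes).

    The rule fires only when all of: erythrocytes > 500/µL; IF(IgM) > 0; and
    the ordering IF IgM > IF IgA > IF IgG holds over whichever of IgA/IgG are
    measured and IF-positive (an IF-negative or unmeasured IgA/IgG does not
    block the rule — the chain is evaluated over the participating analytes).
    """
    fractions = profile.intrathecal_fraction
    if Analyte.IGM not in fractions:
        return False, ("blood-contamination rule not evaluable: IgM pair missing",)
    ec = sample.erythrocytes_csf
    if ec is None:
        return False, ("blood-contamination rule not evaluable: erythrocyte count missing",)
    if ec <= ERYTHROCYTE_THRESHOLD_PER_UL:
        return False, ()
    if_igm = fractions[Analyte.IGM]
    if if_igm <= 0:
        return False, ()
    chain: list[tuple[Analyte, float]] = [(Analyte.IGM, if_igm)]
    for analyte in (Analyte.IGA, Analyte.IGG):
        value = fractions.get(analyte)
        if value is not None and value > 0:
            chain.append((analyte, value))
    for (_, higher), (_, lower) in zip(chain, chain[1:]):
        if not higher > lower:
            return False, ()
    ordering = " > ".join(f"IF({a.value})={v:.1f}%" for a, v in chain)
    return True, (
        f"blood contamination: erythrocytes {ec}/µL > {ERYTHROCYTE_THRESHOLD_PER_UL}/µL "
        f"with IgM-dominant pattern {ordering}",
    )


def detect_blood_contamination(sample: SampleRecord, profile: QuotientProfile) -> bool:
    """Boolean form of :func:`assess_blood_contamination`."""
    verdict, _ = assess_blood_contamination(sample, profile)
    return verdict


def classify_sample(
    sample: SampleRecord,
    profile: QuotientProfile,
    serum_range: SerumReferenceRange | None = None,
) -> ClassificationResult:
    """Apply the case definitions to one sample.

    Raises :class:`IndeterminateReferenceStandardError` when OCB analysis was
    not done and no immunoglobulin pair was measured — such a sample cannot
    enter a diagnostic-accuracy table.
    """
    if serum_range is None:
        serum_range = SerumReferenceRange()

    measured_igs = [a for a in IG_ANALYTES if a in profile.intrathecal_fraction]
    if sample.ocb_status is OCBStatus.NOT_DONE and not measured_igs:
        raise IndeterminateReferenceStandardError(
            f"sample {sample.sample_id!r}: reference standard indeterminate "
            "(OCB not done and no immunoglobulin pair measured)"
        )

    rationale: list[str] = []
    flags = {a: v > 0 for a, v in profile.intrathecal_fraction.items()}
    for analyte in sorted(flags, key=lambda a: a.value):
        if flags[analyte]:
            rationale.append(
                f"IF({analyte.value}) = {profile.intrathecal_fraction[analyte]:.1f}% > 0"
            )

    ocb_positive = sample.ocb_status is OCBStatus.CSF_SPECIFIC_POSITIVE
    if ocb_positive:
        rationale.append("CSF-specific oligoclonal bands present")

    contamination, notes = assess_blood_contamination(sample, profile)
    rationale.extend(notes)

    quantitative_ig = any(flags.get(a, False) for a in IG_ANALYTES)
    if contamination and quantitative_ig:
        rationale.append(
            "quantitative Ig synthesis attributed to blood admixture; "
            "discounted from the reference standard"
        )
    immune_response = ocb_positive or (quantitative_ig and not contamination)
    rationale.append(
        "intrathecal humoral immune response"
        if immune_response
        else "no intrathecal humoral immune response"
    )

    serum_flck_elevated = serum_range.exceeds(sample.flck_serum)
    if serum_flck_elevated:
        rationale.append(
            f"serum FLCκ {sample.flck_serum} mg/L above reference range "
            f"(> {serum_range.upper} mg/L)"
        )

    return ClassificationResult(
        sample_id=sample.sample_id,
        synthesis_flags=flags,
        ocb_positive=ocb_positive,
        blood_contamination=contamination,
        immune_response=immune_response,
        serum_flck_elevated=serum_flck_elevated,
        rationale=tuple(rationale),
    )


def classify_response_pattern(result: ClassificationResult) -> ResponsePattern:
    """Map quantitative Ig synthesis flags to the one/two/three-class
    pattern taxonomy (OCB and FLCκ excluded).

    With unmeasured Ig analytes the pattern is computed over the measured
    subset, i.e. it is a lower bound on the true pattern.
    """
    positive = frozenset(
        a for a in IG_ANALYTES if result.synthesis_flags.get(a, False)
    )
    return _PATTERN_BY_FLAGS[positive]
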