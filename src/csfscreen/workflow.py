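"""FLCκ-first screening algorithm for routine CSF laboratory analysis.

After the basic CSF parameters (cell count, erythrocyte count, lactate,
total protein) are determined, FLCκ is measured in CSF and serum and its
quotient evaluated against the hyperbolic reference range.  The decision
logic is a fixed two-gate sequence:

1. serum FLCκ above the reference range → PROCEED with full Ig quotient
   diagrams and OCB analysis (an elevated serum level depresses the quotient
   and can mask intrathecal synthesis, so the screen is not trustworthy);
2. otherwise, FLCκ intrathecal fraction > 0 → PROCEED;
3. otherwise → the Ig and OCB analyses can be OMITTED.

The serum gate is evaluated first, so a sample that is both serum-elevated
and IF-positive is labelled with the serum trigger.  Clinical suspicion
(imaging, cytology) may always override an OMIT — the decision object carries
this as metadata, it is never automated.  Basic CSF parameters travel with
the sample but do not branch the algorithm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .classify import ClassificationResult, SerumReferenceRange, classify_sample
from .errors import (
    CannotScreenError,
    CsfScreenError,
    DuplicateSampleIdError,
    EmptyCohortError,
)
from .reiber import (
    Analyte,
    HyperbolicCoefficients,
    QuotientProfile,
    SampleRecord,
    build_profile,
)


class Action(str, enum.Enum):
    PROCEED_IG_AND_OCB = "PROCEED_IG_AND_OCB"
    OMIT_IG_AND_OCB = "OMIT_IG_AND_OCB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Trigger(str, enum.Enum):
    FLCK_IF_POSITIVE = "flck_if_positive"
    SERUM_FLCK_ELEVATED = "serum_flck_elevated"
    FLCK_IF_NEGATIVE_SERUM_NORMAL = "flck_if_negative_serum_normal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class WorkflowDecision:
    """Outcome of the screening algorithm for one sample.

    ``override_allowed`` is always true: clinical suspicion justifies a full
    workup regardless of an OMIT decision.  ``low_serum_flck`` flags a serum
    value below the reference range — informational only, the gate escalates
    solely on values above the range.
    """

    sample_id: str
    action: Action
    trigger: Trigger
    flck_if: float
    serum_flck: float
    override_allowed: bool = True
    low_serum_flck: bool = False

    @property
    def proceed(self) -> bool:
        return self.action is Action.PROCEED_IG_AND_OCB


def decide(
    sample: SampleRecord,
    profile: QuotientProfile,
    serum_range: SerumReferenceRange | None = None,
) -> WorkflowDecision:
    """Run the two-gate screening decision for one sample.

    Pure and deterministic; raises :class:`CannotScreenError` when the
    profile lacks an FLCκ entry (full conventional workup required).
    """
    if serum_range is None:
        serum_range = SerumReferenceRange()
    if Analyte.FLCK not in profile.intrathecal_fraction:
        raise CannotScreenError(
            f"sample {sample.sample_id!r}: FLCκ data missing; the screening "
            "algorithm cannot run — perform the full conventional workup"
        )
    flck_if = profile.intrathecal_fraction[Analyte.FLCK]
    serum_flck = float(sample.flck_serum)
    low = serum_range.below(serum_flck)

    if serum_range.exceeds(serum_flck):
        action, trigger = Action.PROCEED_IG_AND_OCB, Trigger.SERUM_FLCK_ELEVATED
    elif flck_if > 0:
        action, trigger = Action.PROCEED_IG_AND_OCB, Trigger.FLCK_IF_POSITIVE
    else:
        action, trigger = Action.OMIT_IG_AND_OCB, Trigger.FLCK_IF_NEGATIVE_SERUM_NORMAL

    return WorkflowDecision(
        sample_id=sample.sample_id,
        action=action,
        trigger=trigger,
        flck_if=flck_if,
        serum_flck=serum_flck,
        low_serum_flck=low,
    )


@dataclass(frozen=True)
class PipelineResult:
    """Per-sample triple produced by :func:`run_cohort`."""

    profile: QuotientProfile
    classification: ClassificationResult
    decision: WorkflowDecision

    @property
    def sample_id(self) -> str:
        return self.profile.sample_id


@dataclass(frozen=True)
class SampleError:
    """A per-sample failure collected during a batch run."""

    sample_id: str
    error_type: str
    message: str


@dataclass(frozen=True)
class CohortRun:
    """Batch result: one triple per successfully processed sample (input
    order preserved) plus an error report for the rest."""

    results: tuple[PipelineResult, ...]
    errors: tuple[SampleError, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.results)


def run_cohort(
    samples: Sequence[SampleRecord],
    coeff_table: Mapping[Analyte, HyperbolicCoefficients] | None = None,
    serum_range: SerumReferenceRange | None = None,
    lloq_policy: str = "clip",
) -> CohortRun:
    """Run profile building, classification and the screening decision over
    a cohort.

    Per-sample errors (incomplete records, indeterminate reference standard,
    unscreenable samples) are collected into the error report rather than
    aborting the batch.  Duplicate sample ids are a batch-level validation
    error raised before any computation.
    """
    if not samples:
        raise EmptyCohortError("cohort is empty")
    seen: set[str] = set()
    duplicates = sorted(
        {s.sample_id for s in samples if s.sample_id in seen or seen.add(s.sample_id)}
    )
    if duplicates:
        raise DuplicateSampleIdError(f"duplicate sample ids: {duplicates}")

    results: list[PipelineResult] = []
    errors: list[SampleError] = []
    for sample in samples:
        try:
            profile = build_profile(sample, coeff_table, lloq_policy=lloq_policy)
            classification = classify_sample(sample, profile, serum_range)
            decision = decide(sample, profile, serum_range)
        except CsfScreenError as exc:
            errors.append(
                SampleError(
                    sample_id=sample.sample_id,
                    error_type=type(exc).__name__,
                    message=str(exc),
                )
            )
            continue
        results.append(PipelineResult(profile, classification, decision))
    return CohortRun(results=tuple(results), errors=tuple(errors))
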