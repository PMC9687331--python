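"""Diagnostic-accuracy evaluation of the FLCκ index test and the screening
workflow against the composite reference standard.

Two evaluation modes exist and are recorded in the report header:

* ``index_test`` — positivity is FLCκ intrathecal fraction > 0 alone
  (the contingency-table analysis of the original cohorts);
* ``workflow`` — positivity is a PROCEED decision of the screening
  algorithm, which additionally escalates serum-elevated samples.

All four accuracy metrics are kept as exact rationals
(:class:`fractions.Fraction`) next to their rounded display forms, so a
printed integer percentage is reproduced without floating-point ambiguity.

Display convention: percentages round half-up to the requested number of
decimals, but a metric whose exact value is below 100% is never displayed
as 100% (a 99.53% negative predictive value prints as 99%, not 100%) — the
usual clinical-report convention that an imperfect test must not be reported
as perfect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

from .classify import ClassificationResult
from .errors import EmptyCohortError, UndefinedMetricError
from .workflow import Action, CohortRun, WorkflowDecision


class EvaluationMode(str, enum.Enum):
    INDEX_TEST = "index_test"
    WORKFLOW = "workflow"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 contingency table of index-test positivity vs the composite
    reference standard (intrathecal humoral immune response)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"confusion count {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negative(self) -> int:
        return self.tn + self.fp


def display_percent(value: Fraction, decimals: int = 0) -> float:
    """Round an exact percentage half-up to ``decimals``, never displaying
    an imperfect metric as exactly 100%."""
    quantum = Decimal(1).scaleb(-decimals)
    rounded = (Decimal(value.numerator) / Decimal(value.denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    if value < 100 and rounded == 100:
        rounded = Decimal(100) - quantum
    return float(rounded)


@dataclass(frozen=True)
class Metric:
    """One accuracy metric: exact rational percentage plus display helpers.

    ``exact`` is None when the denominator was zero (the metric is then
    undefined and flagged, never forced to 0 or 100).
    """

    name: str
    exact: Fraction | None

    @property
    def defined(self) -> bool:
        return self.exact is not None

    def display(self, decimals: int = 0) -> float:
        if self.exact is None:
            raise UndefinedMetricError(f"{self.name} is undefined (zero denominator)")
        return display_percent(self.exact, decimals)

    def __float__(self) -> float:
        if self.exact is None:
            raise UndefinedMetricError(f"{self.name} is undefined (zero denominator)")
        return float(self.exact)


def _metric(name: str, numerator: int, denominator: int) -> Metric:
    if denominator == 0:
        return Metric(name, None)
    return Metric(name, Fraction(100 * numerator, denominator))


@dataclass(frozen=True)
class AccuracyMetrics:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric

    def as_tuple(self) -> tuple[Metric, Metric, Metric, Metric]:
        return (self.sensitivity, self.specificity, self.ppv, self.npv)


@dataclass(frozen=True)
class ReductionSummary:
    """Analysis-reduction accounting: how many Ig + OCB workups the
    screening workflow would omit."""

    reduction_count: int
    total: int

    @property
    def reduction_fraction(self) -> Fraction:
        if self.total == 0:
            return Fraction(0)
        return Fraction(100 * self.reduction_count, self.total)

    def display(self, decimals: int = 1) -> float:
        return display_percent(self.reduction_fraction, decimals)


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion matrix, accuracy metrics and reduction accounting for one
    cohort under one evaluation mode."""

    mode: EvaluationMode
    matrix: ConfusionMatrix
    metrics: AccuracyMetrics
    reduction: ReductionSummary | None = None
    excluded: int = 0
    notes: tuple[str, ...] = ()

    @property
    def sensitivity(self) -> Metric:
        return self.metrics.sensitivity

    @property
    def specificity(self) -> Metric:
        return self.metrics.specificity

    @property
    def ppv(self) -> Metric:
        return self.metrics.ppv

    @property
    def npv(self) -> Metric:
        return self.metrics.npv


def build_confusion(
    results: Iterable[tuple[ClassificationResult, bool]]
) -> ConfusionMatrix:
    """Cross-tabulate index positivity against the reference standard.

    Every classification entering here must have a determinate
    ``immune_response``; indeterminate samples are excluded upstream and
    tallied in the report's ``excluded`` count.
    """
    tp = fp = fn = tn = 0
    empty = True
    for classification, index_positive in results:
        empty = False
        if classification.immune_response:
            if index_positive:
                tp += 1
            else:
                fn += 1
        else:
            if index_positive:
                fp += 1
            else:
                tn += 1
    if empty:
        raise EmptyCohortError("cannot build a confusion matrix from an empty cohort")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy_metrics(matrix: ConfusionMatrix) -> AccuracyMetrics:
    """Sensitivity, specificity, PPV and NPV as exact rational percentages."""
    return AccuracyMetrics(
        sensitivity=_metric("sensitivity", matrix.tp, matrix.tp + matrix.fn),
        specificity=_metric("specificity", matrix.tn, matrix.tn + matrix.fp),
        ppv=_metric("PPV", matrix.tp, matrix.tp + matrix.fp),
        npv=_metric("NPV", matrix.tn, matrix.tn + matrix.fn),
    )


def reduction_accounting(decisions: Sequence[WorkflowDecision]) -> ReductionSummary:
    """Count OMIT decisions and their share of the cohort."""
    omitted = sum(1 for d in decisions if d.action is Action.OMIT_IG_AND_OCB)
    return ReductionSummary(reduction_count=omitted, total=len(decisions))


def evaluate_cohort(
    run: CohortRun, mode: EvaluationMode | str = EvaluationMode.INDEX_TEST
) -> DiagnosticReport:
    """Build the full diagnostic report for a processed cohort.

    In ``index_test`` mode positivity is the FLCκ synthesis flag; in
    ``workflow`` mode it is a PROCEED decision.  Samples that failed
    per-sample processing (including indeterminate reference standards) are
    counted as excluded.
    """
    mode = EvaluationMode(mode)
    pairs = [
        (
            r.classification,
            r.decision.proceed
            if mode is EvaluationMode.WORKFLOW
            else r.classification.flck_synthesis,
        )
        for r in run.results
    ]
    matrix = build_confusion(pairs)
    reduction = reduction_accounting([r.decision for r in run.results])
    notes = tuple(
        f"excluded {e.sample_id}: {e.message}" for e in run.errors
    )
    return DiagnosticReport(
        mode=mode,
        matrix=matrix,
        metrics=accuracy_metrics(matrix),
        reduction=reduction,
        excluded=len(run.errors),
        notes=notes,
    )


def format_report(report: DiagnosticReport, cohort_label: str = "cohort") -> str:
    """Human-readable contingency-table layout with the four metric labels
    used in clinical accuracy tables."""
    m = report.matrix
    met = report.metrics
    lines = [
        f"{cohort_label} — evaluation mode: {report.mode.value}",
        "",
        f"{'':>14}  {'Immune response':>16}  {'No immune response':>19}",
        f"{'test positive':>14}  {m.tp:>16d}  {m.fp:>19d}   PPV: "
        + (f"{met.ppv.display(0):.0f}%" if met.ppv.defined else "undefined"),
        f"{'test negative':>14}  {m.fn:>16d}  {m.tn:>19d}   NPV: "
        + (f"{met.npv.display(0):.0f}%" if met.npv.defined else "undefined"),
        "",
        "Sensitivity: "
        + (f"{met.sensitivity.display(0):.0f}%" if met.sensitivity.defined else "undefined")
        + "   Specificity: "
        + (f"{met.specificity.display(0):.0f}%" if met.specificity.defined else "undefined"),
    ]
    if report.reduction is not None and report.reduction.total:
        r = report.reduction
        lines.append(
            f"Ig/OCB analyses omitted: {r.reduction_count}/{r.total} "
            f"({r.display(1):.1f}%)"
        )
    if report.excluded:
        lines.append(f"Excluded (indeterminate/invalid): {report.excluded}")
    return "\n".join(lines)


def report_to_dict(report: DiagnosticReport) -> dict:
    """Flat key-value serialization of a diagnostic report."""
    m, met = report.matrix, report.metrics
    out: dict[str, object] = {
        "mode": report.mode.value,
        "tp": m.tp,
        "fp": m.fp,
        "fn": m.fn,
        "tn": m.tn,
        "total": m.total,
        "excluded": report.excluded,
    }
    for metric in met.as_tuple():
        key = metric.name.lower()
        if metric.defined:
            out[f"{key}_exact_pct"] = float(metric.exact)
            out[f"{key}_display_pct"] = metric.display(0)
        else:
            out[f"{key}_exact_pct"] = None
            out[f"{key}_display_pct"] = None
    if report.reduction is not None:
        out["reduction_count"] = report.reduction.reduction_count
        out["reduction_exact_pct"] = float(report.reduction.reduction_fraction)
    return out
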