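"""Tabular input/output for cohort files and result tables.

Cohort files are delimited text with one row per lumbar puncture.  Required
columns: ``sample_id``, ``albumin_csf``, ``albumin_serum``, ``flck_csf``,
``flck_serum``.  Optional: the immunoglobulin pairs, ``erythrocytes_csf``,
``leukocytes_csf``, ``ocb_status`` and ``flck_below_lloq``.  Unknown columns
are preserved and passed through untouched.  Empty cells mean "absent",
never zero.

On output, quotients follow the clinical ×10⁻³ display convention (column
headers carry an ``_x1000`` suffix); a dialect flag switches to raw ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classify import ResponsePattern, classify_response_pattern
from .diagnostics import DiagnosticReport, format_report, report_to_dict
from .errors import CsfScreenError, SchemaError
from .reiber import Analyte, OCBStatus, SampleRecord
from .workflow import CohortRun

REQUIRED_COLUMNS = (
    "sample_id",
    "albumin_csf",
    "albumin_serum",
    "flck_csf",
    "flck_serum",
)

OPTIONAL_COLUMNS = (
    "igg_csf",
    "igg_serum",
    "iga_csf",
    "iga_serum",
    "igm_csf",
    "igm_serum",
    "erythrocytes_csf",
    "leukocytes_csf",
    "ocb_status",
    "flck_below_lloq",
)


@dataclass(frozen=True)
class CohortTableDialect:
    """Column/format conventions for cohort tables."""

    delimiter: str = ","
    decimal: str = "."
    quotients_x1000: bool = True  # display scale of quotient columns on output


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number
    sample_id: str
    message: str


@dataclass(frozen=True)
class CohortReadResult:
    records: tuple[SampleRecord, ...]
    row_errors: tuple[RowError, ...]


def _cell(row: pd.Series, column: str) -> float | None:
    if column not in row.index:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_cohort(
    path: str | Path, dialect: CohortTableDialect | None = None
) -> CohortReadResult:
    """Read and validate a cohort table.

    Missing required columns raise :class:`SchemaError`; per-row validation
    failures are collected with their row numbers instead of aborting.
    """
    dialect = dialect or CohortTableDialect()
    frame = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table {path} missing required columns: {missing}")

    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    passthrough = [c for c in frame.columns if c not in known]

    records: list[SampleRecord] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        sample_id = str(row["sample_id"])
        try:
            ocb_raw = row.get("ocb_status")
            if ocb_raw is None or (isinstance(ocb_raw, float) and math.isnan(ocb_raw)):
                ocb = OCBStatus.NOT_DONE
            else:
                ocb = OCBStatus(str(ocb_raw).strip())
            ec = _cell(row, "erythrocytes_csf")
            below = row.get("flck_below_lloq")
            below_flag = bool(below) if isinstance(below, (bool,)) else (
                str(below).strip().lower() in ("1", "true", "yes")
                if below is not None and not (isinstance(below, float) and math.isnan(below))
                else False
            )
            record = SampleRecord(
                sample_id=sample_id,
                albumin_csf=_cell(row, "albumin_csf"),
                albumin_serum=_cell(row, "albumin_serum"),
                flck_csf=_cell(row, "flck_csf"),
                flck_serum=_cell(row, "flck_serum"),
                igg_csf=_cell(row, "igg_csf"),
                igg_serum=_cell(row, "igg_serum"),
                iga_csf=_cell(row, "iga_csf"),
                iga_serum=_cell(row, "iga_serum"),
                igm_csf=_cell(row, "igm_csf"),
                igm_serum=_cell(row, "igm_serum"),
                erythrocytes_csf=int(ec) if ec is not None else None,
                leukocytes_csf=_cell(row, "leukocytes_csf"),
                ocb_status=ocb,
                flck_below_lloq=below_flag,
                extra={c: row[c] for c in passthrough},
            )
        except (CsfScreenError, ValueError, TypeError) as exc:
            errors.append(RowError(row=i, sample_id=sample_id, message=str(exc)))
            continue
        records.append(record)
    return CohortReadResult(records=tuple(records), row_errors=tuple(errors))


def write_cohort(
    samples: Sequence[SampleRecord],
    path: str | Path,
    dialect: CohortTableDialect | None = None,
) -> None:
    """Write sample records to a cohort table (concentrations as given;
    this is the dialect :func:`read_cohort` parses)."""
    dialect = dialect or CohortTableDialect()
    passthrough_keys: list[str] = []
    for s in samples:
        for key in s.extra:
            if key not in passthrough_keys:
                passthrough_keys.append(key)
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "albumin_csf": s.albumin_csf,
            "albumin_serum": s.albumin_serum,
            "igg_csf": s.igg_csf,
            "igg_serum": s.igg_serum,
            "iga_csf": s.iga_csf,
            "iga_serum": s.iga_serum,
            "igm_csf": s.igm_csf,
            "igm_serum": s.igm_serum,
            "flck_csf": s.flck_csf,
            "flck_serum": s.flck_serum,
            "erythrocytes_csf": s.erythrocytes_csf,
            "leukocytes_csf": s.leukocytes_csf,
            "ocb_status": s.ocb_status.value,
            "flck_below_lloq": s.flck_below_lloq,
        }
        for key in passthrough_keys:
            row[key] = s.extra.get(key)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def results_frame(
    run: CohortRun, dialect: CohortTableDialect | None = None
) -> pd.DataFrame:
    """Per-sample result table: quotients (×10⁻³ by default), intrathecal
    fractions in %, classification flags, workflow decision and rationale.
    Deterministic column order."""
    dialect = dialect or CohortTableDialect()
    scale = 1e3 if dialect.quotients_x1000 else 1.0
    suffix = "_x1000" if dialect.quotients_x1000 else ""
    rows = []
    for r in run.results:
        p, c, d = r.profile, r.classification, r.decision
        row: dict[str, object] = {"sample_id": p.sample_id, f"q_alb{suffix}": p.q_alb * scale}
        for analyte in (Analyte.IGG, Analyte.IGA, Analyte.IGM, Analyte.FLCK):
            stem = analyte.value.lower().replace("kappa", "k")
            if analyte in p.q:
                row[f"q_{stem}{suffix}"] = p.q[analyte] * scale
                row[f"q_lim_{stem}{suffix}"] = p.q_lim[analyte] * scale
                row[f"if_{stem}_pct"] = p.intrathecal_fraction[analyte]
                row[f"synthesis_{stem}"] = c.synthesis_flags[analyte]
            else:
                row[f"q_{stem}{suffix}"] = None
                row[f"q_lim_{stem}{suffix}"] = None
                row[f"if_{stem}_pct"] = None
                row[f"synthesis_{stem}"] = None
        row["ocb_positive"] = c.ocb_positive
        row["blood_contamination"] = c.blood_contamination
        row["immune_response"] = c.immune_response
        row["serum_flck_elevated"] = c.serum_flck_elevated
        row["response_pattern"] = classify_response_pattern(c).value
        row["action"] = d.action.value
        row["trigger"] = d.trigger.value
        row["flck_clipped_to_lloq"] = p.flck_clipped_to_lloq
        row["rationale"] = "; ".join(c.rationale)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    run: CohortRun,
    reports: Sequence[DiagnosticReport],
    out_dir: str | Path,
    dialect: CohortTableDialect | None = None,
    cohort_label: str = "cohort",
) -> dict[str, Path]:
    """Write the per-sample table, a summary document (text table + JSON
    key-value form) and — only when non-empty — an error report.

    Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    samples_path = out_dir / "samples.csv"
    frame = results_frame(run, dialect)
    frame.to_csv(samples_path, sep=(dialect or CohortTableDialect()).delimiter, index=False)
    written["samples"] = samples_path

    summary_txt = out_dir / "summary.txt"
    summary_txt.write_text(
        "\n\n".join(format_report(rep, cohort_label) for rep in reports) + "\n"
    )
    written["summary_text"] = summary_txt

    summary_json = out_dir / "summary.json"
    summary_json.write_text(
        json.dumps([report_to_dict(rep) for rep in reports], indent=2) + "\n"
    )
    written["summary_json"] = summary_json

    if run.errors:
        errors_path = out_dir / "errors.csv"
        pd.DataFrame(
            [
                {"sample_id": e.sample_id, "error_type": e.error_type, "message": e.message}
                for e in run.errors
            ]
        ).to_csv(errors_path, index=False)
        written["errors"] = errors_path
    return written
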