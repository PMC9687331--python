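"""Synthetic CSF cohort generator with known ground truth.

Real paired CSF/serum cohorts of this kind are not publicly depositable, so
this module generates cohorts that emulate the published summary structure
of a routine neurology cohort: lognormal albumin and serum-FLCκ quotient
distributions matched by median and quartiles, a categorical mixture of
one/two/three-class immunoglobulin synthesis patterns, oligoclonal-band
(OCB) rates, a small rate of artificial blood contamination with the
IgM-dominant pseudo-synthesis pattern, and FLCκ intrathecal-fraction
positivity drawn conditionally on reference-standard status.

Generation works backwards from the quotient diagram: for each analyte a
target quotient is chosen relative to its discrimination line (above it with
a drawn intrathecal fraction for synthesis-positive analytes, uniformly
below it otherwise) and then inverted to a CSF concentration given a drawn
serum concentration.  Ground-truth labels record what was drawn, so the
classification pipeline can be checked for exact round-trip agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .classify import ResponsePattern, SerumReferenceRange
from .errors import GenerationError
from .reiber import (
    Analyte,
    FLCK_LLOQ_MG_L,
    IG_ANALYTES,
    OCBStatus,
    SampleRecord,
    q_lim,
)

#: 75th-percentile z-score of the standard normal; converts a quartile ratio
#: into a lognormal sigma.
_Z75 = 0.6744897501960817

#: Pattern → set of synthesis-positive Ig analytes.
_PATTERN_ANALYTES: dict[ResponsePattern, frozenset[Analyte]] = {
    ResponsePattern.NONE: frozenset(),
    ResponsePattern.IGG: frozenset({Analyte.IGG}),
    ResponsePattern.IGA: frozenset({Analyte.IGA}),
    ResponsePattern.IGM: frozenset({Analyte.IGM}),
    ResponsePattern.IGG_M: frozenset({Analyte.IGG, Analyte.IGM}),
    ResponsePattern.IGA_M: frozenset({Analyte.IGA, Analyte.IGM}),
    ResponsePattern.IGG_A: frozenset({Analyte.IGG, Analyte.IGA}),
    ResponsePattern.IGG_A_M: frozenset({Analyte.IGG, Analyte.IGA, Analyte.IGM}),
}


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal from its median and quartiles."""
    if not 0 < q1 < median < q3:
        raise GenerationError(
            f"quartiles must satisfy 0 < q1 < median < q3, got ({q1}, {median}, {q3})"
        )
    return math.log(median), math.log(q3 / q1) / (2 * _Z75)


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic cohort.

    ``class_mixture`` is the pattern distribution over *non-contaminated*
    samples; artificial blood contamination is drawn separately with
    ``p_blood_contamination`` and always carries the IgM-dominant ordering
    with a reference-standard-negative ground truth.

    OCB probabilities are conditioned on quantitative Ig pattern presence
    (not on the composite reference standard, which OCB itself defines):
    a pattern-free sample drawing a positive OCB becomes an OCB-only
    responder.

    ``p_serum_flck_elevated`` fixes the probability that serum FLCκ exceeds
    the reference upper bound via a truncated-lognormal mixture; ``None``
    leaves the fitted lognormal untouched.

    ``if_effect_beta`` gives per-analyte Beta(α, β) shapes for the
    intrathecal fraction (scaled to percent) drawn for synthesis-positive
    analytes; support is the open interval (0, 100) by construction.
    """

    n: int
    class_mixture: Mapping[ResponsePattern, float]
    p_ocb_given_ig_pattern: float
    p_ocb_given_no_ig_pattern: float
    p_flck_if_given_response: float
    p_flck_if_given_no_response: float
    p_blood_contamination: float = 18 / 679
    p_serum_flck_elevated: float | None = None
    q_alb_median: float = 6.4e-3
    q_alb_quartiles: tuple[float, float] = (4.7e-3, 9.1e-3)
    serum_flck_median: float = 13.1
    serum_flck_quartiles: tuple[float, float] = (10.2, 18.0)
    serum_range: SerumReferenceRange = field(default_factory=SerumReferenceRange)
    if_effect_beta: Mapping[Analyte, tuple[float, float]] = field(
        default_factory=lambda: {
            Analyte.IGG: (1.3, 1.8),
            Analyte.IGA: (1.3, 1.8),
            Analyte.IGM: (1.3, 1.8),
            Analyte.FLCK: (1.6, 1.2),
        }
    )
    # serum concentration distributions, mg/L (median, sigma of log)
    albumin_serum_log: tuple[float, float] = (42000.0, 0.12)
    igg_serum_log: tuple[float, float] = (10500.0, 0.25)
    iga_serum_log: tuple[float, float] = (2250.0, 0.35)
    igm_serum_log: tuple[float, float] = (1100.0, 0.45)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GenerationError("cohort size n must be >= 1")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"class_mixture must sum to 1, got {total!r}")
        probs = {
            "p_ocb_given_ig_pattern": self.p_ocb_given_ig_pattern,
            "p_ocb_given_no_ig_pattern": self.p_ocb_given_no_ig_pattern,
            "p_flck_if_given_response": self.p_flck_if_given_response,
            "p_flck_if_given_no_response": self.p_flck_if_given_no_response,
            "p_blood_contamination": self.p_blood_contamination,
            **{f"class_mixture[{k.value}]": v for k, v in self.class_mixture.items()},
        }
        if self.p_serum_flck_elevated is not None:
            probs["p_serum_flck_elevated"] = self.p_serum_flck_elevated
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {p!r}")
        for analyte, (alpha, beta) in self.if_effect_beta.items():
            if alpha <= 0 or beta <= 0:
                raise GenerationError(
                    f"if_effect_beta[{analyte}] shapes must be positive, got {(alpha, beta)!r}"
                )

    # -- config-file round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "class_mixture": {k.value: v for k, v in self.class_mixture.items()},
            "p_ocb_given_ig_pattern": self.p_ocb_given_ig_pattern,
            "p_ocb_given_no_ig_pattern": self.p_ocb_given_no_ig_pattern,
            "p_flck_if_given_response": self.p_flck_if_given_response,
            "p_flck_if_given_no_response": self.p_flck_if_given_no_response,
            "p_blood_contamination": self.p_blood_contamination,
            "p_serum_flck_elevated": self.p_serum_flck_elevated,
            "q_alb_median": self.q_alb_median,
            "q_alb_quartiles": list(self.q_alb_quartiles),
            "serum_flck_median": self.serum_flck_median,
            "serum_flck_quartiles": list(self.serum_flck_quartiles),
            "serum_range": [self.serum_range.lower, self.serum_range.upper],
            "if_effect_beta": {k.value: list(v) for k, v in self.if_effect_beta.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortSpec":
        data = dict(data)
        kwargs: dict = {
            "n": int(data["n"]),
            "class_mixture": {
                ResponsePattern(k): float(v) for k, v in data["class_mixture"].items()
            },
            "p_ocb_given_ig_pattern": float(data["p_ocb_given_ig_pattern"]),
            "p_ocb_given_no_ig_pattern": float(data["p_ocb_given_no_ig_pattern"]),
            "p_flck_if_given_response": float(data["p_flck_if_given_response"]),
            "p_flck_if_given_no_response": float(data["p_flck_if_given_no_response"]),
        }
        if "p_blood_contamination" in data:
            kwargs["p_blood_contamination"] = float(data["p_blood_contamination"])
        if data.get("p_serum_flck_elevated") is not None:
            kwargs["p_serum_flck_elevated"] = float(data["p_serum_flck_elevated"])
        for key in ("q_alb_median", "serum_flck_median"):
            if key in data:
                kwargs[key] = float(data[key])
        for key in ("q_alb_quartiles", "serum_flck_quartiles"):
            if key in data:
                kwargs[key] = tuple(float(v) for v in data[key])
        if "serum_range" in data:
            lo, hi = data["serum_range"]
            kwargs["serum_range"] = SerumReferenceRange(float(lo), float(hi))
        if "if_effect_beta" in data:
            kwargs["if_effect_beta"] = {
                Analyte(k): tuple(float(x) for x in v)
                for k, v in data["if_effect_beta"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator drew for one sample."""

    sample_id: str
    pattern: ResponsePattern
    ocb_positive: bool
    blood_contamination: bool
    immune_response: bool
    flck_if_positive: bool
    serum_flck_elevated: bool


def discovery_spec(n: int = 679) -> CohortSpec:
    """Preset emulating the retrospective discovery-style cohort.

    Pattern counts over the 661 non-contaminated samples (IgG 71, IgA 10,
    IgM 19, IgG/M 31, IgA/M 12, IgG/A 9, IgG/A/M 4, none 505); OCB rates set
    so the expected responder count is 245 with 204 OCB-positive; FLCκ
    positivity 241/245 given response and 60/434 without; contamination
    18/679; 9/679 serum-elevated.
    """
    nc = 661.0
    return CohortSpec(
        n=n,
        class_mixture={
            ResponsePattern.NONE: 505 / nc,
            ResponsePattern.IGG: 71 / nc,
            ResponsePattern.IGA: 10 / nc,
            ResponsePattern.IGM: 19 / nc,
            ResponsePattern.IGG_M: 31 / nc,
            ResponsePattern.IGA_M: 12 / nc,
            ResponsePattern.IGG_A: 9 / nc,
            ResponsePattern.IGG_A_M: 4 / nc,
        },
        p_ocb_given_ig_pattern=115 / 156,
        p_ocb_given_no_ig_pattern=89 / 505,
        p_flck_if_given_response=241 / 245,
        p_flck_if_given_no_response=60 / 434,
        p_blood_contamination=18 / 679,
        p_serum_flck_elevated=9 / 679,
        q_alb_median=6.4e-3,
        q_alb_quartiles=(4.7e-3, 9.1e-3),
        serum_flck_median=13.1,
        serum_flck_quartiles=(10.2, 18.0),
    )


def validation_spec(n: int = 278) -> CohortSpec:
    """Preset emulating the prospective validation-style cohort (lower
    response prevalence: 32/278 responders, 31 OCB, contamination 1/278)."""
    nc = 277.0
    return CohortSpec(
        n=n,
        class_mixture={
            ResponsePattern.NONE: 254 / nc,
            ResponsePattern.IGG: 12 / nc,
            ResponsePattern.IGA: 0.0,
            ResponsePattern.IGM: 1 / nc,
            ResponsePattern.IGG_M: 6 / nc,
            ResponsePattern.IGA_M: 1 / nc,
            ResponsePattern.IGG_A: 1 / nc,
            ResponsePattern.IGG_A_M: 2 / nc,
        },
        p_ocb_given_ig_pattern=22 / 23,
        p_ocb_given_no_ig_pattern=9 / 254,
        p_flck_if_given_response=31 / 32,
        p_flck_if_given_no_response=36 / 246,
        p_blood_contamination=1 / 278,
        p_serum_flck_elevated=3 / 278,
        q_alb_median=6.7e-3,
        q_alb_quartiles=(5.1e-3, 9.4e-3),
        serum_flck_median=13.1,
        serum_flck_quartiles=(9.81, 17.97),
    )


def _draw_serum_flck(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Serum FLCκ draws; if p_serum_flck_elevated is set, a truncated
    mixture pins the above-reference tail mass exactly at that probability."""
    mu, sigma = lognormal_params(
        spec.serum_flck_median, *spec.serum_flck_quartiles
    )
    if spec.p_serum_flck_elevated is None:
        return rng.lognormal(mu, sigma, size=n)
    upper = spec.serum_range.upper
    # inverse-CDF sampling within each truncated branch
    z_cut = (math.log(upper) - mu) / sigma
    from scipy.stats import norm

    p_cut = norm.cdf(z_cut)
    elevated = rng.random(n) < spec.p_serum_flck_elevated
    u = rng.random(n)
    q = np.where(elevated, p_cut + u * (1 - p_cut), u * p_cut)
    return np.exp(mu + sigma * norm.ppf(q))


def generate(
    spec: CohortSpec, seed: int | np.random.Generator
) -> tuple[list[SampleRecord], list[GroundTruth]]:
    """Generate a cohort and its ground-truth labels, reproducibly.

    Raises :class:`GenerationError` for infeasible specifications.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n

    q_alb = rng.lognormal(*lognormal_params(spec.q_alb_median, *spec.q_alb_quartiles), size=n)
    contaminated = rng.random(n) < spec.p_blood_contamination

    patterns_list = list(spec.class_mixture.keys())
    probs = np.array([spec.class_mixture[p] for p in patterns_list], dtype=float)
    probs = probs / probs.sum()
    pattern_idx = rng.choice(len(patterns_list), size=n, p=probs)

    ocb_u = rng.random(n)
    flck_u = rng.random(n)

    serum_alb = rng.lognormal(math.log(spec.albumin_serum_log[0]), spec.albumin_serum_log[1], n)
    serum_igg = rng.lognormal(math.log(spec.igg_serum_log[0]), spec.igg_serum_log[1], n)
    serum_iga = rng.lognormal(math.log(spec.iga_serum_log[0]), spec.iga_serum_log[1], n)
    serum_igm = rng.lognormal(math.log(spec.igm_serum_log[0]), spec.igm_serum_log[1], n)
    serum_flck = _draw_serum_flck(spec, rng, n)

    # cell counts: contaminated punctures get erythrocytes well above the
    # 500/µL threshold; clean ones stay below it.
    ec_clean = np.minimum(rng.geometric(1 / 30.0, n) - 1, 500)
    ec_contam = 501 + np.asarray(rng.lognormal(math.log(2000.0), 1.0, n), dtype=int)
    leuko = np.maximum(np.asarray(np.round(rng.lognormal(math.log(1.5), 0.9, n)), dtype=int), 0)
    age = rng.integers(18, 90, size=n)

    serum_by_analyte = {
        Analyte.IGG: serum_igg,
        Analyte.IGA: serum_iga,
        Analyte.IGM: serum_igm,
        Analyte.FLCK: serum_flck,
    }

    samples: list[SampleRecord] = []
    labels: list[GroundTruth] = []
    upper = spec.serum_range.upper

    for i in range(n):
        sample_id = f"S{i + 1:05d}"
        qa = float(q_alb[i])
        is_contam = bool(contaminated[i])
        pattern = ResponsePattern.NONE if is_contam else patterns_list[pattern_idx[i]]
        has_pattern = pattern is not ResponsePattern.NONE

        if is_contam:
            ocb = False
        elif has_pattern:
            ocb = bool(ocb_u[i] < spec.p_ocb_given_ig_pattern)
        else:
            ocb = bool(ocb_u[i] < spec.p_ocb_given_no_ig_pattern)

        responder = (has_pattern or ocb) and not is_contam
        p_flck = (
            spec.p_flck_if_given_response
            if responder
            else spec.p_flck_if_given_no_response
        )
        flck_pos = bool(flck_u[i] < p_flck)

        # target intrathecal fractions per analyte (None → below the line)
        if_targets: dict[Analyte, float | None] = {}
        if is_contam:
            if_igm = float(rng.uniform(15.0, 70.0))
            if_iga = if_igm * float(rng.uniform(0.3, 0.9))
            if_igg = if_iga * float(rng.uniform(0.3, 0.9))
            if_targets[Analyte.IGM] = if_igm
            if_targets[Analyte.IGA] = if_iga
            if_targets[Analyte.IGG] = if_igg
        else:
            positive_set = _PATTERN_ANALYTES[pattern]
            for analyte in IG_ANALYTES:
                if analyte in positive_set:
                    alpha, beta = spec.if_effect_beta[analyte]
                    if_targets[analyte] = float(rng.beta(alpha, beta)) * 100.0
                else:
                    if_targets[analyte] = None
        if flck_pos:
            alpha, beta = spec.if_effect_beta[Analyte.FLCK]
            if_targets[Analyte.FLCK] = float(rng.beta(alpha, beta)) * 100.0
        else:
            if_targets[Analyte.FLCK] = None

        conc: dict[Analyte, float] = {}
        for analyte, target in if_targets.items():
            limit = q_lim(analyte, qa)
            if target is None:
                quotient = limit * float(rng.uniform(0.2, 1.0))
            else:
                if target >= 100.0:
                    raise GenerationError(
                        f"if_effect_beta draw for {analyte} reached {target}% "
                        "(intrathecal fractions must stay below 100%)"
                    )
                quotient = limit / (1.0 - target / 100.0)
            conc[analyte] = quotient * float(serum_by_analyte[analyte][i])

        flck_csf = conc[Analyte.FLCK]
        below_lloq = flck_csf < FLCK_LLOQ_MG_L
        if below_lloq:
            flck_csf = FLCK_LLOQ_MG_L

        samples.append(
            SampleRecord(
                sample_id=sample_id,
                albumin_csf=qa * float(serum_alb[i]),
                albumin_serum=float(serum_alb[i]),
                igg_csf=conc[Analyte.IGG],
                igg_serum=float(serum_igg[i]),
                iga_csf=conc[Analyte.IGA],
                iga_serum=float(serum_iga[i]),
                igm_csf=conc[Analyte.IGM],
                igm_serum=float(serum_igm[i]),
                flck_csf=flck_csf,
                flck_serum=float(serum_flck[i]),
                erythrocytes_csf=int(ec_contam[i] if is_contam else ec_clean[i]),
                leukocytes_csf=float(leuko[i]),
                ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE if ocb else OCBStatus.NEGATIVE,
                flck_below_lloq=below_lloq,
                extra={"age": int(age[i])},
            )
        )
        labels.append(
            GroundTruth(
                sample_id=sample_id,
                pattern=pattern if not is_contam else ResponsePattern.NONE,
                ocb_positive=ocb,
                blood_contamination=is_contam,
                immune_response=responder,
                flck_if_positive=flck_pos,
                serum_flck_elevated=float(serum_flck[i]) > upper,
            )
        )
    return samples, labels


def tabulate_characteristics(
    samples: Sequence[SampleRecord], labels: Sequence[GroundTruth]
):
    """Cohort-characteristics table: medians (first; third quartiles) of the
    quotients and FLCκ concentrations (quotients on the ×10⁻³ display
    scale), plus counts of synthesis patterns, OCB and contamination."""
    import pandas as pd

    from .reiber import build_profile

    profiles = [build_profile(s) for s in samples]
    n = len(samples)

    def med_iqr(values: Sequence[float], scale: float = 1.0) -> str:
        arr = np.asarray(values, dtype=float) * scale
        med, q1, q3 = (float(np.percentile(arr, p)) for p in (50, 25, 75))
        return f"{med:.3g} ({q1:.3g}; {q3:.3g})"

    def count_row(k: int) -> str:
        return f"{k} ({100.0 * k / n:.1f})"

    rows: list[tuple[str, str]] = []
    ages = [s.extra.get("age") for s in samples if "age" in s.extra]
    if ages:
        rows.append(("Age (y)", med_iqr([float(a) for a in ages])))
    rows.append(("QAlb (x10-3)", med_iqr([p.q_alb for p in profiles], 1e3)))
    for analyte, label in [
        (Analyte.IGG, "QIgG (x10-3)"),
        (Analyte.IGA, "QIgA (x10-3)"),
        (Analyte.IGM, "QIgM (x10-3)"),
    ]:
        vals = [p.q[analyte] for p in profiles if analyte in p.q]
        if vals:
            rows.append((label, med_iqr(vals, 1e3)))
    pattern_order = [
        ResponsePattern.IGG,
        ResponsePattern.IGA,
        ResponsePattern.IGM,
        ResponsePattern.IGG_M,
        ResponsePattern.IGA_M,
        ResponsePattern.IGG_A,
        ResponsePattern.IGG_A_M,
    ]
    for pattern in pattern_order:
        k = sum(1 for t in labels if t.pattern is pattern)
        rows.append((f"{pattern.value}-synthesis; n (%)", count_row(k)))
    rows.append(
        ("Artificial blood contamination; n (%)",
         count_row(sum(1 for t in labels if t.blood_contamination)))
    )
    rows.append(
        ("CSF-specific OCB; n (%)", count_row(sum(1 for t in labels if t.ocb_positive)))
    )
    leuko = [s.leukocytes_csf for s in samples if s.leukocytes_csf is not None]
    if leuko:
        rows.append(("Cell count /uL", med_iqr(leuko)))
    rows.append(
        ("FLCk IF > 0%; n (%)", count_row(sum(1 for t in labels if t.flck_if_positive)))
    )
    rows.append(("FLCk serum (mg/L)", med_iqr([s.flck_serum for s in samples])))
    rows.append(("FLCk CSF (mg/L)", med_iqr([s.flck_csf for s in samples])))
    rows.append(
        ("QFLCk (x10-3)", med_iqr([p.q[Analyte.FLCK] for p in profiles], 1e3))
    )
    return pd.DataFrame(rows, columns=["characteristic", "value"])
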