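"""Hyperbolic quotient-diagram mathematics for CSF protein diagnostics.

In a quotient diagram ("Reibergram") the CSF/serum concentration quotient of
a protein (IgG, IgA, IgM or free light chains kappa, FLCκ) is plotted against
the albumin quotient QAlb, which indexes blood–CSF barrier function: albumin
is exclusively blood-derived, so QAlb tells how much of any serum protein is
expected in CSF by passive diffusion alone.  The upper discrimination line

    Qlim(QAlb) = a · sqrt(QAlb² + b) − c

separates the blood-derived fraction from intrathecally synthesized protein;
a quotient above Qlim indicates synthesis inside the CNS.  The intrathecal
fraction IF = (1 − Qlim/Q) · 100 % quantifies the synthesized share.

All quotients in this module are plain dimensionless ratios.  The familiar
×10⁻³ display convention of clinical tables is applied only at I/O and
plotting, never here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .errors import (
    BelowQuantificationError,
    IncompleteSampleError,
    InvalidConcentrationError,
    UndefinedFractionError,
    UnsupportedAnalyteError,
)

#: Lower limit of quantification of the nephelometric FLCκ assay, mg/L.
FLCK_LLOQ_MG_L = 0.034


class Analyte(str, enum.Enum):
    """The five analytes of the quotient diagram.

    Albumin is the x-axis reference and has no discrimination line.
    """

    ALBUMIN = "albumin"
    IGG = "IgG"
    IGA = "IgA"
    IGM = "IgM"
    FLCK = "FLCkappa"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Analytes that possess a hyperbolic discrimination line.
QUOTIENT_ANALYTES: tuple[Analyte, ...] = (
    Analyte.IGG,
    Analyte.IGA,
    Analyte.IGM,
    Analyte.FLCK,
)

#: The three immunoglobulin classes (FLCκ excluded).
IG_ANALYTES: tuple[Analyte, ...] = (Analyte.IGG, Analyte.IGA, Analyte.IGM)


class OCBStatus(str, enum.Enum):
    """Result of oligoclonal-band analysis by isoelectric focusing."""

    CSF_SPECIFIC_POSITIVE = "csf_specific_positive"
    NEGATIVE = "negative"
    NOT_DONE = "not_done"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class HyperbolicCoefficients:
    """Coefficients (a, b, c) of the hyperbolic discrimination line
    Qlim = a·sqrt(QAlb² + b) − c.

    ``a`` is the asymptotic slope; ``b`` (order 10⁻⁶) controls the curvature
    at low QAlb; ``c`` (order 10⁻³) is the subtractive offset.  All three are
    dimensionless and must be strictly positive.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(
                    f"hyperbolic coefficient {name!r} must be finite and > 0, got {v!r}"
                )


def _load_packaged_coefficients() -> dict[Analyte, HyperbolicCoefficients]:
    text = (
        resources.files("csfscreen") / "data" / "reiber_coefficients.yaml"
    ).read_text()
    return parse_coefficients(yaml.safe_load(text))


def parse_coefficients(blocks: Mapping[str, Mapping[str, float]]) -> dict[Analyte, HyperbolicCoefficients]:
    """Build a per-analyte coefficient table from a key-value mapping
    (one block per analyte with keys ``a``, ``b``, ``c``)."""
    table: dict[Analyte, HyperbolicCoefficients] = {}
    for key, block in blocks.items():
        analyte = Analyte(key)
        if analyte is Analyte.ALBUMIN:
            raise UnsupportedAnalyteError("albumin has no discrimination line")
        table[analyte] = HyperbolicCoefficients(
            a=float(block["a"]), b=float(block["b"]), c=float(block["c"])
        )
    return table


def load_coefficients(path: str | None = None) -> dict[Analyte, HyperbolicCoefficients]:
    """Load a coefficient table from a YAML file, or the packaged defaults.

    The packaged defaults are the Reiber coefficients: IgG (0.93, 6e-6,
    1.7e-3), IgA (0.77, 23e-6, 3.1e-3), IgM (0.67, 120e-6, 7.1e-3) and
    FLCκ (3.27, 33e-6, 8.2e-3).
    """
    if path is None:
        return dict(DEFAULT_COEFFICIENTS)
    with open(path) as fh:
        return parse_coefficients(yaml.safe_load(fh))


DEFAULT_COEFFICIENTS: dict[Analyte, HyperbolicCoefficients] = _load_packaged_coefficients()


@dataclass(frozen=True)
class SampleRecord:
    """Raw paired CSF/serum measurements for one lumbar puncture.

    Concentrations are in mg/L (CSF and serum of each analyte must share a
    unit; the reader is responsible for harmonizing units such as g/L serum
    albumin before construction).  Immunoglobulin pairs are optional but must
    be present or absent as a pair.  ``extra`` carries pass-through columns
    (age, lactate, total protein, ...) untouched.
    """

    sample_id: str
    albumin_csf: float
    albumin_serum: float
    flck_csf: float
    flck_serum: float
    igg_csf: float | None = None
    igg_serum: float | None = None
    iga_csf: float | None = None
    iga_serum: float | None = None
    igm_csf: float | None = None
    igm_serum: float | None = None
    erythrocytes_csf: int | None = None
    leukocytes_csf: float | None = None
    ocb_status: OCBStatus = OCBStatus.NOT_DONE
    flck_below_lloq: bool = False
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ocb_status", OCBStatus(self.ocb_status))
        for name in ("albumin_csf", "albumin_serum", "flck_csf", "flck_serum"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InvalidConcentrationError(
                    f"sample {self.sample_id!r}: {name} must be a finite positive "
                    f"concentration, got {v!r}"
                )
        for stem in ("igg", "iga", "igm"):
            csf, serum = getattr(self, f"{stem}_csf"), getattr(self, f"{stem}_serum")
            if (csf is None) != (serum is None):
                raise IncompleteSampleError(
                    f"sample {self.sample_id!r}: {stem} CSF/serum values must be "
                    "provided as a pair",
                    missing=(f"{stem}_csf" if csf is None else f"{stem}_serum",),
                )
            if csf is not None:
                for name, v in ((f"{stem}_csf", csf), (f"{stem}_serum", serum)):
                    if not math.isfinite(v) or v <= 0:
                        raise InvalidConcentrationError(
                            f"sample {self.sample_id!r}: {name} must be finite and > 0, got {v!r}"
                        )
        if self.erythrocytes_csf is not None and self.erythrocytes_csf < 0:
            raise InvalidConcentrationError(
                f"sample {self.sample_id!r}: erythrocyte count must be non-negative"
            )
        if self.leukocytes_csf is not None and self.leukocytes_csf < 0:
            raise InvalidConcentrationError(
                f"sample {self.sample_id!r}: leukocyte count must be non-negative"
            )

    def pair(self, analyte: Analyte) -> tuple[float, float] | None:
        """Return the (csf, serum) pair for ``analyte``, or None if absent."""
        stems = {
            Analyte.ALBUMIN: "albumin",
            Analyte.IGG: "igg",
            Analyte.IGA: "iga",
            Analyte.IGM: "igm",
            Analyte.FLCK: "flck",
        }
        stem = stems[analyte]
        csf = getattr(self, f"{stem}_csf")
        serum = getattr(self, f"{stem}_serum")
        if csf is None or serum is None:
            return None
        return float(csf), float(serum)


@dataclass(frozen=True)
class QuotientProfile:
    """Derived dimensionless quotients, discrimination limits and intrathecal
    fractions for one sample.

    Maps hold an entry for every non-albumin analyte whose CSF+serum pair was
    present; absent analytes are absent from all three maps, never imputed.
    Intrathecal fractions are percentages: negative (unbounded below) when the
    quotient lies under the discrimination line, in (0, 100) above it.
    """

    sample_id: str
    q_alb: float
    q: Mapping[Analyte, float]
    q_lim: Mapping[Analyte, float]
    intrathecal_fraction: Mapping[Analyte, float]
    flck_clipped_to_lloq: bool = False


def compute_quotient(
    csf_conc: float, serum_conc: float, analyte: Analyte | str | None = None
) -> float:
    """CSF/serum concentration quotient as a plain dimensionless ratio.

    Both concentrations must be in the same unit.  The result is NOT scaled
    by 10³ (display scaling belongs to I/O).
    """
    label = str(analyte) if analyte is not None else "analyte"
    if serum_conc is None or not math.isfinite(serum_conc) or serum_conc <= 0:
        raise InvalidConcentrationError(
            f"serum concentration of {label} must be > 0, got {serum_conc!r}"
        )
    if csf_conc is None or not math.isfinite(csf_conc) or csf_conc < 0:
        raise InvalidConcentrationError(
            f"CSF concentration of {label} must be >= 0, got {csf_conc!r}"
        )
    return csf_conc / serum_conc


def q_lim(
    analyte: Analyte | str,
    q_alb: float,
    coeffs: HyperbolicCoefficients | None = None,
) -> float:
    """Hyperbolic upper discrimination limit a·sqrt(QAlb² + b) − c.

    Strictly increasing in ``q_alb`` and asymptotically linear with slope
    ``a``.  ``coeffs`` defaults to the packaged Reiber coefficients for the
    analyte.
    """
    analyte = Analyte(analyte)
    if analyte is Analyte.ALBUMIN:
        raise UnsupportedAnalyteError(
            "albumin is the quotient diagram's x-axis and has no Qlim"
        )
    if not (math.isfinite(q_alb) and q_alb > 0):
        raise InvalidConcentrationError(f"q_alb must be > 0, got {q_alb!r}")
    if coeffs is None:
        coeffs = DEFAULT_COEFFICIENTS[analyte]
    return coeffs.a * math.sqrt(q_alb * q_alb + coeffs.b) - coeffs.c


def intrathecal_fraction(q: float, q_lim_value: float) -> float:
    """Intrathecal fraction IF = (1 − Qlim/Q) · 100, in percent.

    Positive iff the quotient exceeds the discrimination line; always < 100
    for finite quotients; unbounded below.  A non-positive quotient makes the
    fraction undefined (distinct from "no synthesis").
    """
    if not (math.isfinite(q) and q > 0):
        raise UndefinedFractionError(
            f"intrathecal fraction undefined for quotient {q!r} (must be > 0)"
        )
    if not (math.isfinite(q_lim_value) and q_lim_value > 0):
        raise InvalidConcentrationError(f"q_lim must be > 0, got {q_lim_value!r}")
    return (1.0 - q_lim_value / q) * 100.0


def build_profile(
    sample: SampleRecord,
    coeff_table: Mapping[Analyte, HyperbolicCoefficients] | None = None,
    lloq_policy: str = "clip",
) -> QuotientProfile:
    """Compute quotients, discrimination limits and intrathecal fractions
    for every analyte measured in ``sample``.

    The albumin and FLCκ pairs are mandatory; immunoglobulin pairs are
    optional and simply absent from the profile when unmeasured.

    ``lloq_policy`` controls CSF FLCκ values below the assay's lower limit
    of quantification (0.034 mg/L): ``"clip"`` (default) computes the
    quotient at the limit and flags the profile — conservative, since it can
    only overstate the quotient and hence intrathecal-fraction positivity —
    while ``"reject"`` raises :class:`BelowQuantificationError`.
    """
    if coeff_table is None:
        coeff_table = DEFAULT_COEFFICIENTS
    if lloq_policy not in ("clip", "reject"):
        raise ValueError(f"unknown lloq_policy {lloq_policy!r}")

    missing = [
        name
        for name in ("albumin_csf", "albumin_serum", "flck_csf", "flck_serum")
        if getattr(sample, name, None) is None
    ]
    if missing:  # defensive; SampleRecord construction already enforces this
        raise IncompleteSampleError(
            f"sample {sample.sample_id!r} missing required fields: {missing}",
            missing=tuple(missing),
        )

    q_alb = compute_quotient(sample.albumin_csf, sample.albumin_serum, Analyte.ALBUMIN)

    flck_csf = sample.flck_csf
    clipped = bool(sample.flck_below_lloq)
    if flck_csf < FLCK_LLOQ_MG_L or sample.flck_below_lloq:
        if lloq_policy == "reject":
            raise BelowQuantificationError(
                f"sample {sample.sample_id!r}: CSF FLCκ {flck_csf} mg/L below the "
                f"{FLCK_LLOQ_MG_L} mg/L limit of quantification"
            )
        flck_csf = max(flck_csf, FLCK_LLOQ_MG_L)
        clipped = True

    q: dict[Analyte, float] = {}
    qlims: dict[Analyte, float] = {}
    fractions: dict[Analyte, float] = {}
    for analyte in QUOTIENT_ANALYTES:
        pair = sample.pair(analyte)
        if pair is None:
            continue
        csf, serum = pair
        if analyte is Analyte.FLCK:
            csf = flck_csf
        quotient = compute_quotient(csf, serum, analyte)
        limit = q_lim(analyte, q_alb, coeff_table[analyte])
        q[analyte] = quotient
        qlims[analyte] = limit
        fractions[analyte] = intrathecal_fraction(quotient, limit)

    return QuotientProfile(
        sample_id=sample.sample_id,
        q_alb=q_alb,
        q=q,
        q_lim=qlims,
        intrathecal_fraction=fractions,
        flck_clipped_to_lloq=clipped,
    )
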