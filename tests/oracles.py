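"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the discrimination
line is a literal transcription of the printed hyperbolic formulas evaluated
with 50-digit decimal arithmetic, and the accuracy metrics are recomputed by
brute-force iteration over sample lists.
"""

from decimal import Decimal, getcontext
from fractions import Fraction

getcontext().prec = 50

#: (a, b, c) per analyte as exact decimal strings.
DECIMAL_COEFFS = {
    "IgG": (Decimal("0.93"), Decimal("0.000006"), Decimal("0.0017")),
    "IgA": (Decimal("0.77"), Decimal("0.000023"), Decimal("0.0031")),
    "IgM": (Decimal("0.67"), Decimal("0.000120"), Decimal("0.0071")),
    "FLCkappa": (Decimal("3.27"), Decimal("0.000033"), Decimal("0.0082")),
}


def q_lim_decimal(analyte: str, q_alb) -> Decimal:
    """a*sqrt(q_alb^2 + b) - c at 50-digit precision."""
    a, b, c = DECIMAL_COEFFS[analyte]
    q = Decimal(repr(q_alb)) if isinstance(q_alb, float) else Decimal(q_alb)
    return a * (q * q + b).sqrt() - c


def brute_force_metrics(pairs):
    """Accuracy metrics by direct iteration over (reference_positive,
    index_positive) boolean pairs; exact rationals in percent."""
    tp = sum(1 for ref, idx in pairs if ref and idx)
    fp = sum(1 for ref, idx in pairs if not ref and idx)
    fn = sum(1 for ref, idx in pairs if ref and not idx)
    tn = sum(1 for ref, idx in pairs if not ref and not idx)

    def ratio(num, den):
        return Fraction(100 * num, den) if den else None

    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
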