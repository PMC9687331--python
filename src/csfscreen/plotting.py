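"""Quotient-diagram (Reibergram) rendering.

Double-logarithmic axes: QAlb on x, the analyte quotient on y, both with
×10⁻³ tick labelling.  The bold curve is the hyperbolic discrimination line
Qlim; points above it are exactly the samples with a positive intrathecal
fraction.  Points are styled by reference-standard status.  Extra curve
definitions (e.g. alternative reference lines) can be plugged in via the
``extra_curves`` mapping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .classify import ClassificationResult
from .errors import NothingToPlotError
from .reiber import (
    Analyte,
    DEFAULT_COEFFICIENTS,
    HyperbolicCoefficients,
    IG_ANALYTES,
    QuotientProfile,
)

_STYLE = {
    "ocb_positive": dict(marker="^", color="tab:red", label="OCB-positive"),
    "ig_synthesis": dict(marker="s", color="tab:orange", label="Ig synthesis"),
    "negative": dict(marker="o", color="tab:blue", label="no immune response"),
}


def _status(result: ClassificationResult | None) -> str:
    if result is None:
        return "negative"
    if result.ocb_positive:
        return "ocb_positive"
    if result.immune_response and any(
        result.synthesis_flags.get(a, False) for a in IG_ANALYTES
    ):
        return "ig_synthesis"
    return "negative"


def render_quotient_diagram(
    profiles: Sequence[QuotientProfile],
    results: Sequence[ClassificationResult] | None,
    analyte: Analyte | str,
    path: str | Path | None = None,
    coeffs: HyperbolicCoefficients | None = None,
    extra_curves: Mapping[str, HyperbolicCoefficients] | None = None,
):
    """Render the quotient diagram for ``analyte``; returns the Figure.

    ``results`` (parallel to ``profiles``) styles the points by
    reference-standard status; pass None for unstyled points.  When ``path``
    is given the figure is also written there (format from the suffix,
    SVG or PNG).
    """
    analyte = Analyte(analyte)
    pts = [
        (p.q_alb, p.q[analyte], results[i] if results is not None else None)
        for i, p in enumerate(profiles)
        if analyte in p.q
    ]
    if not pts:
        raise NothingToPlotError(f"no profile carries analyte {analyte.value}")
    if coeffs is None:
        coeffs = DEFAULT_COEFFICIENTS[analyte]

    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    lo = min(x.min(), 2e-3) * 0.8
    hi = max(x.max(), 50e-3) * 1.2
    grid = np.logspace(np.log10(lo), np.log10(hi), 400)
    qlim_curve = coeffs.a * np.sqrt(grid**2 + coeffs.b) - coeffs.c

    fig, ax = plt.subplots(figsize=(6, 6))
    mask = qlim_curve > 0
    ax.loglog(grid[mask], qlim_curve[mask], "k-", lw=2.2, label="Qlim", zorder=3)
    if extra_curves:
        for name, extra in extra_curves.items():
            extra_y = extra.a * np.sqrt(grid**2 + extra.b) - extra.c
            m = extra_y > 0
            ax.loglog(grid[m], extra_y[m], "--", lw=1.0, label=name, zorder=2)

    for status, style in _STYLE.items():
        sel = [i for i, p in enumerate(pts) if _status(p[2]) == status]
        if sel:
            ax.scatter(
                x[sel], y[sel], s=14, alpha=0.7, zorder=4,
                marker=style["marker"], color=style["color"], label=style["label"],
            )

    formatter = plt.FuncFormatter(lambda v, _: f"{v * 1e3:g}")
    ax.xaxis.set_major_formatter(formatter)
    ax.yaxis.set_major_formatter(formatter)
    ax.set_xlabel(r"$Q_{Alb}\ (\times 10^{-3})$")
    ax.set_ylabel(rf"$Q_{{{analyte.value}}}\ (\times 10^{{-3}})$")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(f"{analyte.value} quotient diagram")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
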