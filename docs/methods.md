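# Methods

## The quotient-diagram model

Proteins reach the cerebrospinal fluid (CSF) from blood by passive diffusion
across the blood–CSF barrier. Albumin is synthesized only in the liver, so
the albumin quotient QAlb = albumin(CSF)/albumin(serum) is a pure measure of
barrier permeability for the individual patient. For a protein that can
*also* be produced inside the CNS (IgG, IgA, IgM, free light chains kappa —
FLCκ), its quotient Q must be judged against what barrier passage alone
would deliver at this patient's QAlb. The empirical upper reference bound is
hyperbolic:

    Qlim(QAlb) = a · √(QAlb² + b) − c

with per-analyte coefficients

| analyte | a    | b        | c        |
|---------|------|----------|----------|
| IgG     | 0.93 | 6×10⁻⁶   | 1.7×10⁻³ |
| IgA     | 0.77 | 23×10⁻⁶  | 3.1×10⁻³ |
| IgM     | 0.67 | 120×10⁻⁶ | 7.1×10⁻³ |
| FLCκ    | 3.27 | 33×10⁻⁶  | 8.2×10⁻³ |

shipped as a loadable YAML resource (`csfscreen/data/reiber_coefficients.yaml`)
so other published coefficient sets can be swapped in without code changes.
The intrathecal fraction IF = (1 − Qlim/Q)·100 % is the share of the
measured quotient exceeding barrier-derived protein: IF > 0 indicates
intrathecal synthesis, IF ≤ 0 its absence. IF is unbounded below and < 100
above; it is undefined (an error, not "negative") for a non-positive
quotient.

All quotients are stored internally as plain dimensionless ratios. The
clinical ×10⁻³ display convention is applied only in output tables and plot
tick labels, which removes an entire class of thousand-fold scaling bugs.

Numerical choices:

* **Tie-break at the line.** Positivity is strict (`IF > 0`); a quotient
  exactly on Qlim counts as *no* synthesis. This matches the strict
  inequality used in the case definitions and is tested explicitly.
* **Assay floor.** CSF FLCκ below the nephelometric assay's lower limit of
  quantification (0.034 mg/L) is by default clipped to the limit and
  flagged (`flck_clipped_to_lloq`); since clipping can only raise the
  quotient, it is conservative with respect to missing intrathecal
  synthesis. A `reject` policy is available for laboratories that prefer
  hard failures.
* **Units.** CSF and serum of each pair must share a unit before record
  construction (serum albumin is often reported in g/L); the math module
  validates positivity only and is unit-agnostic, verified by a
  scale-invariance test.

## Case definitions

* **Intrathecal humoral immune response** (composite reference standard):
  CSF-specific oligoclonal bands (OCB) and/or IF > 0 for any of IgG/IgA/IgM.
  FLCκ is the index test and never part of the reference standard.
* **Artificial blood contamination:** erythrocyte count > 500/µL *and*
  IF(IgM) > 0 *and* the ordering IF IgM > IF IgA > IF IgG over whichever of
  IgA/IgG are measured and IF-positive. The ordering chain is evaluated over
  the participating analytes only: an unmeasured or IF-negative IgA/IgG does
  not block the rule. This reading follows the mechanism — serum admixture
  inflates quotients in proportion to the serum/CSF gradient, which is
  largest for IgM — and is frozen in fixture tests clause by clause.
  Contamination discounts the quantitative Ig flags from the reference
  standard; OCB positivity still counts, because isoelectric-focusing
  CSF-specific bands cannot be produced by serum admixture.
* **Indeterminate reference standard:** OCB not done *and* no Ig pair
  measured. Such samples raise a dedicated error, are excluded from
  accuracy tables, and are tallied in the report's `excluded` count — never
  silently dropped.

## The screening workflow

The sequential algorithm evaluates, in fixed order: (1) serum FLCκ above
the reference range (manufacturer interval 6.7–22.4 mg/L) → PROCEED with
full Ig + OCB workup, because a high serum level depresses QFLCκ and can
mask intrathecal synthesis; (2) IF(FLCκ) > 0 → PROCEED; (3) otherwise →
OMIT. Putting the serum gate first makes the trigger label of a
serum-elevated, IF-positive sample unambiguous (`serum_flck_elevated`); the
action would be PROCEED either way. Serum FLCκ *below* the range is treated
as normal for the gate (only elevation is a masking risk) and surfaced as an
informational flag. The clinical escape hatch — imaging or cytology
suspicion justifying a full workup despite OMIT — is carried as
`override_allowed` metadata on every decision and never automated. Basic
CSF parameters (cell count, lactate, total protein) pass through untouched
and do not branch the algorithm.

## Diagnostic evaluation

Accuracy metrics are kept as exact rationals (`fractions.Fraction`)
alongside rounded display values, so integer-percent reproduction is a
matter of arithmetic, not floating-point luck. Zero-denominator metrics are
flagged undefined, never forced to 0 or 100. Two modes are reported:
`index_test` (positivity = IF(FLCκ) > 0) and `workflow` (positivity =
PROCEED). Reduction accounting counts OMIT decisions and their exact cohort
share.

**Display convention.** Percentages round half-up, with one guard: a metric
whose exact value is below 100 % is never displayed as 100 % (at integer
precision it caps at 99, at one decimal at 99.9). An NPV of 99.53 % thus
prints as 99 % (or 99.5 % at one decimal) while 98.94 % prints as 99 % —
the usual clinical convention that an imperfect test must not be reported
as perfect. Wilson confidence intervals are deliberately not produced by
default; the core report mirrors the plain contingency-table presentation.

## The synthetic cohort generator

No public data exist for paired CSF/serum cohorts of this kind, so the
generator emulates the published cohort *structure* with known ground
truth:

* **QAlb and serum FLCκ** are lognormal, parameterized by median and
  quartiles (σ = ln(q3/q1)/(2·z₀.₇₅)) — the standard model for
  barrier-function quotients and strictly positive concentrations.
  Discovery preset: QAlb median 6.4×10⁻³ (quartiles 4.7; 9.1), serum FLCκ
  13.1 mg/L (10.2; 18). Validation preset: 6.7×10⁻³ (5.1; 9.4) and
  13.1 mg/L (9.81; 17.97).
* **Serum FLCκ elevation.** A fitted untruncated lognormal would put ~10 %
  of samples above 22.4 mg/L, far more than the workflow accounting of the
  study cohorts implies (≈1–3 %); the real distribution evidently has a
  lighter right tail. `p_serum_flck_elevated` therefore pins the
  above-range mass exactly via a truncated-lognormal mixture (defaults:
  9/679 discovery, 3/278 validation, the latter back-derived from the
  omitted-sample accounting). This slightly shifts the marginal median
  (≈0.2 mg/L); a documented trade-off in favour of correct workflow
  behaviour.
* **Ig patterns** are drawn from the one/two/three-class mixture over
  non-contaminated samples (discovery counts: IgG 71, IgA 10, IgM 19,
  IgG/M 31, IgA/M 12, IgG/A 9, IgG/A/M 4 of 661). OCB is drawn conditional
  on pattern presence — conditioning on the composite reference standard
  would be circular, since OCB positivity itself creates responder status.
  The defaults make the expected responder count 245 with 204 OCB-positive
  (89 OCB-only responders among the 505 pattern-free samples).
* **FLCκ positivity** is Bernoulli conditional on responder status
  (discovery defaults 241/245 and 60/434), so pipeline-recovered
  sensitivity is exactly binomial around the configured rate — the basis of
  the replicate-recovery test.
* **Intrathecal fractions** given synthesis are Beta-distributed on
  (0, 100) % (defaults Beta(1.3, 1.8) for Ig, Beta(1.6, 1.2) for FLCκ,
  reflecting the typically larger FLCκ fractions). Synthesis-negative
  quotients are uniform on (0.2·Qlim, Qlim) — sufficient for the
  sign-based classification the pipeline consumes, with no claim to
  mechanistic realism below the line.
* **Contamination samples** get erythrocytes > 500/µL and a strictly
  ordered IgM-dominant positive triple (IF IgM ~ U(15, 70) %, each next
  fraction a U(0.3, 0.9) multiple), OCB negative, reference-standard
  negative.
* Concentrations are obtained by inverting Q through drawn serum levels
  (albumin 42 g/L, IgG 10.5 g/L, IgA 2.25 g/L, IgM 1.1 g/L medians with
  modest lognormal spread); CSF FLCκ below 0.034 mg/L is clipped and
  flagged, mirroring the assay floor.

What the generator does **not** emulate: correlation between QAlb and
synthesis status (drawn independently; not reported for the source
cohorts), band counts or any isoelectric-focusing detail, assay noise and
platform differences, and any dependence between serum FLCκ elevation and
responder status (the study's three serum-elevated false negatives suggest
such a dependence exists; the generator draws them independently). Passing
end-to-end tests therefore demonstrate the pipeline's internal consistency
and its behaviour under the published cohort structure — not performance on
real patients.

## Problem sizes in tests and the acceptance script

The replicate-recovery check runs 200 cohorts of n = 679 (a few seconds);
the acceptance script averages 50 replicates per preset, enough to put the
Monte-Carlo standard error of the recovered sensitivity well below one
percentage point. The discrimination-line formula suite is verified against
a 50-digit decimal transcription on a 1000-point QAlb grid spanning
[10⁻³, 10⁻¹] at relative error < 10⁻¹².

## Known limitations

* The hyperbolic reference curves Qmean and Qlow that decorate published
  quotient diagrams are not rendered: their coefficients are not part of
  this package's sources, and the screening algorithm never uses them. The
  plot accepts extra curve definitions via configuration for laboratories
  that have them.
* Age-dependent QAlb reference limits are out of scope; the workflow does
  not use them.
* `classify_response_pattern` over partially measured Ig panels returns the
  pattern of the measured subset (a lower bound), with the semantics stated
  in its docstring rather than a separate annotation object.
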