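# csfscreen

Quotient-diagram evaluation of cerebrospinal-fluid (CSF) proteins and an
FLCκ-first screening workflow for the routine CSF laboratory.

## The problem

Detecting an *intrathecal humoral immune response* — antibody production
inside the CNS — is central to the laboratory diagnosis of multiple
sclerosis, neuroborreliosis and other inflammatory CNS diseases. The
classical workup combines quantitative immunoglobulin quotient diagrams
(IgG, IgA, IgM) with oligoclonal-band (OCB) analysis by isoelectric
focusing, which is manual, subjective and expensive. Free light chains
kappa (FLCκ) are released stoichiometrically during antibody assembly, can
be measured on automated nephelometers, and are a highly sensitive marker
of intrathecal B-cell activity. `csfscreen` implements the laboratory
workflow that uses the FLCκ intrathecal fraction as a first-line screen:
when it is negative and the serum FLCκ level is normal, the downstream Ig
and OCB analyses can be omitted with a very high negative predictive value.

## The model

For a protein P with CSF/serum quotient Q_P, judged at the patient's
albumin quotient Q_Alb (the blood–CSF barrier measure), the hyperbolic
upper reference bound is

    Q_lim(Q_Alb) = a · √(Q_Alb² + b) − c

(per-analyte coefficients for IgG, IgA, IgM and FLCκ ship as configuration),
and the intrathecal fraction

    IF = (1 − Q_lim / Q_P) · 100 %

is positive exactly when Q_P exceeds the bound, i.e. when protein is being
synthesized intrathecally. The composite reference standard is CSF-specific
OCB and/or IF > 0 for any of IgG/IgA/IgM, with an erythrocyte-count-gated
rule that discounts IgM-dominant pseudo-synthesis caused by blood admixture
from traumatic puncture. The screening decision is sequential: serum FLCκ
above 22.4 mg/L → full workup (a high serum level can mask intrathecal
synthesis); else IF(FLCκ) > 0 → full workup; else → omit Ig and OCB.

See `docs/methods.md` for the full model account, numerical conventions
and the synthetic-cohort generator's design.

## Worked example

```python
from csfscreen import (SampleRecord, OCBStatus, Analyte,
                       build_profile, classify_sample, decide)

sample = SampleRecord(
    sample_id="LP-001",
    albumin_csf=268.8, albumin_serum=42000.0,   # mg/L; QAlb = 6.4e-3
    flck_csf=0.363, flck_serum=13.1,
    igg_csf=37.8, igg_serum=10500.0,
    iga_csf=4.3,  iga_serum=2250.0,
    igm_csf=0.44, igm_serum=1100.0,
    erythrocytes_csf=2, ocb_status=OCBStatus.NEGATIVE,
)
profile = build_profile(sample)
print(f"QAlb  = {profile.q_alb*1e3:.1f} x10^-3")
for a in (Analyte.FLCK, Analyte.IGG, Analyte.IGA, Analyte.IGM):
    print(f"Q{a.value:<8} = {profile.q[a]*1e3:6.2f} x10^-3   "
          f"Qlim = {profile.q_lim[a]*1e3:6.2f} x10^-3   "
          f"IF = {profile.intrathecal_fraction[a]:6.1f} %")
result = classify_sample(sample, profile)
decision = decide(sample, profile)
print("immune response:", result.immune_response)
print("decision:", decision.action.value, "| trigger:", decision.trigger.value)
```

prints

```
QAlb  = 6.4 x10^-3
QFLCkappa =  27.71 x10^-3   Qlim =  19.92 x10^-3   IF =   28.1 %
QIgG      =   3.60 x10^-3   Qlim =   4.67 x10^-3   IF =  -29.8 %
QIgA      =   1.91 x10^-3   Qlim =   3.06 x10^-3   IF =  -60.0 %
QIgM      =   0.40 x10^-3   Qlim =   1.40 x10^-3   IF = -250.1 %
immune response: False
decision: PROCEED_IG_AND_OCB | trigger: flck_if_positive
```

Reading: all quotients sit at typical cohort medians. The FLCκ quotient
(27.71×10⁻³) exceeds its hyperbolic limit (19.92×10⁻³), an intrathecal
fraction of 28 % — so the screen escalates to the full Ig + OCB workup even
though the three Ig quotients are below their limits and OCB are negative.
(FLCκ synthesis without any Ig response is the main source of the screen's
false positives and the price of its high sensitivity.)

## Command line

```sh
csfscreen simulate --preset validation --seed 3 --out cohort.csv
csfscreen screen   --in cohort.csv --out decisions/
csfscreen evaluate --in cohort.csv --out report/
csfscreen report   --in cohort.csv
csfscreen plot     --in cohort.csv --analyte FLCkappa --out diagram.svg
```

`simulate` writes a synthetic cohort with known ground truth (presets
emulate a discovery-style cohort of n = 679 and a prospective
validation-style cohort of n = 278); `screen` emits per-sample decisions
with triggers and rule rationale; `evaluate`/`report` produce the 2×2
contingency table with sensitivity, specificity, PPV and NPV against the
composite reference standard plus the analysis-reduction accounting; `plot`
renders the double-logarithmic quotient diagram with the bold Q_lim curve.

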