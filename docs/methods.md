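# Methods

## Index computation

All biochemistry is stored in mg/dL (the source laboratory's units) and
converted on demand with fixed molar factors: glucose 18.016, triglycerides
88.57, cholesterol 38.67 mg/dL per mmol/L. These factors reproduce the three
IDF dual-unit thresholds (100 mg/dL = 5.55 mmol/L, 150 mg/dL = 1.7 mmol/L,
50 mg/dL = 1.3 mmol/L) after rounding, and round-trip to ≤ 1e−9 relative
error.

Two formula conventions deserve note:

* **BMFI fat-mass term.** BMFI = BMI × FM × WC(m) is implemented with FM as
  a *fraction* in [0, 1]. At typical severe-obesity values (BMI ≈ 43.6,
  FM ≈ 0.509, WC ≈ 1.21 m) the fraction convention yields ≈ 26.9 kg/m, the
  scale on which the index is reported; the percent convention would yield
  ≈ 2,690. A guard rejects fractional inputs > 1 so a percentage cannot slip
  through silently.
* **VAI parenthesization.** The female VAI is computed as
  (WC / (36.58 + 1.89·BMI)) × (TG/0.81) × (1.52/HDL): waist circumference
  normalized by the whole BMI-linear term, as in the index's original
  female-specific definition. Read literally, a flat left-to-right
  evaluation of the commonly printed one-line form does not produce values
  on the index's reported scale, so the original parenthesization is used.
  Only the female branch is implemented (the intended cohorts are
  women-only); a male variant is out of scope.

WtHR takes stature in centimetres and rejects values < 3 as almost certainly
metre-valued — the one unit mistake this API invites.

## IDF classification

The classifier counts five risk factors — WC ≥ 80 cm, FPG ≥ 100 mg/dL,
SBP ≥ 130 or DBP ≥ 85 mmHg, TG ≥ 150 mg/dL, HDL-C < 50 mg/dL, each also
satisfiable by its drug-treatment flag — and labels MetS when ≥ 3 hold.
Boundary semantics are literal (≥ everywhere, strict < for HDL), and glucose
is compared in mg/dL so the threshold is exact rather than subject to
conversion rounding. This "3 of 5 with WC among the five" rule is the
operationalization used in the index-comparison literature this package
supports; the canonical IDF rule (mandatory central obesity plus ≥ 2 of the
other four) is available as `idf_variant="canonical"`. In cohorts of women
with severe obesity the two coincide in practice because the WC criterion is
essentially universal.

## Diagnostic accuracy

* **ROC/AUC.** The empirical curve is traced over all distinct score values
  used as strict cutoffs (positive ⇔ score > cutoff) plus a −∞ sentinel, so
  it runs from (0, 0) to (1, 1); the trapezoidal area equals the
  Mann–Whitney probability with ties at half credit, and the package carries
  the pairwise-probability estimator as an independent oracle
  (`auc_mann_whitney`), verified to agree to ≤ 1e−12.
* **Inference.** AUC standard errors, confidence intervals and paired
  index-vs-index comparisons use DeLong's structural components (placement
  values), the standard nonparametric treatment of correlated empirical
  AUCs and the method behind the major statistical packages' `roccomp`-style
  commands. CIs are normal-approximation, truncated to [0, 1]; perfect
  separation legitimately yields se = 0 and a point interval. Pairwise
  p-values are two-sided and deliberately unadjusted for multiple testing
  (matching common practice in this literature); the report says so.
* **Youden cutoff.** The optimal cutoff maximizes J = Se + Sp − 1 over the
  curve's finite thresholds. J values are rationals with denominator
  n₊·n₋ but are stored as floats, so maximizer ties are resolved within a
  1e−9 relative tolerance and broken toward the *smallest* threshold —
  favouring sensitivity, and deterministic.
* **Summary metrics.** Se, Sp, PPV, NPV come from the confusion counts;
  PLR = Se/(1−Sp), NLR = (1−Se)/Sp, J = Se + Sp − 1 by their identities.
  PPV/NPV default to the evaluated sample's prevalence; a
  `prevalence_override` recomputes them by Bayes' rule, which is how
  published operating points can be transported to a different base rate.
  Ratios with zero denominators are returned as `inf` (x/0, x > 0) or
  `None` (0/0), never as silently wrong numbers. Clopper–Pearson intervals
  accompany Se and Sp.
* **Descriptives.** Group comparisons use Welch's t-test by default
  (group sizes and variances differ in the motivating data; a `pooled`
  option exists), Pearson correlations are reported with r² and the
  t-transform p-value, and a 4.5-SDS screen (|value − mean|/SD over the
  full sample, SD with ddof = 1) flags outliers before analysis.

## Synthetic cohort generator

The generator emulates the two-group structure of an 876-woman
severe-obesity cohort: group membership is Bernoulli(0.62); within each
group the eleven continuous variables (age, stature, body mass, WC, HC,
fat-mass fraction, SBP, DBP, glucose, TG, HDL) follow a Gaussian copula
with marginal means/SDs fixed to the published group summaries. TG and
glucose are log-normal, moment-matched analytically to the stated mean/SD
(exact to ≤ 1e−9), reflecting their right skew and guaranteeing positive
draws; the rest are normal. Draws are truncated to physiologic bounds
(e.g. stature 1.30–2.00 m, HDL ≥ 5 mg/dL) by whole-row *resampling* — not
clipping, which would pile mass at the bounds — capped at 1,000 rounds.
`fm_kg` is derived as fraction × body mass, so the printed kg-scale fat-mass
SDs are not independently matched (documented limitation).

The within-group correlation matrix is an assumption (only means/SDs are
published): moderate positive anthropometric correlations (body mass–WC
0.8, WC–HC 0.7), SBP–DBP 0.6, TG–HDL −0.3, weaker age/glycemia/lipid links
of 0.1–0.3; it is verified symmetric positive semi-definite at construction.
Drug-treatment probabilities are likewise assumptions, chosen so the
criterion prevalences implied by the "or on drug treatment" clauses resemble
the published ones: MetS− (glucose 0.02, BP 0.10, TG 0.02, HDL 0.01) and
MetS+ (glucose 0.20, BP 0.55, TG 0.15, HDL 0.15) — antihypertensive
treatment common, glucose/lipid treatment mostly confined to the
syndrome-positive group.

Downstream evaluation labels come from applying the IDF classifier to the
generated measurements, never from the latent group, so labels and features
are always consistent; the latent group only selects the generating
distribution. Under the defaults the classified prevalence lands at 60–65%
(target 62%), latent/classified agreement at 82–85%, and the AUC ordering
reproduces the motivating study qualitatively: CMI ≈ VAI ≈ 0.87 ≫ WHR ≈ 0.68
> WtHR ≈ 0.66 > BMFI ≈ 0.58.

**What passing tests do and do not show.** The generator matches first and
second moments, skew direction, and a plausible correlation structure; it
does not reproduce the real cohort's full dependence structure (the real
MetS groups are *defined* by threshold events, concentrating criterion
co-occurrence beyond what a copula over published marginals can express),
age structure beyond its mean/SD, or any longitudinal dynamics. Pipeline
results on synthetic cohorts therefore validate the *machinery* and the
qualitative index ranking, not the study's exact AUCs or cutoffs.

## Problem sizes and determinism

All simulation-based checks run at the motivating study's scale (n = 876)
or, for the binormal DeLong validation, at 10,000 per class, chosen to make
the closed-form comparison (AUC = Φ(δ/√2), δ = 1.19) sharp at 3 standard
errors. Every random draw flows from a single `numpy` `default_rng` seed;
the same seed yields byte-identical cohort CSVs. Reports render at the
field's customary precision (AUC 2 d.p., rates as 1-d.p. percentages,
likelihood ratios 2 d.p.) while JSON retains full precision, with p-values
displayed as "<0.001" below that threshold.

## Known limitations

* Female-specific VAI only; no male or BMI-class-stratified analyses.
* The IDF rule's drug-flag clauses treat treatment as criterion-equivalent;
  dose or control status is not modelled.
* DeLong CIs are normal-approximation; no smoothed/binormal ROC fitting or
  cost-weighted cutoff selection.
* The synthetic correlation matrix and drug probabilities are assumptions;
  conclusions that depend on them (e.g. exact AUC magnitudes) should be
  treated as qualitative.
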