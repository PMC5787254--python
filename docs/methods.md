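# Methods

## The instrument

The Frail-VIG index is a deficit-accumulation frailty index: 22
questions, 25 potential deficits, eight CGA domains. Points: one per
binary deficit; Barthel dependency 0–3 (≥95 → 0, 65–90 → 1, 25–60 → 2,
≤20 → 3); cognitive impairment 0–2 (none / mild-moderate ≡ GDS ≤ 5 /
severe ≡ GDS ≥ 6); each of six chronic diseases 0/1/2, where 2 requires
advanced-illness (NECPAL) criteria — that flag is an *input* here, the
NECPAL test itself is out of scope. Score = points / 25.

Decisions the instrument definition leaves open, and how this package
resolves them:

* **Denominator and cap.** Advanced-disease double points allow a raw
  sum of up to 31. The denominator stays 25 (the instrument's stated
  deficit count, on which the published band arithmetic rests) and the
  score is capped at 1.0. A /31 denominator would shift every published
  band boundary and is rejected.
* **Advanced points per disease vs per patient.** Default: every
  advanced disease scores 2 (the scoring table attaches the rule to the
  disease rows). A `per_patient` mode (single bonus point when any
  disease is advanced) is available, matching descriptive tables that
  report advanced chronic disease as one patient-level binary.
* **Band boundaries.** The published intervals are closed on the 0.04
  lattice (0–0.15, 0.16–0.25, …). Cuts are implemented at the gap
  midpoints (0.155, 0.255, …, 0.655), making categorisation total on
  [0, 1]; every score a record can produce (k/25, a capped 1.0, or a
  rescaled k/m with m ≤ 25) falls strictly inside a printed interval,
  so the two definitions agree everywhere they both apply. On
  achievable scores the frailty rule (score > 0.25) coincides with
  membership of the top five bands.
* **Missing data.** Default strict (refuse to score). An optional
  `rescale` policy divides by the number of assessable deficits,
  refusing when more than 5% of the potential deficits are missing —
  the conventional FI missing-data ceiling; with 25 deficits that
  tolerates exactly one single-point item.
* **Emotional status "not evaluable".** Scores 0 with a warning by
  default (configurable to an error). The instrument never states a
  rule; 0 is conservative and keeps such records scorable.
* **GDS convenience mapping.** Stage 1 → none, 2–5 → mild-moderate,
  6–7 → severe. Only the ≤5/≥6 equivalences are stated by the
  instrument; stage 1 is "no cognitive decline" clinically.
* **Barthel off-grid values.** The published Barthel index only takes
  multiples of 5; other integers are rejected unless rounding is
  requested explicitly.

## Validation analyses

* **Horizon mortality** from grouped alive/deceased counts; zero-total
  bands yield flagged NaN rather than a silent 0%.
* **Kaplan–Meier / log-rank** across the seven bands delegate to
  `lifelines` (hypergeometric tie variance, censoring after deaths at
  tied times, df = k − 1, chi-square p-values, no continuity
  correction). Tests cross-check the statistic against a hand O−E
  tabulation.
* **Grouped AUC** is the tie-corrected Mann–Whitney concordance over
  band order: AUC = (Σ_j D_j·A_{<j} + ½ Σ_j D_j·A_j) / (D·A). It equals
  the rank-based AUC of any per-patient expansion that is constant
  within bands; tests verify both that identity and agreement with
  brute-force pair enumeration.
* **Youden scan** evaluates each band lower bound as a cutoff
  (test-positive = bands at or above it) and returns the J-maximising
  operating point; ties resolve to the lowest cutoff. Two-decimal
  rounding is display-only.
* **Bootstrap CI** for the AUC: percentile bootstrap, 2000 resamples by
  default, seeded; a single-class resample is redrawn. The interval
  method is a package choice — the original analysis reports CIs
  without naming one.
* **Horizon ROC on raw follow-up** refuses data censored before the
  horizon: with administrative censoring at 24 months only (the design
  here and in the validation study, which lost no patients), deaths
  before the horizon are positives and everyone else is a negative.
  Censoring-weighted (IPCW) estimation is *not* implemented — a known
  limitation if the package is pointed at cohorts with early dropout.

On the bundled validation tables the grouped AUC is 0.891 (12 months)
and 0.840 (24 months). The study's printed AUCs (0.90, 0.85) were
computed on the underlying continuous scores, which were never
published; the grouped statistic loses the within-band ordering, so it
is checked against the printed confidence-interval lower bounds (0.88,
0.82) rather than the point estimates. Whether the original ROC used
raw scores or band midpoints is unknowable from the published tables;
both views are exposed (`continuous_auc`, `grouped_auc`).

The bundled tables store counts only. Two printed percentages are
inconsistent with their own counts (the 12-month per-band "deceased %"
row, and one baseline prevalence); counts are internally consistent —
they reproduce the published sensitivity/specificity pair exactly — and
are treated as authoritative, with percentages always recomputed.

## Synthetic cohorts

The generator emulates a cohort of elderly acute-geriatric inpatients
(the validation cohort: mean age ≈ 86, 57% women, n = 590) at the level
the published tables constrain: marginal deficit prevalences, ordinal
level frequencies, patient-level advanced-disease prevalence (44.1%),
and 24-month band mortality. No joint deficit distribution is
recoverable from published data, so correlation is induced by a single
standard-normal latent frailty z:

* binary deficit i: Bernoulli(logistic(a_i + b·z)), a_i solved by
  Gauss–Hermite quadrature so the marginal matches its target;
* ordinal items (Barthel band, cognitive level, emotional status):
  cumulative-logistic thresholding of the same z, thresholds calibrated
  to the marginal frequencies; the Barthel value is uniform on the
  5-point grid inside its band;
* a present disease is advanced with probability q, calibrated
  (integrating over z) to the 44.1% patient-level target;
* survival: death time ~ Exponential(λ0·exp(β·score)), administrative
  censoring at 24 months. Identical configs are bit-identical.

Values the published tables do not pin down, chosen once: per-item IADL
prevalence 0.85/3 (only the mean IADL deficit count is published);
Barthel band probabilities (0.20, 0.37, 0.28, 0.15), which reproduce
the published mean Barthel ≈ 62.8 within about one point.

**Loading.** All items share one loading b (no correlation structure is
published that would justify more). The single-factor model trades
right-tail mass against skewness: strong loadings (b ≥ 0.75) give
skewness ≈ 0.3 but put 5–15% of scores above the 0.7 submaximal limit,
which real FI cohorts essentially never exceed (99.3% below 0.7 in the
validation cohort). The default b = 0.35 keeps the fraction below 0.7
at ≈ 0.994 with skewness ≈ 0.19 and still populates all seven bands at
n = 590. The empirical skewness of the real cohort (0.37) is therefore
matched in sign and rough magnitude only — a documented limit of the
single-factor construct.

**Hazard calibration.** (λ0, β) are fitted by least squares of
1 − exp(−λ0·e^{β·m_c}·t) to the 24-month band mortality of the bundled
table. The representative scores m_c are *not* the nominal band
midpoints: the top printed band (0.66–1) is occupied only near its
lower edge, so midpoints bias λ0 by ~16% in recovery experiments.
Instead a fixed-seed 20,000-patient pilot draw supplies per-band mean
scores (~1% recovery error at n = 10,000). `fit_hazard` exposes the
same choice via its `band_scores` argument and defaults to midpoints
for plain grouped tables. With the default calibration, pooled band
mortality across 20 study-sized replicates stays within ~6 percentage
points of the published table in every band; the exponential-in-score
hazard cannot bend sharply enough to hit the steep 0.6-band value
(97.5%) exactly, which bounds the residual.

**What passing tests do and do not show.** The simulator reproduces
marginals, the score distribution's shape constraints, and band-level
mortality — not the true joint deficit distribution, deficit
accumulation during follow-up (frailty is dynamic; baseline scores are
static here), cause-specific mortality, or informative censoring.
Agreement of the pipeline on synthetic cohorts is evidence of
implementation correctness, not of clinical transportability.

## Problem sizes and numerics

Default test/validation workloads: 20 replicates at the study size
(n = 590) for construct checks; n = 10,000 for hazard-parameter
recovery (10% relative tolerance); 1000 replicates for log-rank null
calibration (α = 0.05 within 3 binomial standard errors); 80-node
Gauss–Hermite quadrature for all marginal calibrations (intercepts
accurate to ≪ 0.005); Levenberg–Marquardt least squares for the hazard
fit with a log-cumulative-hazard regression start. Skewness is the
adjusted Fisher–Pearson estimator G1; at n = 590 its standard error is
≈ 0.10, so simulator skewness is asserted on the mean over replicates,
not per replicate.
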