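# Methods

## Staging model

A visit is staged from three ingredients: biomarker state (S = CSF
α-synuclein seed amplification, positive/negative; D = dopaminergic deficit
on DAT imaging, read as binary; genetic variant class), subtle clinical
signs per domain, and functional severity bands per domain. The rules, in
order:

1. fully penetrant *SNCA* variant, asymptomatic (no signs, no impairment,
   D−) → stage 0;
2. no signs, no impairment: D− → 1A, D+ → 1B;
3. signs without impairment: D− → 2A, D+ → 2B;
4. any severity band above "none" requires D+; stage = 3/4/5/6 for a
   maximal band of slight/mild/moderate/severe, and the tracks are the
   domains at that maximum.

Staging is defined only for S+ individuals; S− or S-missing visits raise an
"unstageable" signal rather than receiving a stage. Two deliberately
engineered edge cases:

- **Impairment with D−** is not a defined NSD-ISS state. Rather than fail
  on messy data, the engine assigns stage 2A (the "2A or lower" grouping
  used in longitudinal displays) and attaches an
  `impairment_without_dopaminergic_deficit` warning, so the anomaly is
  visible in outputs.
- **Stage 0 is asymptomatic by construction**: an *SNCA* carrier with signs
  or impairment is staged by the general rules.

### Anchors

All thresholds live in a versioned YAML `AnchorConfig`; the engine itself is
threshold-agnostic, and the config hash is echoed into every manifest.
Bands are half-open `[lo, hi)` — a score exactly at a threshold belongs to
the higher band; this boundary convention is a package decision (the
framework literature does not state one) and is pinned by tests.

The bundled config (`anchors_synthetic_v1.yaml`) is a synthetic
reconstruction: the operational anchor thresholds are published as
supplementary material of the staging-system literature and are not
redistributed here. Users applying the pipeline to real cohort data must
supply them. In the bundled config the other-nonmotor domain has no
"slight" band, encoding as *definitional* the convention that stage 3 is
reached through the cognitive and motor domains only (other-nonmotor cells
of stage-3 track tables are reported as N/A, not zero). That reading of the
published tables is a package decision, flagged here.

### Carry-forward

A follow-up visit missing stage-determining fields is completed from the
nearest earlier visit at which each field was observed — a generalization
of "carry forward from the previous annual visit" that also covers
consecutive gaps. Every filled field is recorded per row (`carried_fields`),
so strict single-step behaviour can be audited; a never-observed field
leaves the visit unstageable rather than being defaulted. The operation is
idempotent. Dopaminergic status is carried like any other field, since DAT
imaging is acquired per protocol rather than annually.

## Synthetic cohort generator

The generator emulates an early-PD/prodromal annual-visit cohort so that
every downstream stage is testable without restricted data. Defaults were
chosen once, as the study conditions, and are:

- **n = 576 participants, 5 annual follow-ups**, baseline stage mix =
  published PPMI NSD baseline distribution over stages 0–4, renormalized:
  (0: 0.002, 1A: 0.018, 1B: 0.003, 2A: 0.042, 2B: 0.240, 3: 0.567,
  4: 0.128).
- **Latent dynamics**: discrete annual steps along the ladder
  0→1A→1B→2B, 2A→2B→3→4→5→6, with geometric sojourns parameterized by
  their median m (annual step probability `1 − 0.5^(1/m)`), matching the
  annual-visit cadence; the latent path never decreases. Default medians
  (years): 0: 10, 1A: 6, 1B: 4, 2A: 3, **2B: 2, 3: 5, 4: 8**, 5: 10. The
  2B/3/4 values were set so that annual-grid KM medians from baseline are
  of the order reported for early-PD cohorts (fast out of 2B, slow out of
  4); the earlier stages are unconstrained by available data and set long.
- **Scores**: drawn uniformly on the integer grid of the latent band (no
  distributional claim beyond the band is made), then jittered by ±1
  integer, clipped to the band. Visit-level fluctuation therefore never
  flips a band on its own — assigned stage equals latent stage absent
  medication — which keeps ground truth identifiable. This is a known
  idealization: real rating-scale noise does cross anchors, so passing
  tests demonstrate pipeline correctness, not robustness to band-crossing
  measurement error.
- **Medication**: stage-dependent annual initiation hazard (2A: 0.05,
  2B: 0.28, 3: 0.55, 4–6: 0.60), chosen to put median initiation at ≈2
  years from 2B and ≈1 year from 3/4 on the annual grid, as observed in
  early-PD cohorts. The start time is drawn uniformly inside the preceding
  visit interval, so the 90-day exposure rule has bite. While on
  medication, each domain score is reduced by a fixed amount (motor 4,
  cognitive 0, other-nonmotor 1 score units; floored at 0) — a
  deterministic mechanism that makes stage reversion producible and exactly
  testable. Stochastic treatment response is out of scope.
- **Dropout** 0.05/year, independent of stage by default with an optional
  stage multiplier; **missingness** 0.05 per stageable field per follow-up
  visit (baseline is never blanked).

The random-number layout is fixed per participant, so parameter changes
under a common seed preserve common random numbers (monotone-comparison
tests rely on this). Everything is bit-deterministic given the seed.

Not emulated: item-level MDS-UPDRS responses, DAT binding ratios, CSF
assay kinetics, correlated multi-domain progression, informative
missingness, calendar-date effects.

## Longitudinal analysis

- **Exclusions** (each participant lands in the analysis set or the log,
  never both): unstageable/S− baseline; no stageable follow-up; baseline
  below 2A (the published analysis restricts to stage 2+); baseline 2A
  without a follow-up DAT assessment actually observed (not carried).
- **Tabulation**: visits bin to the nearest integer year (±6-month window;
  synthetic data are nominal already). Observed mode counts attended,
  stageable visits; LOCF-completers mode restricts to participants
  stageable at the year-5 visit and fills interim gaps with the last
  stage carried forward. LOCF never invents a label absent from the
  participant's history, and both modes agree exactly on complete data.
  Unstageable attended visits are dropped with a log, not carried.
- **First stage increase**: earliest visit with stage rank strictly above
  the *baseline* rank. A reversion followed by return to baseline is not an
  increase; stage skips are kept as-is (they arise from missed visits).
- **Flows**: year-pair transition counts over LOCF-completed completers
  with baseline 2B/3/4; conservation (flows sum to the completer count at
  every step) is enforced by construction and by test.

## Time-to-event

Product-limit estimation via `lifelines` behind the module surface, ties
resolved events-before-censorings; tests pin the estimator to a
hand-computed oracle. Median CI by inversion of the log–log (exponential
Greenwood) band — the CI method is a package choice, made swappable via the
fit's `alpha`. An undefined bound is reported as "not reached". Event times
sit on the annual visit grid; the medication event is the first *attended*
visit on medication, not the start date. Formal interval-censored
estimators are out of scope.

## Track attribution and medication impact

A domain "contributes" to a progression event iff its severity band at the
destination visit is at least the band anchoring the destination stage —
equivalently, the domains at the visit's maximal band. The seven mutually
exclusive combinations partition the progressors; per-domain marginals
equal the sum of combinations containing the domain. The 3-year restricted
table treats the boundary as closed (an event at exactly 3.0 years is
included) — flagged for sensitivity toggling.

For medication impact, the pre/post pair is the last visit before the
medication start time and the first visit at or after it. Pairs are
excluded when exposure at the post visit is under 90 days or when either
visit cannot be staged *without* carry-forward (enforced by re-staging both
visits with carry-forward disabled). Reversion compares the post-visit
stage to the pre-visit stage (not to baseline), per the pre/post framing.
Percentages are printed nearest-integer; raw fractions are retained in
machine outputs.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 150–2000 participants over 2–5
years — large enough for the binomial/KM checks' 3-standard-error bands,
small enough to run in seconds. Tolerances: exact equality for rule and
arithmetic checks; 3 Monte-Carlo SE for stochastic recovery checks; one
visit interval (1 year) for KM medians on the annual grid. Stage labels are
strings ordered through `stage_rank`; severity bands through `band_rank`;
all probabilities validated to [0, 1] and the baseline mix to sum 1 ± 1e-9.

## Known limitations

- The bundled anchors are synthetic; absolute staging results on real data
  require the operational thresholds.
- Single-path latent dynamics (one primary impairment track per
  participant, independent secondary tracks at a fixed probability) are a
  simplification; real domain progression is correlated.
- Medication effect is deterministic and time-constant; no dose, class, or
  wearing-off structure.
- Annual-grid event times understate true continuous-time precision;
  medians inherit the grid.
- The stage-4 reversion fraction under defaults is governed by the ratio of
  the medication effect to band widths, not fitted to any cohort.
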