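# Methods

## Scope and data model

The package evaluates three cervical-spine-injury (CSI) prediction rules on
patient-level cohorts of children (0–17 y) after blunt trauma. A record
carries demographics, a mechanism of injury with CCR-relevant sub-flags,
GCS/AVPU, nineteen tri-state predictor variables, the reference-standard
CSI status, the imaging actually obtained, and a descriptive management
annotation (never used in statistics). Tri-state predictors take exactly
`present` / `absent` / `unknown`; `unknown` is preserved through CSV I/O
(empty cell ⇒ unknown) because the engines treat it differently from
`absent`. Age strata split at the 8/9 birthday, matching the anatomic
transition that changes the typical level and type of pediatric CSI.

## Rule engines and the unknown-handling policy

The engines are deterministic functions record → decision. Where a source
cohort's variables do not perfectly match a rule's items, the gaps are
bridged by an explicit policy (all switches on `RulePolicy`):

* **Three-tier pediatric rule.** Presence-of-factor logic: `unknown` counts
  as absent. High-risk evaluation strictly precedes the radiography tier.
  With GCS missing, AVPU alone decides the severe-impairment item.
* **NEXUS.** Clearance requires positive verification of every criterion,
  so `unknown` fails clearance — except the two memory/response items,
  which default to satisfied in an alert, GCS-15 child because they cannot
  be administered to preverbal children (switchable). When the dedicated
  painful-distracting-injury field is unknown, it is mapped from
  substantial head/torso injury (switchable); that mapping narrows the
  NEXUS notion of a distracting injury (e.g. an isolated femur fracture
  would not be captured), which is a structural caveat of any such
  crosswalk, not a computational one.
* **CCR.** The rule is defined for GCS 15 with normal vital signs; records
  failing that gate are classified positive and flagged `gated_positive`
  so downstream statistics can cover the whole cohort while audits can
  separate gate failures from rule-driven positives. Unknown low-risk
  criteria do not count as satisfied; unknown rotation means imaging.
  The age ≥ 65 item is retained for fidelity though unreachable here.

Criterion identifiers (`pecarn.high.gcs3_8`, `ccr.low.none_satisfied`, …)
are stable strings so fired criteria are machine-comparable.

## Accuracy statistics

Wald intervals are the default because recomputing every published
confidence bound from its own confusion counts reproduces the printed
values exactly under half-up 1-decimal rounding (z = Φ⁻¹(0.975); 1.96
rounds identically on every cell). Wilson is available for extreme
proportions; at p̂ ∈ {0, 1} the Wald interval collapses to a point and is
reported with a logged warning rather than silently substituted. A zero
denominator leaves the statistic undefined, never 0. All percentage
formatting (half-up, 1 decimal; AUC 2 decimals) is centralized so reports
cannot disagree with the statistics module.

The AUC is the single-operating-point trapezoid (sensitivity +
specificity)/2 — each rule is a single-threshold classifier, so its ROC
contains one non-trivial point. This matches all published AUC values.

## Imaging projection

The observed radiography:CT ratio is computed over children imaged by
radiography or CT only; MRI-only and other modalities are excluded from
the denominator (their published counts confirm this convention). For the
binary rules, CT = round-half-up(positives × CT share) and radiography is
obtained by subtraction, so cleared + radiography + CT equals the cohort
size exactly; rounding both components independently could violate
conservation. Age-stratum projections use stratum-specific observed
ratios — this choice reproduces the published per-age predicted rows
exactly, whereas a single overall ratio does not.

## Stochastic cohort generator

The generator emulates the study conditions: n = 22 430, CSI prevalence
1.9%, age split 11 633 / 10 797, published per-stratum factor prevalences
(e.g. self-reported neck pain 32.1% at 9–17 y vs 10.7% at 0–8 y), the
published mechanism-of-injury and observed-imaging distributions, and
58.3% male (the count-consistent figure).

Factor–outcome association uses per-predictor multipliers: given marginal
p and multiplier m, P(factor | CSI) = m·p/(1 + (m−1)·prev), with the
mixture pinned to p, so configured marginals hold exactly in expectation
regardless of m; an infeasible pair (conditional > 1) raises an error
naming the predictor. Multipliers were calibrated analytically against the
published rule sensitivities; younger children need stronger association
(multipliers 4–10) than older ones (2–6) because their factor base rates
are lower. Only marginals and sensitivities are published, so this
conditional-independence-with-couplings structure is the simplest
calibratable model; a full copula would be unidentifiable.

Couplings (all marginal-preserving conditionals, defaults on
`GeneratorConfig`): examination tenderness given self-reported pain (0.70);
GCS 3–8 and focal deficit enriched given abnormal ABC (severe-physiology
cluster); unresponsive AVPU drawn within the GCS 3–8 subset (guaranteeing
the AVPU/GCS invariant); posterior midline tenderness given examination
tenderness (0.75); dangerous-mechanism sub-flags drawn per mechanism
category with CSI enrichment; memory/response items unknown below age 4.

At the default seed the generated cohort lands at CSI 1.87%, overall rule
positivity 41.4% / 36.1% / 41.9% (pediatric rule / NEXUS / CCR) and
sensitivities 88% / 78% / 84% — near, not on, the published operating
points (93% / 86% / 91%). The residual gap is expected: the real joint
distribution of predictors is unknown, and the conditional-independence
structure spreads risk factors more evenly across injured children than
real severity clustering would. Passing generator-based tests therefore
demonstrates calibration of prevalences, marginals and qualitative
discrimination ordering, not exact reproduction of the published accuracy
table — that is the fixture's job.

## Table-exact fixture

`build_table_exact_fixture()` constructs a deterministic 22 430-record
cohort that reproduces every published per-stratum confusion row for all
three rules, the three-tier rule's cleared/radiography/CT allocation
(including the per-stratum CT splits), and the observed imaging counts.
The construction exploits rule-private triggers — abnormal ABC (CT tier),
self-reported neck pain (radiography tier), intoxication (NEXUS),
paresthesias (CCR) — none of which is read by another engine, so each
rule's marginal counts are satisfied independently by assigning positives
to leading index ranges within each (stratum × CSI) cell. The published
age-stratum rows sum exactly to the overall rows, so stratum-exact implies
overall-exact. No constraint needed relaxing; would the archetype solving
ever become infeasible under different targets, the builder's contract is
to satisfy per-rule marginals and report the relaxed joint constraints.

Two quantities are modeling choices because they were never published:
the cross-rule joint overlap (leading-range assignment makes the rules'
positive sets maximally nested), and the CT/radiography split of the
three-tier rule's true positives (all placed in the CT tier). Archetype
records are intentionally stylized — e.g. an intoxication flag may appear
on a young child, and abnormal ABC coexists with nominally normal vital
signs — the fixture encodes published margins, not clinical realism.

## Numerical and testing choices

* Rounding uses `decimal` half-up (away from zero); binary `round()`
  would bankers-round 0.05 boundaries down.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  default seed is fixed at 20251219 for documentation reproducibility and
  every entry point accepts a seed.
* Large-n checks run at n = 100 000 (marginal convergence) and n = 50 000
  (independence oracle), sizes at which binomial noise on a marginal is
  ≲ 0.2 pp. The independence oracle (all multipliers 1 ⇒ decisions carry
  no information about CSI) compares each rule's sensitivity to its
  positivity rate within 3× the binomial standard error of the
  difference; with only ~950 CSI records at that size, a fixed absolute
  band materially tighter than that would reject a true null for a
  substantial fraction of seeds.
* Property suites (tier monotonicity, NEXUS conjunctivity, CCR cascade
  order, count conservation) run both as derandomized hypothesis tests
  and over ≥ 1 000 seeded uniform-random records whose field combinations
  (contradictory flags, all-unknown) are far outside the generator's
  realistic envelope.

## Known limitations

* The exact variable crosswalk used by the source study for NEXUS/CCR is
  not public; the policy here follows its narrative description and is
  switch-configurable, but item-level agreement cannot be verified.
* Whether the study scored the CCR rotation stage at all is not stated;
  this implementation scores it, with `unknown` conservative.
* The generator reproduces marginal structure, not the true predictor
  joint; accuracy statistics on generated cohorts are approximate by
  design (see above).
* No MRI-decision logic, radiation-dose, or cost modeling; no
  multi-threshold ROC analysis (the rules define single thresholds).
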