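# csirules

Tools for comparing clinical prediction rules for **pediatric cervical spine
injury (CSI)** after blunt trauma. CSI is rare in children (≈1–2% of those
evaluated after trauma) but devastating when missed, and the imaging used to
find it — especially CT — carries a lifetime radiation-induced cancer risk.
Three prospectively derived prediction rules compete for this decision:

* the **pediatric three-tier PECARN CSI rule** — high-risk factors
  (GCS 3–8 or unresponsive on AVPU; abnormal airway, breathing or
  circulation; focal neurologic deficit) → consider CT; otherwise
  CART-derived factors (altered mental status; self-reported neck pain or
  neck tenderness on examination; substantial head or torso injury) →
  consider radiography; otherwise clinically cleared;
* **NEXUS** — imaging unless *all* low-risk criteria are verified (no
  posterior midline tenderness, no intoxication, normal alertness, no focal
  deficit, no painful distracting injury);
* the **Canadian C-spine Rule (CCR)** — for patients with GCS 15 and normal
  vital signs, a cascade of high-risk factors, low-risk criteria, and active
  45° neck rotation.

The package is aimed at clinical epidemiologists and methodologists: it
provides deterministic rule engines over typed patient records (with an
explicit, configurable policy for `unknown` predictor values),
diagnostic-accuracy statistics, projected imaging-rate estimation, and two
synthetic stand-ins for the (non-public) study cohort of 22 430 children.

## The statistics

For a rule applied to a cohort with reference-standard CSI status, the 2×2
confusion table (TP, FP, FN, TN) yields

sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
NPV = TN/(TN+FN), PPV = TP/(TP+FP),

each with a 95% Wald interval p̂ ± z·√(p̂(1−p̂)/n) clipped to [0, 1]
(Wilson optional). Each rule operates at a single threshold, so its ROC has
one operating point and AUC = (sensitivity + specificity)/2.

Projected imaging allocation: the three-tier rule maps its tiers directly to
CT / radiography / cleared. The binary rules (NEXUS, CCR) do not choose a
modality, so their positives are split by the *observed* radiography:CT
ratio among imaged children (per age stratum), with
CT = round-half-up(positives × CT share) and radiography the remainder —
conservation of the cohort size is exact by construction.

## Worked example

```bash
python examples/reproduce_accuracy_table.py
```

builds the deterministic table-exact cohort (22 430 records whose predictor
patterns encode the study's per-rule confusion counts), classifies it with
all three engines and prints, for the overall stratum:

```
 stratum   rule  tp   fp  fn    tn  sensitivity  specificity  npv  ppv  auc
     all    ccr 393 9436  40 12561         90.8         57.1 99.7  4.0 0.74
     all  nexus 371 7639  62 14358         85.7         65.3 99.6  4.6 0.75
     all pecarn 404 8821  29 13176         93.3         59.9 99.8  4.4 0.77
```

Reading: of 433 children with CSI, the pediatric rule flags 404
(sensitivity 93.3%, 95% CI 90.9–95.7) while clearing 13 176 of 21 997
uninjured children (specificity 59.9%); its one-point AUC 0.77 is the best
of the three. `examples/projected_imaging_rates.py` adds the imaging
allocation — the pediatric rule projects the lowest CT rate (1549 children,
6.9%, vs 10.8% for NEXUS and 13.2% for the CCR) because only its high-risk
tier is routed to CT.

Other examples: `classify_patients.py` (single records, which criteria
fired), `simulate_cohort.py` (stochastic cohort at study conditions),
`full_pipeline.py` (config-driven run writing JSON/Markdown reports). The
same capabilities are exposed as a thin CLI:

```bash
csirules simulate --n 22430 --seed 1 --out cohort.csv
csirules evaluate --in cohort.csv --out report.csv
csirules run --config run.yaml
```

## Layout

```
src/csirules/
  records.py     typed patient records, validation, CSV I/O, age strata
  rules.py       the three rule engines and unknown-handling policy
  diagnostics.py confusion tables, test characteristics, CIs, one-point AUC
  projection.py  observed modality ratios and imaging projections
  simulate.py    stochastic generator + deterministic table-exact fixture
  report.py      end-to-end pipeline and comparison report
  cli.py         thin click CLI
docs/methods.md  model, calibration, and design notes
```
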