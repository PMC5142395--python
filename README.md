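# limbscreen

Diagnostic accuracy of lower-limb peripheral arterial disease (PAD)
screening strategies, for clinicians and methodologists studying
non-invasive vascular assessment.

Podiatrists and other front-line clinicians screen for PAD with pressure
indices: the ankle–brachial index (ABI, ankle over brachial systolic
pressure; < 0.90 conventionally indicates PAD) and the toe–brachial index
(TBI, toe over brachial; < 0.70 positive). The ABI fails in populations
prone to medial arterial calcification (MAC) — diabetes, renal disease,
advanced age — where stiff ankle vessels yield falsely elevated or
*incompressible* readings. `limbscreen` implements and compares two
strategies for choosing the test, against a colour duplex ultrasound
reference standard (PAD = any artery with > 50% stenosis):

* **Targeted** — pick the TBI up front when diabetes or renal disease is
  present or age exceeds 75; otherwise use the ABI.
* **AHA guideline** — use the ABI for everyone, substituting the TBI only
  when the ABI exceeds 1.4 (or the vessel is incompressible).

The package provides:

* a screening engine (eligibility, test selection, per-patient calls,
  exclusion handling) over validated cohort/duplex CSV files;
* the full accuracy statistics of a strategy: sensitivity, specificity,
  predictive values, diagnostic accuracy, likelihood ratios
  (LR+ = sens/(1−spec), LR− = (1−sens)/spec), exact Clopper–Pearson
  binomial confidence intervals for proportions and Simel log-method
  intervals `exp(ln LR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))` for
  likelihood ratios, with clinical-importance annotations;
* a **reconstruction oracle** that recovers a study's 2×2 contingency
  table exhaustively from its printed N, diseased count, sensitivity and
  specificity — making published results tables fully checkable without
  patient data;
* a **synthetic cohort simulator** calibrated to an elderly,
  diabetes-enriched screening population (n = 119, 61.34% diabetes,
  42.85% PAD prevalence, 13.44% incompressible ankle pressures), with an
  explicit MAC mechanism and a hemodynamic-significance mixture.

## Worked example

Recover the 2×2 table behind a published strategy column (117 analyzed,
50 diseased, sensitivity 62.00%, specificity 85.07%) and print its full
statistics:

```sh
$ limbscreen reconstruct --n 117 --diseased 50 --sens 62.00 --spec 85.07
tp=31 fn=19 fp=10 tn=57
```

```python
>>> from limbscreen import ContingencyTable, full_report, report_to_dict, ReportOptions
>>> t = ContingencyTable(31, 19, 10, 57, denominator_override=119)
>>> rep = report_to_dict(full_report(t), ReportOptions(paper_compat=True))
>>> rep["metrics"]["ppv"]["estimate"], rep["metrics"]["npv"]["estimate"]
(75.61, 75.0)
>>> rep["metrics"]["lr_pos"]["estimate"], rep["metrics"]["lr_pos"]["annotation"]
(4.15, 'may_be_important')
>>> rep["metrics"]["accuracy"]["estimate"]
73.94
```

The reconstruction is unique: only TP = 31 and TN = 57 round to the
printed sensitivity and specificity. The positive likelihood ratio 4.15
means a positive targeted screen multiplies the odds of PAD about
four-fold — enough to "may be important" on the conventional 2–5 band.
`denominator_override=119` quotes diagnostic accuracy against the
recruited cohort rather than the 117 analyzed, and `paper_compat`
truncates that row the way published tables often do.

Simulate a cohort and run both strategies end to end:

```sh
$ limbscreen --seed 11 simulate --out-prefix synth
wrote synth_cohort.csv and synth_duplex.csv (n=119)
$ limbscreen run --cohort synth_cohort.csv --duplex synth_duplex.csv
                          targeted targeted 95% CI    AHA      AHA 95% CI
Sensitivity                  44.90  30.67 to 59.77  40.82  27.00 to 55.79
Specificity                  91.43  82.27 to 96.79  92.86  84.11 to 97.64
...
```

A single synthetic cohort of 119 is noisy (the sensitivity CI spans ~30
points); the simulator's *mean* operating characteristics over hundreds
of replicates are what the calibration pins down.

## Layout

| module | contents |
| --- | --- |
| `limbscreen.cohort` | participant/pressure/duplex domain types, validation |
| `limbscreen.indices` | ABI/TBI computation, conventions, limb aggregation |
| `limbscreen.screening` | eligibility, targeted and AHA strategies |
| `limbscreen.reference` | duplex reference standard, prevalence summaries |
| `limbscreen.dx_stats` | contingency tables, CIs, likelihood ratios, reports |
| `limbscreen.reconstruct` | 2×2 recovery from printed summaries |
| `limbscreen.simulate` | calibrated synthetic cohort generator |
| `limbscreen.io` / `limbscreen.cli` | CSV dialects, YAML config, pipeline, CLI |

See `docs/methods.md` for the model, calibration and limitations.
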