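# Methods

## Screening model

Each participant carries bilateral brachial, ankle (dorsalis pedis and
posterior tibial) and toe systolic pressures. Indices are computed per
limb — ABI as the higher ankle vessel over the higher arm, TBI as the toe
pressure over the higher arm — and collapsed to one per-patient value by
the worst-limb (lower-index) rule. All three conventions (ankle vessel,
arm, limb aggregation) are configurable because none is universal in
practice and each shifts sensitivity; the defaults are the dominant
clinical choices. An ankle vessel the cuff cannot occlude is an explicit
*incompressible* state, assigned either by input flag or when a recorded
ankle pressure exceeds a configurable cuff ceiling (default 250 mmHg; the
population this package emulates reports an incompressible fraction but
no ceiling, so the value is a package choice).

Strategy logic, with strict boundaries throughout:

* **Targeted**: TBI if diabetes ∨ renal disease ∨ age > 75, else ABI.
  A required TBI with no toe pressure excludes the participant from this
  strategy (the analyzed set shrinks, mirroring how such exclusions are
  reported). An ABI that comes back incompressible or above 1.4 falls
  through to TBI; if that TBI is also unavailable the screen is
  indeterminate.
* **AHA**: ABI unless it *exceeds* 1.4 (strictly), in which case TBI.
  Incompressible ABIs also fall through to TBI by default; this is the
  guideline's evident intent for vessels that cannot be occluded, but the
  written rule mentions only the >1.4 substitution, so the behaviour is
  switchable (`aha_incompressible_to_tbi`).

Positivity thresholds ABI < 0.90 and TBI < 0.70 are the conventional
cut-offs; the comparison source for this package does not state its
thresholds, so both are config-exposed. Doppler waveforms are carried as
data and an optional adjunct mode (`waveform_adjunct:
monophasic_positive`) upgrades a negative screen on any
monophasic/absent pedal waveform; it is off by default because how
waveforms entered the original binary classification is not documented.

The reference standard is colour duplex: PAD iff any arterial segment
shows stenosis strictly greater than 50%. Segments are classed proximal
(aorto-iliac through popliteal) versus distal (infrapopliteal); the
boundary is not standardized, so it lives in an editable vocabulary file
(`src/limbscreen/data/segments.csv`) rather than code.

## Statistics

Proportion CIs are exact Clopper–Pearson, computed from beta quantiles:
lower = Beta(k, n−k+1) at α/2 (0 when k = 0), upper = Beta(k+1, n−k) at
1−α/2 (1 when k = n). The choice is deliberate: the printed proportion
intervals this package reproduces match exact binomial and not
Wald/Wilson. Likelihood-ratio CIs use the Simel log method,
`var(ln LR⁺) = 1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)` (and the FN/TN
analogue for LR⁻); a zero cell makes the interval undefined rather than
an error. LR importance annotation: important if LR⁺ ≥ 5 or LR⁻ ≤ 0.2,
may-be-important if LR⁺ ∈ [2, 5) or LR⁻ ∈ (0.2, 0.5]; the bands are the
conventional post-test-probability heuristics, inferred here because the
reproduced table gives footnote letters without a rule, and are
config-exposed.

Percent metrics are rendered round-half-up to two decimals. A
`paper_compat` switch truncates the diagnostic-accuracy row only, and
`denominator_override` lets accuracy be quoted against the recruited
rather than analyzed N — both exist because the published accuracy cells
this package checks against are truncated and use the recruited
denominator (88/119 → 73.94, 89/119 → 74.78).

## Reconstruction oracle

Sensitivity constrains only TP (given the diseased count) and
specificity only TN, so enumerating TP ∈ [0, D] × TN ∈ [0, N−D] and
keeping values within ±0.005 (proportion scale) of the printed two-
decimal figures recovers every consistent table; optional printed
PPV/NPV/LRs rank candidates. For the two strategy columns checked in the
acceptance suite the recovery is unique. The analyzed-set inputs
(117/50 for the targeted arm) are themselves derived: 119 recruited with
51 PAD, minus two toe-pressure exclusions of whom exactly one must have
been PAD-positive for the printed CI denominators (50 diseased, 67
non-diseased) to hold.

## Synthetic cohort generator

The generator emulates the marginal structure of an elderly,
diabetes-enriched screening population: n = 119, 63.02% male, age
truncated-normal (73.1, 7.2) on [53, 92], diabetes 61.34%, PAD 42.85%
split distal-only/proximal-only/both 37:7:7, occlusions concentrated
distally (targeting 33.61% of participants), 13.44% incompressible ankle
pressures, and a 2/119 per-participant chance of missing toe pressures.
Renal disease (8%), smoking (15%) and exertional leg pain (30%) are
plausible placeholders — they are not reported for the emulated
population. Participants who would fail the screening eligibility rule
are assigned leg pain, since everyone in such a cohort met the inclusion
criteria.

Hemodynamics per participant:

* brachial base pressure ~ Normal(140, 15) truncated to [100, 220] mmHg,
  arms differing by Normal(0, 4);
* disease affects one limb (60%) or both (40%); each diseased territory
  is *hemodynamically significant* (pressure-reducing) with probability
  0.45 — duplex lesions in the 50–95% range frequently leave distal
  pressures near normal, and this mixture is the main reason neither
  strategy approaches perfect sensitivity;
* true ankle and toe perfusion ratios drawn per limb from severity-class
  normals (ankle: none 1.08±0.08, subcritical 1.02±0.10, distal
  0.85±0.15, proximal 0.65±0.12, both 0.55±0.12; toe: 0.88±0.10,
  0.82±0.10, 0.45±0.15, 0.55±0.12, 0.35±0.12), clipped to [0.05, 2.5];
* MAC with probability logistic(−1.45 + 1.3·diabetes + 1.0·renal +
  0.5·(age−70)/10); MAC multiplies measured ankle pressures by a shared
  LogNormal(ln 1.35, 0.35) inflation factor (toe vessels spared); any
  reading driven above the 250 mmHg cuff ceiling becomes incompressible;
* every cuff reading carries Normal(0, 4) mmHg measurement noise;
  waveform classes are sampled conditional on the limb's true ankle
  ratio.

Every hemodynamic number is a synthetic calibration value, not a
published measurement (the emulated study reports no pressures). The
calibration requirement is that over 500 replicated cohorts of n = 119
the mean sensitivity and specificity of each strategy fall inside the
published 95% CIs — targeted (47.17, 75.35) and (74.26, 92.60), AHA
(34.75, 63.40) and (85.62, 98.37) — and that large-n marginals hit their
targets within Monte-Carlo error. The shipped defaults satisfy all of
these (means ≈ 56/89 targeted, ≈ 45/90 AHA); they are not unique in
doing so, and the bands are wide, so the generator should be read as *a*
population consistent with the published operating characteristics, not
an inference about the true one.

Randomness: one seed, split into per-participant substreams with
`numpy.random.SeedSequence.spawn`, so growing a cohort never reshuffles
earlier participants and identical seed+config gives byte-identical CSV
output. Replicate r of a calibration run uses seed
`(base·1 000 003 + r) mod 2³¹`, making runs with different hemodynamic
settings paired draw-for-draw (used by the MAC-suppression monotonicity
test).

What the generator does **not** model: limb-level arterial anatomy,
correlation between PAD and its risk factors (disease status is drawn
independently of diabetes, so strategy arms are not confounded by test
selection), vasospastic disorders, segmental pressures, exercise
testing, sonographer error in the duplex reference. Passing calibration
therefore shows the pipeline reproduces a population with the published
screening behaviour, not that it would reproduce any particular real
cohort.

## Numerical and design notes

* Problem sizes: property suites use 300–1000 random tables, CI coverage
  2000 binomial draws, calibration 500 replicates in the test suite and
  200 in the acceptance script (the extra replicates change the means by
  less than Monte-Carlo noise), marginal checks n = 10⁵.
* `screen_cohort` aborts when more than half the screened records are
  indeterminate — in practice that signature means a misconfigured
  convention block, not data.
* The worst-limb aggregation treats an incompressible limb as
  artifactually high: a numeric contralateral limb index always takes
  precedence; a patient is incompressible only when no limb yields a
  number.
* Ties/boundaries: age cut-offs and the 1.4 ceiling are strict; an index
  exactly at a positivity threshold is a negative screen (`<`, not `≤`).
* Truncation in `round_percent` adds 10⁻⁹ before flooring to keep values
  that are exact at two decimals (e.g. 62.00 stored as 61.999…) stable.

## Known limitations

Reconstruction needs the diseased/non-diseased split; it cannot recover
tables from CIs alone. The PPV/NPV confidence intervals reported are
Clopper–Pearson on the predictive-value proportions and therefore do not
match summary tables whose PPV/NPV CI cells are typeset copies of the
likelihood-ratio intervals. The simulator's calibration is
underdetermined (many hemodynamic settings satisfy the bands), so its
parameters should not be interpreted as estimated physiology.
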