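# Methods

## The validation model

The package implements the analysis stage of a fixed-design device
validation: 33 subjects, nine measurements each (slots BPA, BPB,
BP1…BP7), alternating a two-observer auscultatory reference with the test
device. BPA/BPB are entry/familiarisation readings; the analysed device
slots are BP2, BP4, BP6, each flanked by observer slots. Per pressure type
this yields 99 comparisons *d = device − reference*.

Grading applies the protocol thresholds exactly and only at the design
size: Part 1 on the pooled cumulative band counts (two-of-three 73/87/96
and all-of 65/81/93 at ≤5/≤10/≤15 mmHg over 99 pairs), Part 2 on
per-subject tallies (≥ 24 of 33 subjects with ≥ 2 of 3 within 5 mmHg,
≤ 3 subjects with 0 of 3). Other sample sizes raise
`UnsupportedSampleSizeError` rather than interpolating: the thresholds are
calibrated to n = 33/99 and scaling them would change their operating
characteristics silently.

"Within X mmHg" is inclusive (|d| ≤ X), the convention of banded-difference
reporting. Banding, Part-2 tallies and the Bland–Altman inside-limits check
all derive from the same absolute differences, so their agreement is an
internal consistency invariant, tested as such.

## The device–reference pairing rule

The observer reference at a slot is the mean of the two blinded observers,
an exact integer because both read to the nearest 2 mmHg. How a device
reading is anchored to its neighbouring observer slots is genuinely open in
summary write-ups, so it is a configurable `PairingStrategy` recorded in
the report's provenance:

* `flanking_mean` (default): mean of the observer references immediately
  before and after the device slot — the symmetric reading of "the average
  was taken", and the one whose reference noise has a closed-form weight
  (each flanking reference contributes 1/4 of a single observer's variance).
* `preceding`, `following`: one-sided anchoring.
* `flanking_closest`: the flanking reference closer to the device value
  (ties to the preceding one).

When the within-session true pressure is constant and observers are
noiseless, all strategies coincide; this limit is a property test.

## Observer handling

Observers are blinded and simultaneous; pairs differing by ≥ 4 mmHg in
either pressure are flagged for repetition (`check_observer_agreement`)
and an unresolved disagreement cannot enter the analysis
(`observer_reference` raises). Note the boundary: a 4-mmHg gap *is* a
disagreement, so the largest admissible gap is 2 mmHg on the 2-mmHg grid.

The observer-difference summary (second minus first observer) pools the
four observer slots that feed the comparisons (BP1, BP3, BP5, BP7; BPA is
entry-only) and reports the signed range/mean/SD per pressure type plus
the absolute-difference summary, because published observer-agreement
tables are ambiguous about which of the two is meant.

## Synthetic cohorts

`generate_cohort(CohortSpec, DeviceErrorModel)` emulates the study
conditions; all defaults are fixed design choices, not tuning knobs.

* **Recruitment**: 33 subjects split 11/11/11 across low/medium/high
  strata (shuffled), 12 men / 21 women. Entry pressures are drawn uniformly
  on the 2-mmHg grid within per-stratum spans — SBP 107–129 / 130–160 /
  161–180, DBP 67–79 / 80–100 / 101–128 — the intersection of the protocol
  strata with the observed span of the emulated cohort. SBP and DBP strata
  are assigned jointly (a subject low in one is low in the other), which is
  clinically realistic and guarantees DBP < SBP structurally. The 2-mmHg
  grid makes the noiseless limit exact: error-free observers read the true
  value with zero rounding residue, so an error-free device shows
  identically zero differences.
* **Within-session drift**: the true pressure follows a Gaussian random
  walk across the nine slots, step SD 0.5 mmHg by default — enough serial
  variation to make the pairing rule observable, small against the
  5-mmHg band.
* **Observers**: reading = true + N(0, σ_obs), rounded to the nearest
  2 mmHg, independently per observer; σ_obs = 1.0 mmHg by default, giving
  an inter-observer difference SD ≈ √(2(σ² + 1/3)) ≈ 1.6 mmHg — on the
  scale of reported observer-agreement tables — while keeping ≥ 4 mmHg
  repeats rare. Disagreeing pairs are redrawn (counted as repeats) up to
  `max_repeats`, then consensus is forced; the truncation shrinks the
  realised SD slightly, which the calibration test tolerates.
* **Device**: reading = true + bias + slope·(true − 120) + N(0, σ_dev),
  rounded to 1 mmHg, clipped to 0–299 mmHg. Presets: `IDEAL_DEVICE` (0, 0),
  `PAPER_LIKE_DEVICE` (bias 1.9, σ 1.5 — the scale of the emulated study's
  reported mean ± SD), `GROSS_BIAS_DEVICE` (bias 20, σ 2, which fails with
  probability ≈ 1 since P(|d| ≤ 15) ≈ Φ(−2.5) per pair).
* **Demographics** (age 36–79 y, weight 88–136 kg, BMI 31.48–81.75, wrist
  13–28 cm, arm 33–90 cm) are sampled uniformly within the emulated
  cohort's printed ranges; height is derived from weight and BMI so the
  BMI-consistency invariant holds. They are I/O payload only — no
  statistic depends on them.
* **Screening funnel**: exclusion counts are rates × screened total,
  rounded, with the screened total then fixed as recruited + excluded so
  the accounting identity holds exactly. The default rates reproduce the
  emulated study's funnel (90 screened → 36 + 18 + 3 excluded → 33
  recruited) deterministically.

Gaussian noise everywhere is a modelling choice that buys closed-form
checks (folded-normal band probabilities, analytic variance budgets); the
generator makes no claim about real error distributions. Inter-observer
correlation beyond the shared true pressure is not modelled, terminal-digit
preference is reduced to symmetric rounding, and arrhythmia/poor-signal
failure modes are absent — so passing tests demonstrate the pipeline's
correctness on data satisfying the protocol's assumptions, not device
performance on real patients.

## Determinism and numerics

All randomness flows through one `numpy` generator seeded from
`CohortSpec.seed`; an identical spec writes a byte-identical cohort CSV.
Reference means of even integers are exact in floating point, so band
membership at the 5/10/15 boundaries involves no tolerance. Rounding to
the 2-mmHg grid uses banker's rounding (numpy/python default), a symmetric
and deterministic tie-break. Cuff boundaries are closed on their printed
endpoints; values in the unprinted one-decimal gaps round half-up before
lookup. Degenerate inputs error loudly: empty cohorts, < 2 pairs for an SD,
subjects without exactly 3 pairs, non-cumulative counts, negative
differences, pressures outside the 0–299 mmHg detection range.

## Problem sizes in the test suite

Monte-Carlo tests use 30–40 seeded cohorts for calibration checks, 50 for
the oracle-equivalence sweep, 100 for the certain-failure property and 200
for bias recovery — sizes at which the assertions' tolerances (3 standard
errors; ≥ 95% of runs) have comfortable margins under the analytic error
rates while the full suite runs in seconds.

## Known limitations

* Grading is ESH-IP2 only; other standards (AAMI/ISO 81060-2, BHS letter
  grades) are out of scope.
* The "maximum difference" row of range-distribution tables is reported as
  explicitly not computed: the quantity is not well defined from a summary
  table alone.
* No signal-level modelling (Korotkoff sounds, oscillometric envelopes):
  the device is an error model, not an instrument model.
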