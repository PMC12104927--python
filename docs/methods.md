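# Methods

## Costing model

The package implements the six TDABC steps as a pipeline: (1–2) a process
map of discrete activities with expert-elicited durations, (3–4) labour
costing and capacity cost rates, (5) cost aggregation, (6) Monte Carlo
uncertainty analysis, followed by scenario composition and annual
projection.

**Activities and elicitation.** Each activity binds one staff resource
(administrative officer, physiotherapist, or referral-hub officer) to an
elicited duration `(mean, low, high)` in minutes. The `(low, high)` pair
is interpreted as a symmetric **95% uncertainty interval**, not as hard
bounds: a normal is fitted with `μ = mean` and
`σ = (high − low)/(2 × 1.959964)`. This interpretation is a deliberate
design choice — it uniquely reproduces the simulated SDs of the bundled
study data (e.g. 8.16 for the 20 (10–30) min telephone-conversion
activity, where reading the triple as an absolute range or as ±1 SD does
not) — and applies identically to capacity cost rates, which carry their
own intervals.

**Capacity cost rates.** `c_r = salary × (1 + on-costs) /
(contracted minutes × practical fraction)`, defaults 25% on-costs and 80%
practical capacity. The bundled fixture carries the rates directly (admin
and referral-hub 1.01 (0.81–1.21) A$/min, physiotherapist 1.48
(1.18–1.77) A$/min, costing year July 2023) because the underlying award
salaries are not part of the dataset; the salary route exists for
user-defined clinics and is cross-checked against a declared rate to
within half a cent when both are given.

**Monte Carlo engine.** Default 1000 iterations (the study's scale).
Per iteration, each activity's time and its performer's rate are drawn
independently from their fitted normals and multiplied; scenario costs sum
the draws across the bundle. Choices that matter:

- *No truncation at zero.* Wide intervals admit negative draws; they are
  retained (a warning is logged above 1% negative) so the spread reflects
  the stated elicitation uncertainty. The bundled data's widest activity
  (complex triage, 17.5 (5–30) min) yields ≈0.3% negative draws.
- *Empirical percentile CIs* (2.5th/97.5th, linear interpolation between
  order statistics) rather than mean ± 1.96 SD: the product of two
  normals is right-skewed, and the percentile interval's asymmetry — e.g.
  a lower bound near 7.8 rather than the normal approximation's 6.4 for
  complex triage — is a property the tests assert.
- *Independence across activities* in a scenario bundle (no correlation
  structure is part of the dataset). An optional `shared_rates` mode
  reuses one rate draw per resource per iteration across the bundle,
  inducing positive correlation and a wider spread; it is off by default
  because the per-activity SDs of the study data are reproduced by the
  independent interpretation.
- *Seeding.* Every entry point takes an integer seed; the default is
  2023, the costing year. Per-activity and per-scenario sub-streams are
  derived with `numpy.random.SeedSequence` from (seed, purpose, id), so
  tables are reproducible bit-for-bit and stable under row reordering.
  Draws within a scenario are made in activity-id order, making the
  estimate exactly invariant to how a bundle lists its activities.

**Oracle.** The exact product moments
`E[TR] = μ_tμ_r`, `Var[TR] = μ_t²σ_r² + μ_r²σ_t² + σ_t²σ_r²` (independent
normals) provide a simulation-free reference; the test suite requires
simulated means within 1% and SDs within 3% of the oracle at 100 000
iterations for every fixture and synthetic activity.

## Scenario roster

The published scenario set (30 referral-source × response bundles) is
**reconstructed** from the workflow branch structure, as the itemised
supplementary listing is not part of the dataset: 3 referral routes
(internal simple, internal complex, external) × [4 failure-to-attend
responses (convert to telephone; reschedule after the patient answers;
reschedule after no answer; discharge) × 2 reminder timings (within /
after one week) + 2 cancellation responses (rebook with or without an
interpreter) under the within-one-week reminder] = 30. Crossing
cancellations with reminder timing as well would give 36, so the
reconstruction keeps them on the single (SMS) reminder path. Every bundle
contains exactly one reminder path; failure-to-attend bundles exclude the
consult that did not happen — with these choices the four headline bundle
means computed from the elicited point values are 113.43, 90.49, 85.85
and 96.41 A$, matching the published A$113/90/86/96 to rounding. The two
reschedule responses (answered vs unanswered call) share the same
activity list and hence the same cost; they are kept as distinct paths.

**Projection.** `annual cost = annual referrals × event rate × mean
scenario cost`, with the non-attendance rate applied to
failure-to-attend scenarios and the cancellation rate to cancellation
scenarios, under the explicit hypothetical that 100% of such events
resolve through the one scenario. The published annual *ranges* are not
reproduced: their generating formula is not stated and their implied
per-event costs exceed any single scenario mean, so only this generic
linear projection is offered, and its linearity/monotonicity are what the
tests check.

## Bundled fixture

`src/tdabc/data/clinics.yaml` carries the complete study inputs: 28
numbered activities with elicited times, performers and pathway structure;
the three staff rates; and both clinic profiles (2997 and 3347 annual
referrals; 8%/10% non-attendance; 4%/8% cancellation; 5/6
physiotherapists). Consult activities 14–16 belong to the musculoskeletal
clinic and 17–21 to the pelvic-health clinic; everything else is stored
once and shared, as the clinics share the same four administrative staff.
Unnumbered structural rows of the published table (waiting time, patient
answers / does not answer) carry no time or cost and exist only as branch
structure. Each activity also carries the *published* 1000-iteration
mean/SD/CI as a `reported` block used purely as a cross-check reference.
The published SMS-troubleshooting activity (0.05 min) is stored as
printed, i.e. per referral.

## Synthetic clinics

`tdabc.synthetic` generates random clinics with the same structure:
durations log-uniform on (0.5, 60) minutes, every elicited triple built as
`(m, m(1−w), m(1+w))` with half-width `w = 0.20` by default (the dominant
pattern in the study data), three staff roles with rates near the study's
(1.0/1.5/1.0 A$/min), and volumes/rates drawn from ranges bracketing the
two real clinics (500–5000 referrals, 5–15% non-attendance, 2–10%
cancellation). The generator's stream is separate from simulation seeds,
so recovery experiments (simulated vs analytic moments) measure the Monte
Carlo engine alone. What the generator does **not** emulate: elicitation
bias or disagreement between raters, asymmetric intervals, correlated
activities, and seasonal or patient-level structure — so passing recovery
tests demonstrate the engine's correctness under the stated model, not
robustness of the costing to violations of it.

## Problem sizes and tolerances

Default runs use the study's own scale (1000 iterations; seconds on one
CPU). Oracle-equivalence and recovery checks use 100 000 iterations,
where Monte Carlo error on a mean is ≈0.3 × CV% and tolerances of 1%
(mean) and 3% (SD) are comfortably diagnostic. Comparisons against
published numbers allow 3 SE of Monte Carlo error at 1000 iterations on
means, 15% on SDs, plus the table's two-decimal display resolution
(±0.005 — material only for the 0.05-minute SMS-troubleshooting activity,
whose printed SD of 0.01 has a single significant digit). Monetary
outputs are computed at full precision and rounded to cents only at
serialization.

## Known limitations

- Labour costs only: no consumables, equipment, overheads or space, and
  no opportunity cost of the vacant appointment slot.
- No queueing or wait-list dynamics; scenarios are static bundles, not
  patient trajectories over time.
- The normal-interval interpretation is an assumption of the uncertainty
  analysis; alternative families (gamma, PERT) are not implemented,
  though the fitting interface does not preclude them.
- The scenario roster is a documented reconstruction of the published
  branch products, not a copy of the published supplementary listing.
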