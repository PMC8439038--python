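# Methods

## Assay model

One physical plate carries, per sample, a triplicate of antigen-coated
wells and a triplicate of background wells (coating buffer only), plus
two plate-level controls: a secondary-antibody control (serum dilution
buffer) and a positive control serum. Per-well optical density is the
dual-wavelength difference A450 − A620; the reference wavelength removes
plate and path-length artefacts, and the subtraction is the universal
dual-wavelength convention.

The net value for one subject and one antigen corrects both replicate
means by the secondary-control mean before differencing. The correction
cancels algebraically — net ≡ mean(antigen) − mean(background) — but the
two corrected intermediates are retained in logs, since the secondary
control is what documents the non-specific background of the detection
antibody on that plate. Consequences that matter downstream:

* net values are **invariant to plate-wide additive shifts** and to the
  secondary-control level (property-tested);
* net values can be **negative** and are never clamped; cutoffs operate
  on the raw scale.

**Replicates.** No wells are ever excluded. The coefficient of variation
(sample SD over |mean|) is reported per group and flagged above 0.20 —
a conventional immunoassay warning level — along with a flag when a
group is not a triplicate. A zero mean leaves the CV undefined
(flagged), not infinite.

**Plate QC.** The positive control and the secondary control must each
sit within a relative tolerance (default ±10%, configurable) of their
lot-assigned expected ODs, which come from configuration, not from the
data. The tolerance is interpreted as relative; with an expected OD
near 0.08 for the secondary control this is a tight window, and with the
generator's default noise roughly one plate in ten fails it — which is
deliberate, as it exercises the strict-QC path. Strict mode (default)
drops all samples from an invalid plate; lenient mode emits them with a
plate-level flag. Background wells are assumed paired per sample on the
same plate run.

## Cutoffs and classification

The diagnostic threshold is anchored on specificity, not balanced
against sensitivity: given a reference population of size n and target
specificity s, allowed exceedances are ⌊(1−s)·n⌋ and the threshold is
the smallest candidate with no more than that many reference values
strictly above it. Candidates are midpoints between consecutive sorted
distinct reference values plus the maximum itself, so a threshold never
lands on an observed value where the strict/non-strict boundary choice
would matter. Positivity is strictly greater than the threshold, which
makes "threshold = reference maximum" yield exactly 100% specificity.
Because exceedances are floored, achieved specificity is always ≥ the
target (conservative side). Reference sets below n = 10 are refused for
diagnostic cutoffs; the bare threshold search (no size floor) is used
for response strata, which are legitimately small.

Two reference families are maintained in parallel throughout — healthy
controls and other diseases excluding SLE — and every table reports both
("x/y" cells). The delta marker receives its own cutoffs from the delta
values of the reference populations by the same procedure; it is never
classified through the single-marker cutoffs.

The target specificity is a parameter (default 0.98). Any externally
published threshold (e.g. an RA-specific OD of 0.371) is accepted as an
explicit input to the response analysis, never hard-coded.

ROC curves use the same midpoint-candidate construction with ±∞
sentinels and trapezoid AUC; ties are pooled by the strict-greater rule.

## CN-index and panel

Δ = net(cit) − net(native), per subject within one assay run. The
primary stratification splits at 0 (negative vs non-negative); Δ < −0.1
OD is kept as a separate "strong negative" annotation rather than the
primary split. The combined panel is the logical OR of the three marker
statuses against the same reference family, so panel sensitivity is
bounded below by the largest single-marker sensitivity and above by
their sum (both property-tested). Percentages in the table view are
rounded half-up to integers to match conventional reporting; full
precision is kept in separate columns.

The "ratio mean OD positive" summary is the mean of the signals strictly
above the cutoff divided by the cutoff; it is undefined (rendered "-")
exactly when no signal exceeds the threshold, and is ≥ 1 whenever
defined.

## Statistical tests

All tests are two-sided; p-values are nominal with Benjamini-Hochberg
adjustment as an opt-in column (the analyses these mirror report
unadjusted p-values).

**Mann-Whitney U.** For combined n ≤ 12 the two-sided p is computed by
full enumeration of all C(n, n_a) assignments of the combined multiset,
counting assignments whose |U − n_a·n_b/2| is at least the observed
deviation. Enumeration over the multiset is exact with or without ties;
in particular two identical samples give p = 1 exactly. Above the
threshold, scipy's normal approximation with tie correction and
continuity correction is used. The switch point keeps exactness where it
is cheap (≤ 924 assignments) and matches common desktop-statistics
behaviour above.

**Spearman.** rho is the Pearson correlation of mid-ranks. For n ≤ 8
the p-value is an exact two-sided permutation test over all n!
pairings; above, the t approximation. Constant input leaves rho
undefined with a flag.

**Response analysis.** Non-responders form the reference population;
the threshold comes from the same specificity-anchored search, and
sensitivity is reported among responders. The direction — responders
expected to sit *higher* on the native signal — is an explicit,
logged parameter (`higher_in_responders`), since the direction was
established for the native marker and need not transfer to other
strata. Responder rates by CN-index sign come with exact 95%
Clopper-Pearson intervals; empty strata report missing rates with
n = 0. Records missing the grouping covariate are excluded per-analysis
and logged, never imputed.

## Synthetic-study generator

The generator emulates the data structure the analysis assumes, not the
biology:

* **Latent states.** Each subject has a pair of latent antibody states
  (cit-reactive, native-reactive) drawn from a 2×2 joint distribution
  with fixed margins and a configurable odds multiplier θ (a Plackett
  coupling; θ = 1 gives independence; the implementation reproduces the
  requested cross-product ratio exactly and is tested for it).
* **Signals.** Net ODs are two-component lognormal mixtures. ODs are
  positive and right-skewed with heavy positive tails; the lognormal is
  the simplest shape honouring that. Defaults: antibody-negative
  component median 0.04 OD (log-sd 0.6) — near-background, so plate
  noise naturally produces some negative measured nets, exercising the
  no-clamp rule — and positive component median 0.85 OD (log-sd 0.55).
* **Genetics.** Shared-epitope dosage (0/1/2 copies) multiplies the
  citrullinated signal by a per-copy factor (default 1.25–1.30 in the
  demo cohorts), giving the dosage trend the contrast suite looks for.
* **Response.** For treated cohorts, the 6-month EULAR responder label
  is logistic in the native net OD with an explicit negative-delta
  indicator, so "87% responders among negative-index patients" is a
  settable parameter rather than an emergent accident. In the demo
  early-RA cohort the coefficients are intercept 0.2, native 1.0,
  indicator 1.7: σ(1.9) = 0.87 at native = 0, with the realized stratum
  rate a few points higher because responders also sit higher on the
  native signal. Pain VAS is linear in the native signal with Gaussian
  noise, clipped to 0–100.
* **Plates.** Triplicate wells are lognormal around their target means
  with a common replicate CV (default 0.08); plate controls drift by a
  per-plate lot factor (relative SD 0.02); A620 is a small constant
  plus proportional noise so the dual-wavelength arithmetic round-trips
  (exactly, at CV = 0). Subjects are chunked onto plates with both
  antigens and their shared background on the same plate.
* **Seeding.** One root seed; per-cohort substreams are keyed by
  `SeedSequence([root, crc32(cohort_name)])` and per-plate substreams by
  `SeedSequence([root, tag, plate_index])`, so adding a cohort leaves
  the draws of the others untouched. Fixed spec + seed reproduces every
  output file byte for byte.

The demo study uses the published cohort sizes (Risk-RA 71, LURA 106,
EIRA 404, established-RA 127, SLE 89, other diseases 127, healthy
controls 86). Mixture parameters and prevalences are **illustrative**:
no raw data are deposited for the original cohorts, so the demo is
calibrated to reproduce the qualitative layout (strong citrullinated
reactivity in RA, native-dominated negative-delta reactivity in SLE,
near-silence in controls), not any published cell. One consequence worth
knowing: the synthetic healthy controls carry 2% latent reactivity, so
the 98%-specificity cutoff on n = 86 controls tracks those rare
reactives and lands near OD 1.0, well above the between-component gap —
the same mechanism that makes real specificity-anchored cutoffs
sensitive to reference-population contamination. Passing tests therefore
demonstrate the pipeline's correctness and calibration on data with this
structure; they say nothing about assay performance on real sera, where
component shapes, prevalences and dependencies are unknown.

## Numerical and design choices

* Cutoff candidates are midpoints; achieved specificity is reported from
  the reference set itself.
* An all-identical reference yields that value as the threshold, with a
  warning.
* Percent cells round half-up; machine-readable columns keep full
  precision; TSV floats are written at 6 significant digits.
* Bootstrap CIs for thresholds (percentile, 2000 resamples, seeded) are
  available but off by default.
* The pipeline is a pure function of (input files, config, seed): result
  tables are byte-identical across reruns; timestamps exist only in the
  run manifest, alongside the config hash and input checksums.
* Problem sizes in the test suite and acceptance script (e.g. 50-seed
  specificity checks at n = 500/5000, 100-seed recovery at n = 2000,
  1000 null simulations at n = 50/arm) were chosen to make binomial
  noise small relative to the asserted margins while keeping the default
  run quick on one CPU.

## Known limitations

* No 4PL curve fitting or concentration calibration — the analysis
  operates on net ODs, as the workflow it mirrors does.
* No inter-plate normalisation beyond the stated controls.
* EULAR response and DAS28 are input labels; they are never derived
  from joint counts here.
* Longitudinal trajectories (within-subject index evolution) are out of
  scope; the generator draws one timepoint.
* The exact Mann-Whitney enumeration is O(C(n, n_a)) and is capped at a
  combined n of 12 by design.
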