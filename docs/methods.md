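# Methods

## The measurement model

The package analyzes per-well quantification cycles (Cq) from nanowell
qPCR chips. The emulated chip holds 2500 wells of ~20 nl; each assay —
164 miRNA targets plus 7 controls — occupies a fixed 9-well replicate
cluster. A well either amplifies, yielding Cq ∈ (0, 40] cycles (40 cycles
is the thermal protocol's length), or does not; no-amplification is kept
as explicit missingness (`NA` on disk, NaN in memory), never recoded as a
sentinel Cq, because the downstream imputation rule must distinguish
"below detection" from "late but measured".

The synthetic generator uses the standard exponential-amplification law

    Cq*(c) = intercept − log(min(c, c_sat)) / log(1 + E)

with per-assay efficiency E (E = 1 doubles template each cycle; one cycle
is then one log2 unit) and intercept the Cq at one copy per nanowell.
Measured Cq adds Gaussian technical noise (sd `cq_noise_sd`, default 0.20
cycles — typical well-to-well scatter for nano-volume qPCR) and clips to
(0, 40]. Above `saturation_copies` (default 1e8 copies/nanowell) Cq stops
decreasing, emulating reaction saturation at the top of the input range.

Detection is stochastic: a well amplifies with probability
p(c) = 1 − e^(−c/φ). This one-parameter curve is what Poisson occupancy
of a fixed reaction volume predicts, up to the scale φ; the default
φ = 40 copies/nanowell puts the detection knee just below 80
copies/nanowell, the lowest spike level the emulated platform resolves.
Zero copies never amplify except through the NTC contamination process.

Copy numbers, not volumes or masses, are the generator's primitive;
mixing reference RNAs is linear on the copy scale (mixing masses mixes
molecule counts).

## QC battery definitions

**Detection call.** A cluster is detected when at least
`detection_min_wells` (default 5 of 9 — a majority vote; no well-level
rule is standard, so majority was chosen and exposed in `Config`) of its
wells amplify with Cq strictly below `cq_cutoff` (default 34). The
collapsed Cq is the median of those wells (robust to single-well
outliers; mean available by config). The cutoff is strict: Cq = 34.0
fails.

**Efficiency.** Ordinary least squares of collapsed Cq on log10 relative
concentration over a dilution series (≥ 3 points);
E% = (10^(−1/slope) − 1)·100. On noise-free generator output this
recovers the generator's true E to numerical precision, because the OLS
slope of an exactly linear series is exact.

**Reproducibility.** Over two replicate runs, the denominator is the set
of assays detected in at least one run; double positives are detected in
both, single positives in exactly one (the two percentages sum to 100 by
construction). Expression is −Cq (or −ΔCq after normalization); the
expression range is the max−min span over double-positive values, in
log2 units. The ALC — area left of the empirical CDF of absolute
replicate differences, integrated over the full F ∈ [0, 1] band with no
truncation of the d-axis — is computed by the exact step-function
identity ALC = mean(d). The test suite cross-checks this closed form
against direct geometric integration of the step ECDF to 1e−9.

**Titration.** Each assay detected in both pure mixtures (A = 100%
reference A, B = 0%) is scored by the three adjacent inequalities of the
chain A > C > D > B (C = 75%, D = 25%), oriented by sign(A − B);
q = (number holding strictly)/3. Ties and missing intermediate values
count as failures (ties have measure zero on continuous Cq; a missing
mixture genuinely failed to titrate into detection). The AUC is one
minus the area between the ideal cumulative distribution of q (unit step
at 1) and the empirical one, which reduces algebraically to mean(q):
scale-invariant, 1 for perfect titration, and invariant under any
strictly increasing transform of the expression scale (a tested
property). The exact formulas used by the originating multi-platform QC
methodology are not restated in accessible form, so these definitions
are this package's own concrete stand-ins satisfying every stated
property of that statistic; they are not claimed reconstructions. The
"random-ordering null" used in testing draws the three inequality
outcomes as independent fair coins (E[AUC] = 0.5); note that this null
lives on the score scale — orderings of four distinct reals cannot make
all three chain comparisons fail simultaneously, so the coin model is
not realizable as expression quadruples, and i.i.d. expressions give
E[q] ≈ 0.61 instead.

**Specificity.** For a panel where family member i alone is spiked onto
a carrier background, cross-reactivity of off-target assay j is
CR = 100·2^(Cq_on − Cq_off) — the signal fraction the Cq gap implies at
doubling efficiency — when j is detected, else 0 (a censored bound would
overstate observed cross-talk); the diagonal is 100 by definition. The
summary reports the percent of off-target combinations with CR > 0 and
their median CR.

**NTC positivity.** The no-template control counts target assays with an
amplification signal in ≥ `detection_min_wells` wells *without* applying
the Cq-34 cutoff (configurable): contamination is characteristically
late (the generator draws contaminated clusters at Cq ~ U(33, 39)), and
the question asked of an NTC is whether any signal exists, not whether
it is quantifiable. With the cutoff applied, most late positives would
be invisible and the count would no longer estimate the contamination
rate. The generator's per-assay contamination probability defaults to
0.10, so the expected count on a 164-assay panel is ~16.4.

**Dynamic range.** Over an ascending, constant-fold spike series, the
reported range is the longest run of consecutive detected levels whose
adjacent Cq steps each lie within ±30% (configurable) of the theoretical
step log(fold)/log(1+E); the count of levels in that run is the "orders
of magnitude", with the run's first/last copy numbers as bounds. When
the true E is unknown (e.g. data loaded from files), the nominal E = 1
is used; the ±30% band covers the whole 90–110% efficiency range.
The default battery series spans 8 to 8×10^8 copies/nanowell in 9
ten-fold steps: the bottom level sits below the detection knee and the
top level beyond saturation, so the recovered range is the inner
80 … 8×10^7 span — 7 orders.

## Preprocessing chain

Fixed order: hemolysis QC → normalization → replicate averaging →
feature filtering → imputation → standardization.

* **Hemolysis**: plasma with absorbance ratio A414/A375 strictly greater
  than 2 is excluded before any modelling (boundary 2.0 passes); the
  ratio flags free haemoglobin, which distorts plasma miRNA content.
* **Normalization**: ΔCq = Cq − mean(Cq over the configured factor
  assays). The QC battery normalizes against five factors (three
  endogenous reference genes plus the RT and qPCR process controls,
  averaged jointly); the cohort pipeline uses the two spiked process
  controls only, since endogenous references are less stable in plasma.
  A factor undetected in a sample is an error naming that factor — a
  profile without its controls is not interpretable.
* **Averaging**: per-assay arithmetic mean over a subject's repeat
  chips, available-case (missing only if missing in all repeats).
* **Filtering**: assays missing in every subject are dropped; everything
  else is kept, in panel order.
* **Imputation**: each profile's missing values are replaced by that
  profile's maximum ΔCq — the least-abundant signal the profile itself
  measured, a conservative "at or below my own detection floor" value.
* **Standardization**: each profile is z-scored to zero mean and unit
  variance with the population divisor n (the divisor is a convention
  choice; n is used and documented).

Imputation and standardization are deliberately *row-wise* (per
profile), not column-wise: no cross-subject statistic enters them, so
they cannot leak information across cross-validation folds, and
standardizing inside or outside CV is equivalent. Both are idempotent
(standardize∘standardize = standardize to 1e−12) and imputation never
alters an observed value — both tested properties. Filtering commutes
with imputation (dropping an all-missing column cannot change any row
maximum).

## Classifier

A linear-kernel SVM with misclassification cost C = 1 and no class
weighting (the kernel and cost are exposed; linear/C=1 is the natural
default for 134 standardized features on 122 subjects). Evaluation is
stratified 10-fold cross-validation — each fold's class proportions
match the cohort's to within one subject — with all held-out predictions
pooled into a single confusion matrix, so the matrix total equals the
cohort size. Reported metrics (sensitivity, specificity, PPV, NPV,
accuracy) are percentages rounded half-up to one decimal for display,
full precision internally; a zero-denominator metric is returned as NaN
and flagged, never fabricated.

## Synthetic cohort

Defaults emulate the study design the analysis assumes: 38 cases vs 84
controls, two repeat chips per subject, 20 differential assays shifted
by 3 cycles in cases (direction randomized per assay, fixed across
subjects). Per-subject baselines draw log-normally around the assay
reference (sd 1.5 log2 units across subjects — plasma miRNAs vary over
orders of magnitude), with subject-level biological noise of 0.75 cycles
and well-level technical noise of 0.20 cycles; a configurable fraction
of subjects (default 5%) draws hemolysis absorbances failing the ratio
rule. These variability scales are the package's definition of a
realistic plasma cohort; no published per-assay variance table exists to
calibrate against.

What the generator does *not* emulate: batch/chip-position effects,
primer-specific amplification artefacts, RNA-extraction yield variation,
correlated miRNA co-regulation, or real between-platform differences.
Passing tests therefore demonstrate the correctness and internal
consistency of the statistics and pipeline, not platform performance on
real plasma — the published real-data summary values (titration AUC
0.75, ALC 0.58, and so on) are qualitative anchors, not targets, since
the underlying chip data are not publicly deposited.

## Numerical and design choices

* All randomness flows through one `numpy.random.Generator` per stage,
  spawned from a single `SeedSequence` in fixed order, so any stage is
  independently reproducible and whole runs are bit-identical under a
  seed.
* Strict inequalities throughout the titration chain; exact Cq range
  validation at I/O time ((0, 40], `NA` token only); duplicate wells and
  layout mismatches are hard errors, never coerced.
* Cq values round-trip through CSV at 4-decimal precision exactly.
* Problem sizes in the test suite and acceptance script are the emulated
  study sizes (164 assays, 9 wells, 38/84 subjects, 2 repeats); unit
  tests use scaled-down chips (1–10 assays) where only the logic, not
  the scale, is under test.

## Known limitations

* The titration AUC and ALC definitions are principled stand-ins (see
  above), so their absolute values on real exports may differ from
  implementations that integrate a differently-parameterized CDF.
* `dynamic_range` assumes constant-fold level spacing and uses a single
  efficiency for the theoretical step; strongly efficiency-shifted
  assays at the series boundary could mis-classify one level.
* The NTC contamination model is per-assay (a contaminated primer
  cluster amplifies as a whole); per-well contamination would produce
  lower counts at the same rate.
* The classifier wrapper exposes only the linear kernel and cost; users
  wanting probability calibration or other kernels should drop to
  scikit-learn directly on the `CohortMatrix`.
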