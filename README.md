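# panelqc

Quality control and cross-validated classification for nanowell qPCR
miRNA panels.

Multi-assay qPCR chips measure hundreds of microRNAs at once: each assay
occupies a small cluster of replicate nanowells (9 wells on the emulated
2500-well chip), and every well reports a quantification cycle Cq — the
PCR cycle at which fluorescence crosses threshold, with one cycle ≈ one
log2 unit of template abundance — or no amplification at all. Before such
a platform can be trusted for plasma biomarker work, its analytical
performance has to be quantified, and its ΔCq profiles have to be
preprocessed consistently before any classifier sees them. `panelqc`
implements that whole chain for analysts working with panel-chip Cq
exports:

* **Platform QC battery** (the standard miRQC-style metric set):
  * *Detection*: an assay is detected when ≥ 5 of its 9 wells amplify with
    Cq < 34; the cluster collapses to the median Cq of those wells.
  * *PCR efficiency*: OLS fit of Cq against log10 concentration over a
    dilution series; E = 10^(−1/slope) − 1, acceptable range 90–110%.
  * *Reproducibility*: % double/single positives across two replicate
    runs, the detectable expression range (log2 units), and the ALC —
    the area left of the cumulative distribution of absolute replicate
    differences, which for a step ECDF equals mean|Δ| exactly (lower =
    more reproducible).
  * *Titration response*: for mixtures A (100% reference A), C (75%),
    D (25%), B (0%), an assay with A_x > B_x must order
    A_x > C_x > D_x > B_x (mirrored when B_x > A_x). Each assay scores
    q ∈ {0, ⅓, ⅔, 1} — the fraction of the three adjacent inequalities
    that hold — and the titration AUC = mean(q) ∈ [0, 1] is the area-based
    summary against the ideal distribution (all q = 1).
  * *Specificity*: cross-reactivity of closely related assays (e.g. the
    let-7 family), CR_ij = 100·2^(Cq_on − Cq_off) % for single-member
    spike-ins; no-template-control positivity.
  * *Dynamic range*: the longest run of 10-fold spike levels that is both
    detected and locally log-linear (adjacent ΔCq within ±30% of the
    theoretical log(10)/log(1+E) step).
* **ΔCq preprocessing chain**: hemolysis exclusion (A414/A375 > 2),
  control normalization ΔCq = Cq − mean(Cq of factor assays), replicate
  averaging, removal of never-detected assays, per-profile imputation
  with the profile's maximum ΔCq, and per-profile standardization to zero
  mean and unit variance. The matrix stages are sklearn transformers and
  compose with `sklearn.pipeline`.
* **Classifier**: a linear maximum-margin SVM (libsvm via scikit-learn,
  C = 1) evaluated by stratified 10-fold cross-validation with pooled
  held-out predictions, reporting the confusion matrix and
  sensitivity / specificity / PPV / NPV / accuracy.
* **Synthetic chip generator**: a seeded simulator of the full study
  design — the copy→Cq law Cq = intercept − log(copies)/log(1+E),
  Poisson-occupancy dropout p(copies) = 1 − e^(−copies/φ), saturation,
  titration mixtures, spike dilution series, specificity panels, NTC
  contamination, and a two-class cohort (38 cases / 84 controls, repeat
  chips, differential assays) — so every stage is testable without any
  instrument export.

## Worked example

```python
from panelqc import Config, workflows
from panelqc.synthdata import SimConfig

config = Config()                      # Cq < 34, 5-of-9 wells, median collapse
data = workflows.simulate_battery(seed=1)
res = workflows.analyze_battery(data, config)
r = res.report
print(f"clusters passing cutoff : {r.n_clusters_after_cutoff} / 164")
print(f"double positives        : {r.pct_double_positive:.2f} %")
print(f"ALC                     : {r.alc:.3f}")
print(f"titration AUC           : {r.titration_auc:.3f}")
print(f"NTC positives           : {r.ntc_positive_count}")

run = workflows.simulate_cohort_run(seed=1,
                                    sim=SimConfig(rng_seed=1, hemolysis_fraction=0.0))
_, cm, m, _ = workflows.classify_cohort(run, config, seed=1)
print(f"confusion matrix        : TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
```

prints

```
clusters passing cutoff : 151 / 164
double positives        : 96.69 %
ALC                     : 0.094
titration AUC           : 0.949
NTC positives           : 17
confusion matrix        : TP=38 FP=0 FN=0 TN=84
```

Reading it: 151 of the 164 simulated assays clear the Cq < 34 detection
cutoff; 96.7% of those are found in both replicate runs; the ALC of 0.094
cycles says replicate expression values differ by under a tenth of a
cycle on average; the titration AUC of 0.949 means nearly every assay
orders the A/C/D/B reference mixtures correctly; and ~17 NTC positives
reflect the generator's 10% per-assay contamination rate. The cohort —
38 cases vs 84 controls with 20 assays shifted by 3 cycles — separates
perfectly under 10-fold cross-validation.

The same pipelines are scriptable from the shell:

```bash
panelqc simulate --seed 1 --out bundle/
panelqc mirqc    --inputs bundle/ --out qc/
panelqc classify --seed 1 --inputs bundle/ --out clf/
panelqc report   --mirqc-dir qc/ --classify-dir clf/ --out summary.json
```

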