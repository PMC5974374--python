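# e2fsig

Transcriptome-based E2F subtyping for bulk tumor cohorts.

Pancreatic ductal adenocarcinoma (and other solid tumors) split into
clinically distinct phenotypes by the activity of **E2F transcriptional
targets** — the cell-cycle program driven by the E2F family of
transcription factors. `e2fsig` implements the full analysis a
transcriptomics group runs on such a cohort:

* expression-matrix, gene-set (GMT) and annotation I/O, with
  technical-duplicate averaging and replicate-concordance QC;
* unsupervised hierarchical clustering (complete linkage, Euclidean for
  samples / correlation for genes) with **R/D cluster-robustness indices**
  from Gaussian-perturbation reclustering;
* four-criterion differential-transcript selection (permutation Welch t,
  Benjamini-Hochberg FDR, t-score and signed fold-change thresholds);
* the **24-gene ratio-median signature**: per-gene sum-to-100
  normalization, all up/down expression ratios per sample, and the
  median-vs-1 rule that calls each sample E2F-high or E2F-low;
* Kaplan-Meier survival comparison with both the Gehan-Breslow-Wilcoxon
  and standard log-rank tests, written from their defining formulas;
* robust log-dose vs normalized-response IC50 fitting and per-drug group
  comparison (chemograms);
* a synthetic PDX-like cohort generator providing ground truth for every
  stage, plus a CLI (`e2fsig`) and an end-to-end pipeline runner.

## The score

For a signature with up-regulated genes U and down-regulated genes D
(bundled default: |U| = 11, |D| = 13), each gene row is first rescaled so
its values sum to 100 across the cohort. For sample *s* with normalized
values x̃, the score is

    M(s) = median { x̃_us / x̃_ds : u ∈ U, d ∈ D }     (11 × 13 = 143 ratios)

and the call is **E2F-high** if M(s) > 1, **E2F-low** if M(s) < 1.
Missing markers shrink the ratio grid and are reported; a panel lacking
three down genes still classifies with 110 ratios per sample.

## Worked example

Simulate the default study design — 55 patients hybridised in duplicate,
12 latently E2F-high, 146 differential transcripts among 1000 genes —
then score, compare survival and compare chemosensitivity:

```python
import e2fsig as e

cohort = e.simulate_cohort(e.SimConfig(seed=1))
matrix = e.average_duplicates(cohort.expression, cohort.pairing)

result = e.classify(matrix, reference_labels=cohort.truth.sample_labels)
print(result.summary())
# Signature: E2F24 (11 up / 13 down)
# Samples scored: 55
# Missing markers: 0 (up: -; down: -)
# Labels: E2F-high=12, E2F-low=43
# vs reference: 0 false positives, 0 false negatives

surv = e.compare_by_label(cohort.samples, "truth_label", endpoint="os")
print(surv["tests"]["gehan-breslow-wilcoxon"].summary())
# gehan-breslow-wilcoxon: chi2 = 3.4746, p = 0.06232 (O/E group1 10/6.21)

fits = e.fit_response_table(cohort.responses)
cmp = e.compare_ic50_by_group(fits, cohort.truth.sample_labels)
print(cmp[["drug", "mean_ic50_E2F-high", "mean_ic50_E2F-low", "p_value"]].round(4))
#          drug  mean_ic50_E2F-high  mean_ic50_E2F-low  p_value
#   gemcitabine             10.8176            10.5841   0.7157
#   oxaliplatin             10.3544            10.3767   0.9582
# e2f_inhibitor             21.7990            45.1328   0.0000
```

Every sample's 143-ratio median lands cleanly on one side of 1
(`result.scores` holds the per-sample values), the E2F-high group shows
the shorter median survival, and only the E2F-inhibitor-like compound —
not the cytotoxics — separates the two groups' IC50s (≈22 vs ≈45 µM
here). The same flow runs from the shell:

```bash
e2fsig simulate --seed 1 --out cohort/
e2fsig score --matrix cohort/expression.tsv --duplicates --out scores.tsv
e2fsig survival --annotations cohort/samples.tsv --label truth_label --endpoint os --out surv.json
e2fsig chemo --responses cohort/responses.tsv --labels scores.tsv --out chemo.tsv
e2fsig run-all --config pipeline.yaml   # all stages + manifest
```

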