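# Methods

`e2fsig` implements a transcriptome-based subtyping workflow for bulk tumor
cohorts — pancreatic ductal adenocarcinoma (PDAC) grown as patient-derived
xenografts (PDX) is the motivating setting — in which tumors are split into
**E2F-high** and **E2F-low** phenotypes by the activity of E2F
transcriptional targets, and the split is then interrogated for prognostic
value (survival) and predictive value (drug sensitivity). This note records
the models, conventions and numerical choices behind each stage, and what
the synthetic-cohort tests do and do not establish.

## Expression matrices and technical duplicates

All stages consume a strictly positive gene-by-sample intensity matrix with
a declared scale (`linear` or `log2`). Cohorts hybridised in technical
duplicate carry `<sample>_rep1/_rep2` columns; replicate concordance is
checked by pairwise Pearson correlation and the per-sample arithmetic mean
of the duplicates, taken on the declared scale, feeds every downstream
stage. Missing values are rejected at load time rather than imputed:
nothing downstream defines a sensible behavior for an absent intensity.
Whether a given deposited matrix is linear or log2 is not always
discoverable from the file, so the scale is explicit user input.

## Unsupervised clustering and the R/D robustness indices

Samples are clustered by agglomerative hierarchical clustering with
complete linkage on Euclidean distance; genes with correlation distance
(1 − Pearson r), where zero-variance genes are excluded because their
correlation is undefined. Clusters are labeled by decreasing size.

Cluster stability is measured by perturb-and-recluster: i.i.d. Gaussian
noise N(0, σ²) is added to every matrix entry and the perturbed matrix is
reclustered at the same k, repeated `n_perturbations` times (default 100).

* **R index** — mean proportion of sample pairs sharing an original
  cluster that still co-cluster after perturbation; 1 means perfectly
  reproducible clusters.
* **D index** — perturbed clusters are matched to original clusters by
  greedy maximal membership overlap (ties broken toward the smaller
  cluster id), and D is the mean total of additions plus omissions across
  matched pairs; 0 means no discrepancies.

The noise σ defaults to the median of the per-gene standard deviations of
the input matrix. The index definitions leave σ open; a data-driven
default keeps R and D comparable between datasets of different overall
variability while remaining overridable. R is 1 and D is 0 in the
vanishing-noise limit by construction, and the test suite checks that the
seed-averaged R is non-increasing in σ.

## Four-criterion marker selection

Differential transcripts between two groups are selected by the joint
filter: permutation Welch-t raw p < 0.002, Benjamini-Hochberg q < 0.05,
Welch t > 6 (up-regulated) or t ≤ −6 (down-regulated), and signed linear
fold change > 1.2 or ≤ −1.2. The signed convention reports a gene lower in
the reference group as −(mean_B/mean_A), so "fold change ≤ −1.2" is
expressible; a plain ratio never drops below 0.

Scale handling is the standard microarray compromise: t statistics (and
their permutation null) are computed on log2 intensities, fold changes on
linear group means; both views derive from the declared input scale. The
permutation p-value uses (1 + exceedances)/(n_perm + 1), so its floor is
1/(n_perm + 1): `n_perm` must exceed 500 for any gene to clear the 0.002
threshold (the default is 10,000; `select_markers` warns when the floor
blocks the filter). A single set of label permutations is shared by all
genes, which vectorises the computation and matches array-tool practice.
No variance shrinkage is applied — the filter is plain Welch by design.

## The 24-gene ratio-median signature

The bundled signature holds 11 up-regulated genes (BIRC5, LMNB1, POLA2,
DEPDC1, MCM2, CDK1, PTTG1, CDC20, PLK1, KPNA2, AURKA) and 13 down-regulated
genes (RHBDL2, DLEU7-AS1, TMEM63A, IGSF9, NEIL1, BDKRB2, PDZK1IP1, ERN2,
CTSE, VSIG2, BCL2L15, LOC100505633, TXNIP), shipped as a two-set GMT file
(`E2F24_UP`, `E2F24_DN`) and overridable everywhere.

Scoring proceeds on linear intensities (log2 input must be converted
first — sums and ratios of logs would distort the construction):

1. each signature gene's row is rescaled to sum to 100 across the cohort's
   samples;
2. for each sample, every up/down gene pair forms a ratio of normalized
   values — 11 × 13 = 143 ratios with the full signature;
3. the per-sample median ratio calls **E2F-high** when > 1 and **E2F-low**
   when < 1.

A median of exactly 1 is labeled *indeterminate* rather than forced to a
side, since only the strict inequalities are defined; the label is
configurable downstream only in the sense that indeterminate samples are
dropped (and counted) before survival comparison. Missing markers shrink
the ratio grid and are reported by name — a panel lacking three of the
down genes yields 11 × 10 = 110 ratios and classification proceeds. An
even ratio count (possible only with missing markers, 143 being odd) takes
the mean of the two central order statistics. Ratios with a zero
normalized down-gene value are dropped and counted; a sample with no
defined ratio is an error.

Two consequences of the construction are worth flagging. It is
**cohort-relative**: normalization sums run over the cohort, so adding or
removing samples can move every score (a test constructs such a case).
And it is invariant to any per-gene positive rescaling, hence insensitive
to probe-level scale differences between genes.

Supervised clustering on an E2F-target gene set (any GMT, e.g. an MSigDB
selection) restricts the matrix to the set's members, clusters exactly as
in the unsupervised stage, and orients the two clusters by mean member
expression: higher mean ⇒ E2F-high.

## Survival analysis

Kaplan-Meier product-limit curves are computed from their defining
formula, with the convention that subjects censored at t remain at risk
for events at t (events precede censorings at ties). The reported median
is the smallest t with S(t) ≤ 0.5, undefined (NA) when S plateaus above
0.5. The two-group tests share one computation: at each distinct event
time, O₁ − E₁ with E₁ = d·n₁/n and the hypergeometric variance; the
statistic [Σ wⱼ(O₁ⱼ−E₁ⱼ)]² / Σ wⱼ²Vⱼ is referred to χ²(1). Weights wⱼ = 1
give the standard log-rank test, wⱼ = nⱼ the Gehan-Breslow-Wilcoxon test
(early-event-weighted). Both variants are always computed and reported,
because the two are genuinely different hypotheses about where group
hazards diverge and practice in the field mixes them; neither is asserted
as canonical. Implementations are cross-checked against lifelines in the
test suite; lifelines is never the computation path.

## Dose-response IC50 fitting

The default model is the normalized two-parameter logistic
y = 100 / (1 + 10^((log₁₀d − log₁₀IC50)·h)) with hill slope h > 0 and the
response constrained to fall from 100% to 0% (the "normalized response"
convention; equivalent to the negative-HillSlope parameterisation used by
common plate-analysis software). A four-parameter variant frees the
plateaus. Zero-dose wells cannot enter a log-dose model; they anchor the
renormalization of responses to percent-of-vehicle and are then dropped.

Fitting is two-stage robust nonlinear least squares: an ordinary fit
provides residuals whose scaled MAD (1.482·MAD, floored at 1 so noiseless
data invert exactly) sets the soft-L1 loss scale for the refit. A single
gross outlier point moves the noiseless 8-point fixture's log₁₀IC50 by
< 0.02. Initial values: log₁₀IC50 at the dose nearest 50% response, h = 1.
`converged` is False — never an exception — when the optimizer fails or the
fitted IC50 sits more than 2 decades outside the dose grid; flat series
(range < 10 percentage points) raise a "no inhibition" error instead,
since an IC50 is undefined rather than poorly estimated. Fits are
unit-agnostic: refitting in nM instead of µM shifts log₁₀IC50 by exactly 3.

Group comparison reports per-drug group means ± SEM on the linear µM scale
and a two-sided Welch t-test on log₁₀IC50 (the scale on which assay error
is approximately symmetric); non-converged fits are excluded and counted.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
with full ground truth. Defaults encode the emulated study design: 55
patients hybridised in duplicate (110 columns), 12 latently E2F-high, 1000
genes of which 35 up- and 111 down-regulated markers (146 differential
transcripts) are shifted by effect_log2 = 1.5 in the appropriate subgroup,
per-gene biological noise SD 0.4 and technical replicate SD 0.15, all on
the log2 scale with N(8, 1.5²) baselines, exported as 2^x linear
intensities. The first 11 up- and 13 down-markers carry the bundled
signature's gene names so the shipped signature applies directly. Noise
SDs were set to give replicate correlations above 0.95 and a clear but not
trivial group separation, the regime a well-run array experiment shows.

Survival is exponential per subgroup with rate ln2/median (defaults: OS
9.5 vs 16.8 months, RFS 6.0 vs 10.6). Censoring is an independent
per-group exponential whose rate is chosen so the expected censored
fraction equals `censor_rate` (default 0.2). An "administrative" reading
of uniform censoring on (0, t) would make censoring depend on the event
time and bias the KM estimate, so the independent-censoring form was
chosen; with it the generator is verifiably unbiased (the KM median of a
2000-patient group recovers the configured median to < 1%). At the default
cohort size the 12-patient subgroup's KM median has a sampling spread of
roughly ±50%, which is why the validation harness reports median recovery
but gates it only when the caller supplies a tolerance, and why the
acceptance script measures median recovery on a 1500-patient cohort.

Chemograms use an 8-point half-log dose grid (0.1–316 µM) with responses
from the logistic forward model plus 5%-point Gaussian noise. Per-sample
true log₁₀IC50s are N(mean, 0.1²) with subgroup-independent means of 10 µM
for the cytotoxic-like drugs and subgroup-dependent means of 19.4 µM
(high) vs 44.1 µM (low) for the E2F-inhibitor-like compound.

What the generator does **not** emulate: probe-level array artifacts,
batch effects, stromal admixture, correlated gene programs beyond the
marker blocks, non-exponential hazards, or informative censoring. Passing
recovery tests therefore demonstrates internal consistency of the pipeline
under its own assumptions, not performance on real tumor cohorts.

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 20–55 patients with
100–1000 genes, 600–2000 label permutations, 5–100 noise perturbations and
200-replicate calibration loops — sizes at which every stochastic check is
stable under its fixed seed while the whole suite completes in well under
a minute. Every random draw flows through a single `numpy` generator
seeded per stage; identical seeds give byte-identical outputs, which the
suite asserts.

## Known limitations

* The signature score is cohort-relative by construction; single-sample
  scoring requires a frozen reference cohort, which is out of scope.
* The marker filter's permutation p resolution is bounded by n_perm (see
  above); with the default thresholds, n_perm < 500 selects nothing.
* The D index's greedy cluster matching is not guaranteed optimal for
  k > 2 (ties are broken deterministically); for the k = 2 pipeline it is
  exact.
* IC50s far outside the tested dose range are flagged unconverged rather
  than extrapolated.
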