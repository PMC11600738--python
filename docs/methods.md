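# Methods

This note documents the statistical models behind `bandscape`, the
conventions chosen where several readings were defensible, what the
synthetic-cohort generator does and does not emulate, and the numerical
details that matter for reproducing results.

## Band-status calling

Input is a gene × sample matrix of GISTIC-thresholded integer calls
(−2 two-copy loss, −1 one-copy loss, 0 diploid, +1 gain, +2
amplification), with blanks for missing cells. Genes are assigned to the
cytoband containing their interval midpoint (coordinates are 0-based
half-open internally; gene tables declared 1-based inclusive are converted
at the reader). Per band and sample:

* all non-missing gene values equal → the corresponding status label;
* ≥ 2 distinct non-missing values → **ambiguous** (an intra-band
  breakpoint: the band's genes sit on different copy-number segments);
* no non-missing values → missing.

The call is a total function of the multiset of gene values — permuting
genes within a band can never change it — and is validated in the test
suite against exhaustive enumeration of all value vectors up to length 4.

Conventions (the upstream literature is silent on all three):

* *Loss* for every downstream two-group contrast means status ∈ {loss,
  deep loss}; the comparison group is neutral only. Gains, amplifications
  and ambiguous samples are excluded from contrasts, because homozygous
  loss is rare (a few percent) and ambiguous samples have an undefined
  dosage.
* Ambiguous samples count in the callable denominator of band loss
  frequencies but in no status numerator.
* Missing CN cells are excluded per-gene from frequency denominators
  (pairwise-complete).

Frequency ranking breaks ties by genomic order (chromosome, then start).
The band-versus-genome contrast treats the **gene** as the replicate unit:
per-gene alteration frequencies (fraction of samples with the sign of
interest) inside the anchor band are compared with all other genes by a
two-sample t-test. This replicate-unit choice is a package convention —
the construction is not uniquely determined by the frequency histograms it
mimics — and is stated here prominently for that reason.

## Association screen

For a binary anchor (1 = band loss, 0 = neutral) and each binary feature,
the 2×2 table (a, b, c, d) = (anchor+feature+, anchor+feature−,
anchor−feature+, anchor−feature−) is tested with the two-sided Fisher
exact test on the raw counts. Summaries:

* odds ratio = (a·d)/(b·c), with the Haldane–Anscombe +0.5 added to **all
  four** cells iff any cell is zero (the p-value never uses the
  correction);
* `Direction = log2(OR)`;
* `score = −log10(p) · Direction`, with score ≡ 0 when p = 1 so the
  ±0 ambiguity of an exactly-null table cannot arise;
* call = co-occurring (p < α and Direction > 0), mutually exclusive
  (p < α and Direction < 0), else not significant; α defaults to 0.05 on
  the raw p (no multiplicity correction by default — a BH option exists
  but is off, matching the screen's original usage).

The two published sentences defining Direction and score contradict each
other; the definitions above make both coherent and are fixed here.
Features below 2% prevalence among anchored samples are dropped before
testing. Band features on the anchor's own chromosome arm are *flagged*
(adjacent losses are partly the same segmental event) but not removed.
Cross-cohort consistency means the same significant call in both cohorts.

Calibration: with 200 independent null features at n = 400 the screen's
empirical type-I error at p < 0.05 is ≈ 0.044 — slightly conservative, as
expected for an exact test on discrete tables.

## Differential expression

Genes are standardised across samples (sample sd, n−1). "z-scores per
sample" is read as per-gene standardisation across samples — the only
reading under which per-gene median differences are meaningful. The group
contrast uses the **independent-samples** rank-sum (Mann–Whitney) test:
the groups being compared (loss vs neutral) are unpaired and of unequal
size, so a paired signed-rank test is undefined; the naming discrepancy in
the upstream description is recorded here. Exact enumeration is used when
both groups have ≤ 12 tie-free observations, otherwise the mid-rank normal
approximation with tie-corrected variance. Gene-level runs adjust with
Bonferroni, protein-level runs with Benjamini–Hochberg, over all tested
genes.

Pathway input selection ranks by adjusted p (ties: |effect| descending),
removes downregulated genes on the anchor's chromosome arm **before** the
top-k cut (k = 50), and keeps upregulated arm genes. Over-representation
is the upper-tail hypergeometric test of the selection against each gene
set intersected with the universe, BH-corrected across sets.

## Deconvolution

The mixing model is `P_j = SM·β_j + ε`: `SM_ik` is the mean expression of
gene i in cell type k, `β_kj` the fraction of type k in sample j, ε noise.
The solver is per-sample non-negative least squares on the genes shared
between bulk matrix and signature matrix, followed by renormalisation to
the simplex. This deliberately implements the printed linear model rather
than any particular published solver pipeline (no ν-SVR, no batch
correction); at the level of the model equation the estimates are
comparable. Choices:

* Sum-to-one is imposed post hoc by default (fraction semantics with a
  simple solver); a constrained mode appends a heavily weighted equality
  row to the NNLS system.
* An all-zero solution (pathological input) is flagged and replaced by
  uniform fractions.
* A rank-deficient signature matrix triggers a warning with its condition
  number; collinear types split arbitrarily but fractions still sum to 1.
* Input scaling offers `log2_scale` (log2(1+x) then per-gene z) for
  RNA-seq-like data and `scale` (z only) for microarray-like data.

Ensembling averages fraction estimates element-wise over K signature
matrices (types harmonised by name, mismatches are an error) and
renormalises; with K = 10 noisy references the ensemble's mean absolute
error is measurably below the median single-matrix error, the variance-
reduction rationale for the 10-matrix design. Fraction contrasts between
loss and neutral tumors use the rank-sum test per cell type with BH across
types; cross-cohort consistency requires the same sign and q < 0.05 in
both.

## Pharmacogenomic screen

Responses are log10 IC50 values keyed by (cell line, drug, screen).
Features are binary genomic indicators. Per testable pair (≥ 3 lines in
each genotype class, non-degenerate variance):

* mean difference (feature-positive − feature-negative; negative =
  sensitivity);
* Glass' Δ = |mean difference| / group sd, computed against **both** group
  sds; the volcano cutoff (1.4) applies to the smaller of the two — the
  conservative reading, fixed here as a convention;
* Mann–Whitney p (exact for pooled n ≤ 20 without ties);
* BH q computed **per screen** by default, because IC50 scales differ
  between screens (a pooled mode exists);
* point-biserial r (Pearson with the 0/1 indicator), Fisher-z 95% CI with
  se = 1/√(n−3), magnitude negligible/small/medium/large at |r| = 0.10 /
  0.24 / 0.37.

Genome-wide hits must satisfy p < 0.001, q < 0.25 and min-Δ > 1.4. The
anchor-only screen keeps one feature across all drugs and screens
(duplicate drugs across screens stay as separate records) and gates on
q < 0.05 in place of the raw-p cutoff. The elastic-net ranking
standardises features, picks the penalty by 10-fold cross-validation with
the 1-SE rule on a 50-point log-spaced grid (mixing 0.5), and reports
coefficients rescaled to the raw 0/1 feature scale; it accompanies the
Mann–Whitney statistics rather than replacing them — the screen's p-values
here are always the rank-based ones. PDX-style responses (AUC) run
through the identical two-group machinery with no curve fitting.

## Survival

The Kaplan–Meier estimator and two-group log-rank test are implemented
directly; they are the module's entire statistical content and the tests
exercise every censoring pattern on small inputs against an independent
reference implementation. At tied times events are processed before
censorings (a sample censored at t is at risk for an event at t). The
log-rank statistic uses the hypergeometric variance at each distinct event
time and a 1-df chi-square reference; zero total events yields p = 1 with
a flag. Stratified comparisons require a configurable floor (default 5)
of patients per anchor class per stratum; smaller strata are reported
untestable. Hazard-ratio point estimates (Cox models) are deliberately
out of scope.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with planted
ground truth for recovery tests. One global seed expands into per-stage
child seeds (`numpy.random.SeedSequence.spawn`, fixed stage order), so
identical seeds give bit-identical cohorts and changing one stage's
parameters never perturbs another stage's draws.

* **Genome**: a toy genome (default 4 chromosomes × 10 bands × 4 genes);
  bands are 1 Mb, genes 10 kb.
* **Copy number**: per sample a first-order Markov chain over bands
  (persistence 1 − 1/mean segment length, default mean 4 bands; state
  distribution defaults P(−2…+2) = 0.01/0.22/0.60/0.15/0.02). The anchor
  band is overridden by a Bernoulli loss draw — default prevalence 0.44
  overall, realised through per-PAM50 prevalences (0.35 luminal A … 0.55
  basal/HER2/luminal B) whose mixture average is ≈ 0.44, mirroring the
  enrichment of the loss outside luminal-A tumors. With probability
  `breakpoint_rate` (default 0.02) a band acquires a state switch at a
  uniform within-band gene index, producing the mixed values an ambiguous
  call detects.
* **Mutations**: planted features are drawn from the exact 2×2 cell
  probabilities implied by (marginal prevalence, odds ratio vs anchor),
  solved on the log-odds scale by bracketed root finding; defaults plant
  one strongly co-occurring mutation (OR 3, prevalence 0.35) and two
  mutually exclusive ones (OR 0.35), the consistent-cohort pattern.
  Background genes are anchor-independent at 5% prevalence, and 0.8% of
  samples carry a pathogenic truncating mutation in the first anchor-band
  gene — the carrier-exclusion rule's target.
* **Expression**: baseline per gene ~ N(8, 1), plus cis dosage
  (0.5 units per CN step), plus trans genes shifted by 1 noise-sd in
  anchor-loss samples, plus N(0, 1) noise.
* **Mixtures**: `SM` entries ~ Gamma(2, 1); β per sample from a symmetric
  Dirichlet (concentration 1; the fraction prior is a package choice);
  `P = SM·β + ε` with ε ~ N(0, 0.05); the K = 10 signature-matrix
  ensemble consists of noisy observations of the generating matrix
  (sd 0.1, clipped at 0). A default +0.08 shift of the first cell type in
  loss samples (renormalised) emulates the macrophage-like increase.
* **Drugs**: log10 IC50 = per-drug baseline N(0, 1) + planted feature
  effects + N(0, 0.5); defaults plant anchor-loss sensitivity to three
  drugs, one replicated in both screens (the BCL2-inhibitor pattern).
* **Survival**: exponential event times with hazard 0.015/month ×
  HR^anchor (default HR 2), independent exponential censoring at
  0.008/month (≈ 30–35% censored).

What the generator does **not** emulate: correlated gene-gene expression
structure, subclonal/fractional copy numbers, mutation signatures,
measurement batch effects, non-proportional hazards, and informative
censoring. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to those
real-data complications.

## Problem sizes and numerical details

The validation suite and `scripts/acceptance.py` use deliberately modest
problem sizes chosen so each stage's check is statistically informative:
type-I calibration at 100 000 (suite) / 20 000 (script) null Fisher tests;
Fisher-versus-enumeration on all 2×2 tables to n = 40 (suite) / 25
(script); deconvolution recovery at 200 genes × 5 types with ensemble
comparisons over 100 / 50 seeds; pharmacogenomic power at 300 drugs × 50
cell lines over 20 / 10 seeds and null screens over 50 / 20 seeds;
differential-expression power at 200 samples per group over 100 / 25
seeds; log-rank calibration over 200 / 100 seeds and power at n = 500
over 100 / 50 seeds. Tolerances: effect-size formulas are checked to
1e-12; noiseless NNLS recovery to 1e-6; simplex sums to 1e-9. Ties in
rank tests use mid-ranks with tie-corrected variance. All randomness
flows from explicit seeds; CLI outputs contain no timestamps and
fixed-precision floats ("%.10g"), so identical seeds reproduce output
files byte-identically.
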