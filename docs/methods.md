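# Methods

`splicescreen` implements a desk-scale analysis chain for alternative
terminal-exon biology of the kind exemplified by the TP63 γ exon in head and
neck squamous cell carcinoma: quantify how often a splice junction is chosen
among its competitors, find RNA-binding proteins (RBPs) whose expression
tracks that choice across tissues, test whether the candidate's behaviour in
tumors is sign-consistent, ask whether the splice choice stratifies patient
survival, characterise the transcriptome of the resulting patient groups,
and quantify direct protein–RNA binding by an equilibrium isotherm.

## Depth normalization

For sample *s*, the total read count `Ts` is the column sum of the count
matrix; `Mrd` is the median of the retained `Ts`; the per-sample factor is

    Ns = Mrd / Ts,    Egs = Rgs × Ns.

This is the unique depth-equalising reading of a "read depth normalization
factor": after scaling, every column totals `Mrd`, a sample at exactly
median depth is untouched, and multiplying all counts by a constant leaves
`Ns` unchanged. Samples with `Ts = 0` are excluded from the median and
reported; they are never silently dropped. We deliberately do not use
TPM/TMM or composition-aware normalization — junction usage is a
within-sample ratio in which `Ns` cancels, and the correlation screen is
scale-invariant per gene, so simple depth equalisation is sufficient and
transparent.

The expressing-tissue test summarises a gene's normalized expression per
tissue with the **median** by default (a single outlier sample should not
qualify a tissue; the mean is available by flag) and selects tissues at or
above a threshold. No universal threshold exists for "expressing"; the
threshold is a parameter, and the synthetic panel documents its own design
threshold in its truth record.

## Junction usage and PSI

Junctions compete for splice sites. The default competing set groups
junctions of one gene that share their **donor** (5′) coordinate — the
configuration of a terminal-exon choice in which one 5′SS splices either
into the alternative terminal exon or past it (the γ-exon J11-12 / J11-13
competition). `shared_acceptor`, `either_end` (transitive closure over
either shared coordinate) and `whole_gene` modes support sensitivity
analyses. Usage of junction *j* in sample *s* is its share of
depth-normalized reads within its set:

    usage(j, s) = N_js / Σ_{k∈set(j)} N_ks.

When the denominator is below `min_coverage` (default 8 normalized reads,
in the range splicing databases use before reporting PSI) the value is
**missing**, not zero: a coverage-free event carries no information, and
coding it as 0 would fabricate an exclusion signal. Within every covered
set, usages sum to 1 by construction (property-tested), and per-sample
depth cancels exactly.

Event-level PSI is reported on the 0–100 percent scale,
`100 × inclusion/(inclusion + exclusion)`, missing below the same coverage
floor.

## Regulator screen

Pearson correlation between each RBP's normalized expression and the target
junction's usage, over pairwise-complete individual samples (not tissue
means — per-sample correlation preserves within-tissue information). The
p-value is the usual `t = r√((n−2)/(1−r²))` on `n−2` df, two-sided (we do
not presume the direction of regulation). RBPs with zero variance or fewer
than 3 complete pairs are reported untestable rather than ranked. Ranking
is by |r| — a strong repressor is as interesting as a strong enhancer —
with deterministic tie-breaking by smaller p, then symbol. Expression is
correlated as-is; a `log1p` flag exists because the choice is defensible
either way for lognormal-ish expression.

The **concordance filter** confronts cross-tissue candidates with tumor
data: a two-sided Wilcoxon rank-sum between high- and low-PSI tumor groups,
at α = 0.05 by default. A negatively correlated candidate (putative
repressor, PTBP1-like) passes only if significantly *lower* in high-PSI
tumors; a positively correlated one (GRSF1-like) only if *higher*. A
candidate whose tumor shift contradicts its correlation sign (the
SFRS9-like pattern) is rejected: the two observations cannot be explained
by the same causal direction.

## Survival stratification

Patients split at a PSI threshold; the boundary value goes to "high"
(`psi ≥ threshold`). Kaplan–Meier and the two-group log-rank test are
implemented from first principles (the product-limit recursion and the
hypergeometric-variance log-rank with tied deaths aggregated per time,
`V = d(n₁/n)(1−n₁/n)(n−d)/(n−1)`), and validated against `lifelines` to
1e-12 in the test suite — the external library is an oracle, never the
implementation. The median survival is the smallest event time with
S(t) ≤ 0.5 and is reported as NA when the curve never reaches 0.5 (not
+∞). Since published PSI cutoffs rarely come with a derivation,
`scan_cutpoints` makes the choice explicit: scan a quantile grid, keep
cutoffs leaving at least `min_group_frac` (default 10%) of patients per
arm, return the p-minimising threshold **flagged with a multiple-testing
caveat** — the minimised p is optimistically biased and is reported for
threshold selection, not inference.

## Differential expression and enrichment

Gene-wise two-sided Wilcoxon rank-sum between the PSI groups — a
deliberately distribution-free choice consistent with the rest of the
toolkit; the engine is recorded in the results metadata. Exact enumeration
of the rank-sum null when both groups have ≤ 25 samples and no ties,
otherwise the normal approximation with tie and continuity correction.
Constant genes are untestable and excluded from the Benjamini–Hochberg
family (BH implemented as the standard step-up and cross-checked against
`statsmodels` in tests). The fold change is `log2((mean_high + 1) /
(mean_low + 1))` — the unit pseudocount guards against zero means on
normalized counts. Prognostic-marker annotation is a plain overlay: genes
absent from the marker map get "none", untestable genes keep their label.

Gene-set enrichment is the **classic hypergeometric** upper tail with
observed/expected fold enrichment `(k/n)/(K/N)` and BH across sets. We
intentionally do not implement GO-graph-aware decorrelation (topGO's elim):
it requires the term DAG, and the classic test is the transparent,
oracle-checkable baseline; results are labelled `hypergeometric_classic`.

## Binding kinetics

Single-site equilibrium isotherm, bound fraction `f = 1/(1 + Kd/[P])`
(amplitude fixed at 1 — the printed model form has no plateau parameter; a
free-plateau variant exists behind a flag for partially active probe
preparations). Fitting is least squares over **log Kd**: positivity by
construction and uniform conditioning from 1 to 10⁴ nmol/L; the initial
value is the concentration whose bound fraction is nearest 0.5.
Uncertainty is the SD across per-replicate fits when ≥ 3 replicates exist
(matching how EMSA replicates are usually summarised), otherwise a seeded
200-resample nonparametric bootstrap over points. Probes with no rising
signal (max bound fraction < 0.2, or a fitted Kd beyond 10× the highest
tested concentration) are declared **unbound** with Kd censored at
"> max conc" rather than forced to a meaningless point estimate. Affinity
comparisons report `Kd_b/Kd_a` with a delta-method interval on the log
scale; a censored numerator yields a lower bound ("≥ x-fold").

## Synthetic data

The generators produce every input with planted truth; they are pure
functions of (config, seed).

* **Multi-tissue panel** (GTEx-like, scaled to desk size): 54 tissues × 30
  samples by default, 10 tissues expressing the target gene — preserving
  the 10/54 expressing fraction of the motivating screen at roughly 1/10
  of its per-tissue sample count. RBP expression has lognormal tissue
  means (between-tissue σ = 0.5, within σ = 0.3); the planted regulator
  drives inclusion through a logistic link
  `inclusion = expit(a + b·z(regulator))` with default slope b = −1.5
  (repressor). Junction totals are negative binomial (mean 200, dispersion
  0.3) — overdispersion is the realistic stress for a ratio statistic —
  split binomially between the two competing junctions, then passed
  through per-sample lognormal depth (σ = 0.2) so normalization has real
  work to do.
* **Cohort**: PSI from a beta mixture (low component mean 2%, high mean
  8%, 35% high weight — a weakly included exon with a high-inclusion
  minority); the true group is `psi ≥ 4.07`. Survival is exponential with
  hazard `h0·HR^[high]` (h0 = 1/1500 per day, HR default 3) — the minimal
  model for which the log-rank test is exact, making type-I and power
  targets clean; uniform censoring is calibrated numerically to the target
  rate (default 30%). Expression is lognormal (σ = 0.5) with planted
  multiplicative shifts (default 100 of 1000 genes at 2-fold) in the high
  group; planted up-genes are labelled unfavorable markers and an equal
  number of null genes favorable.
* **Titration**: isotherm plus Gaussian noise (σ = 0.05) on a two-fold
  ladder 12.5–1600 nmol/L, clipped to [0, 1], 4 replicates.

What the generators do **not** emulate: batch effects, tumor
heterogeneity/purity, isoform-level read assignment ambiguity, more than
two competing junctions per event, non-proportional hazards, correlated
gene-gene expression structure. Passing recovery tests therefore shows the
estimators are correct and calibrated under their own assumptions, not
that real-cohort effect sizes will replicate.

## Numerical choices and degenerate inputs

Usage/PSI: missing (NA) below coverage, never 0/0. KM ties: deaths
aggregated per time. Log-rank with no events: statistic 0, p 1, warning.
BH: stable sort, monotonicity enforced from the largest rank. Screen ties:
p then symbol, so output is byte-stable. Kd: `lm` least squares with
xtol/ftol 1e-14; noise-free data is recovered to < 1e-6 relative error
across kd ∈ [1, 10⁴]. Serialization: fixed column order, tab separator,
`.` decimal, `NA` missing, no locale dependence.

## Problem sizes

The bundled experiments use 10–54 tissues × 30 samples, 50–100 RBPs,
cohorts of 80–500 patients, 1000 genes, 500 null replicates for type-I
calibration and 20 replicates for recovery rates — sizes at which every
recovery and calibration experiment completes in seconds while keeping
Monte-Carlo error well below the tolerances being checked.

## Known limitations

* The screen is marginal Pearson correlation: tissue-level confounding
  (an RBP merely co-varying with tissue identity) is addressed only by the
  tumor concordance filter, not by partial correlation or regression.
* `scan_cutpoints` p-values are selection-biased by design and flagged as
  such; no cross-validation or permutation correction is applied.
* The DE engine is a two-group rank test; covariates (HPV status, batch)
  can be handled only by pre-filtering samples.
* The isotherm assumes protein excess and 1:1 binding; cooperative (Hill)
  or multi-site binding is out of scope.
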