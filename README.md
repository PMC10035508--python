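# splicescreen

Toolkit for analysing **alternative terminal-exon choice** and its
consequences, built around the kind of question posed by the TP63 γ exon in
head and neck squamous cell carcinoma: two splice junctions share one 5′
splice site — one includes an alternative terminal exon, the other skips
past it — and the fraction of transcripts taking each route varies across
tissues, correlates with the expression of trans-acting RNA-binding
proteins (RBPs), and stratifies patient survival.

The package covers the full chain on tabular inputs (junction count
matrices, expression matrices, clinical tables, PSI tables, titration
tables), with a synthetic-data module that generates every input with
planted ground truth so each stage can be validated end to end:

1. **Depth normalization** — `Ns = Mrd/Ts`, `Egs = raw × Ns` (median read
   depth over total reads per sample), plus expressing-tissue selection.
2. **Junction usage** — competing-junction sets (shared donor by default)
   and `usage(j,s) = N_js / Σ_{k∈set(j)} N_ks` over normalized reads;
   event-level PSI on the 0–100% scale; coverage-aware missingness.
3. **Regulator screen** — per-sample Pearson correlation of each RBP's
   normalized expression with a junction's usage, t-based p-values, |r|
   ranking, and a tumor sign-concordance filter (Wilcoxon between high/low
   PSI groups must agree in direction with the correlation sign).
4. **Survival stratification** — PSI-threshold split (boundary to "high"),
   from-scratch Kaplan–Meier `S(t) = Π(1 − d_i/n_i)` and two-group
   log-rank with hypergeometric variance, plus an explicit cutpoint scan.
5. **Differential expression** — gene-wise Wilcoxon rank-sum,
   Benjamini–Hochberg FDR, pseudocount log2 fold changes,
   prognostic-marker overlay, classic hypergeometric gene-set enrichment.
6. **Binding kinetics** — single-site isotherm `f = 1/(1 + Kd/[P])` fitted
   in log-Kd space with replicate or bootstrap SDs, censored "unbound"
   verdicts, and Kd fold-change comparisons.

Statistical stages follow a model/results pattern: build
`RegulatorScreen`, `SurvivalStratification`, `DifferentialExpression` or
`BindingModel` from data, call `.fit()`, and read estimates, uncertainties
and a `summary()` off the results object.

## Worked example

Generate a 10-tissue panel (30 samples each, 50 RBPs) with a planted
repressor of the terminal-exon junction, then screen for it:

```python
import splicescreen as ss
from splicescreen.simulate import INCLUSION_JUNCTION, TARGET_GENE

cfg = ss.PanelConfig(n_tissues=10, samples_per_tissue=30, n_rbps=50, seed=1)
junctions, expression, attrs, truth = ss.gen_multitissue_panel(cfg)
result = ss.screen_junction_regulators(junctions, expression,
                                       INCLUSION_JUNCTION,
                                       exclude_genes=(TARGET_GENE,))
print(result.summary())
```

```
Regulator correlation screen
  samples used : 300
  RBPs tested  : 50
  untestable   : 0

   rbp       r          p   n sign  rank
RBP000 -0.9444 5.914e-146 300    -     1
RBP024 -0.4116  1.079e-13 300    -     2
RBP040  0.4113  1.123e-13 300    +     3
...
```

`RBP000` is the planted repressor (logistic slope −1.5): it is recovered at
rank 1 with r = −0.94, far ahead of the background RBPs whose correlations
are noise. Survival stratification on a simulated cohort (hazard ratio 3
between PSI groups, threshold 4.07%):

```python
clinical, psi, expr, truth = ss.gen_cohort(ss.CohortConfig(seed=1))
print(ss.SurvivalStratification(clinical, psi, 4.07).fit().summary())
```

```
PSI-threshold survival stratification
  threshold (PSI %)    : 4.07
  n high / low         : 76 / 124
  median survival high : 366.1 days
  median survival low  : 955.9 days
  log-rank chi-square  : 39.0675
  log-rank p           : 4.094e-10
```

High inclusion carries the planted 3-fold hazard: the high-PSI arm's median
survival is roughly a third of the low arm's, and the log-rank test detects
the separation. Binding-isotherm fitting on a simulated titration
(Kd = 104 nmol/L, 4 replicates, noise σ = 0.05):

```python
fit = ss.fit_kd(ss.gen_titration(104.0, noise_sd=0.05, n_replicates=4,
                                 seed=1, probe_name="150PY"))
print(fit.summary())
# 150PY: Kd = 106.0 +/- 5.1 nmol/L (replicate SD, 32 points, SSE 0.05879)
```

The same stages are available from the shell (`splicescreen simulate`,
`usage`, `screen`, `survive`, `de`, `kd`); see `splicescreen --help`.

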