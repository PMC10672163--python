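# Methods

This note defines the statistical models, parameter choices, numerical
conventions, and known limitations of `neuromirnet`. Everything here is
implemented in the package; problem sizes quoted for the simulator are the
package's own defaults, chosen to keep end-to-end validation runs under a
couple of minutes on one CPU.

## Count model and differential expression (`diffexp`)

Counts are modelled as negative binomial, `Var(K) = mu + alpha * mu^2`,
with a log link and a two-group (control vs case) design.

**Sample QC.** Samples with fewer than 1,000,000 assigned reads are
excluded before any estimation; the inequality is strict, so a sample with
exactly 1,000,000 reads is retained. If an exclusion leaves fewer than two
samples in either condition the analysis aborts with an error rather than
proceeding underpowered.

**Size factors.** Median-of-ratios: for each sample, the median over
features of the ratio of its count to the per-feature geometric mean
(computed in log space over features with all-positive counts). The raw
medians are rescaled so their geometric mean is exactly 1. An error is
raised if no feature is positive in every sample (no pseudo-reference).

**Variance-stabilizing transform.** `log2(q + 4)` on normalized counts
`q = k / s_j` — the `+4` pseudo-count keeps low-count features from
dominating heatmap z-scores.

**Dispersion estimation.** Three stages:

1. *Per-feature method-of-moments.* Within-condition pooled variance
   (df-weighted) `v_pool` gives `alpha_hat = (v_pool - mu) / mu_sq_term`
   on normalized counts, floored at 0.
2. *Trend.* Least squares fit of `alpha_tr(mu) = a1 / mu + a0` over
   features with positive estimates, with `a1 >= 0` and `a0 >= 1e-8`.
3. *Shrinkage toward the trend in log space.* The final estimate is
   `exp(w * log(alpha_hat) + (1 - w) * log(alpha_tr))`. The weight `w` is
   chosen empirically per dataset: the sampling variance of a log
   dispersion estimate at residual degrees of freedom `df` is approximately
   `trigamma(df / 2)`; the spread of the observed log-residuals around the
   trend is measured robustly as `(1.4826 * MAD)^2`; the excess of the
   observed spread over the sampling variance estimates the true
   between-feature dispersion variance `sigma_prior^2`, and
   `w = sigma_prior^2 / (sigma_prior^2 + trigamma(df / 2))`, capped at
   `n_eff / (n_eff + 4)` with `n_eff` the residual degrees of freedom.

   Rationale: a fixed weight `n_eff / (n_eff + 4)` passes most of the
   method-of-moments noise through at small n (e.g. `w = 2/3` at n = 5 vs
   5), which anti-conservatively inflates Wald statistics for features
   whose dispersion is under-estimated by chance — in null simulations the
   raw p < 0.05 fraction reached 0.077 instead of the nominal 0.05. The
   empirical-Bayes weight adapts: when features genuinely differ in
   dispersion it approaches the fixed cap, and when the observed spread is
   explained by estimation noise alone it collapses the estimates onto the
   trend. With it, null simulations at n = 5 vs 5 give a raw p < 0.05
   fraction of 0.05–0.06 across seeds while the power to detect planted
   |log2FC| = 1.5 at mean 500 stays above 0.95.

**Wald test.** Per-feature IRLS fit of the two-parameter NB GLM
(intercept + condition effect) with fixed dispersion and size-factor
offsets; coefficients are clipped to `|beta| <= 30` (log scale),
convergence tolerance 1e-8, at most 100 iterations. The standard error
comes from the Fisher information; the p-value is two-sided normal on
`lfc / se` (the reported `lfc` is in log2 units). Features that are zero
in every sample are reported with `lfc = NaN`, `p = 1` and excluded from
multiple-testing correction; non-converged fits are reported with `p = 1`
and logged. FDR is Benjamini–Hochberg over the tested features. When no
control label is given, the control level is auto-detected from the
condition names ("control", "ctrl", "healthy", "vehicle"), else the
alphabetically first level.

**Calling rule.** A feature is differentially expressed iff
`fdr < 0.05` (strict) **and** `|lfc| > log2(1.5) ≈ 0.585` (strict), i.e. a
mean change of more than 50%. `fdr = 0.05` exactly is not called.

## Cross-cohort consensus (`consensus`)

Candidates are the intersection of the per-cohort DE call sets. By default
a candidate must change in the same direction in every cohort; discordant
features are excluded and logged (`require_concordance=False` disables
this). The ranking score is the maximum over cohorts of `-log10(fdr)` with
the FDR floored at 1e-300 so that zero FDRs remain finite; ties are broken
by lexicographic feature identifier, and ranks are ordinal (1, 2, 3, …).

## Target integration (`target_integration`)

**Gene-level CWCS.** TargetScan-style predictions are per transcript; the
gene-level cumulative weighted context++ score is the minimum (most
negative, strongest predicted repression) over transcripts and the
conserved-site count is the maximum.

**Confidence tiers.** A prediction is retained iff `cwcs < -0.2` (strict:
exactly −0.2 is dropped); retained predictions are `high` confidence iff
`cwcs < -0.4` (strict: exactly −0.4 is `moderate`).

**Integration.** An edge (miRNA, gene) enters the network iff the miRNA is
an up-regulated consensus candidate, its seed family has a retained
prediction for the gene, and the gene is in the down-regulated mRNA call
set. Candidates without a prediction family are skipped and logged.

**Seed-site scanning.** The seed is miRNA nucleotides 2–8 (5′→3′). With
`core = revcomp(seed[1:7])` (positions 2–7) the canonical site motifs in
the 3′UTR (5′→3′) are:

- `8mer` — `comp(seed[8]) + core + A`
- `7mer-m8` — `comp(seed[8]) + core`
- `7mer-A1` — `core + A`
- `6mer` — `core`

Each core occurrence is classified once, by priority
8mer > 7mer-m8 > 7mer-A1 > 6mer. The reported `start` is the 1-based
position of the 5′-most matched UTR base (the m8 base for 8mer/7mer-m8,
the first core base otherwise). T and t are accepted as U; other
characters raise an error.

## Networks (`network`)

The integrated edge list forms a bipartite graph (miRNA and gene nodes).
Gene node size is the maximum |CWCS| over incident edges; a gene is
flagged for labelling when any incident edge is high-confidence. Duplicate
edges are an error. The summary reports node/edge counts, per-tier edge
counts, and degree maps.

## Enrichment (`enrichment`)

Overrepresentation p-values are upper hypergeometric tails
`P(X >= x)` with population = universe size, successes = set ∩ universe,
draws = query ∩ universe; genes outside the universe are dropped and
logged. FDR is Benjamini–Hochberg across the tested sets, and the headline
slice is the top 12 terms ordered by (fdr, pvalue, term_id).

## Assay statistics (`assays`)

**qPCR (2^−ΔΔCt).** Technical replicates enter as their mean Ct.
`dCt = Ct_target − Ct_reference` per sample,
`ddCt = dCt − mean(dCt of the control group)`, `RQ = 2^−ddCt`; control
samples therefore average RQ 1 in log space.

**Viability.** Each well is normalized to its own luminescence at the
baseline time (default 5 h); percent viability at time t is
`100 * (R − mean_death(R)) / (mean_vehicle(R) − mean_death(R))`. Because
every well has R = 1 at the baseline itself, the vehicle and death means
coincide there by construction, so only time points strictly after the
baseline are reported; if the two group means coincide at any later time
the normalization is degenerate and an error is raised. Vehicle wells
average 100, death-control wells 0.

**Dual luciferase.** Per-well firefly/renilla ratio, divided by the mean
ratio of the scrambled-control group.

**Clinical scores.** Scores live on the discrete scale
(0, 1, 2, 3, 3.5, 4, 5). Animals with all-zero observed scores are
excluded (and reported); isolated missing values are imputed with the
group × day mean of observed scores (reported as (animal, day, value));
a day with no observed value in a group is an error. Disease burden per
animal is the trapezoid AUC of score over days; by default the AUC is
computed over the common window of days observed for all animals
(`window="full"` uses each animal's own span). Groups are compared with a
two-sided Mann–Whitney U test: the U statistic and midrank handling are
computed in-package; the p-value is exact (full permutation distribution)
when `n1 * n2 <= 400` and there are no ties, otherwise a normal
approximation with tie correction and continuity correction is used.

## Simulator (`simulate`)

All randomness derives from a single integer seed through
`numpy.random.SeedSequence([seed, stream])` substreams, one per data
domain (miRNA design, miRNA counts, mRNA, predictions, UTRs, assays), so
each output is reproducible and independent of whether the others are
generated. Defaults model a two-cohort study: cohorts of 5 and 4 animals
per group, 300 miRNAs with log-uniform base means in [20, 2000], NB
dispersion 0.1, and 24 planted miRNAs (half up, half down,
|log2FC| ∈ [2, 3]) drawn from the robustly expressed stratum (base mean
≥ 100). The mRNA cohort has 2,000 genes; each planted up-miRNA receives
`target_density * n_gene` (default 40) true target genes silenced by
log2FC −2 in case samples, and the prediction table contains every true
edge with CWCS in [−0.9, −0.25] plus an equal number of decoy edges with
CWCS in [−0.15, −0.01] — the separated ranges make edge recovery a test
of the pipeline's bookkeeping, not of borderline thresholding. UTRs are
random sequences with planted canonical sites (overlaps rejected); the
authoritative per-UTR truth is obtained by re-scanning the final sequence,
so sites that upgrade by chance (e.g. a random A after a planted 7mer-m8)
are recorded as their true type. Assay generators plant a ΔΔCt effect, a
viability plateau, and a clinical-score severity shift, with configurable
missingness and forced all-zero animals.

## Limitations

- The GLM supports two-group comparisons only: no covariates, interaction
  terms, or continuous designs, and no outlier refitting (Cook's
  distance). The dispersion trend is the parametric `a1/mu + a0` form
  only.
- The Wald test uses the normal approximation; no likelihood-ratio test
  or lfc shrinkage for ranking-by-effect-size is provided.
- The seed scanner handles canonical site types only — no supplementary
  3′ pairing, bulges, or wobble pairs — and reports non-overlapping
  classifications per core occurrence.
- The exact Mann–Whitney path enumerates the permutation distribution and
  is limited to `n1 * n2 <= 400` without ties; beyond that the normal
  approximation is used.
- The simulator is a statistical generator for validation, not a
  biophysical model: miRNA–target silencing is a fixed mean shift, UTR
  backgrounds are i.i.d. uniform, and assay noise models are simple
  log-normal/Gaussian forms.
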