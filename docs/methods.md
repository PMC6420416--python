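# Methods

`ilmqtl` implements the statistical core of a metabolite-QTL (mQTL) study
on an introgression-line (IL) population: a set of genotypes each carrying
one marker-defined chromosome segment from a wild donor in the background
of a recurrent parent (the control, M82), phenotyped for a few dozen
primary metabolites with replicate plants in two independent experiments
(environments).

## The observation model and the synthetic generator

All modelling is on the log2 scale. The generator draws

    y[i,j,k,m] = mu[m] + g[i,m] + e[k,m] + ge[i,k,m] + delta[i,m] + eps[i,j,k,m]

for genotype *i*, replicate *j*, experiment *k*, metabolite *m*, with
independent zero-mean Gaussian effects: genotype `g` (SD `sigma_g`),
experiment `e` (`sigma_env`), genotype-by-experiment `ge` (`sigma_ge`) and
residual `eps` (`sigma_eps`). `delta` is a planted QTL shift applied, by
default, identically in both experiments, so every planted effect is
"conserved" by construction; an option restricts an effect to chosen
experiments to study false negatives. The control genotype carries `g = 0`,
`ge = 0` and no QTL. Panels are exported on the raw scale (`2**y`),
mirroring fold-change tables relative to the control.

Defaults (chosen once): 76 ILs + control, 4 replicates, 2 experiments, 42
metabolites, `sigma_g = 0.8`, `sigma_env = 0.3`, `sigma_ge = 0.55`,
`sigma_eps = 0.35` (log2 units), 5% missing cells. Lognormal moment algebra
places the genotypic coefficient of variation near 75%, the environmental
one near 25%, and plot-basis heritability near 0.6 — the regime reported
for leaf primary metabolites in this population type. Two caveats. First,
the defaults give *every* IL a genotype effect on *every* metabolite, so a
default run yields far more conserved calls than a real leaf study, where
effects are sparse and environment-dominated; power and calibration studies
therefore use explicit null/planted configurations rather than the
defaults. Second, metabolite columns are independent unless
`rho_g > 0`, which shares an exchangeable factor across the genotype
effects of all metabolites — real panels are strongly inter-correlated
(that is what relevance networks detect), and imputation quality can only
be demonstrated with `rho_g > 0`.

Missingness is MCAR by default; a left-censoring mode masks the lowest
`missing_rate` fraction of each metabolite instead, emulating
below-detection readings.

## Preprocessing

Filtering: (i) lines with no detectable metabolite at all are removed;
(ii) a metabolite is removed when it is unavailable, at line level (all
replicate cells missing), in strictly more than half of the lines. The
metabolite rule is evaluated per experiment and the surviving sets are
intersected (a flag evaluates it on the concatenated data instead); the two
steps iterate to a fixed point, making the filter idempotent.

Imputation is a missForest-style chained scheme: columns are visited in
order of increasing missingness, each regressed on all others with a
random forest (sklearn, `mtry = sqrt(p)`, 15 trees, depth ≤ 8 by default)
and its missing entries replaced by predictions, for up to 3 passes or
until the relative change in the imputed cells stops decreasing (the
iterate before the first increase is kept). The whole run is repeated 10
times with independent sub-seeds and the runs are averaged; observed cells
are never altered. The tree counts and depth were set for throughput on
panels of this size (~600 rows x 40 metabolites); because ten independent
runs are averaged, small ensembles per run cost little accuracy. Panels
too small for forests (< 4 metabolites or < 10 rows) fall back to kNN
imputation (k = 5, Euclidean distance on standardized metabolites).
Imputation operates on log2 values and maps back to the original scale,
so imputed values stay within each metabolite's observed range.

Fold changes: `lfc = log2(mean_genotype / mean_control)` per experiment on
raw-scale values. Exact zeros (below detection) are replaced by half the
smallest positive observed value of that metabolite before averaging; a
zero control mean is an error naming the metabolite and experiment.

## Variance components, Cvg/Cve, heritability

Per experiment, a one-way random-effects ANOVA over genotypes gives the
genotype and error mean squares, from which

    sigma2_g = (QMg - QMe) / r,   sigma2_e = QMe / r,
    Cvg(%) = 100 sqrt(sigma2_g) / mc,   Cve(%) = 100 sqrt(sigma2_e) / mc

with `r` the replicate count and `mc` the trait mean. Note `sigma2_e` is
the error variance of a genotype mean (QMe/r), not the residual variance.
Cvg/Cve are computed on raw-scale values, per experiment, since a log2
trait mean near zero would make the ratio meaningless.

Across two experiments, the balanced two-way random model (genotype,
environment, GxE, residual) is solved by equating observed to expected
mean squares:

    E[MS_G]  = s2_eps + r s2_GE + rE s2_G      E[MS_GE] = s2_eps + r s2_GE
    E[MS_E]  = s2_eps + r s2_GE + rG s2_E      E[MS_W]  = s2_eps

Negative solutions are truncated at zero and flagged — the standard
convention; truncation keeps H2 inside [0, 1]. Broad-sense heritability is
reported on the plot basis `H2 = s2_G / (s2_G + s2_GE + s2_eps)` by
default, or the entry-mean basis `s2_G / (s2_G + s2_GE/E + s2_eps/(rE))`;
the basis label travels with the output. On balanced data this moment
estimator coincides with REML whenever the estimates are interior (the
test suite cross-checks against lme4); for unbalanced data the harmonic
mean replicate count enters the EMS coefficients (flagged), and an
optional direct REML refinement (Nelder-Mead on log variances) is
available. Heritability is computed on log2 values and is invariant to
affine transforms of the data.

## Conserved mQTL calling

Each IL is compared with the control per experiment and per metabolite on
log2 abundances; an (IL, metabolite) pair significant at the 5% level in
both experiments with the same direction of change is a conserved mQTL.
Direction is the sign of the raw-scale fold change; an exact zero sign
never yields a call. Significance is inclusive (`p <= alpha`). There is no
multiple-testing correction in calling: replication across independent
environments is the error control, and under the global null the per-pair
false-call rate is `alpha^2/2` (two independent two-sided tests at level
alpha, times 1/2 for direction agreement).

The default per-experiment test is the ANOVA-consistent contrast: the IL
mean minus the control mean over the square root of the residual mean
square pooled across *all* genotypes in that experiment (a Dunnett-style t
without multiplicity adjustment, df = sum over genotypes of (n_g - 1)).
With homoscedastic residuals this is exactly calibrated and, at r = 4, has
per-experiment power 0.988 against shifts of 3 residual SDs (conserved
recall 0.977), where the two-sample Student test (df = 6) would reach only
0.939 (recall 0.88). The two-sample pooled ("student") and Welch variants
remain available for heteroscedastic data. Pairs where either group has
fewer than two observed replicates are reported untestable, never silently
dropped.

One subtlety for calibration studies: ILs within an experiment share the
control replicates and the pooled variance, so their calls are positively
correlated and the *variance* of a null-rate estimate exceeds the binomial
variance (the mean is unaffected). The packaged calibration study
therefore uses many small blocks (10 ILs x 100 metabolites x 100 seeds,
100,000 pairs), for which the binomial error model is accurate.

Summaries count conserved calls by direction, compound class (amino acid /
sugar / organic acid / other), chromosome and IL, erroring on unmapped ILs
or unclassified metabolites; per-call annotated-gene counts come from the
IL's introgressed segment in the bin map. The overlay heat map adds the
two experiments' fold-change matrices and categorizes each cell as
conserved up/down (both significant, same sign), inconsistent (both
significant, opposite signs) or neutral. Overlapping introgressions are
not deconvolved into bins; the bin is a reporting field only.

## Relevance networks

Pairwise Pearson correlations are computed on line-level mean profiles
(replicates averaged on the log2 scale, after imputation), with two-sided
p-values from the t distribution with n-2 df; with residual missingness,
pairwise-complete observations are used (minimum 3). Zero-variance
features are excluded with a warning. Benjamini-Hochberg step-up runs over
the upper triangle and edges require `q <= 0.01` by default. BH (not BY)
is used. Cross-tissue networks intersect the line sets, label nodes
`tissue:metabolite`, flag intra- vs inter-tissue edges, and apply BH
globally over all tested pairs by default (a per-tissue-pair scope is
available).

## Trait-metabolite association

Each trait (one value per line) is regressed on the line-level metabolite
profiles of both seasons, concatenated as *columns* (one predictor per
metabolite per season; a row-stacking mode exists behind a flag). The
elastic net minimizes

    (1/2n) ||y - Xb||^2 + lambda_ridge ||b||^2 / 2 + lambda_lasso ||b||_1

by cyclic coordinate descent on column-standardized predictors and
response, with the per-sweep objective asserted non-increasing and
convergence when the largest coefficient update falls below 1e-7 (at most
10,000 sweeps). The single published penalty grid (0.01, 0.05, 0.1, 0.5,
1, 1.5, 2, 10, 100) is interpreted as the ridge penalty with the lasso
penalty a fixed fraction (0.5) of it — the era's elastic-net tooling was
parameterized by an L2 penalty plus an L1 fraction yet reported one grid;
both the fraction and the grid are configurable. The penalty minimizing
mean out-of-fold squared error under 10-fold CV (seeded permutation folds;
ties go to the larger penalty) is refit on all data and the in-sample
r-squared recorded — it sizes the trait node in the bipartite association
network, whose edges are the nonzero coefficients signed by their sense.
Coefficients are reported on the standardized scale.

## What the synthetic studies do and do not show

The generator reproduces the study's *design* (sample sizes, replication,
two environments, variance structure, missingness) but not its biology:
real panels have sparse, correlated, occasionally non-Gaussian effects,
non-MCAR missingness and heteroscedastic residuals. Passing the packaged
studies shows the estimators and decision rules are correct and calibrated
under the stated model — not that the biological conclusions of any
particular dataset are right. Reproducing totals reported for real leaf
panels of this population (on the order of a hundred conserved mQTL)
requires the replicate-level tables themselves, which are not
redistributable here; `read_panel` accepts that layout directly, so the
pipeline runs on real tables when available.

## Problem sizes and numerical choices

The packaged studies use: 100,000 (IL, metabolite) null pairs for caller
calibration; 10 seeds of 40 planted QTL for power; 20 seeds for variance
and heritability recovery; 50 seeds for network FDR; 8 random 8x3 problems
against the brute-force elastic-net oracle; plus one default-condition
pipeline run. Tolerances follow the analytic error of each study (3
binomial/Monte-Carlo SEs, 15% relative on variance components, +-0.05 on
H2, 1e-5 on the elastic-net objective). Degenerate inputs (all-missing
panels, zero-variance features, zero control means, too-few replicates)
raise typed errors naming the offender rather than propagating NaNs.
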