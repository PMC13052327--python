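# Methods

`proteoage` implements a multi-stage analysis for three-group plasma
proteomics: healthy Young Controls (YC), Older Controls with low disease
burden (OC), and Older Patients (OP) matched 1:1 to the controls on age and
sex. The goal is to separate proteins that merely track chronological age
from proteins at the intersection of age and disease burden — candidate
markers of *biological* aging — and to distill a mortality signature from
that intersection. Because cohort data of this kind are typically
access-restricted, the package ships a synthetic-cohort generator with
ground-truth labels, and every stage is validated against it.

## Differential expression

For each protein, two pairwise comparisons are run: OC vs YC (independent
samples; the age contrast) and OP vs OC (paired through the matching; the
disease contrast). The test is chosen per protein by a Shapiro-Wilk screen
at `alpha_normality` (default 0.05): if normality is not rejected, a
t-test (independent or paired); otherwise a Wilcoxon rank-sum or
signed-rank test. For the unpaired branch both groups must pass the screen
by default (`normality_rule="both"`; an `"any"` variant is provided because
the gating convention is not uniquely determined by the design).
Rank tests use exact p values up to n = 25 without ties and the normal
approximation with continuity correction beyond. Constant vectors, where
the Shapiro-Wilk statistic is undefined, route to the rank test with a
warning.

Fold changes are geometric-mean ratios on the linear scale; since NPX is
log2-scale expression, `fc = 2^(mean_a - mean_b)`, which makes fold changes
exactly transitive. p values are Benjamini-Hochberg corrected across the
full panel of each comparison, and significance means BH-adjusted p < 0.05.

## Aging-protein classification and literature overlap

Proteins significant in both comparisons are classified as biological
Aging Proteins (APs); proteins significant in exactly one comparison are
chronological-age-only or disease-only. The four categories partition the
panel by construction, so the printed-count identities
(|AP| + |age-only| = |significant in the age comparison|, etc.) hold on any
input.

Overlap with literature-derived protein lists is computed on UniProt
accessions with isoform suffixes stripped, restricted to the measured
panel. Both denominators — the category size and the list-within-panel
size — are emitted, since published overlap percentages do not always state
which is used. Percentages are reported to one decimal, half-up. "Novel"
candidates are category members absent from the union of *all* supplied
lists; this deliberately ignores whether the lists' source platforms could
have measured the protein (the panel-coverage statistic quantifies that
caveat separately).

## Co-expression clustering and stability

Each protein is z-scored across all samples (sample SD, n-1; the choice
only rescales all distances by a common factor) and proteins are clustered
by complete-linkage agglomerative hierarchical clustering, Euclidean
distance by default and Manhattan as a sensitivity analysis. Proteins are
sorted lexicographically before clustering so ties break deterministically.

The number of clusters comes from the merge-height scree: k is chosen at
the largest second difference of the descending merge-height sequence
within k in [2, 20]. A visual scree read-off is not an algorithm, so the
automatic rule is overridable (`k=` argument / `--k`). A flat scree returns
k = 2 with a warning.

Stability: for each subsampling proportion (0.85, 0.90, 0.95, following the
usual protocol), 100 random protein subsamples are reclustered at the
full-data k and compared with the full-data labels (restricted to the
subsample) by the pair-counting Rand index. Because the Rand index scales
trivially with cluster-size profiles, a chance baseline is estimated as the
mean Rand of 100 random partitions with the subsample partition's size
profile, and the normalized score is `(mean_rand - baseline) / (1 -
baseline)` — approximately 0 at chance, 1 for perfect reproduction. Note
that even structureless data yields slightly positive scores (up to ~0.15
at proportion 0.95) because the subsample shares most of its noise with the
reference partition; genuinely stable structure scores above 0.95.

Cluster-category enrichment uses upper-tail hypergeometric tests (category
size K out of the N-protein panel, cluster size n, overlap k), BH-corrected
across all cluster-by-category tests.

## Over-representation analysis

Gene-set collections (GO, KEGG, Reactome, Hallmark in GMT format) are
stacked into one collection, mapped to UniProt space through an explicit
protein-gene mapping table (many-to-many allowed; a protein counts once per
set), and intersected with the measured panel, which serves as the
background. Sets smaller than 5 or larger than 2000 proteins after
intersection are skipped (configurable). Upper-tail hypergeometric p
values are BH-corrected once across the whole stacked collection, never per
database. The rich factor k/(K·n/N) is the observed/expected overlap ratio.

## Mortality signature: stratified Cox-LASSO with bootstrap stability

Only older participants enter the survival analysis (the young group is
event-free). The model is a Cox proportional-hazards regression with

* an L1 penalty on the standardized protein covariates (coefficients are
  log hazard ratios per SD of NPX),
* an unpenalized sex adjustment, and
* a baseline hazard stratified by group (OC / OP), so the groups' very
  different mortality enters through separate baselines rather than a
  proportionality assumption.

The optimizer minimizes `-(1/n) l(beta, gamma) + lambda * sum|beta_j|`
where `l` is the stratified Breslow partial log-likelihood (Breslow tie
handling; ties are expected with coarsely recorded times). Fitting is
proximal Newton: at each step the full Hessian of the partial likelihood on
the active columns is assembled and the penalized quadratic subproblem is
solved by cyclic coordinate descent, with an active set grown by KKT
screening of the zero coordinates, warm starts along the path, and a
step-halving safeguard on the penalized objective. Convergence requires a
maximum coefficient change below 1e-7. On strongly collinear designs
(bootstrap resamples duplicate rows) coordinate descent is periodically
short-circuited by solving the linear system implied by the current sign
pattern and accepting the solution only if it satisfies the subproblem's
KKT conditions. KKT optimality of every reported solution is checked in
tests at tolerance 1e-5, and the path agrees with an independent
glmnet-style implementation on single-stratum instances to 1e-4.

The grid is 100 log-spaced values from `lambda_max` (the smallest penalty
zeroing all protein coefficients, computed from the score at beta = 0 with
sex at its unpenalized fit) down to 0.01·lambda_max. The penalty weight is
chosen by 10-fold cross-validation on the Verweij-van Houwelingen deviance
`-2(l_full(beta) - l_train(beta))`, with folds stratified jointly by group
and event status so every training fold keeps events. Both `lambda_min`
(the default selection rule) and the 1-SE rule are reported, as published
descriptions of this procedure differ on which was used; a zero-event
stratum contributes exactly zero to the partial likelihood and is inert.

Robustness: the entire cross-validated selection is rerun on stratified
bootstrap resamples (each stratum drawn with replacement at its original
size; resamples that lose all events in a stratum are redrawn and logged,
keeping the resample count exact). A protein's selection frequency is the
fraction of resamples with a nonzero coefficient; proteins at or above 50%
are "robustly selected". Note that `lambda_min` over-selects by design, so
individual resamples typically include noise proteins; the bootstrap
frequency is what separates planted signal (frequency near 1) from noise.

## Clinical correlates

Pearson correlations between selected proteins' NPX values and clinical or
functional measures, pairwise-complete per cell, with 95% confidence
intervals from the Fisher z transform (z ± 1.96/sqrt(n-3)). No multiplicity
correction is applied — these are descriptive. Group restriction (e.g.
older participants only) is a parameter because published correlate tables
rarely state the pooling convention.

## Synthetic cohorts

`simulate_cohort` emulates the study design: 20 YC, 52 OC-OP pairs, and a
protein panel partitioned into null / age-only / disease-only / both
classes (default fractions 0.77 / 0.09 / 0.083 / 0.057, chosen to resemble
the reported 486 / 450 / 311 split of a 5416-protein panel). NPX values
are per-protein baselines (N(5, 2)) plus an age shift in both older groups,
a disease shift in patients only, an optional OC-OP pair random effect, and
unit-SD noise:

* shifts default to 1.0 NPX (a doubling), with 20% of age shifts and 5% of
  disease shifts negative, matching the predominantly-upregulated direction
  ratios such studies report;
* half the proteins carry a shared pair effect (SD 0.5) so both the paired
  test's power gain and the unpaired path are exercised; within-pair
  correlation is not reported in the literature this emulates, so 0.5 SD
  (intra-pair correlation about 0.2) was fixed as a plausible value;
* 20% of proteins get centred log-normal noise (sigma_log 0.8, rescaled to
  unit SD) so the normality gate routes a nontrivial fraction of proteins
  to rank tests.

Survival uses group-stratified exponential baselines (OC 0.0115/yr, OP
0.115/yr — a ten-fold patient excess calibrated to ~8% vs ~56% seven-year
mortality) scaled by `exp(beta' z + beta_sex male)` where z are the planted
hazard proteins standardized within older participants (default two
proteins from the "both" class at 1.0 per SD, sex at 0.25), censored
administratively at 7 years; Young Controls never have events.

`simulate_clusters` plants k trajectory prototypes across the three groups.
Because downstream clustering standardizes each protein, clusters are
distinguishable only by trajectory *direction*, so prototypes sit at
equally spaced directions in the two-dimensional group-contrast plane and
`separation` scales amplitude against unit noise; `separation = 0` yields
no structure.

What the generator does **not** model: plate/bridging batch effects,
limit-of-detection censoring or missingness, longitudinal sampling,
protein-protein correlation beyond the pair effect and planted clusters,
and real biological pathway structure. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the assumed
data-generating process, not performance on real cohorts.

## Validation scales and known limitations

The acceptance checks (`scripts/acceptance.py`, `tests/test_acceptance.py`)
run at scales chosen to keep a complete run within minutes on one CPU:
AP recovery on 1000-protein cohorts (5 replicates), cluster recovery on a
200-protein 4-cluster panel with 100 stability repeats, survival-signature
robustness over 10 seeds with 100 bootstrap resamples and a 50-value lambda
grid, and null calibration runs (3 cohort nulls, 20 survival nulls).

Known limitations:

* With 20 young controls, delta = 1 NPX and unit noise, the age contrast
  has per-protein power around 0.85-0.9 at the BH-realized threshold
  (SE = sqrt(1/52 + 1/20) = 0.263, noncentrality 3.8), so end-to-end AP
  recovery plateaus near 85%, limited by the study's own design rather than
  the implementation; the paired disease contrast at 52 pairs has power
  ~1.0.
* `lambda_min` cross-validation over-selects on purpose; sparse, stable
  signatures come from the bootstrap frequency filter, not from a single
  CV fit.
* The random-label stability baseline is an empirical convention; published
  normalized stability scores computed with a different baseline constant
  are not directly comparable.
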