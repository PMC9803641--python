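# Methods

This note documents the statistical model behind `dcmmet`, the
assumptions of the synthetic-data generator, and the numerical and
design choices, in enough detail to judge what a passing test suite
does and does not establish.

## Study design and contrasts

The target design is a four-group cross of disease (dilated
cardiomyopathy vs. healthy control) and baseline diet (non-traditional
vs. traditional) with default group sizes 38/8/12/17 (75 dogs), an
untargeted plasma metabolome of ~1027 compounds, and a 9-month
follow-up sample for the surviving subset of the DCM-NT group after a
switch to a traditional intervention diet.

Three two-group contrasts are fit per metabolite by ordinary least
squares on the natural-log abundance with age and sex (female = 1) as
covariates:

* disease: control = 0, DCM = 1 — positive β = higher in DCM;
* diet: T = 0, NT = 1 — positive β = higher with NT diets;
* within-DCM diet: NT = 0, T = 1 — *negative* β = higher in DCM-NT.

Reference levels are configurable; the defaults encode the sign
conventions above. P values are two-sided from the t distribution on
the residual degrees of freedom — the smallest group has n = 8, so
normal-approximation p values would be anticonservative. Covariates
are applied to all three contrasts by default (a switch removes them),
and to nothing else; the paired follow-up comparison is a one-sample
t test on within-dog month9 − baseline differences, which removes any
time-constant covariate by construction. Pairing with fewer than three
dogs is refused outright: a two-survivor group carries no usable
paired information.

## Preprocessing

Raw abundances are processed in the fixed order batch normalisation →
imputation → log:

1. zeros are treated as missing (below detection);
2. each metabolite is scaled per batch so the batch median of observed
   values equals the metabolite's grand median (multiplicative factors,
   recorded in the preprocessing report; an all-missing metabolite ×
   batch cell keeps factor 1 with a warning). Scaling to the grand
   median rather than to 1 is arbitrary but is cancelled by the log
   transform in every downstream group contrast;
3. missing cells are imputed at the metabolite's minimum observed
   value — the convention matching left-censored missingness, where a
   non-detect most plausibly sits at or below the detection limit;
4. natural log, which requires strict positivity (violations name the
   offending metabolite).

Minimum imputation is deliberately simple and shared with common
referenced-laboratory practice, but it *attenuates* group differences:
censoring removes the low tail of the lower group and the imputed
value overstates it. Under the default generator conditions (15%
missingness) the mean planted |t| drops from ≈ 7.9 (complete data) to
≈ 6.0. This is a property of the method being modelled, not of the
implementation, and it is the main reason recovery rates below are not
near 100%.

## Effective number of tests

Metabolite panels are strongly correlated, so the family-wise
threshold uses the effective number of independent tests

    Meff = Σ_i f(λ_i),   f(λ) = 1{λ ≥ 1} + (λ − ⌊λ⌋),

over the eigenvalues of the metabolite correlation matrix (the
Li & Ji 2005 estimator), with significance bands

    significant: p < α / Meff        nominal: α/Meff ≤ p < 0.05.

**Why the correlation matrix is shrunk.** With n samples ≪ m
metabolites the sample correlation matrix has rank ≤ n − 1; its
spectrum is dominated by estimation noise and the Li–Ji sum collapses
to roughly the rank (~110 for n = 75, m = 500 even for a perfectly
independent metabolome). The resulting α/Meff threshold is then far
too lenient: the expected count of null discoveries is m·α/Meff ≫ α.
The pipeline therefore estimates the correlation matrix with
Schäfer–Strimmer shrinkage toward the identity (the `corpcor`
convention standard in omics), λ* = Σ Var̂(r̂ᵢⱼ) / Σ r̂ᵢⱼ², before
taking the spectrum. Under an independent metabolome the estimated
intensity approaches 1 and Meff ≈ m, restoring the Bonferroni-type
guarantee; genuine correlation structure survives shrinkage and still
lowers Meff (the default synthetic cohort gives Meff ≈ 750 of 1027).
`effective_tests` itself is pure Li–Ji on whatever matrix it is given;
negative round-off eigenvalues are clamped to zero, and an externally
supplied Meff (`from_meff`, CLI `--meff`) reproduces published
thresholds exactly — 0.05/511 = 9.78 × 10⁻⁵ with `--meff 511`.

BH adjustment is the standard step-up procedure (via statsmodels),
order-preserving and verified against the literal step-up definition.

## Overlap panel and its evaluation

The panel is the intersection of the significant (α/Meff-tier) sets of
the disease and diet contrasts, ordered by descending min(|β/se|) over
the two contrasts with ties broken by metabolite id — a deterministic,
symmetric rule.

*Post-intervention direction* (↓/↑/NS) requires a significant paired
change with the matching sign. Significance is judged within the
panel: the panel metabolites' paired p values are BH-adjusted across
the panel and called at q < 0.05 (configurable to a nominal p < 0.05
band) — the narrower family reflects that only the panel is under
scrutiny at this stage.

*Random forest.* 500 trees, plain bootstrap, out-of-bag accuracy as
the headline number (stratified bootstrap is not available in
scikit-learn and the class imbalance here is mild; a stratified 5-fold
cross-validation estimate is available as `method="cv"`). Importance
is permutation importance (mean decrease in accuracy, 10 repeats,
computed on the training matrix), which unlike impurity importance is
comparable across correlated features; ranks break ties by metabolite
id so output is deterministic.

*Clustering.* Pairwise Pearson correlations, Ward linkage on the
dissimilarity 1 − r cut into k = 3 clusters. SciPy's `ward` applies
the Lance–Williams update to squared input dissimilarities, which is
exactly the `hclust ward.D2` convention; the equivalence is verified
against R in the test suite. Panel ids are sorted internally, so the
result does not depend on column order; constant columns are rejected
by name.

*Prior-study lookups* left-join a contrast table onto an external
results table on canonically lower-cased compound names and report the
tier × tier match counts.

## Network enrichment chain

1. **Protein over-representation.** For each protein in the
   metabolite→protein table, the exact hypergeometric upper-tail
   probability of its overlap with the significant metabolite set,
   within a background defaulting to all annotated metabolites (the
   convention of metabolite-set enrichment servers; overridable). BH
   across proteins; *eligible* requires overlap ≥ 2 **and** q < 0.05 —
   the count rule takes precedence no matter how small p is.
2. **Networks.** Per contrast, the interactome edges with at least one
   eligible endpoint (first-neighbour expansion — "input proteins plus
   their identified interactions"); an induced-subgraph mode requiring
   both endpoints is provided as a switch. Self-loops and duplicate /
   reversed edges collapse; isolated seeds remain as nodes.
3. **Intersection.** Shared edges of the disease and diet networks are
   retained only if some endpoint is eligible in *both* analyses; the
   deduplicated endpoints are the query for enrichment. The operation
   is a subset of both inputs and monotone under edge addition (tested
   as properties).
4. **Gene sets.** The standardised hypergeometric Z with finite-
   population correction, converted to p = 2 Φ(−|z|), BH-adjusted
   across all tested sets (a switch restricts adjustment to sets with
   ≥ 2 overlapping genes), with the ≥ 2-gene rule always applied to
   the significant list. Sets empty or saturating the background are
   skipped (zero variance). The background defaults to the collection
   union ∩ interactome nodes, again overridable, since server-side
   backgrounds are not reproducible offline. The normal conversion is
   rank-concordant with the exact hypergeometric tail on large
   backgrounds (Spearman > 0.99 in tests) but is discrete: with small
   sets p takes few values, which is why calibration checks use large
   populations where the KS reference distribution applies.

## Synthetic-data generator

Log abundances follow

    log X_ij = μ_j + sd_j · [ √s_d · u_i + √(1−s_d) · g_ij ] + effects + batch_bj

with μ_j ~ U(2, 8), sd_j ~ U(0.4, 1.2), a per-dog intercept u_i
(variance share s_d = 0.10) shared across metabolites and across the
two timepoints (this is what makes pairing informative), and g a
unit-variance noise field with compound-symmetric correlation ρ = 0.5
inside 50 blocks of 10 metabolites (the remainder independent).
Planted effects shift the DCM and/or NT margins by
`effect_size` × sd_j (default 1.5 within-group SDs) with sign +1 with
probability 0.8; overlap metabolites carry both effects with one
shared sign. Batch offsets are N(0, 0.25²) per batch × metabolite on
the log scale (2 batches). Missingness (rate 0.15) is left-censored:
the masking probability decreases linearly in the within-metabolite
rank. cTnI is log-normal, linked linearly to 10 disease-planted
metabolites plus noise. Follow-up samples exist for a survivor
fraction 20/38 of the DCM-NT group; diet-driven planted components are
attenuated by `intervention_reversal` (default 0.8 — most, not all, of
the diet signature resolves), disease-driven components persist.
Defaults mirror the reference cohort: 38/8/12/17 dogs, 1027
metabolites, 153 disease / 63 diet / 12 overlap effects. Group-level
covariate distributions (age, sex, weight) are centred on the
reference cohort's group summaries.

One RNG stream per logical component (covariates, abundances,
missingness, biomarker, annotations, follow-up) is spawned from the
single seed, so enlarging one component does not perturb the others,
and identical configs give bit-identical tables.

*Annotation bundle.* Each seed protein is annotated to 4 overlap-
planted metabolites (hence ≥ 2 members of both significant sets) plus
one random covered metabolite; 60 decoy proteins attach to random
non-planted metabolites; coverage of the metabolite→protein table is
deliberately partial (~300 of 1027 metabolites), as real annotation
resources are, and disease-only/diet-only planted metabolites are left
unannotated so that protein-level signal concentrates on the
dual-significant compounds — this is what makes the planted gene-set
recovery experiment well-posed. The interactome is a seed ring plus
one decoy neighbour per seed plus random decoy–decoy edges; planted
gene sets contain 7 of 8 seed proteins, 25 decoy sets are random.

**What the generator does not emulate:** raw spectra, retention times
or peak picking; annotation errors and many-to-many metabolite–protein
ambiguity; non-normal abundance distributions, heavy tails or outlier
samples; informative dropout beyond rank-based censoring; breed
structure or any covariate→metabolite effects. Passing recovery tests
therefore demonstrate that the chain is correctly wired and calibrated
under its own model, not that the thresholds or accuracies transfer to
any particular real cohort.

## Self-validation experiments and problem sizes

* **Null calibration** — 200 replicates of 75 samples × 500
  metabolites with zero effects and with blocks, the dog intercept,
  missingness and batches switched off, so p values are iid and the
  pooled Kolmogorov–Smirnov test is exact (under cross-metabolite
  dependence the pooled KS reference distribution would not hold;
  marginal uniformity is the property of interest). Both contrasts'
  pooled p values pass KS at the 1% level, the shrinkage-based Meff
  sits near 500, and the mean count of α/Meff-tier discoveries per
  family is compared against its expectation 0.05 with a one-sided
  exact Poisson test at the same 1% level — a simulated mean can only
  be tested against a bound with a sampling-noise allowance.
* **Recovery** — 50 seeded cohorts at the full default conditions.
  Mean recovery of the 12 planted overlap metabolites into the
  computed panel is ≈ 0.81 (the ≥ 0.8 requirement holds, with little
  margin; the gap to the ≈ 0.95 analytic power is the imputation
  attenuation discussed above). The network chain recovers *all*
  planted gene sets at q < 0.05 in ≥ 90% of runs while ≈ 1% of decoy
  sets reach significance.
* **Classifier sanity** — OOB accuracy ≥ 0.9 on 3-SD-separated
  synthetic classes (n = 60, 12 features) and 0.5 ± 0.1 on permuted
  balanced labels over 20 seeds.

These sizes keep the full suite around five minutes on one CPU while
leaving the binomial/Poisson allowances small relative to the effects
being checked.

## Degenerate inputs and tie-breaking

Zero-variance metabolites are flagged (β = 0, p = 1, note) rather than
dropped; constant paired differences are flagged degenerate with no p;
constant biomarkers and single-class labels are rejected; empty
overlap panels, empty shared intersections and empty enrichment tables
are valid empty outputs. All orderings (panel rows, importance ranks,
enrichment rows, edge lists) have explicit deterministic tie-breaks by
identifier. Fisher's exact test for r × c demographic tables sums the
probabilities of all margin-preserving tables no more probable than
the observed one (enumeration; fine for the cohort-sized tables it is
applied to, cross-checked against R's `fisher.test`).

## Known limitations

* Minimum imputation biases contrasts toward the null; no
  censored-likelihood alternative is provided.
* Meff estimation, and hence the significance tier of borderline
  metabolites, depends on the shrinkage intensity; the `--meff`
  override exists precisely so externally fixed thresholds can be
  reproduced.
* The Z-score gene-set p is a normal approximation — conservative and
  discrete for very small sets; the ≥ 2-gene rule removes the worst
  cases but exact hypergeometric gene-set p values are not computed.
* The random forest protocol (plain bootstrap, OOB) is one of several
  defensible conventions; accuracies from small panels on small
  cohorts carry wide binomial uncertainty regardless.
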