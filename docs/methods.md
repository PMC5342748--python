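# Methods

## The analysis

`methscreen` implements a discovery procedure for linking epigenetic
silencing of DNA-repair genes to an inflamed, immune-checkpoint-high tumor
phenotype in squamous cell carcinomas. The pipeline has five analytic
stages over gene × sample methylation (HM450-style beta values in [0, 1])
and expression (RSEM-style, non-negative) matrices:

1. **Correlation screen.** For each repair gene g in a curated catalog, the
   Spearman rank correlation ρ(β_g, x_m) between its methylation and the
   mRNA expression of a checkpoint marker m ∈ {CD274, CTLA4} is computed on
   the samples with complete pairs. ρ is the Pearson correlation of
   mid-ranks; the two-sided p-value uses the large-sample t approximation.
   Raw p-values are Bonferroni-multiplied by the family size m = number of
   genes retained in that (cohort, marker) screen — genes without
   methylation data, with fewer than 10 complete pairs, or with zero rank
   variance are excluded and reported, never silently dropped.
2. **Candidate selection.** A gene is a candidate when ρ strictly exceeds
   the cutoff for *both* markers. The conventional cutoff is 0.3; it can
   also be calibrated as the smallest value on the observed-rho midpoint
   grid such that at most a target fraction (default 10%) of screened genes
   exceeds it. Corrected significance is carried alongside candidates but
   does not gate membership.
3. **Cross-validation.** Each cohort's candidate list is re-screened in the
   other cohorts; genes with ρ > 0 in every tested (cohort, marker)
   association are flagged as cross-cohort consistent.
4. **Pathway enrichment.** With N background genes (those screened), K in a
   repair-pathway group, n candidates and k candidate-group members, the
   one-sided Fisher exact p is the hypergeometric upper tail P(X ≥ k),
   X ~ Hypergeom(N, K, n). Candidates are counted inside the background.
   Only the group with the highest candidate-vs-background share difference
   is flagged as the headline test, reproducing the published procedure;
   because selecting the maximum inflates that single p-value, a
   Bonferroni-over-groups option is provided for selection-adjusted
   inference. When the both-marker candidate list is too small to test, the
   union of the two per-marker hit sets is used instead.
5. **Signatures.** Per sample: the six-gene interferon-γ inflammatory score
   S = (1/6) Σ_g log2(x_g + 1) over {IFNG, HLA-DRA, CXCL9, CXCL10, IDO1,
   STAT1}; the binary methylation call per candidate gene (1 iff β strictly
   exceeds the gene's cohort mean); the methylation score M (count of
   hypermethylated candidates); mutation scores U (count of genes with ≥ 1
   somatic mutation, per gene not per record); and the combined score
   M + U_all. The ROC AUC of the continuous S against a binary methylation
   class is the mid-rank Mann–Whitney statistic. Dose dependence is
   summarized as the mean S per M level plus Spearman(M, S).

Descriptive structure of candidate methylation is examined by per-gene
mean-centering (within-cohort: "differential" means relative to the
cohort's own mean, not matched normals), agglomerative clustering under a
1 − Pearson distance with average linkage, covariance/correlation
matrices, and a stratified rank-sum comparison (e.g. TP53-mutant vs
wild-type) Bonferroni-corrected over genes.

## The synthetic cohort generator

Real inputs of this kind come from TCGA; the package ships a seeded
generator so every stage is testable without external data. One latent
"inflammation" factor L_i ~ N(0, 1) per sample induces all the couplings
the pipeline looks for:

* immune-gene expression: log2(x + 1) = μ_g + b_g·L + ε, ε ~ N(0, σ_e),
  emitted on the raw scale x = max(2^v − 1, 0);
* methylation of a planted subset of repair genes:
  β = logit⁻¹(a_g + c_g·L + η), η ~ N(0, σ_m); unplanted genes omit the
  c_g·L term and are therefore independent of every immune gene;
* every repair gene's own expression is depressed by
  γ·(β − mean β) with γ ≤ 0, so within-gene methylation–expression
  correlation is negative, as on real tumors;
* mutations are i.i.d. Bernoulli per (sample, gene), independent of L, so
  mutation scores are null against checkpoint expression by construction.

Because β and x are strictly monotone transforms of jointly Gaussian
variables, the population Spearman correlation has the closed form
ρ_S = (6/π)·arcsin(r/2) with
r = c_g·b_m / √((c_g² + σ_m²)(b_m² + σ_e²)). `loading_for_target_rho`
inverts this to plant genes at a chosen population ρ_S;
`expected_rho` provides an independent fixed-seed Monte-Carlo estimate of
the same quantity for tests.

### Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `b_g` (expr loading) | 1.0 | latent share of immune-gene log-expression variance 1/(1+σ_e²) = 0.8, a strongly inflamed-phenotype-driven panel |
| `σ_e` (expr noise) | 0.5 | log2-scale residual spread of expression |
| `σ_m` (meth noise) | 1.0 | logit-scale spread of beta values; with baselines a_g ~ U(−2, 1) this yields realistic beta distributions centered between ~0.1 and ~0.7 |
| `c_g` (meth loading) | from target ρ_S | study-shaped fixtures plant genes at population ρ_S = 0.45 vs each checkpoint, comfortably above the 0.3 cutoff at n = 278 yet far from saturation |
| `γ` (own-gene coupling) | −2.0 | gives within-gene methylation–expression Spearman ≈ −0.4 |
| mutation rate | 0.012/gene | calibrated so ~88% of samples carry ≥ 1 repair-gene mutation over a 179-gene catalog |
| TP53 mutation rate | 0.7 | typical of HPV-negative head-and-neck tumors; makes the TP53-stratified comparison meaningful while staying independent of L |
| μ_g baselines | U(5, 12) | log2 RSEM scale; high enough that the x ≥ 0 clip almost never binds, preserving rank structure |

Per-gene baselines are drawn once under the config seed, independent of the
number of samples, so growing a cohort does not change gene identities.
A single run seed fans out to named per-stage seeds via a CRC32 hash, so
stages re-run in isolation reproduce their draws.

The study-shaped fixtures mirror the real cohorts' dimensions: 278, 191 and
74 samples with 152, 153 and 158 of the 179 catalog genes carrying
methylation data, and 15, 3 and 2 planted genes respectively (RAD51B
planted in all three, so cross-validation has a shared positive). The
27/26/21 unmeasured genes are drawn from the non-planted,
non-homologous-recombination genes, keeping the HR group fully measured
(19/152 = 12.5% of the HNSCC background).

### What the generator does not emulate

No HM450 probe chemistry or probe selection, copy number, tumor purity,
HPV integration, batch effects, or cohort-specific expression scale
differences. Couplings are driven by a *single* latent factor, so the
simulated correlation structure among planted genes is more homogeneous
than real tumor methylation. Passing tests therefore demonstrate that the
pipeline recovers planted structure of realistic strength at realistic
sample sizes and stays null where the model is null — not that any
particular real-data estimate is correct.

## Numerical choices

* Candidate membership uses strict inequality (ρ > cutoff); ties at the
  cutoff are out. Significance never gates membership.
* Cutoff calibration searches the midpoint grid between consecutive
  distinct rho values (plus one point below the minimum and the maximum
  itself) and returns the smallest feasible value; an all-tied screen
  returns the common value with a warning (zero genes strictly exceed it).
* Bonferroni family size is the retained-row count of that screen, per
  marker — not 2× the gene count — and is recorded in every run summary.
* Clustering sorts genes lexicographically before computing the linkage, so
  merge-distance ties resolve by gene name and the leaf order is invariant
  to input row and sample order.
* Missing values are handled pairwise; missing binary methylation calls
  contribute 0 to the methylation score (conservative under-count, logged);
  genes with < 10 complete pairs are excluded from screens and listed.
* Matrices are genes-as-rows; samples-as-rows input is rejected rather than
  auto-detected. Methylation outside [0, 1] or a non-numeric cell is a hard
  error with coordinates; duplicate gene or sample IDs are hard errors.
* Result TSVs serialize floats at full repr precision; re-reading with a
  round-trip float parser reproduces them bit-exactly.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the three study-shaped cohorts (up to 278 samples × ~190 matrix rows), a
5 000-sample cohort for the null contrasts, and Monte-Carlo oracles of up
to 10⁶ draws for population-correlation checks. The whole suite completes
in well under a minute on one core.

## Known limitations

* The bundled 179-gene catalog is a literature-derived reconstruction and
  is explicitly replaceable input; pathway group sizes other than the
  19-gene homologous-recombination group may differ from any particular
  published list.
* The headline enrichment test reproduces the published
  select-the-max-group-then-test procedure; its p-value is anti-conservative
  under selection (use `adjust_over_groups` for honest inference).
* Probe-level methylation selection (which CpG represents a gene) is
  upstream of this package and not modeled.
* No survival, treatment-response, purity-adjusted, or partial-correlation
  analyses.
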