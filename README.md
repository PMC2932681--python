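# lfcna — latent-factor dissection of stress signatures and CNA discovery

`lfcna` implements an integrative pipeline for a recurring question in cancer
genomics: *in-vitro* stress gene signatures (hypoxia, lactic acidosis)
project poorly onto tumors as monolithic gene sets — what drives their
variation *in vivo*?  The pipeline dissects a signature into sparse latent
factors ("sub-signatures") learned from tumor expression, projects those
factors across cohorts, and asks whether each factor's variation is explained
by DNA copy-number alterations (CNAs) — either in *cis* (the factor's genes
sit inside the altered segment, a gene-dosage effect) or in *trans* (the
factor's genes are scattered but its activity tracks a distant segment).

It is aimed at computational biologists who have gene-by-sample
log-expression matrices, a gene annotation, and (for the association stage)
array-CGH clone measurements on the same samples.  All heavy lifting is pure
Python (numpy/scipy/pandas); a `lfcna` command-line tool wraps the library.

## The models

**Sparse signature regression.** For a designed experiment with known design
matrix `H` (r design vectors × n samples), expression is modeled per gene as

    X = B H + μ 1' + ε,   ε_gi ~ N(0, ψ_g)

with a point-mass mixture ("spike and slab") prior on each coefficient,
`β_gj ~ (1−π_j)·δ₀ + π_j·N(0, τ²)`, a low-mean Beta prior on each π_j, and
conjugate priors on μ and ψ.  A Gibbs sampler yields posterior inclusion
probabilities; signature genes are those exceeding a probability threshold
(default .99).

**Sparse latent factor model.** On tumor expression restricted to signature
genes, `X = A Λ + ε` with the same sparsity prior on the loadings A, standard
normal factor scores Λ, and gene-wise noise variances V.  Each factor j
carries per-gene posterior inclusion probabilities π*_gj.

**Projection (inverse regression).** Factors fitted in one cohort are scored
on a new cohort Y through the shrinkage estimator

    Λ_y = (I_k + A' V⁻¹ A)⁻¹ A' V⁻¹ Y

(the posterior mean under the standard-normal score prior); the same formula
with B in place of A scores signatures.

**Local enrichment ratio (LER).** For one factor, the spatial concentration
of its genes along the genome is

    LER(t) = [ Σ_g π*_g κ_g(t) / M ] / [ Σ_g κ_g(t) / M₀ ]

where κ_g is a discretized normal kernel at the gene's start position
(sd = 5% of the chromosome length by default, truncated and renormalized per
chromosome) and M = Σπ*, M₀ = p normalize both smoothed densities.
Genome-wide significance of the max LER is calibrated by permuting the π*
values over gene positions.

**CNA association and cis/trans calls.** Projected factor scores are
Pearson-correlated with every CGH clone; Bonferroni across the clone panel,
and a factor counts as CNA-associated only when significant in *both* of two
independent cohorts.  A selected factor is *cis* when its LER peak is
permutation-significant and co-localizes with the top clone, *trans* when
clone association exists without spatial enrichment.

**Coexpression conservation.** For a gene list measured in two cohorts, each
cohort's genes are summarized by their correlation ρ with the first principal
component (sign fixed so most ρ are positive); Kendall's τ between the two ρ
vectors, with an exact small-n p-value, quantifies how well coexpression
structure transfers.

## Worked example

The bundled demo simulates a full study with known ground truth — 1500 genes
on human-proportioned chromosomes, a 120-tumor cohort paired with an
80-sample cohort, a 400-clone CGH panel, and five planted factors (two cis,
one trans, two neutral) — then runs every stage:

```bash
lfcna run --config configs/demo.yaml --out results/demo
```

The run takes a few seconds and ends with a JSON report
(`results/demo/report.json`).  With the bundled seed it prints, per fitted
factor:

| factor  | planted mode | selected | call  | max LER | LER threshold |
|---------|--------------|----------|-------|---------|---------------|
| factor1 | neutral      | no       | none  | 12.9    | 25.1          |
| factor2 | neutral      | no       | none  | 9.2     | 27.8          |
| factor3 | cis          | yes      | cis   | 51.8    | 25.1          |
| factor4 | trans        | yes      | trans | 9.4     | 30.5          |
| factor5 | cis          | yes      | cis   | 62.2    | 30.1          |

i.e. all three planted CNA-driven factors are selected (significant clone
association in both cohorts), both dosage factors are labelled cis (their
gene membership is spatially enriched at the planted segment far above the
permutation threshold), the trans factor shows clone association without
spatial enrichment, and the neutral factors are left alone — precision,
recall and label accuracy all 1.0 in the report.  The report also shows the
signature stage (36 of 59 planted response genes recovered at the .99
posterior bar with zero false positives in a 3 × 12-sample experiment) and
per-factor cross-cohort conservation (Kendall τ between 0.72 and 0.83, all
p < 5 × 10⁻⁶).

The equivalent library calls are `simulate_factor_cohort` /
`simulate_paired_cohorts`, `fit_factor_model`, `project_factors`,
`scan_factors`, `correlate_scores_with_clones`, `select_cna_factors` and
`conservation_between`; see `docs/methods.md` for the statistical details
and `lfcna --help` for the other subcommands (`fit-signature`,
`fit-factors`, `project`, `ler`, `associate`, `conserve`).

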