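# Methods

This note documents the statistical models, numerical choices and synthetic
study conditions behind `lfcna`, at the level of detail a user needs to judge
what the package's results do and do not show.

## Sparse design regression

For a designed experiment with `p` genes, `n` samples and `r` known design
vectors (rows of `H`), expression is modeled gene by gene as

    x_gi = mu_g + sum_j beta_gj h_ji + eps_gi,   eps_gi ~ N(0, psi_g).

Priors: `beta_gj ~ (1 - pi_j) delta_0 + pi_j N(0, tau^2)` with slab variance
`tau^2 = 1` (appropriate for data on a log-expression scale of order one;
configurable); `pi_j ~ Beta(1, 199)` (mean .005 — few genes respond to any
one design vector); `psi_g ~ InvGamma(2, 1)`; `mu_g ~ N(0, 100^2)`.

A Gibbs sampler alternates the conjugate updates (coefficients by factor-wise
spike/slab draw, intercepts, noise variances, inclusion rates).  Defaults:
5000 sweeps, 1000 burn-in, no thinning, all draws seeded.  Posterior
summaries for coefficients and inclusion probabilities are Rao-Blackwellized
— the conditional inclusion probability and conditional mean are averaged
over sweeps rather than the binary indicator draws — which reduces Monte
Carlo noise by an order of magnitude at no cost.

Two behaviors worth knowing:

* A planted gene whose *realized* group difference is shrunk by noise (an
  observed z around 3 instead of the design's 6) will correctly sit below a
  .99 posterior inclusion bar; recovery tests therefore distinguish genes by
  their realized effects.  For borderline genes the include/exclude states
  are self-reinforcing through the noise-variance update (excluding the gene
  inflates `psi_g`, further weakening the inclusion odds), so their
  inclusion probabilities mix slowly; this is a property of the model, not
  of the implementation.
* The inverse-gamma noise prior has a scale floor near `b/(a + n/2)`;
  signals far below that scale are absorbed as noise.  The default prior
  expects data of order-one variance.

Signature support for projection is the set of genes with posterior
inclusion probability above 1/2 (the Rao-Blackwellized coefficient means are
never exactly zero, so the point-mass posterior, not the mean, defines
membership).

## Sparse latent factor model

On gene-centered expression, `X = A L + eps`, with the same point-mass
mixture prior on each loading column (one inclusion rate per factor),
independent standard-normal priors on the scores, and inverse-gamma noise
variances.  The Gibbs sweep is: joint per-sample score update
`L_i ~ N((I + A'Psi^-1 A)^-1 A'Psi^-1 x_i, (I + A'Psi^-1 A)^-1)`, factor-wise
spike/slab loading updates, noise-variance updates, inclusion-rate updates.
Defaults: 2000 sweeps, 500 burn-in.

**Initialization.** Loadings start at the top-k principal directions rotated
by varimax, scores at the corresponding projections.  The rotation matters:
when several factors explain comparable variance the principal subspace is
rotation-ambiguous, and a chain started at an arbitrary rotation can settle
permanently into a mixed mode (observed as stable ~0.7 score correlations
with the planted factors).  Starting at the sparsest orthogonal orientation
lets the mixture prior lock onto the factor axes; planted-factor score
correlations then exceed 0.98.

**Conventions.** Factors are ordered by decreasing explained variance and
signed so the largest-magnitude loading is positive.  Factors explaining
less than 0.5% of total variance are pruned (configurable; set 0 to
disable).  `k` is user-fixed — there is no model-size search — and label
alignment across fits is done at comparison time by maximum-|correlation|
assignment (Hungarian algorithm).

A split-chain diagnostic (first- vs second-half score correlation < 0.5)
flags non-convergence in the fit metadata with a warning.

## Factor projection

Scores on a new cohort `Y` (gene-centered with the target's own means by
default; the training means are available as an option) are the posterior
mean under the standard-normal score prior:

    L_y = (I_k + A' V^-1 A)^-1 A' V^-1 Y.

The identity block makes the system strictly well conditioned (conditioning
is asserted), shrinks toward zero for weak data, and approaches generalized
least squares as loadings grow; a `ridge_scale` parameter exposes the
flat-prior limit for testing only.  Gene matching is by identifier; with
`missing_gene_policy="drop"` unmatched rows of `A` and `V` are removed, and
fewer than 50% matched genes is an error.

## Local enrichment ratio

For one factor with per-gene posterior inclusion probabilities `pi*` and
gene start positions `x_g`,

    LER(t) = [ sum_g pi*_g k_g(t) / M ] / [ sum_g k_g(t) / M0 ],
    M = sum_g pi*_g,   M0 = p,

where `k_g` is a normal kernel centered at `x_g` with standard deviation
equal to `kernel_fraction` (default 0.05) times the length of the gene's
chromosome, discretized on a per-chromosome evaluation grid (default 200
evenly spaced cell centers), truncated at the chromosome edges and
renormalized to sum to one.  Genes are treated as points at their start
coordinate — CNAs span regions orders of magnitude longer than a gene.  With
these normalizations a flat `pi*` gives LER = 1 everywhere, and LER is
invariant to rescaling `pi*`.

**Permutation null.** Genome-wide significance of the maximum LER is
calibrated by shuffling the `pi*` values over gene positions (jointly,
genome-wide) and recording the genome max per permutation; thresholds are
empirical quantiles of those maxima.

**Support masking and the behavior of the null.** A density *ratio* is
meaningful only where the background density estimate has support.  At grid
points far from any gene ("deserts"), the ratio degenerates to the `pi*` of
whichever single gene is nearest, so for a spiky `pi*` vector the null
maximum saturates at its ceiling `p / sum(pi*)` — tens to fifties —
regardless of any spatial structure.  Real gene annotations are densely
clustered at the 5%-of-chromosome scale and largely avoid this regime, but
sparse synthetic annotations do not.  `scan_factors` therefore restricts
both the observed and the null maxima to *supported* grid points, those with
background kernel density at least 20% of the genome-wide mean density
(`support_fraction`, configurable); `compute_ler` itself evaluates the bare
formula everywhere the denominator is positive.  The mask is applied
identically to observed and permuted profiles, so the calibration remains
exact by construction.

Two empirical consequences on synthetic genomes, measured with this package
and worth stating because they differ from intuition: (i) with a spiky
factor-like `pi*` (a few dozen genes near 1, the rest near 0) the
permutation-null genome maximum on a uniformly annotated genome is far above
3 at every kernel width tested, and (ii) the extreme null quantiles
*decrease* as the kernel widens, because narrow kernels make single permuted
genes locally dominant.  Calibrated per-factor thresholds — not fixed
cutoffs — are therefore the only defensible significance rule on such
annotations, and that is what `scan_factors` uses (default `alpha = 1e-4`
on the factor's own permutation distribution).

## Clone association and cis/trans classification

Projected factor (or signature) scores are Pearson-correlated against every
CGH clone; two-sided p-values use the t distribution with n-2 degrees of
freedom on pairwise-complete samples.  Clones with more than 20% missing
values or fewer than 10 complete pairs are dropped; zero-variance pairs are
flagged degenerate with p = 1.  Bonferroni correction uses the retained
clone count (overridable to mirror a fixed historical panel size).

A factor is **selected** as CNA-associated when its minimum clone p-value
survives Bonferroni at `alpha = .01` in *both* of two independent cohorts —
the dual-cohort rule suppresses cohort-specific artifacts.  Selected factors
are then labelled:

* **cis** — the factor's LER genome max exceeds its permutation threshold
  *and* the most significant clone lies within a colocalization window
  (default 2 kernel standard deviations on that chromosome) of the
  super-threshold LER region.  The whole significant region is used rather
  than the argmax point because the argmax of a density ratio drifts toward
  the low-density flank of a gene cluster.
* **trans** — clone association without LER significance.
* **none** — no Bonferroni-significant clone.

## Coexpression conservation

For a fixed gene list in one cohort, compute the first principal component
`u1` of the gene-centered submatrix, let `rho_j = corr(u1, gene j)`, and
flip the sign of `u1` so that more genes have positive than negative `rho`
(ties broken toward positive total).  Conservation between two cohorts is
Kendall's tau-b between their `rho` vectors — a rank statistic, invariant to
any monotone transform of either summary — with an exact two-sided p-value
for 10 or fewer genes and the normal approximation otherwise.  Exact ties in
`rho` are broken by stable gene order before ranking.

## Synthetic study conditions

The generators plant complete ground truth and are pure functions of their
seeds.

* **Annotation.** Genes are assigned to 23 human-proportioned chromosomes
  (1-22 + X, GRCh37 lengths) with probability proportional to length;
  positions are uniform at `clustering = 0` or drawn around Gaussian density
  peaks (default 4 per chromosome, sd 1.5% of the chromosome) for the
  clustered fraction.  End-to-end studies use `clustering = 1.0` so that no
  gene is spatially isolated — the property of real annotations that keeps
  the LER null informative (see above) — with explicit double-weight peaks
  at the planted amplicons, since amplified segments of interest are
  gene-dense in practice.
* **Copy number.** Each planted segment gets a per-sample latent level:
  amplified in a 30% subset of samples at `N(1.5, 0.3)`, zero otherwise —
  subset amplification as seen in tumor cohorts.  Clones inside a segment
  report the latent plus `N(0, 0.2)` noise; other clones pure noise.  The
  default panel spaces 400-500 clones evenly along the genome; panel spacing
  must be finer than the segment width for a segment to be discoverable.
* **Factors.**  Cis factors load *all* genes inside their segment (a
  segmental dosage effect touches every expressed gene there); trans and
  neutral factors load 25 scattered genes.  Loading magnitudes are
  `loading_scale x Uniform(0.5, 1.5)`, positive.  Cis/trans scores equal the
  segment latent plus `N(0, 0.2)`; neutral scores are standard normal.
  Gene noise sds are log-normal around the configured median (spread 0.25)
  to emulate heteroskedastic arrays.  Default geometry anchors to recurrent
  breast-cancer loci: cis segments chr8:2-12 Mb (8p-like) and chr17:35-45 Mb
  (17q21-like), a trans driver at chr12:65-75 Mb (12q14-15-like).
* **Cohort sizes.**  The standard paired study uses 250 samples (discovery)
  and 120 (validation), 3000 candidate genes, 500 clones; the designed
  experiment uses 2-3 groups with an affected fraction of 0.1 and additive
  effects of 2 noise sds.

What the generator does **not** emulate: probe-level artifacts,
normalization and batch effects, correlated (non-diagonal) noise, overlapping
factor memberships, allele-specific or deletion-biased copy number, and
missing expression values.  Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to real-array pathologies.

## Problem sizes and runtime choices

Test and acceptance runs use sizes chosen to exercise the full pipeline at
realistic dimensionality while completing on a single CPU in minutes: factor
fits at 3000 x 250 with 600-1200 Gibbs sweeps (posterior summaries are
stable well before that under the varimax-anchored initialization; doubling
sweeps changes posterior means by < 0.02 RMS), LER calibrations with
1500-10000 permutations batched through a precomputed kernel matrix, and 5-10
replicate seeds for end-to-end precision/recall.  The permutation batch size
(500) only controls memory.

## Known limitations

* The factor count `k` must be supplied; the pruning rule removes clearly
  empty factors but will not discover structure beyond `k`.
* Gibbs inclusion probabilities for borderline genes mix slowly (bistable
  include/exclude states); very long chains or tempering would be needed to
  resolve genes sitting exactly at the decision boundary.
* The LER is a scan statistic over a fixed grid; segments much narrower than
  the kernel (or the grid spacing) are smoothed away, and on sparsely
  annotated genomes its null distribution is dominated by low-density
  regions unless support masking is applied.
* Cis/trans classification inherits the resolution of both the LER (kernel
  sd) and the clone panel (spacing); a trans driver inside a gene-dense
  region of the factor's own members would be labelled cis.
* Conservation testing assumes the gene list's coexpression is approximately
  rank-one per cohort; multi-factor lists dilute `rho` and lower tau.
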