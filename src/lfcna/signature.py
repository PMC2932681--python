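"""Sparse Bayesian regression of expression on a known design.

Model, per gene g and sample i:

    x_{g,i} = mu_g + sum_j beta_{g,j} h_{j,i} + eps_{g,i},   eps ~ N(0, psi_g)

with a point-mass mixture ("spike and slab") prior on each coefficient,

    beta_{g,j} ~ (1 - pi_j) * delta_0 + pi_j * N(0, tau^2),

a low-mean Beta prior on the inclusion rate pi_j of each design vector, an
inverse-gamma prior on the gene noise variances and a diffuse normal prior on
the intercepts.  A Gibbs sampler alternates conjugate updates; posterior
summaries for coefficients and inclusion probabilities are Rao-Blackwellized
(conditional means/probabilities averaged over sweeps), which converges much
faster than averaging raw draws and makes degenerate checks exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import DesignMatrix, ExpressionMatrix

__all__ = [
    "PriorSpec",
    "McmcSpec",
    "SignatureModel",
    "fit_sparse_regression",
    "select_signature_genes",
    "project_signature",
]


@dataclass
class PriorSpec:
    """Hyperparameters of the sparse-regression prior.

    slab_var: variance tau^2 of the nonzero-coefficient (slab) component.
    pi_a, pi_b: Beta prior on the inclusion rate; Beta(1, 199) has mean .005,
        encoding that few genes respond to any given design vector.
    noise_a, noise_b: inverse-gamma prior on gene noise variances.
    intercept_sd: sd of the (near-flat) normal prior on intercepts.
    always_include: replace the mixture with the slab alone (Bayesian ridge);
        used for conjugacy cross-checks, not for analysis.
    fixed_noise_var: if set, noise variances are held at this value.
    """

    slab_var: float = 1.0
    pi_a: float = 1.0
    pi_b: float = 199.0
    noise_a: float = 2.0
    noise_b: float = 1.0
    intercept_sd: float = 100.0
    always_include: bool = False
    fixed_noise_var: Optional[float] = None


@dataclass
class McmcSpec:
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("mcmc iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class SignatureModel:
    """Posterior summaries of the sparse regression fit."""

    coefficients: np.ndarray      # p x r posterior-mean beta
    inclusion_prob: np.ndarray    # p x r P(beta != 0 | data)
    intercepts: np.ndarray        # p
    noise_var: np.ndarray         # p
    gene_ids: list
    vector_names: list
    prior_spec: PriorSpec
    mcmc_meta: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.coefficients.shape[1]


def _spike_slab_row_update(R, h, psi, slab_var, pi, rng, always_include):
    """One sweep of the mixture update for all genes against one design row.

    R: p x n residual matrix *excluding* this row's contribution.
    Returns (beta draws, indicator draws, RB inclusion prob, RB coefficient mean).
    """
    hh = float(h @ h)
    prec = hh / psi + 1.0 / slab_var
    m = (R @ h) / psi / prec
    # log Bayes factor for inclusion vs exclusion
    log_bf = 0.5 * (np.log(1.0 / slab_var) - np.log(prec)) + 0.5 * prec * m * m
    if always_include:
        p_inc = np.ones_like(m)
    else:
        logit = np.log(pi / (1.0 - pi)) + log_bf
        p_inc = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    z = rng.random(p_inc.shape) < p_inc
    draw = m + rng.standard_normal(m.shape) / np.sqrt(prec)
    beta = np.where(z, draw, 0.0)
    return beta, z, p_inc, p_inc * m


def fit_sparse_regression(
    X: ExpressionMatrix,
    H: DesignMatrix,
    prior_spec: Optional[PriorSpec] = None,
    mcmc_spec: Optional[McmcSpec] = None,
    seed: int = 0,
) -> SignatureModel:
    """Gibbs sampler for the sparse design regression; deterministic given seed."""
    prior = prior_spec or PriorSpec()
    mcmc = mcmc_spec or McmcSpec()
    if X.n_samples != H.values.shape[1]:
        raise ValueError(
            f"expression has {X.n_samples} samples but design has {H.values.shape[1]}"
        )
    Hv = H.values
    r, n = Hv.shape
    p = X.n_genes
    # duplicated design vectors make the fit ambiguous but not invalid
    if r > 1:
        for a in range(r):
            for b in range(a + 1, r):
                if np.allclose(Hv[a], Hv[b]):
                    warnings.warn(
                        f"design vectors {H.vector_names[a]!r} and "
                        f"{H.vector_names[b]!r} are identical; coefficients are "
                        "not separately identifiable",
                        stacklevel=2,
                    )

    rng = np.random.default_rng(seed)
    Xv = X.values

    beta = np.zeros((p, r))
    mu = Xv.mean(axis=1)
    psi = (
        np.full(p, prior.fixed_noise_var)
        if prior.fixed_noise_var is not None
        else np.maximum(Xv.var(axis=1), 1e-8)
    )
    pi = np.full(r, prior.pi_a / (prior.pi_a + prior.pi_b))

    acc_beta = np.zeros((p, r))
    acc_inc = np.zeros((p, r))
    acc_mu = np.zeros(p)
    acc_psi = np.zeros(p)
    kept = 0

    R = Xv - mu[:, None] - beta @ Hv
    for it in range(mcmc.n_iter):
        rb_beta = np.zeros((p, r))
        rb_inc = np.zeros((p, r))
        for j in range(r):
            R += np.outer(beta[:, j], Hv[j])
            b_j, z_j, p_j, rb_j = _spike_slab_row_update(
                R, Hv[j], psi, prior.slab_var, pi[j], rng, prior.always_include
            )
            beta[:, j] = b_j
            rb_inc[:, j] = p_j
            rb_beta[:, j] = rb_j
            R -= np.outer(beta[:, j], Hv[j])
            if not prior.always_include:
                n_in = int(z_j.sum())
                pi[j] = rng.beta(prior.pi_a + n_in, prior.pi_b + p - n_in)

        # intercept
        R += mu[:, None]
        prec_mu = n / psi + 1.0 / prior.intercept_sd**2
        mean_mu = R.sum(axis=1) / psi / prec_mu
        mu = mean_mu + rng.standard_normal(p) / np.sqrt(prec_mu)
        R -= mu[:, None]

        # noise variances
        if prior.fixed_noise_var is None:
            a_post = prior.noise_a + 0.5 * n
            b_post = prior.noise_b + 0.5 * (R * R).sum(axis=1)
            psi = b_post / rng.gamma(a_post, 1.0, size=p)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            kept += 1
            acc_beta += rb_beta
            acc_inc += rb_inc
            acc_mu += mean_mu
            if prior.fixed_noise_var is None:
                acc_psi += b_post / (a_post - 1.0)
            else:
                acc_psi += psi

    return SignatureModel(
        coefficients=acc_beta / kept,
        inclusion_prob=acc_inc / kept,
        intercepts=acc_mu / kept,
        noise_var=acc_psi / kept,
        gene_ids=list(X.gene_ids),
        vector_names=list(H.vector_names),
        prior_spec=prior,
        mcmc_meta={
            "n_iter": mcmc.n_iter,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
            "seed": seed,
            "kept": kept,
        },
    )


def select_signature_genes(
    model: SignatureModel,
    threshold: float = 0.99,
    design_columns: Optional[Sequence] = None,
) -> list:
    """Genes whose max inclusion probability over the chosen columns exceeds threshold."""
    if not 0.0 <= threshold < 1.0 and threshold != 0.0:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
    if design_columns is None:
        cols = list(range(model.n_vectors))
    else:
        design_columns = list(design_columns)
        if not design_columns:
            raise ValueError("empty design column subset")
        name_idx = {v: i for i, v in enumerate(model.vector_names)}
        cols = [c if isinstance(c, int) else name_idx[c] for c in design_columns]
    best = model.inclusion_prob[:, cols].max(axis=1)
    return [g for g, b in zip(model.gene_ids, best) if b > threshold]


def project_signature(
    model: SignatureModel,
    Y: ExpressionMatrix,
    missing_gene_policy: str = "error",
    max_missing_fraction: float = 0.05,
) -> np.ndarray:
    """Per-sample signature scores on a new cohort via the shrinkage estimator.

    Uses the inverse-regression posterior mean with the coefficient matrix B in
    the role of the loadings:  scores = (I_r + B' V^-1 B)^-1 B' V^-1 Y_c,
    restricted to signature genes present in ``Y``.  A gene is part of the
    signature support when its posterior inclusion probability exceeds 1/2
    (the Rao-Blackwellized coefficient means are never exactly zero, so the
    point-mass posterior, not the mean, defines the support).  Returns an
    r x m array, one score row per design vector.
    """
    from .projection import _inverse_regression  # local import; shared estimator

    sig_mask = (model.inclusion_prob > 0.5).any(axis=1)
    sig_genes = [g for g, s in zip(model.gene_ids, sig_mask) if s]
    present = set(Y.gene_ids)
    missing = [g for g in sig_genes if g not in present]
    if missing:
        frac = len(missing) / max(len(sig_genes), 1)
        if missing_gene_policy == "error" or frac > max_missing_fraction:
            raise KeyError(
                f"{len(missing)} of {len(sig_genes)} signature genes missing "
                f"from target: {missing[:10]}"
            )
    used = [g for g in sig_genes if g in present]
    rows = [model.gene_ids.index(g) for g in used]
    B = model.coefficients[rows]
    V = model.noise_var[rows]
    Ysub = Y.subset_genes(used)
    Yc = Ysub.values - Ysub.values.mean(axis=1, keepdims=True)
    return _inverse_regression(B, V, Yc)
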