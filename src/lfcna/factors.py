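"""Sparse Bayesian latent factor model X = A L + eps on gene-centered data.

The loadings matrix A carries the same point-mass mixture prior as the sparse
regression coefficients (one inclusion rate per factor), factor scores get
independent standard-normal priors, and gene noise variances get inverse-gamma
priors.  The Gibbs sampler alternates:

  (a) per-gene sparse loading updates under the mixture prior,
  (b) joint per-sample score updates, L_i ~ N((I + A'Psi^-1 A)^-1 A'Psi^-1 x_i, ...),
  (c) conjugate noise-variance updates,
  (d) Beta updates of the per-factor inclusion rates.

Loadings are initialized from the top-k principal directions and scores from
their projections, which anchors factor labels and avoids most label
switching; remaining sign/order ambiguity is resolved post hoc (largest
absolute loading positive, factors sorted by explained variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy.optimize import linear_sum_assignment

from .containers import ExpressionMatrix
from .signature import McmcSpec, PriorSpec, _spike_slab_row_update

__all__ = [
    "FactorModel",
    "fit_factor_model",
    "factor_gene_lists",
    "align_factors",
]


@dataclass
class FactorModel:
    """Posterior summaries of the sparse latent factor fit."""

    loadings: np.ndarray        # p x k posterior-mean A
    scores: np.ndarray          # k x n posterior-mean factor scores
    inclusion_prob: np.ndarray  # p x k posterior inclusion probabilities
    noise_var: np.ndarray       # p, diagonal of V
    gene_ids: list
    sample_ids: list
    gene_means: np.ndarray      # centering offsets removed before the fit
    prior_spec: PriorSpec = field(default_factory=PriorSpec)
    mcmc_meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def factor_ids(self) -> list:
        return [f"factor{j + 1}" for j in range(self.k)]


def _varimax(A: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal rotation maximizing the varimax criterion; returns R."""
    p, k = A.shape
    R = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        L = A @ R
        U, s, Vt = np.linalg.svd(
            A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        R = U @ Vt
        new = s.sum()
        if new <= obj * (1 + tol):
            break
        obj = new
    return R

def _pca_init(Xc: np.ndarray, k: int):
    """Varimax-rotated top-k principal directions/projections of the data.

    The principal subspace is rotation-ambiguous when factor strengths are
    comparable; starting at the varimax (sparsest) orientation keeps the
    sampler from settling into a rotated mixture of the true factors.
    """
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = Xc.shape[1]
    A0 = U[:, :k] * (s[:k] / np.sqrt(n))
    L0 = np.sqrt(n) * Vt[:k]
    if k > 1:
        R = _varimax(A0)
        A0 = A0 @ R
        L0 = R.T @ L0
    return A0, L0


def fit_factor_model(
    X: ExpressionMatrix,
    k: int,
    prior_spec: Optional[PriorSpec] = None,
    mcmc_spec: Optional[McmcSpec] = None,
    seed: int = 0,
    prune_ev_share: float = 0.005,
) -> FactorModel:
    """Fit the sparse factor model with ``k`` factors; deterministic given seed.

    Factors whose explained-variance share falls below ``prune_ev_share`` are
    dropped from the returned model (set to 0 to disable).  The number of
    factors is otherwise user-fixed; no search over k is attempted.
    """
    prior = prior_spec or PriorSpec()
    mcmc = mcmc_spec or McmcSpec(n_iter=2000, burn_in=500)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= X.n_samples:
        raise ValueError(f"k={k} must be smaller than the sample count {X.n_samples}")

    rng = np.random.default_rng(seed)
    p, n = X.values.shape
    gene_means = X.values.mean(axis=1)
    Xc = X.values - gene_means[:, None]

    A, Lam = _pca_init(Xc, k)
    psi = (
        np.full(p, prior.fixed_noise_var)
        if prior.fixed_noise_var is not None
        else np.maximum((Xc - A @ Lam).var(axis=1), 1e-6)
    )
    pi = np.full(k, prior.pi_a / (prior.pi_a + prior.pi_b))

    acc_A = np.zeros((p, k))
    acc_inc = np.zeros((p, k))
    acc_scores = np.zeros((k, n))
    acc_psi = np.zeros(p)
    kept = 0
    half = None  # split-chain score means for the convergence heuristic
    half_kept = [0, 0]
    half_acc = [np.zeros((k, n)), np.zeros((k, n))]

    for it in range(mcmc.n_iter):
        # (b) scores: joint conditional across factors, shared across samples
        AtVi = (A / psi[:, None]).T            # k x p
        G = np.eye(k) + AtVi @ A               # I + A'Psi^-1 A
        cho = sla.cho_factor(G, lower=True)
        mean_L = sla.cho_solve(cho, AtVi @ Xc)  # k x n
        Lfac = np.linalg.cholesky(sla.cho_solve(cho, np.eye(k)))
        Lam = mean_L + Lfac @ rng.standard_normal((k, n))

        # (a) loadings: spike-slab per factor, vectorized over genes
        rb_inc = np.zeros((p, k))
        rb_A = np.zeros((p, k))
        R = Xc - A @ Lam
        for j in range(k):
            R += np.outer(A[:, j], Lam[j])
            a_j, z_j, p_j, rb_j = _spike_slab_row_update(
                R, Lam[j], psi, prior.slab_var, pi[j], rng, prior.always_include
            )
            A[:, j] = a_j
            rb_inc[:, j] = p_j
            rb_A[:, j] = rb_j
            R -= np.outer(A[:, j], Lam[j])
            if not prior.always_include:
                n_in = int(z_j.sum())
                pi[j] = rng.beta(prior.pi_a + n_in, prior.pi_b + p - n_in)

        # (c) noise variances
        if prior.fixed_noise_var is None:
            a_post = prior.noise_a + 0.5 * n
            b_post = prior.noise_b + 0.5 * (R * R).sum(axis=1)
            psi = b_post / rng.gamma(a_post, 1.0, size=p)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            kept += 1
            acc_A += rb_A
            acc_inc += rb_inc
            acc_scores += mean_L
            if prior.fixed_noise_var is None:
                acc_psi += b_post / (a_post - 1.0)
            else:
                acc_psi += psi
            h = 0 if (it - mcmc.burn_in) < (mcmc.n_iter - mcmc.burn_in) / 2 else 1
            half_acc[h] += mean_L
            half_kept[h] += 1

    A_mean = acc_A / kept
    inc_mean = acc_inc / kept
    scores_mean = acc_scores / kept
    psi_mean = acc_psi / kept

    meta = {
        "n_iter": mcmc.n_iter,
        "burn_in": mcmc.burn_in,
        "thin": mcmc.thin,
        "seed": seed,
        "kept": kept,
        "k_requested": k,
    }
    # convergence heuristic: first- vs second-half score agreement
    if min(half_kept) > 0:
        h0 = half_acc[0] / half_kept[0]
        h1 = half_acc[1] / half_kept[1]
        corrs = [
            abs(np.corrcoef(h0[j], h1[j])[0, 1]) if h0[j].std() > 0 and h1[j].std() > 0 else 0.0
            for j in range(k)
        ]
        meta["split_chain_score_corr"] = [float(c) for c in corrs]
        if min(corrs) < 0.5:
            import warnings

            warnings.warn(
                "split-chain score correlation < 0.5 for at least one factor; "
                "the chain may not have converged",
                stacklevel=2,
            )
            meta["converged"] = False
        else:
            meta["converged"] = True

    # explained variance per factor, then prune / order / sign conventions
    ev = np.array(
        [float((A_mean[:, j] ** 2).sum() * scores_mean[j].var()) for j in range(k)]
    )
    total_var = float(Xc.var(axis=1).sum())
    keep = np.arange(k)
    if prune_ev_share > 0 and total_var > 0:
        keep = np.where(ev / total_var >= prune_ev_share)[0]
        if len(keep) == 0:
            keep = np.array([int(np.argmax(ev))])
    order = keep[np.argsort(-ev[keep])]
    A_mean = A_mean[:, order]
    inc_mean = inc_mean[:, order]
    scores_mean = scores_mean[order]
    meta["explained_variance"] = [float(e) for e in ev[order]]
    meta["k"] = len(order)

    for j in range(A_mean.shape[1]):
        g = int(np.argmax(np.abs(A_mean[:, j])))
        if A_mean[g, j] < 0:
            A_mean[:, j] *= -1
            scores_mean[j] *= -1

    return FactorModel(
        loadings=A_mean,
        scores=scores_mean,
        inclusion_prob=inc_mean,
        noise_var=psi_mean,
        gene_ids=list(X.gene_ids),
        sample_ids=list(X.sample_ids),
        gene_means=gene_means,
        prior_spec=prior,
        mcmc_meta=meta,
    )


def factor_gene_lists(model: FactorModel, membership_threshold: float = 0.95) -> dict:
    """Per-factor gene lists: gene g belongs to factor j iff pi*_{g,j} > threshold."""
    if not 0.0 < membership_threshold <= 1.0:
        raise ValueError("membership threshold must be in (0, 1]")
    out = {}
    for j, fid in enumerate(model.factor_ids):
        mask = model.inclusion_prob[:, j] > membership_threshold
        out[fid] = [g for g, m in zip(model.gene_ids, mask) if m]
    return out


def align_factors(est_scores: np.ndarray, true_scores: np.ndarray):
    """Match estimated factors to reference factors by maximal |score correlation|.

    Returns ``(perm, signs, corrs)`` where ``perm[j]`` is the estimated factor
    assigned to reference factor j, ``signs[j]`` the sign making the
    correlation positive, and ``corrs[j]`` the |correlation| achieved.
    Handles unequal factor counts by matching up to min(k_est, k_true).
    """
    est = np.atleast_2d(est_scores)
    true = np.atleast_2d(true_scores)
    ke, kt = est.shape[0], true.shape[0]
    C = np.zeros((kt, ke))
    for a in range(kt):
        for b in range(ke):
            if true[a].std() == 0 or est[b].std() == 0:
                C[a, b] = 0.0
            else:
                C[a, b] = np.corrcoef(true[a], est[b])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.full(kt, -1, dtype=int)
    signs = np.zeros(kt)
    corrs = np.zeros(kt)
    for a, b in zip(rows, cols):
        perm[a] = b
        signs[a] = 1.0 if C[a, b] >= 0 else -1.0
        corrs[a] = abs(C[a, b])
    return perm, signs, corrs
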