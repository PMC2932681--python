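"""Cross-cohort conservation of a gene set's coexpression pattern.

For a fixed gene list measured in two independent cohorts, each cohort is
summarized by the correlation rho_j of every gene with the cohort's first
principal component u1 (computed on the gene-centered submatrix).  The sign
of u1 is chosen so that more genes correlate positively than negatively
(|rho|+ > |rho|-), which makes the summary invariant to the arbitrary sign of
a principal component.  Conservation is then the Kendall rank correlation
between the two cohorts' rho vectors: coexpression structure carried by the
gene set is conserved exactly when the two cohorts order the genes the same
way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["ConservationResult", "pc_gene_ordering", "conservation_test"]


@dataclass
class ConservationResult:
    rho_a: np.ndarray
    rho_b: np.ndarray
    kendall: float
    p_value: float
    n_genes: int
    gene_ids: list


def pc_gene_ordering(X_subset: ExpressionMatrix):
    """First-principal-component gene correlations and sample ordering.

    Returns ``(rho, sample_order)`` where ``rho[j]`` is the Pearson
    correlation between u1 and gene row j, and ``sample_order`` sorts samples
    by decreasing u1.  Rows are centered before the principal component; the
    sign rule |rho|+ > |rho|- is applied (ties broken toward positive total
    correlation).
    """
    if X_subset.n_genes < 3 or X_subset.n_samples < 3:
        raise ValueError("need at least 3 genes and 3 samples")
    Xc = X_subset.values - X_subset.values.mean(axis=1, keepdims=True)
    if not Xc.any():
        raise ValueError("zero-variance submatrix")
    _U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] == 0:
        raise ValueError("zero-variance submatrix")
    u1 = Vt[0]

    sd_u = u1.std()
    sds = Xc.std(axis=1)
    if sd_u == 0 or (sds == 0).all():
        raise ValueError("zero-variance submatrix")
    # rows of Xc are centered already; center u1 for a proper Pearson r
    cov = Xc @ (u1 - u1.mean()) / X_subset.n_samples
    rho = np.divide(cov, sds * sd_u, out=np.zeros_like(cov), where=sds > 0)
    n_pos = int((rho > 0).sum())
    n_neg = int((rho < 0).sum())
    if n_pos < n_neg or (n_pos == n_neg and rho.sum() < 0):
        rho = -rho
        u1 = -u1
    order = np.argsort(-u1, kind="stable")
    return rho, order


def conservation_test(rho_a, rho_b):
    """Kendall rank correlation between two cohorts' rho vectors.

    Two-sided p-value: exact enumeration for n <= 10, normal approximation
    otherwise.  Tie-corrected tau-b is used; exact real-valued rho ties are
    vanishingly rare but determinism requires a rule.
    """
    rho_a = np.asarray(rho_a, dtype=float)
    rho_b = np.asarray(rho_b, dtype=float)
    if rho_a.shape != rho_b.shape or rho_a.ndim != 1:
        raise ValueError("rho vectors must be 1-d and of equal length")
    n = len(rho_a)
    if n < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(rho_a) == 0 or np.ptp(rho_b) == 0:
        raise ValueError("constant rho vector: ordering is undefined")
    method = "exact" if n <= 10 else "asymptotic"
    res = stats.kendalltau(rho_a, rho_b, method=method)
    return float(res.statistic), float(res.pvalue)


def conservation_between(
    cohort_a: ExpressionMatrix,
    cohort_b: ExpressionMatrix,
    gene_ids,
) -> ConservationResult:
    """Convenience wrapper: restrict both cohorts to a gene list and test."""
    gene_ids = list(gene_ids)
    sub_a = cohort_a.subset_genes(gene_ids)
    sub_b = cohort_b.subset_genes(gene_ids)
    rho_a, _ = pc_gene_ordering(sub_a)
    rho_b, _ = pc_gene_ordering(sub_b)
    tau, p = conservation_test(rho_a, rho_b)
    return ConservationResult(
        rho_a=rho_a, rho_b=rho_b, kendall=tau, p_value=p,
        n_genes=len(gene_ids), gene_ids=gene_ids,
    )
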