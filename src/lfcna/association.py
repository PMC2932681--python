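"""Factor/signature score association with array-CGH clone copy numbers.

Each factor's projected per-sample scores are Pearson-correlated against the
copy-number measurements of each clone; two-sided p-values come from the
t-distribution with n-2 degrees of freedom on pairwise-complete samples, and
multiplicity over the clone panel is controlled by Bonferroni correction.  A
factor is called a copy-number-associated factor when its most significant
clone survives Bonferroni in *both* of two independent cohorts; it is then
labelled *cis* when the factor's gene membership shows a significant local
enrichment (LER) peak co-localizing with the peak clone, and *trans* when the
clone association exists without any spatial enrichment of the member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CGHProfile
from .ler import LERNullCalibration, LERProfile
from .projection import ProjectedScores

__all__ = [
    "AssociationResult",
    "CisTransCall",
    "correlate_scores_with_clones",
    "signature_clone_association",
    "select_cna_factors",
    "classify_cis_trans",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Factor-by-clone Pearson correlations with Bonferroni-adjusted flags."""

    r: np.ndarray                # factors x clones
    p: np.ndarray                # two-sided p-values
    factor_ids: list
    clone_ids: list
    clone_chrom: np.ndarray
    clone_pos: np.ndarray
    bonferroni_alpha: float
    n_tests: int
    degenerate: np.ndarray = None  # True where a zero-variance pair forced p=1

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.p, dtype=bool)

    @property
    def neg_log_p(self) -> np.ndarray:
        return -np.log(self.p)

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.bonferroni_alpha / self.n_tests

    def min_p(self, factor) -> float:
        i = self.factor_ids.index(factor)
        return float(self.p[i].min())

    def peak_clone(self, factor):
        """(clone id, chrom, pos, r, p) of the most significant clone."""
        i = self.factor_ids.index(factor)
        j = int(np.argmin(self.p[i]))
        return (
            self.clone_ids[j],
            self.clone_chrom[j],
            float(self.clone_pos[j]),
            float(self.r[i, j]),
            float(self.p[i, j]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (factor, clone, chrom, pos, r, p, significant)."""
        rows = []
        sig = self.significant
        for i, f in enumerate(self.factor_ids):
            for j, c in enumerate(self.clone_ids):
                rows.append((f, c, self.clone_chrom[j], self.clone_pos[j],
                             self.r[i, j], self.p[i, j], bool(sig[i, j])))
        return pd.DataFrame(
            rows, columns=["factor", "clone", "chrom", "pos", "r", "p", "significant"]
        )


def _pearson_with_p(S: np.ndarray, C: np.ndarray):
    """Rowwise Pearson r and two-sided t-test p between score rows and clone rows.

    Handles NaNs in C pairwise-complete.  Zero-variance pairs get r=0, p=1 and
    a degenerate flag.
    """
    k, n = S.shape
    m = C.shape[0]
    r = np.zeros((k, m))
    p = np.ones((k, m))
    degen = np.zeros((k, m), dtype=bool)
    ncomp = np.full(m, n)

    if not np.isnan(C).any():
        Ssd = S.std(axis=1)
        Csd = C.std(axis=1)
        Zs = np.where(Ssd[:, None] > 0, (S - S.mean(axis=1, keepdims=True)), 0.0)
        Zc = np.where(Csd[:, None] > 0, (C - C.mean(axis=1, keepdims=True)), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = Zs @ Zc.T
            den = np.outer(np.sqrt((Zs * Zs).sum(axis=1)),
                           np.sqrt((Zc * Zc).sum(axis=1)))
            r = np.where(den > 0, num / den, 0.0)
        degen = den == 0
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(degen, 1.0, np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0))
        return r, p, degen, ncomp

    for j in range(m):
        ok = ~np.isnan(C[j])
        ncomp[j] = int(ok.sum())
        if ncomp[j] < 3:
            degen[:, j] = True
            continue
        c = C[j, ok]
        if c.std() == 0:
            degen[:, j] = True
            continue
        for i in range(k):
            s = S[i, ok]
            if s.std() == 0:
                degen[i, j] = True
                continue
            rr, pp = stats.pearsonr(s, c)
            r[i, j], p[i, j] = rr, max(pp, np.finfo(float).tiny)
    return r, p, degen, ncomp


def correlate_scores_with_clones(
    scores: ProjectedScores,
    cgh: CGHProfile,
    alpha: float = 0.05,
    n_tests_override: Optional[int] = None,
    max_missing_fraction: float = 0.2,
    min_complete_pairs: int = 10,
) -> AssociationResult:
    """Pearson-correlate every factor score against every clone's copy numbers.

    Clones with more than ``max_missing_fraction`` missing values, or fewer
    than ``min_complete_pairs`` complete pairs, are dropped (logged).
    Bonferroni uses the retained clone count unless ``n_tests_override`` is
    given (e.g. to mirror a fixed historical panel size).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if scores.sample_ids != cgh.sample_ids:
        shared = [s for s in scores.sample_ids if s in set(cgh.sample_ids)]
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared samples between scores and CGH")
        s_idx = [scores.sample_ids.index(s) for s in shared]
        c_idx = [cgh.sample_ids.index(s) for s in shared]
        S = scores.scores[:, s_idx]
        C = cgh.values[:, c_idx]
    else:
        S = scores.scores
        C = cgh.values
    if S.shape[1] < 3:
        raise ValueError("need at least 3 shared samples")

    miss = np.isnan(C).mean(axis=1)
    keep = miss <= max_missing_fraction
    complete = (~np.isnan(C)).sum(axis=1)
    keep &= complete >= min_complete_pairs
    if (~keep).any():
        logger.info("dropping %d clones with too many missing values", int((~keep).sum()))
    C = C[keep]
    clone_ids = [c for c, k in zip(cgh.clone_ids, keep) if k]
    clone_chrom = cgh.clone_chrom[keep]
    clone_pos = cgh.clone_pos[keep]

    r, p, degen, _ncomp = _pearson_with_p(S, C)
    n_tests = n_tests_override if n_tests_override is not None else len(clone_ids)
    return AssociationResult(
        r=r, p=p,
        factor_ids=list(scores.factor_ids),
        clone_ids=clone_ids,
        clone_chrom=clone_chrom,
        clone_pos=clone_pos,
        bonferroni_alpha=alpha,
        n_tests=int(n_tests),
        degenerate=degen,
    )


def signature_clone_association(
    signature_scores,
    cgh: CGHProfile,
    alpha: float = 0.05,
    sample_ids: Optional[list] = None,
    n_tests_override: Optional[int] = None,
) -> AssociationResult:
    """Clone association for one signature score vector (a single score row)."""
    v = np.atleast_2d(np.asarray(signature_scores, dtype=float))
    ps = ProjectedScores(
        scores=v,
        factor_ids=[f"signature{i + 1}" for i in range(v.shape[0])],
        sample_ids=list(sample_ids) if sample_ids is not None else list(cgh.sample_ids),
    )
    return correlate_scores_with_clones(ps, cgh, alpha=alpha,
                                        n_tests_override=n_tests_override)


@dataclass
class CisTransCall:
    """Cis/trans designation of one copy-number-associated factor."""

    factor_id: str
    call: str                      # "cis" | "trans" | "none"
    peak_clone: Optional[tuple] = None    # (id, chrom, pos, r, p)
    peak_region: Optional[tuple] = None   # (chrom, window start, window end)
    ler_peak: Optional[tuple] = None      # (chrom, pos) when LER significant
    ler_max: float = np.nan
    ler_threshold: float = np.nan


def classify_cis_trans(
    factor_id: str,
    assoc: AssociationResult,
    ler_profile: LERProfile,
    ler_calibration: LERNullCalibration,
    alpha_ler: float = 1e-4,
    colocalization_window: Optional[float] = None,
    chrom_lengths: Optional[dict] = None,
) -> CisTransCall:
    """Label one factor cis, trans or none.

    cis:   clone association significant, LER genome-max significant, and the
           most significant clone lies within ``colocalization_window`` base
           pairs of the significantly enriched region (grid points at or
           above the null threshold) on the same chromosome.
    trans: clone association significant but no significant LER peak.
    none:  no Bonferroni-significant clone.

    Colocalization is judged against the whole super-threshold region rather
    than the single argmax point: the argmax of a density ratio drifts toward
    the low-density flank of a gene cluster, while the enriched region is
    stable.  The default window is 2 kernel standard deviations on the peak
    chromosome, matching the LER's spatial resolution (requires
    ``chrom_lengths``; else pass the window explicitly).
    """
    i = assoc.factor_ids.index(factor_id)
    if not assoc.significant[i].any():
        return CisTransCall(factor_id=factor_id, call="none")
    peak = assoc.peak_clone(factor_id)
    _cid, c_chrom, c_pos, _r, _p = peak

    thr = ler_calibration.threshold_at(alpha_ler)
    mx = ler_profile.max_ler
    if not mx > thr:
        return CisTransCall(
            factor_id=factor_id, call="trans", peak_clone=peak,
            ler_max=mx, ler_threshold=thr,
        )
    l_chrom, l_pos = ler_profile.peak
    if colocalization_window is None:
        if chrom_lengths is None:
            raise ValueError(
                "provide colocalization_window or chrom_lengths for the default"
            )
        colocalization_window = 2.0 * ler_profile.kernel_fraction * chrom_lengths[l_chrom]
    # distance from the peak clone to the nearest super-threshold grid point
    # on the clone's chromosome
    g_chrom, g_pos = ler_profile.grid.concatenated()
    with np.errstate(invalid="ignore"):
        sig_here = (g_chrom == c_chrom) & (ler_profile.values >= thr)
    colocal = bool(sig_here.any()) and (
        np.abs(g_pos[sig_here] - c_pos).min() <= colocalization_window
    )
    call = "cis" if colocal else "trans"
    return CisTransCall(
        factor_id=factor_id,
        call=call,
        peak_clone=peak,
        peak_region=(c_chrom, c_pos - colocalization_window, c_pos + colocalization_window),
        ler_peak=(l_chrom, l_pos),
        ler_max=mx,
        ler_threshold=thr,
    )


def select_cna_factors(
    result_cohort_a: AssociationResult,
    result_cohort_b: AssociationResult,
    ler_table: Optional[pd.DataFrame] = None,
    alpha: float = 0.01,
    chrom_lengths: Optional[dict] = None,
) -> pd.DataFrame:
    """Factors whose clone association survives Bonferroni in BOTH cohorts.

    The dual-cohort requirement guards against cohort-specific artifacts.  The
    LER criterion is *not* part of selection; it only drives the cis/trans
    label, which is attached when ``ler_table`` (the output of
    ``scan_factors``) is provided.  Returns a per-factor evidence table with a
    ``selected`` flag and, when labelled, the cis/trans call.
    """
    if list(result_cohort_a.factor_ids) != list(result_cohort_b.factor_ids):
        raise ValueError("association results cover different factor sets")
    profiles = ler_table.attrs.get("profiles", {}) if ler_table is not None else {}
    calibs = ler_table.attrs.get("calibrations", {}) if ler_table is not None else {}
    alpha_ler = ler_table.attrs.get("alpha", 1e-4) if ler_table is not None else 1e-4

    rows = []
    for fid in result_cohort_a.factor_ids:
        thr_a = alpha / result_cohort_a.n_tests
        thr_b = alpha / result_cohort_b.n_tests
        pa = result_cohort_a.min_p(fid)
        pb = result_cohort_b.min_p(fid)
        selected = (pa < thr_a) and (pb < thr_b)
        rec = {
            "factor": fid,
            "min_p_a": pa,
            "min_p_b": pb,
            "selected": selected,
            "call": "none",
        }
        if selected:
            peak_a = result_cohort_a.peak_clone(fid)
            rec["peak_clone_a"] = peak_a[0]
            rec["peak_chrom_a"] = peak_a[1]
            rec["peak_pos_a"] = peak_a[2]
            if fid in profiles:
                # both-cohort selection passed; label from cohort A's peak
                assoc_a = result_cohort_a
                # temporarily tighten to the selection alpha for the call
                call = classify_cis_trans(
                    fid,
                    _with_alpha(assoc_a, alpha),
                    profiles[fid],
                    calibs[fid],
                    alpha_ler=alpha_ler,
                    chrom_lengths=chrom_lengths,
                    colocalization_window=None if chrom_lengths else float("inf"),
                )
                rec["call"] = call.call
                rec["ler_max"] = call.ler_max
                rec["ler_threshold"] = call.ler_threshold
        rows.append(rec)
    return pd.DataFrame.from_records(rows).set_index("factor")


def _with_alpha(assoc: AssociationResult, alpha: float) -> AssociationResult:
    return AssociationResult(
        r=assoc.r, p=assoc.p,
        factor_ids=assoc.factor_ids, clone_ids=assoc.clone_ids,
        clone_chrom=assoc.clone_chrom, clone_pos=assoc.clone_pos,
        bonferroni_alpha=alpha, n_tests=assoc.n_tests,
        degenerate=assoc.degenerate,
    )
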