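"""Synthetic experiments and tumor cohorts with fully known ground truth.

The generators emulate the data regimes the pipeline is meant for:

* a small designed in-vitro experiment (2-3 exposure groups, a stated fraction
  of genes shifted by a stated effect size) for the sparse-signature stage;
* tumor cohorts whose expression is driven by a handful of sparse latent
  factors, some of which track a per-sample segmental copy-number level either
  in *cis* (member genes inside the altered segment) or in *trans* (member
  genes scattered, scores driven by a distant segment), together with an
  array-CGH clone panel measuring those copy-number levels;
* a paired second cohort sharing the same loadings but fresh samples, for
  projection and coexpression-conservation checks.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import CGHProfile, DesignMatrix, ExpressionMatrix, GeneAnnotation

__all__ = [
    "HUMAN_CHROM_LENGTHS",
    "FactorSpec",
    "SyntheticTruth",
    "simulate_annotation",
    "simulate_designed_experiment",
    "simulate_factor_cohort",
    "simulate_paired_cohorts",
    "default_clone_positions",
]

# Approximate lengths (bp) of human chromosomes 1-22 + X, GRCh37 scale.
HUMAN_CHROM_LENGTHS = {
    "chr1": 249_250_000, "chr2": 243_200_000, "chr3": 198_000_000,
    "chr4": 191_150_000, "chr5": 180_900_000, "chr6": 171_100_000,
    "chr7": 159_100_000, "chr8": 146_400_000, "chr9": 141_200_000,
    "chr10": 135_500_000, "chr11": 135_000_000, "chr12": 133_850_000,
    "chr13": 115_200_000, "chr14": 107_300_000, "chr15": 102_500_000,
    "chr16": 90_350_000, "chr17": 81_200_000, "chr18": 78_100_000,
    "chr19": 59_100_000, "chr20": 63_000_000, "chr21": 48_100_000,
    "chr22": 51_300_000, "chrX": 155_300_000,
}


@dataclass
class FactorSpec:
    """One planted latent factor.

    mode: "cis"     -- member genes drawn from inside ``segment``; scores track
                       the segment's per-sample copy-number level.  With
                       ``n_members=None`` every gene inside the segment loads
                       on the factor (a pure gene-dosage response).
          "trans"   -- scores track the segment's copy-number level but member
                       genes are placed independently of it.
          "neutral" -- standard-normal scores, no copy-number linkage.
    segment: (chromosome, start, end) in base pairs; required for cis/trans.
    """

    n_members: Optional[int]
    loading_scale: float = 1.0
    mode: str = "neutral"
    segment: Optional[tuple] = None

    def __post_init__(self):
        if self.mode not in ("cis", "trans", "neutral"):
            raise ValueError(f"unknown factor mode {self.mode!r}")
        if self.mode in ("cis", "trans") and self.segment is None:
            raise ValueError(f"{self.mode} factor requires a segment")
        if self.n_members is None and self.mode != "cis":
            raise ValueError("n_members=None (all in-segment genes) needs mode='cis'")


@dataclass
class SyntheticTruth:
    """Everything the generator knows; the oracle for all downstream tests."""

    loadings_true: np.ndarray          # genes x factors
    scores_true: np.ndarray            # factors x samples
    segment_map: list                  # (factor idx, chrom, start, end, mode)
    copy_number_latent: np.ndarray     # segments x samples
    noise_sd: np.ndarray               # per gene
    seed: int
    affected_genes: dict = field(default_factory=dict)
    factor_specs: list = field(default_factory=list)
    clone_segment: Optional[np.ndarray] = None  # per clone: segment idx or -1
    score_noise_sd: float = 0.0
    clone_noise_sd: float = 0.0
    amplified_fraction: float = 0.3
    amplification_mean: float = 1.5
    amplification_sd: float = 0.3

    def validate_against(self, expr: ExpressionMatrix) -> None:
        p, k = self.loadings_true.shape
        if p != expr.n_genes or self.scores_true.shape != (k, expr.n_samples):
            raise ValueError("truth dimensions inconsistent with emitted cohort")


def simulate_annotation(
    n_genes: int,
    chrom_lengths: Sequence[float] | dict,
    clustering: float = 0.0,
    seed: int = 0,
    n_peaks: int = 4,
    peak_sd_fraction: float = 0.015,
    extra_peaks: Optional[Sequence[tuple]] = None,
) -> GeneAnnotation:
    """Place ``n_genes`` genes on chromosomes, uniformly or around density peaks.

    Chromosomes are chosen with probability proportional to length.  With
    ``clustering == 0`` positions are uniform; with ``clustering > 0`` that
    fraction of genes is drawn around Gaussian density peaks (``n_peaks`` per
    chromosome, sd = ``peak_sd_fraction`` of the chromosome length), emulating
    the gene-dense islands of real annotations.  ``extra_peaks`` optionally
    adds explicit peaks as ``(chromosome, center)`` pairs, e.g. to guarantee
    genes inside a planted copy-number segment.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must be in [0, 1]")
    if isinstance(chrom_lengths, dict):
        names = list(chrom_lengths)
        lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    else:
        lengths = np.asarray(list(chrom_lengths), dtype=float)
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    if len(lengths) == 0:
        raise ValueError("chromosome length list is empty")
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")

    rng = np.random.default_rng(seed)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=probs)
    extra = {}
    if extra_peaks:
        for c, center in extra_peaks:
            extra.setdefault(c, []).append(float(center))

    pos = np.empty(n_genes)
    for ci, name in enumerate(names):
        mask = chrom_idx == ci
        n = int(mask.sum())
        if n == 0:
            continue
        L = lengths[ci]
        u = rng.uniform(0.0, L, size=n)
        if clustering > 0.0:
            peaks = list(rng.uniform(0.0, L, size=n_peaks)) + extra.get(name, [])
            peaks = np.asarray(peaks)
            pick = peaks[rng.integers(0, len(peaks), size=n)]
            clustered = pick + rng.normal(0.0, peak_sd_fraction * L, size=n)
            clustered = np.clip(clustered, 0.0, np.nextafter(L, 0.0))
            take = rng.random(n) < clustering
            u = np.where(take, clustered, u)
        pos[mask] = u

    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    return GeneAnnotation(
        gene_ids=gene_ids,
        chromosome=np.array([names[i] for i in chrom_idx], dtype=object),
        start=pos,
        chrom_lengths={c: float(l) for c, l in zip(names, lengths)},
    )


def simulate_designed_experiment(
    n_genes: int,
    group_sizes: Sequence[int],
    affected_fraction: float,
    effect_size: float,
    noise_sd: float,
    seed: int = 0,
):
    """Designed exposure experiment: groups of samples, a fraction of genes shifted.

    Group 1 is the reference; each further group contributes one design vector
    (its indicator).  For each design vector an independent set of
    ``round(affected_fraction * n_genes)`` genes receives an additive shift of
    ``effect_size * noise_sd`` in that group.  Returns
    ``(ExpressionMatrix, DesignMatrix, SyntheticTruth)``.
    """
    group_sizes = [int(g) for g in group_sizes]
    if len(group_sizes) < 2:
        raise ValueError("need at least 2 groups")
    if noise_sd <= 0 and effect_size != 0:
        # noise-free limit is allowed only as an explicit degenerate request
        if noise_sd < 0:
            raise ValueError("noise_sd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be positive")
    n_affected = int(round(affected_fraction * n_genes))
    if not 0 < affected_fraction < 1 or n_affected < 1:
        raise ValueError("affected_fraction * n_genes must be >= 1")

    rng = np.random.default_rng(seed)
    n = sum(group_sizes)
    group_of = np.repeat(np.arange(len(group_sizes)), group_sizes)
    r = len(group_sizes) - 1
    H = np.zeros((r, n))
    names = []
    for j in range(r):
        H[j] = (group_of == j + 1).astype(float)
        names.append(f"group{j + 2}_vs_group1")

    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n)]

    shift = effect_size * noise_sd
    B = np.zeros((n_genes, r))
    affected = {}
    for j in range(r):
        genes = rng.choice(n_genes, size=n_affected, replace=False)
        B[genes, j] = shift * rng.choice([-1.0, 1.0], size=n_affected)
        affected[names[j]] = sorted(gene_ids[g] for g in genes)

    X = B @ H + rng.normal(0.0, noise_sd, size=(n_genes, n))
    truth = SyntheticTruth(
        loadings_true=B,
        scores_true=H,
        segment_map=[],
        copy_number_latent=np.zeros((0, n)),
        noise_sd=np.full(n_genes, float(noise_sd)),
        seed=seed,
        affected_genes=affected,
    )
    expr = ExpressionMatrix(X, gene_ids, sample_ids)
    design = DesignMatrix(H, names, sample_ids)
    truth.validate_against(expr)
    return expr, design, truth


def default_clone_positions(chrom_lengths: dict, n_clones: int = 500) -> list:
    """Evenly spaced clone positions along the genome (BAC-panel stand-in)."""
    total = sum(chrom_lengths.values())
    spacing = total / n_clones
    out = []
    carry = spacing / 2.0
    for c, L in chrom_lengths.items():
        t = carry
        while t < L:
            out.append((c, t))
            t += spacing
        carry = t - L
    return out[:n_clones]


def _draw_segment_latents(rng, n_segments, n_samples, frac, mean, sd):
    """Per-segment, per-sample amplification level: a two-component mixture.

    A fraction of samples is 'amplified' at Normal(mean, sd); the rest sit at
    zero, mimicking subset amplification in tumor cohorts.
    """
    amp = rng.random((n_segments, n_samples)) < frac
    level = rng.normal(mean, sd, size=(n_segments, n_samples))
    return np.where(amp, level, 0.0)


def _gene_noise_sds(rng, n_genes, median_sd, spread=0.25):
    """Log-normal gene-wise noise sds around a median (heteroskedastic arrays)."""
    if median_sd == 0:
        return np.zeros(n_genes)
    return median_sd * np.exp(rng.normal(0.0, spread, size=n_genes))


def simulate_factor_cohort(
    annotation: GeneAnnotation,
    n_samples: int,
    factor_specs: Sequence[FactorSpec],
    noise_sd: float,
    clone_positions: Sequence[tuple],
    clone_noise_sd: float,
    seed: int = 0,
    score_noise_sd: float = 0.2,
    amplified_fraction: float = 0.3,
    amplification_mean: float = 1.5,
    amplification_sd: float = 0.3,
    noise_sd_spread: float = 0.25,
):
    """Cohort with planted sparse factors and a matched array-CGH panel.

    Returns ``(ExpressionMatrix, CGHProfile, SyntheticTruth)``.  For cis and
    trans factors the factor score equals the segment's latent per-sample
    copy-number level plus independent Normal(0, score_noise_sd) noise; clones
    inside a segment report that latent level plus clone noise, clones outside
    any segment report zero-centered clone noise.
    """
    if noise_sd < 0 or clone_noise_sd < 0:
        raise ValueError("noise sds must be non-negative")
    rng = np.random.default_rng(seed)
    p = annotation.n_genes
    k = len(factor_specs)

    # validate segments and build the segment table
    segment_map = []
    segments = []
    for j, spec in enumerate(factor_specs):
        if spec.segment is not None:
            c, s, e = spec.segment
            if c not in annotation.chrom_lengths:
                raise ValueError(f"segment on unknown chromosome {c!r}")
            if not (0 <= s < e <= annotation.chrom_lengths[c]):
                raise ValueError(f"segment ({c}, {s}, {e}) outside chromosome")
            segment_map.append((j, c, float(s), float(e), spec.mode))
            segments.append((j, c, float(s), float(e)))

    latents = _draw_segment_latents(
        rng, len(segments), n_samples,
        amplified_fraction, amplification_mean, amplification_sd,
    )

    # loadings
    A = np.zeros((p, k))
    seg_of_factor = {j: si for si, (j, *_rest) in enumerate(segments)}
    for j, spec in enumerate(factor_specs):
        if spec.mode == "cis":
            c, s, e = spec.segment
            inside = np.where(
                (annotation.chromosome == c)
                & (annotation.start >= s)
                & (annotation.start < e)
            )[0]
            if spec.n_members is None:
                if len(inside) < 2:
                    raise ValueError(
                        f"cis factor {j}: segment {spec.segment} holds "
                        f"{len(inside)} genes; need at least 2"
                    )
                members = inside
            elif len(inside) < spec.n_members:
                raise ValueError(
                    f"cis factor {j}: only {len(inside)} genes inside segment "
                    f"{spec.segment}, {spec.n_members} members requested"
                )
            else:
                members = rng.choice(inside, size=spec.n_members, replace=False)
        else:
            members = rng.choice(p, size=spec.n_members, replace=False)
        A[members, j] = spec.loading_scale * rng.uniform(0.5, 1.5, size=len(members))

    # scores
    Lam = np.empty((k, n_samples))
    for j, spec in enumerate(factor_specs):
        if spec.mode == "neutral":
            Lam[j] = rng.standard_normal(n_samples)
        else:
            Lam[j] = latents[seg_of_factor[j]] + rng.normal(0.0, score_noise_sd, n_samples)

    gene_sds = _gene_noise_sds(rng, p, noise_sd, noise_sd_spread)
    X = A @ Lam + gene_sds[:, None] * rng.standard_normal((p, n_samples))

    # clones
    clone_positions = list(clone_positions)
    m = len(clone_positions)
    clone_seg = np.full(m, -1, dtype=int)
    for ci, (c, pos) in enumerate(clone_positions):
        if c not in annotation.chrom_lengths:
            raise ValueError(f"clone on unknown chromosome {c!r}")
        if not (0 <= pos < annotation.chrom_lengths[c]):
            raise ValueError(f"clone position {pos} outside chromosome {c}")
        for si, (_j, sc, ss, se) in enumerate(segments):
            if c == sc and ss <= pos < se:
                clone_seg[ci] = si
                break
    CG = rng.normal(0.0, clone_noise_sd, size=(m, n_samples))
    inside = clone_seg >= 0
    CG[inside] += latents[clone_seg[inside]]

    sample_ids = [f"t{i:03d}" for i in range(n_samples)]
    expr = ExpressionMatrix(X, list(annotation.gene_ids), sample_ids)
    cgh = CGHProfile(
        clone_ids=[f"clone{ci:04d}" for ci in range(m)],
        clone_chrom=np.array([c for c, _ in clone_positions], dtype=object),
        clone_pos=np.array([pos for _, pos in clone_positions], dtype=float),
        values=CG,
        sample_ids=sample_ids,
        chrom_lengths=annotation.chrom_lengths,
    )
    truth = SyntheticTruth(
        loadings_true=A,
        scores_true=Lam,
        segment_map=segment_map,
        copy_number_latent=latents,
        noise_sd=gene_sds,
        seed=seed,
        factor_specs=list(factor_specs),
        clone_segment=clone_seg,
        score_noise_sd=score_noise_sd,
        clone_noise_sd=clone_noise_sd,
        amplified_fraction=amplified_fraction,
        amplification_mean=amplification_mean,
        amplification_sd=amplification_sd,
    )
    truth.validate_against(expr)
    _check_cis_invariant(annotation, truth)
    return expr, cgh, truth


def _check_cis_invariant(annotation: GeneAnnotation, truth: SyntheticTruth) -> None:
    """>=80% of each cis factor's loaded genes must lie inside its segment."""
    for j, c, s, e, mode in truth.segment_map:
        if mode != "cis":
            continue
        loaded = np.where(truth.loadings_true[:, j] != 0)[0]
        if len(loaded) == 0:
            continue
        inside = (
            (annotation.chromosome[loaded] == c)
            & (annotation.start[loaded] >= s)
            & (annotation.start[loaded] < e)
        )
        if inside.mean() < 0.8:
            raise AssertionError(
                f"cis factor {j}: only {inside.mean():.0%} of members in segment"
            )


def simulate_paired_cohorts(
    truth: SyntheticTruth,
    annotation: GeneAnnotation,
    clone_positions: Sequence[tuple],
    n_samples_b: int,
    score_distribution_shift: float = 0.0,
    seed: int = 1,
):
    """Second cohort sharing cohort A's loadings and noise model, fresh samples.

    Copy-number latents, factor scores, expression noise and clone noise are
    redrawn; ``score_distribution_shift`` adds a constant to every factor
    score (a cohort-level mean shift).  Gene order matches cohort A.  Returns
    ``(ExpressionMatrix, CGHProfile, SyntheticTruth)`` for the new cohort.
    """
    rng = np.random.default_rng(seed)
    A = truth.loadings_true
    p, k = A.shape
    segments = [(j, c, s, e) for (j, c, s, e, _m) in truth.segment_map]
    seg_of_factor = {j: si for si, (j, *_r) in enumerate(segments)}
    latents = _draw_segment_latents(
        rng, len(segments), n_samples_b,
        truth.amplified_fraction, truth.amplification_mean, truth.amplification_sd,
    )
    modes = {j: m for (j, _c, _s, _e, m) in truth.segment_map}
    Lam = np.empty((k, n_samples_b))
    for j in range(k):
        if j in seg_of_factor:
            Lam[j] = latents[seg_of_factor[j]] + rng.normal(
                0.0, truth.score_noise_sd, n_samples_b
            )
        else:
            Lam[j] = rng.standard_normal(n_samples_b)
    Lam += score_distribution_shift

    X = A @ Lam + truth.noise_sd[:, None] * rng.standard_normal((p, n_samples_b))

    clone_positions = list(clone_positions)
    m = len(clone_positions)
    clone_seg = np.full(m, -1, dtype=int)
    for ci, (c, pos) in enumerate(clone_positions):
        for si, (_j, sc, ss, se) in enumerate(segments):
            if c == sc and ss <= pos < se:
                clone_seg[ci] = si
                break
    CG = rng.normal(0.0, truth.clone_noise_sd, size=(m, n_samples_b))
    inside = clone_seg >= 0
    CG[inside] += latents[clone_seg[inside]]

    sample_ids = [f"u{i:03d}" for i in range(n_samples_b)]
    expr = ExpressionMatrix(X, list(annotation.gene_ids), sample_ids)
    cgh = CGHProfile(
        clone_ids=[f"clone{ci:04d}" for ci in range(m)],
        clone_chrom=np.array([c for c, _ in clone_positions], dtype=object),
        clone_pos=np.array([pos for _, pos in clone_positions], dtype=float),
        values=CG,
        sample_ids=sample_ids,
        chrom_lengths=annotation.chrom_lengths,
    )
    truth_b = SyntheticTruth(
        loadings_true=A,
        scores_true=Lam,
        segment_map=list(truth.segment_map),
        copy_number_latent=latents,
        noise_sd=truth.noise_sd,
        seed=seed,
        factor_specs=list(truth.factor_specs),
        clone_segment=clone_seg,
        score_noise_sd=truth.score_noise_sd,
        clone_noise_sd=truth.clone_noise_sd,
        amplified_fraction=truth.amplified_fraction,
        amplification_mean=truth.amplification_mean,
        amplification_sd=truth.amplification_sd,
    )
    truth_b.validate_against(expr)
    return expr, cgh, truth_b
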