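import math

import numpy as np
import pytest

from lfcna import GeneAnnotation, simulate_annotation


@pytest.fixture
def toy_annotation():
    """3 genes on two chromosomes of length 100 (positions 20, 80, 50)."""
    return GeneAnnotation(
        gene_ids=["gA", "gB", "gC"],
        chromosome=np.array(["chr1", "chr1", "chr2"], dtype=object),
        start=np.array([20.0, 80.0, 50.0]),
        chrom_lengths={"chr1": 100.0, "chr2": 100.0},
    )


@pytest.fixture(scope="session")
def human_annotation_300():
    """300 genes uniformly placed on human-proportioned chromosomes."""
    from lfcna import HUMAN_CHROM_LENGTHS

    return simulate_annotation(300, HUMAN_CHROM_LENGTHS, clustering=0.0, seed=7)


def ler_bruteforce(ann: GeneAnnotation, pi, kernel_fraction, grid_points: dict):
    """Direct, loop-based evaluation of the local enrichment ratio formula.

    Independent of the vectorized implementation: plain Python floats, one
    gene and one grid point at a time.
    """
    p = len(pi)
    weights = []
    for gi in range(p):
        c = ann.chromosome[gi]
        sd = kernel_fraction * ann.chrom_lengths[c]
        raw = [math.exp(-0.5 * ((t - ann.start[gi]) / sd) ** 2)
               for t in grid_points[c]]
        tot = sum(raw)
        weights.append([x / tot for x in raw])
    M = sum(pi)
    M0 = float(p)
    out = {}
    for c, pts in grid_points.items():
        vals = []
        on_c = [gi for gi in range(p) if ann.chromosome[gi] == c]
        for ti in range(len(pts)):
            num = sum(pi[gi] * weights[gi][ti] for gi in on_c)
            den = sum(weights[gi][ti] for gi in on_c)
            vals.append((num / M) / (den / M0) if den > 0 else float("nan"))
        out[c] = vals
    return out
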