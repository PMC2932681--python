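"""Core in-memory containers shared across the pipeline.

All tabular payloads are plain numpy arrays with parallel identifier lists,
convertible to/from pandas for I/O.  Validation happens at construction time
so downstream code can assume consistent dimensions and unique identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DesignMatrix",
    "GeneAnnotation",
    "CGHProfile",
]


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Log-expression values for ``p`` genes by ``n`` samples."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-dimensional")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], list(gene_ids), list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class DesignMatrix:
    """Known design vectors (``r`` vectors by ``n`` samples)."""

    values: np.ndarray
    vector_names: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.vector_names = _check_unique(self.vector_names, "design vector")
        r, n = self.values.shape
        if r != len(self.vector_names):
            raise ValueError("design vector count does not match names")
        if n != len(self.sample_ids):
            raise ValueError("design sample count does not match sample ids")

    @property
    def n_vectors(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.vector_names, columns=self.sample_ids)


@dataclass
class GeneAnnotation:
    """Genomic positions of genes: per-gene chromosome and start coordinate.

    ``start`` is the gene's representative point position (transcription start);
    CNAs span regions much larger than a gene, so a point mass suffices.
    """

    gene_ids: list
    chromosome: np.ndarray
    start: np.ndarray
    chrom_lengths: dict

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.start = np.asarray(self.start, dtype=float)
        if not (len(self.gene_ids) == len(self.chromosome) == len(self.start)):
            raise ValueError("annotation arrays have inconsistent lengths")
        if not self.chrom_lengths:
            raise ValueError("chromosome length map is empty")
        for c, s in zip(self.chromosome, self.start):
            if c not in self.chrom_lengths:
                raise ValueError(f"gene on unknown chromosome {c!r}")
            if not (0 <= s < self.chrom_lengths[c]):
                raise ValueError(
                    f"gene start {s} outside chromosome {c} (length {self.chrom_lengths[c]})"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_ids) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([index[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in annotation") from None

    def to_bed(self) -> pd.DataFrame:
        """4-column BED (0-based half-open; end = start + 1)."""
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": self.start.astype(int),
                "end": self.start.astype(int) + 1,
                "name": self.gene_ids,
            }
        )


@dataclass
class CGHProfile:
    """Array-CGH copy-number measurements: clones by samples, with positions."""

    clone_ids: list
    clone_chrom: np.ndarray
    clone_pos: np.ndarray
    values: np.ndarray
    sample_ids: list
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.clone_ids = _check_unique(self.clone_ids, "clone")
        self.clone_chrom = np.asarray(self.clone_chrom, dtype=object)
        self.clone_pos = np.asarray(self.clone_pos, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.clone_ids)
        if self.values.shape != (m, len(self.sample_ids)):
            raise ValueError(
                f"CGH value shape {self.values.shape} inconsistent with "
                f"{m} clones / {len(self.sample_ids)} samples"
            )
        if len(self.clone_chrom) != m or len(self.clone_pos) != m:
            raise ValueError("clone position arrays inconsistent with clone ids")
        if self.chrom_lengths:
            for c, s in zip(self.clone_chrom, self.clone_pos):
                if c in self.chrom_lengths and not (0 <= s < self.chrom_lengths[c]):
                    raise ValueError(f"clone position {s} outside chromosome {c}")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)
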