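"""Readers and writers for the pipeline's plain-text formats.

Canonical dialects: tab-separated tables with a header row for matrices,
4-column BED (0-based, half-open) for gene annotation, and JSON sidecars for
model metadata.  Write-then-read round-trips preserve values to full float
precision (repr-exact) and preserve row/column orderings.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CGHProfile, DesignMatrix, ExpressionMatrix, GeneAnnotation
from .factors import FactorModel
from .signature import PriorSpec, SignatureModel

__all__ = [
    "read_expression", "write_expression",
    "read_design", "write_design",
    "read_annotation", "write_annotation",
    "read_cgh", "write_cgh",
    "write_factor_model", "read_factor_model",
    "write_signature_model", "read_signature_model",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def read_expression(path) -> ExpressionMatrix:
    """Genes in rows (first column = gene id), samples in header columns."""
    df = _read_tsv(path)
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicated gene id {dup[0]!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: NaN cells in rows {rows[:5]}")
    return ExpressionMatrix.from_dataframe(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_design(path) -> DesignMatrix:
    df = _read_tsv(path)
    return DesignMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_design(design: DesignMatrix, path) -> None:
    design.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_annotation(path, chrom_lengths: dict | None = None) -> GeneAnnotation:
    """4-column BED: chrom, start, end, gene id (0-based half-open).

    ``start`` is used as the gene's point position.  ``end != start + 1`` is
    tolerated (a warning is logged).  Chromosome lengths default to the
    maximum end seen per chromosome unless provided.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gene_ids, chroms, starts = [], [], []
    ends = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: malformed BED line (need 4 columns)")
            c, s, e, name = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e = int(s), int(e)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from None
            if e != s + 1:
                logger.warning("%s:%d: end != start + 1; using start as the position",
                               path, ln)
            gene_ids.append(name)
            chroms.append(c)
            starts.append(s)
            ends[c] = max(ends.get(c, 0), e)
    if chrom_lengths is None:
        chrom_lengths = {c: float(e) for c, e in ends.items()}
    return GeneAnnotation(
        gene_ids=gene_ids,
        chromosome=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=float),
        chrom_lengths=chrom_lengths,
    )


def write_annotation(ann: GeneAnnotation, path, lengths_path=None) -> None:
    ann.to_bed().to_csv(path, sep="\t", header=False, index=False)
    if lengths_path is not None:
        with open(lengths_path, "w") as fh:
            json.dump(ann.chrom_lengths, fh, indent=1)


def read_cgh(path, chrom_lengths: dict | None = None) -> CGHProfile:
    """TSV: clone id (index), chrom, pos, then one column per sample."""
    df = _read_tsv(path)
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValueError(f"{path}: expected columns 'chrom', 'pos', then samples")
    return CGHProfile(
        clone_ids=list(df.index),
        clone_chrom=df["chrom"].to_numpy(dtype=object),
        clone_pos=df["pos"].to_numpy(dtype=float),
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        sample_ids=list(df.columns[2:]),
        chrom_lengths=chrom_lengths or {},
    )


def write_cgh(cgh: CGHProfile, path) -> None:
    df = pd.DataFrame(cgh.values, index=cgh.clone_ids, columns=cgh.sample_ids)
    df.insert(0, "pos", cgh.clone_pos)
    df.insert(0, "chrom", cgh.clone_chrom)
    df.index.name = "clone"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_factor_model(model: FactorModel, directory) -> None:
    """Three TSVs (loadings, scores, inclusion probabilities) + JSON metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fids = model.factor_ids
    pd.DataFrame(model.loadings, index=model.gene_ids, columns=fids).to_csv(
        d / "loadings.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame(model.scores, index=fids, columns=model.sample_ids).to_csv(
        d / "scores.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame(model.inclusion_prob, index=model.gene_ids, columns=fids).to_csv(
        d / "inclusion.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = {
        "noise_var": model.noise_var.tolist(),
        "gene_means": model.gene_means.tolist(),
        "prior_spec": vars(model.prior_spec),
        "mcmc_meta": model.mcmc_meta,
    }
    with open(d / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_factor_model(directory) -> FactorModel:
    d = Path(directory)
    loadings = _read_tsv(d / "loadings.tsv")
    scores = _read_tsv(d / "scores.tsv")
    inclusion = _read_tsv(d / "inclusion.tsv")
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    return FactorModel(
        loadings=loadings.to_numpy(dtype=float),
        scores=scores.to_numpy(dtype=float),
        inclusion_prob=inclusion.to_numpy(dtype=float),
        noise_var=np.asarray(meta["noise_var"], dtype=float),
        gene_ids=list(loadings.index),
        sample_ids=list(scores.columns),
        gene_means=np.asarray(meta["gene_means"], dtype=float),
        prior_spec=PriorSpec(**meta["prior_spec"]),
        mcmc_meta=meta["mcmc_meta"],
    )


def write_signature_model(model: SignatureModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.coefficients, index=model.gene_ids,
                 columns=model.vector_names).to_csv(
        d / "coefficients.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame(model.inclusion_prob, index=model.gene_ids,
                 columns=model.vector_names).to_csv(
        d / "inclusion.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = {
        "intercepts": model.intercepts.tolist(),
        "noise_var": model.noise_var.tolist(),
        "prior_spec": vars(model.prior_spec),
        "mcmc_meta": model.mcmc_meta,
    }
    with open(d / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_signature_model(directory) -> SignatureModel:
    d = Path(directory)
    coef = _read_tsv(d / "coefficients.tsv")
    inclusion = _read_tsv(d / "inclusion.tsv")
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    return SignatureModel(
        coefficients=coef.to_numpy(dtype=float),
        inclusion_prob=inclusion.to_numpy(dtype=float),
        intercepts=np.asarray(meta["intercepts"], dtype=float),
        noise_var=np.asarray(meta["noise_var"], dtype=float),
        gene_ids=list(coef.index),
        vector_names=list(coef.columns),
        prior_spec=PriorSpec(**meta["prior_spec"]),
        mcmc_meta=meta["mcmc_meta"],
    )
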