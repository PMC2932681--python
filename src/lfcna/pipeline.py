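"""End-to-end pipeline driver on synthetic data, plus its configuration.

The driver wires the stages together in the order the analysis is meant to be
run: simulate -> fit signature -> select genes -> fit factors -> project ->
LER scan -> clone association -> cis/trans selection -> conservation.  Every
stage writes its outputs as plain-text tables under the results directory and
the run ends with a manifest recording the configuration, all seeds, and a
SHA-256 hash per output file, so a rerun with the same configuration can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as lio
from .association import correlate_scores_with_clones, select_cna_factors
from .conservation import conservation_between
from .factors import align_factors, factor_gene_lists, fit_factor_model
from .ler import scan_factors
from .projection import project_factors
from .signature import McmcSpec, fit_sparse_regression, select_signature_genes
from .synthetic import (
    HUMAN_CHROM_LENGTHS,
    FactorSpec,
    default_clone_positions,
    simulate_annotation,
    simulate_designed_experiment,
    simulate_factor_cohort,
    simulate_paired_cohorts,
)

__all__ = ["PipelineConfig", "default_config", "study_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """All pipeline knobs; every random stage has an explicit seed."""

    seed: int = 0
    # synthetic study conditions
    n_genes: int = 1500
    clustering: float = 1.0
    n_samples_a: int = 120
    n_samples_b: int = 80
    n_clones: int = 400
    noise_sd: float = 0.5
    clone_noise_sd: float = 0.2
    score_noise_sd: float = 0.2
    cis_segments: list = field(default_factory=lambda: [
        ["chr8", 2_000_000, 12_000_000],
        ["chr17", 35_000_000, 45_000_000],
    ])
    trans_segments: list = field(default_factory=lambda: [
        ["chr12", 65_000_000, 75_000_000],
    ])
    n_neutral: int = 2
    n_members: int = 25
    loading_scale: float = 1.0
    # designed-experiment stage
    experiment_genes: int = 300
    group_sizes: list = field(default_factory=lambda: [12, 12, 12])
    affected_fraction: float = 0.1
    effect_size: float = 2.0
    signature_iters: int = 1500
    signature_burn_in: int = 300
    signature_threshold: float = 0.99
    # factor stage
    factor_iters: int = 600
    factor_burn_in: int = 200
    membership_threshold: float = 0.95
    # LER stage
    kernel_fraction: float = 0.05
    ler_permutations: int = 500
    alpha_ler: float = 2e-3
    # association stage
    alpha_assoc: float = 0.01
    # stage toggles
    run_signature: bool = True
    run_factors: bool = True
    run_conservation: bool = True
    write_intermediate: bool = True  # write cohort/model tables, not just reports

    def validate(self) -> None:
        for name in ("alpha_ler", "alpha_assoc", "affected_fraction",
                     "signature_threshold", "membership_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.kernel_fraction <= 0:
            raise ValueError("kernel_fraction must be positive")
        if self.seed is None:
            raise ValueError("a seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def study_config(seed: int = 0) -> PipelineConfig:
    """Conditions of the paired-cohort CNA discovery study.

    Two cohorts at the scale of the breast-tumor/cell-line pairing this
    pipeline targets (250 and 120 samples), 3000 candidate genes on 23
    human-proportioned chromosomes, a 500-clone CGH panel, and eight planted
    factors: two cis (chr8p and chr17q amplicon-like segments), one trans
    (driven by a chr12q segment), five neutral.
    """
    return PipelineConfig(
        seed=seed,
        n_genes=3000,
        n_samples_a=250,
        n_samples_b=120,
        n_clones=500,
        n_neutral=5,
        factor_iters=600,
        factor_burn_in=200,
        ler_permutations=1500,
        alpha_ler=1e-3,
        run_signature=False,
        run_conservation=False,
        write_intermediate=False,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every enabled stage; returns the summary report (also written).

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are left in place.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # ---- simulate ------------------------------------------------------
        stage = "simulate"
        specs = []
        for seg in config.cis_segments:
            # cis factors are pure dosage responses: all in-segment genes load
            specs.append(FactorSpec(None, config.loading_scale, "cis", tuple(seg)))
        for seg in config.trans_segments:
            specs.append(FactorSpec(config.n_members, config.loading_scale,
                                    "trans", tuple(seg)))
        for _ in range(config.n_neutral):
            specs.append(FactorSpec(config.n_members, config.loading_scale, "neutral"))

        ann = simulate_annotation(
            config.n_genes, HUMAN_CHROM_LENGTHS,
            clustering=config.clustering, seed=config.seed,
            # double-weight peaks at cis segments: amplicons are gene-dense
            extra_peaks=[(c, (s + e) / 2) for c, s, e in
                         (tuple(x) for x in config.cis_segments) for _ in range(2)],
        )
        clones = default_clone_positions(ann.chrom_lengths, config.n_clones)
        expr_a, cgh_a, truth_a = simulate_factor_cohort(
            ann, config.n_samples_a, specs, config.noise_sd, clones,
            config.clone_noise_sd, seed=config.seed + 1,
            score_noise_sd=config.score_noise_sd,
        )
        expr_b, cgh_b, truth_b = simulate_paired_cohorts(
            truth_a, ann, clones, config.n_samples_b, seed=config.seed + 2,
        )
        if config.write_intermediate:
            lio.write_expression(expr_a, out / "cohort_a.tsv")
            lio.write_expression(expr_b, out / "cohort_b.tsv")
            lio.write_cgh(cgh_a, out / "cgh_a.tsv")
            lio.write_cgh(cgh_b, out / "cgh_b.tsv")
            lio.write_annotation(ann, out / "genes.bed", out / "chrom_lengths.json")

        # ---- signature stage ----------------------------------------------
        if config.run_signature:
            stage = "fit-signature"
            ex_expr, ex_design, ex_truth = simulate_designed_experiment(
                config.experiment_genes, config.group_sizes,
                config.affected_fraction, config.effect_size,
                noise_sd=config.noise_sd, seed=config.seed + 3,
            )
            sig = fit_sparse_regression(
                ex_expr, ex_design,
                mcmc_spec=McmcSpec(config.signature_iters, config.signature_burn_in),
                seed=config.seed + 4,
            )
            if config.write_intermediate:
                lio.write_signature_model(sig, out / "signature_model")
            stage = "select-genes"
            selected = select_signature_genes(sig, config.signature_threshold)
            (out / "signature_genes.txt").write_text("\n".join(selected) + "\n")
            planted = sorted(set().union(*ex_truth.affected_genes.values()))
            report["signature"] = {
                "n_selected": len(selected),
                "n_planted": len(planted),
                "recovered": len(set(selected) & set(planted)),
            }

        # ---- factor stage ---------------------------------------------------
        if config.run_factors:
            stage = "fit-factors"
            model = fit_factor_model(
                expr_a, k=len(specs),
                mcmc_spec=McmcSpec(config.factor_iters, config.factor_burn_in),
                seed=config.seed + 5,
            )
            if config.write_intermediate:
                lio.write_factor_model(model, out / "factor_model")

            stage = "project"
            proj_a = project_factors(model, expr_a, missing_gene_policy="drop")
            proj_b = project_factors(model, expr_b, missing_gene_policy="drop")
            if config.write_intermediate:
                import pandas as pd
                for name, pr in (("scores_a.tsv", proj_a), ("scores_b.tsv", proj_b)):
                    pd.DataFrame(pr.scores, index=pr.factor_ids,
                                 columns=pr.sample_ids).to_csv(
                        out / name, sep="\t", float_format="%.17g")

            stage = "ler"
            ler_table = scan_factors(
                model, ann, kernel_fraction=config.kernel_fraction,
                n_permutations=config.ler_permutations,
                seed=config.seed + 6, alpha=config.alpha_ler,
            )
            ler_table.to_csv(out / "ler_scan.tsv", sep="\t")

            stage = "associate"
            assoc_a = correlate_scores_with_clones(proj_a, cgh_a, alpha=config.alpha_assoc)
            assoc_b = correlate_scores_with_clones(proj_b, cgh_b, alpha=config.alpha_assoc)
            selection = select_cna_factors(
                assoc_a, assoc_b, ler_table, alpha=config.alpha_assoc,
                chrom_lengths=ann.chrom_lengths,
            )
            selection.to_csv(out / "cna_factors.tsv", sep="\t")

            # compare against the planted truth
            perm, _signs, corrs = align_factors(model.scores, truth_a.scores_true)
            mode_of = {j: m for (j, _c, _s, _e, m) in truth_a.segment_map}
            truth_pos = {j for j, m in mode_of.items() if m in ("cis", "trans")}
            # map estimated factor index -> planted index
            est_to_planted = {int(b): int(a) for a, b in enumerate(perm) if b >= 0}
            per_factor = []
            selected_planted = set()
            n_selected = 0
            for i, fid in enumerate(model.factor_ids):
                sel_flag = bool(selection.loc[fid, "selected"])
                pl = est_to_planted.get(i)
                true_mode = mode_of.get(pl, "neutral") if pl is not None else "unmatched"
                if sel_flag:
                    n_selected += 1
                    if pl in truth_pos:
                        selected_planted.add(pl)
                per_factor.append({
                    "factor": fid,
                    "true_mode": true_mode,
                    "selected": sel_flag,
                    "call": selection.loc[fid, "call"],
                    "max_ler": float(ler_table.loc[fid, "max_ler"]),
                    "ler_threshold": float(ler_table.loc[fid, "threshold"]),
                })
            tp = len(selected_planted)
            precision = tp / max(n_selected, 1)
            recall = tp / max(len(truth_pos), 1)
            labels_ok = all(
                pf["call"] == pf["true_mode"]
                for pf in per_factor
                if pf["selected"] and pf["true_mode"] in ("cis", "trans")
            )
            report["factors"] = {
                "k_fitted": model.k,
                "alignment_corr": [float(c) for c in corrs],
                "cna_precision": precision,
                "cna_recall": recall,
                "labels_correct": labels_ok,
                "per_factor": per_factor,
            }

            if config.run_conservation:
                stage = "conserve"
                lists = factor_gene_lists(model, config.membership_threshold)
                cons = {}
                for fid, genes in lists.items():
                    if len(genes) >= 3:
                        res = conservation_between(expr_a, expr_b, genes)
                        cons[fid] = {"kendall": res.kendall, "p_value": res.p_value,
                                     "n_genes": res.n_genes}
                report["conservation"] = cons
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - reported with stage context
        raise PipelineError(stage, e) from e

    stage = "manifest"
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    from . import __version__

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "hashes": {
            f.name: _sha256(f)
            for f in sorted(out.rglob("*"))
            if f.is_file() and f.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
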