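"""End-to-end orchestration of the two stages of the analysis.

Stage 1 (cell lines): normalize paired normoxic/hypoxic expression,
run the nested-LOO l1-l2 selection and the fold-change/BH differential
expression independently, and intersect the two lists into the hypoxia
signature.

Stage 2 (tumors): normalize the tumor matrix, stratify the patients by
k-means on the signature probesets, test the stability of the split
against random signatures, and evaluate prognosis (KM, log-rank,
multivariate Cox, MYCN-normal subgroup).

All randomness is routed through named integer seeds; rerunning with
the same config and seeds reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import de_select, fold_changes
from .io import ClinicalTable, ExpressionMatrix, PairedDesign, log2_transform, normalize_chain
from .l1l2 import L1L2Config, LabeledDataset, SelectionFrequencyTable, frequency_signature, outer_loo_selection
from .signature import Signature, intersect_signatures, write_signature
from .stratify import (
    ClusterAssignment,
    StabilityResult,
    hcluster_complete,
    kmeans2,
    label_prognosis,
    permutation_stability,
    prepare_cluster_matrix,
)
from .survival import survival_report

log = logging.getLogger("hyposig")

__all__ = ["DerivationConfig", "EvaluationConfig", "ReportBundle", "run_derivation", "run_evaluation"]


@dataclass
class DerivationConfig:
    target_mean: float = 500.0
    fc_threshold: float = 2.0
    alpha: float = 0.05
    fc_rule: str = "mean"
    frequency_threshold: float = 0.5
    l1l2: L1L2Config = field(default_factory=L1L2Config)


@dataclass
class EvaluationConfig:
    target_mean: float = 500.0
    restarts: int = 100
    n_perm: int = 300
    seed: int = 0
    zscore: bool = True
    ties: str = "efron"
    horizon: float | None = None  # years; None = KM at last observed time


@dataclass
class ReportBundle:
    """Artifacts of a pipeline stage plus reproducibility metadata."""

    metadata: dict
    l1l2_signature: Signature | None = None
    de_signature: Signature | None = None
    signature: Signature | None = None
    frequency_table: SelectionFrequencyTable | None = None
    assignment: ClusterAssignment | None = None
    stability: StabilityResult | None = None
    survival: dict | None = None
    heatmap_row_order: list[str] | None = None


def _config_hash(cfg) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_derivation(
    E: ExpressionMatrix,
    design: PairedDesign,
    cfg: DerivationConfig | None = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Cell-line stage: normalization, l1-l2 + DE lists, intersection."""
    cfg = cfg or DerivationConfig()
    design.validate_against(E)
    stage = "normalization"
    try:
        norm = normalize_chain(E, target_mean=cfg.target_mean)
        stage = "l1l2 selection"
        dataset = LabeledDataset.from_expression(log2_transform(norm), design)
        freq = outer_loo_selection(dataset, cfg.l1l2)
        sig_l1l2 = frequency_signature(freq, cfg.frequency_threshold, name="l1l2")
        log.info("l1l2 list: %d probesets, LOO error %.3f", len(sig_l1l2), freq.loo_error)
        stage = "differential expression"
        fc = fold_changes(norm, design)
        sig_de = de_select(fc, cfg.fc_threshold, cfg.alpha, cfg.fc_rule, name="de")
        log.info("DE list: %d probesets", len(sig_de))
        stage = "intersection"
        sig = intersect_signatures(sig_l1l2, sig_de, name="hypoxia-signature")
        log.info("intersection: %d probesets", len(sig))
    except Exception as exc:
        raise RuntimeError(f"derivation failed at stage '{stage}': {exc}") from exc
    bundle = ReportBundle(
        metadata={
            "stage": "derivation",
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "n_lines": len(design.entries),
            "n_probesets": E.shape[0],
            "loo_error": freq.loo_error,
            "list_sizes": {"l1l2": len(sig_l1l2), "de": len(sig_de), "intersection": len(sig)},
        },
        l1l2_signature=sig_l1l2,
        de_signature=sig_de,
        signature=sig,
        frequency_table=freq,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_signature(sig_l1l2, outdir / "l1l2_signature.txt")
        write_signature(sig_de, outdir / "de_signature.txt")
        write_signature(sig, outdir / "hypoxia_signature.txt")
        freq.to_tsv(outdir / "frequency_table.tsv")
        fc.as_frame().to_csv(outdir / "fold_changes.tsv", sep="\t")
        (outdir / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    return bundle


def run_evaluation(
    E_tumors: ExpressionMatrix,
    cohorts: ClinicalTable | dict[str, ClinicalTable],
    S: Signature,
    cfg: EvaluationConfig | None = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Tumor stage: stratification, stability test, survival report.

    ``cfg.n_perm = 0`` skips the permutation stability test.
    """
    cfg = cfg or EvaluationConfig()
    if len(S) == 0:
        raise ValueError("empty signature: nothing to stratify on")
    missing = [p for p in S.probesets if p not in set(E_tumors.probeset_ids)]
    if missing:
        raise ValueError(f"signature probesets absent from tumor matrix: {missing[:5]}")
    stage = "normalization"
    try:
        norm = normalize_chain(E_tumors, target_mean=cfg.target_mean)
        stage = "stratification"
        M = prepare_cluster_matrix(norm, zscore=cfg.zscore)
        sig_idx = [norm.probeset_ids.index(p) for p in S.probesets]
        M_sig = M[:, sig_idx]
        assignment = kmeans2(M_sig, restarts=cfg.restarts, seed=cfg.seed,
                             sample_ids=norm.sample_ids)
        assignment = label_prognosis(assignment, M_sig)
        log.info("clusters: %s, prognosis %s", assignment.sizes, assignment.prognosis)
        stage = "stability"
        stability = None
        if cfg.n_perm:
            stability = permutation_stability(
                norm, S, n_perm=cfg.n_perm, seed=cfg.seed, restarts=cfg.restarts,
                zscore=cfg.zscore,
            )
            log.info("stability: mean distance %.3f, p %.3g",
                     stability.distances.mean(), stability.p_value)
        stage = "survival"
        report = survival_report(cohorts, assignment, ties=cfg.ties, horizon=cfg.horizon)
        stage = "heatmap ordering"
        if len(S) >= 2:
            order_idx, _ = hcluster_complete(M_sig.T)
            row_order = [S.probesets[i] for i in order_idx]
        else:
            row_order = list(S.probesets)
    except Exception as exc:
        raise RuntimeError(f"evaluation failed at stage '{stage}': {exc}") from exc
    bundle = ReportBundle(
        metadata={
            "stage": "evaluation",
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "signature_size": len(S),
            "cluster_sizes": assignment.sizes,
        },
        signature=S,
        assignment=assignment,
        stability=stability,
        survival=report,
        heatmap_row_order=row_order,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignment.as_series().to_csv(outdir / "assignment.csv")
        if stability is not None:
            (outdir / "stability.json").write_text(json.dumps(
                {"t": stability.t_statistic, "p": stability.p_value,
                 "n_perm": stability.n_perm,
                 "mean_distance": float(stability.distances.mean()),
                 "mean_baseline": float(stability.baselines.mean())}, indent=2))
        (outdir / "survival_report.json").write_text(json.dumps(report, indent=2, default=float))
        (outdir / "heatmap_row_order.txt").write_text("".join(f"{p}\n" for p in row_order))
        (outdir / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    return bundle
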