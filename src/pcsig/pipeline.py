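"""End-to-end orchestration of the attribution workflow.

Stages: (1) low-expression filter; (2) pan-PCA over all samples with
eta-squared attribution of components to experimental factors; (3) per-cell-
line PCA; (4) hierarchical clustering of samples on each component's
signature, marking a component overexpression-related when its concordance
with the overexpression split is high and beats its cell-line concordance;
(5) ORA of the overexpression-related signatures; (6) moderated-t
differential expression per control type with cross-line intersection;
(7) an optional re-run restricted to empty-vector controls.

Every intermediate is persisted when an output directory is given, and the
report carries the numbers a reader needs to audit each stage's decision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pcsig.cluster import cluster_concordance, hierarchical_cluster
from pcsig.diffexpr import (
    DEFAULT_ALPHA_ADJ,
    call_and_intersect,
    run_contrast,
    write_de_table,
)
from pcsig.enrichment import DEFAULT_ALPHA, run_ora, write_ora_table
from pcsig.io_formats import GeneSetCollection, align_annotation, write_expression_matrix
from pcsig.pca_signature import (
    DEFAULT_W,
    pc_factor_association,
    run_pca_svd,
    scale_center,
    select_signature,
)
from pcsig.preprocess import FilterSpec, filter_low_expression, quantile_normalize

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place (defaults follow the study)."""

    filter_spec: FilterSpec = FilterSpec()
    quantile: bool = False
    w: float = DEFAULT_W
    n_pcs: int = 2
    scale_genes: bool = False
    alpha_adj: float = DEFAULT_ALPHA_ADJ
    ora_alpha: float = DEFAULT_ALPHA
    distance: str = "euclidean"
    linkage: str = "average"
    concordance_min: float = 0.9
    run_vector_only_rerun: bool = True

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    """Machine-readable account of the run; every number is recomputable
    from the persisted intermediates."""

    config_hash: str
    n_genes_input: int
    n_genes_filtered: int
    pan_variance_fraction: dict[str, float]
    pan_eta_squared: dict[str, dict[str, float]]
    pan_dominant_pc: dict[str, str]
    per_line: dict[str, dict] = field(default_factory=dict)
    overexpression_components: dict[str, int] = field(default_factory=dict)
    signature_sizes: dict[str, int] = field(default_factory=dict)
    ora_significant_counts: dict[str, int] = field(default_factory=dict)
    de_significant_counts: dict[str, int] = field(default_factory=dict)
    de_intersection_size: int | None = None
    vector_only: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)


def _overexpression_split(ann: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.where(ann["condition"] == "OVEREXPR", "OVEREXPR", "CONTROL"),
        index=ann.index,
    )


def attribute_components(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    pca,
    config: PipelineConfig,
) -> tuple[dict[int, dict[str, float]], int | None]:
    """Cluster samples on each component's signature and score concordance.

    Returns per-PC concordance tables and the 1-based index of the first
    component judged overexpression-related: concordance with the
    overexpression split at k=2 at least ``concordance_min`` and strictly
    greater than that component's cell-line concordance (the latter check is
    skipped when only one cell line is present).
    """
    over = _overexpression_split(ann)
    lines = ann["cell_line"]
    multi_line = lines.nunique() > 1
    per_pc: dict[int, dict[str, float]] = {}
    related = None
    for pc in range(1, min(config.n_pcs, pca.k) + 1):
        sig = select_signature(pca, pc, config.w)
        entry: dict[str, float] = {"signature_size": len(sig)}
        if len(sig) == 0:
            per_pc[pc] = entry
            continue
        clustering = hierarchical_cluster(
            matrix.loc[sig.gene_ids], distance=config.distance, method=config.linkage
        )
        entry["concordance_overexpression"] = cluster_concordance(clustering, over)
        if multi_line:
            entry["concordance_cell_line"] = cluster_concordance(clustering, lines)
        per_pc[pc] = entry
        ok = entry["concordance_overexpression"] >= config.concordance_min
        if multi_line:
            ok = ok and entry["concordance_overexpression"] > entry["concordance_cell_line"]
        if ok and related is None:
            related = pc
    return per_pc, related


def run_pipeline(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    collection: GeneSetCollection,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full attribution workflow; see the module docstring."""
    ann = align_annotation(ann, matrix)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # (1) optional normalization, then the low-expression filter
    if config.quantile:
        matrix = quantile_normalize(matrix)
    filtered, mask = filter_low_expression(matrix, config.filter_spec)
    universe = set(filtered.index)
    if out is not None:
        write_expression_matrix(filtered, out / "filtered_expr.tsv")

    # (2) pan-PCA and factor attribution by eta-squared
    pan_pca = run_pca_svd(scale_center(filtered, unit_variance=config.scale_genes))
    over = _overexpression_split(ann)
    eta = {
        "cell_line": pc_factor_association(pan_pca, ann, "cell_line"),
        "overexpression": pc_factor_association(pan_pca, ann, over),
    }
    report = PipelineReport(
        config_hash=config.hash(),
        n_genes_input=matrix.shape[0],
        n_genes_filtered=filtered.shape[0],
        pan_variance_fraction={
            pc: float(v) for pc, v in pan_pca.variance_fraction.items()
        },
        pan_eta_squared={k: {pc: float(v) for pc, v in s.items()} for k, s in eta.items()},
        pan_dominant_pc={k: str(s.idxmax()) for k, s in eta.items()},
    )
    if out is not None:
        pan_pca.scores.to_csv(out / "pan_pca_scores.tsv", sep="\t")

    # (3)+(4) per-cell-line PCA, signature clustering, attribution
    signatures = {}
    for line in sorted(ann["cell_line"].unique()):
        cols = list(ann.index[ann["cell_line"] == line])
        sub = filtered[cols]
        line_pca = run_pca_svd(scale_center(sub, unit_variance=config.scale_genes))
        per_pc, related = attribute_components(sub, ann.loc[cols], line_pca, config)
        report.per_line[line] = {
            "variance_fraction": {
                pc: float(v) for pc, v in line_pca.variance_fraction.head(5).items()
            },
            "components": per_pc,
        }
        if related is None:
            report.warnings.append(f"{line}: no overexpression-related component")
            continue
        report.overexpression_components[line] = related
        sig = select_signature(line_pca, related, config.w)
        signatures[line] = sig
        report.signature_sizes[line] = len(sig)
        if out is not None:
            sig.to_frame().to_csv(out / f"signature_{line}.tsv", sep="\t", index=False)

    # (5) ORA of each overexpression-related signature
    for line, sig in signatures.items():
        table = run_ora(set(sig.gene_ids), collection, universe, config.ora_alpha)
        report.ora_significant_counts[line] = int(table["significant"].sum())
        if out is not None:
            write_ora_table(table, out / f"ora_{line}.tsv")

    # (6) moderated-t per control type, intersections across cell lines
    lines = sorted(ann["cell_line"].unique())
    if len(lines) >= 2:
        for control in ("VECTOR", "WT"):
            results = {
                line: run_contrast(filtered, ann, line, control=control)
                for line in lines
            }
            call = call_and_intersect(results, config.alpha_adj)
            for line, genes in call.per_model.items():
                report.de_significant_counts[f"{line}_vs_{control}"] = len(genes)
            if control == "VECTOR":
                report.de_intersection_size = len(call.intersection)
                if out is not None:
                    for line, res in results.items():
                        write_de_table(res, out / f"de_{line}_vs_{control}.tsv", config.alpha_adj)
                    (out / "de_intersection.txt").write_text(
                        "\n".join(sorted(call.intersection)) + "\n"
                    )

    # (7) empty-vector-only re-run of the per-line signature analysis
    if config.run_vector_only_rerun:
        keep = ann["condition"].isin(["VECTOR", "OVEREXPR"])
        sub_ann = ann[keep]
        report.vector_only = {}
        for line in sorted(sub_ann["cell_line"].unique()):
            cols = list(sub_ann.index[sub_ann["cell_line"] == line])
            if len(cols) < 3:
                continue
            sub = filtered[cols]
            line_pca = run_pca_svd(scale_center(sub, unit_variance=config.scale_genes))
            per_pc, related = attribute_components(sub, sub_ann.loc[cols], line_pca, config)
            entry = {"components": per_pc, "overexpression_component": related}
            if related is not None:
                sig = select_signature(line_pca, related, config.w)
                entry["signature_size"] = len(sig)
                if line in signatures:
                    full = set(signatures[line].gene_ids)
                    part = set(sig.gene_ids)
                    union = full | part
                    entry["jaccard_vs_full_design"] = (
                        len(full & part) / len(union) if union else 1.0
                    )
            report.vector_only[line] = entry

    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report
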