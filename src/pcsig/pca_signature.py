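"""PCA by SVD of the gene-standardized matrix and loading-threshold signatures.

Samples are the observations and genes the variables: each gene row is
centered and scaled to unit standard deviation, the sample-space SVD yields
per-sample scores and unit-norm per-gene loadings, and a gene signature for a
component collects the genes whose loading magnitude exceeds ``W / sqrt(N)``
with N the number of genes entering the decomposition (recommended W > 3;
default 3.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_W = 3.5


def scale_center(matrix: pd.DataFrame, unit_variance: bool = True) -> pd.DataFrame:
    """Center each gene row; with ``unit_variance`` also scale to sd 1.

    Zero-variance genes carry no information for PCA and are dropped with a
    warning; an all-constant matrix is an error. Standard deviation uses the
    n-1 denominator.

    With heteroskedastic noise (gene variances from a heavy-tailed prior),
    unit-variance scaling hands every background gene the same weight as a
    responding gene and can dilute a planted effect's loadings below the
    ``W / sqrt(N)`` threshold; centering without scaling preserves the
    effect's natural variance and is what the pipeline uses by default.
    """
    if matrix.shape[1] < 2:
        raise ValueError("scaling needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("every gene has zero variance; nothing to decompose")
    if not keep.all():
        dropped = matrix.index[~keep]
        log.warning("excluding %d zero-variance gene(s) before PCA", len(dropped))
    values = values[keep]
    centered = values - values.mean(axis=1, keepdims=True)
    if unit_variance:
        centered = centered / sd[keep, None]
    return pd.DataFrame(centered, index=matrix.index[keep], columns=matrix.columns)


@dataclass
class PCAResult:
    """SVD decomposition of a scaled genes x samples matrix.

    ``loadings`` (genes x K) has unit-norm columns, ``scores`` (samples x K)
    are the sample coordinates, ``variance_fraction`` the share of total
    variance per component, and ``n_genes`` the N of the signature threshold.
    Component columns are named PC1, PC2, ... in order of decreasing variance.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: pd.Series
    n_genes: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def run_pca_svd(scaled: pd.DataFrame, k: int | None = None) -> PCAResult:
    """Decompose a scaled/centered matrix by SVD.

    ``k`` defaults to min(samples - 1, 10). Variance fractions are squared
    singular values over their total (all components, not just the retained
    ones). Each component is oriented so that its largest-magnitude loading
    is positive, making the decomposition deterministic.
    """
    n_genes, n_samples = scaled.shape
    if n_samples < 3:
        raise ValueError("PCA needs at least 3 samples for a meaningful PC2")
    max_k = n_samples - 1
    k = min(max_k, 10) if k is None else min(k, max_k)

    # samples x genes: rows are observations, columns (genes) are centered
    u, s, vt = np.linalg.svd(scaled.to_numpy(dtype=float).T, full_matrices=False)
    total = float((s**2).sum())
    var_frac = (s[:max_k] ** 2) / total

    loadings = vt[:k].T  # genes x k, unit columns
    scores = u[:, :k] * s[:k]

    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        pivot = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=scaled.index, columns=pcs),
        scores=pd.DataFrame(scores, index=scaled.columns, columns=pcs),
        variance_fraction=pd.Series(
            var_frac, index=[f"PC{i + 1}" for i in range(max_k)], name="variance_fraction"
        ),
        n_genes=n_genes,
    )


@dataclass
class GeneSignature:
    """Genes whose |loading| on one component exceeds ``W / sqrt(N)``.

    ``members`` maps gene id -> signed loading, sorted by |loading|
    descending.
    """

    source_pc: int
    w: float
    threshold: float
    members: dict[str, float] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene_id": list(self.members),
                "loading": list(self.members.values()),
            }
        )
        frame["abs_loading"] = frame["loading"].abs()
        frame["threshold"] = self.threshold
        frame["source_pc"] = self.source_pc
        return frame


def select_signature(pca: PCAResult, pc: int, w: float = DEFAULT_W) -> GeneSignature:
    """Select the signature of component ``pc`` (1-based) at weight ``w``.

    Membership is the strict exceedance ``|loading| > w / sqrt(N)``; an empty
    signature is legal.
    """
    if not 1 <= pc <= pca.k:
        raise ValueError(f"pc must be in 1..{pca.k}, got {pc}")
    if w <= 0:
        raise ValueError("W must be positive")
    threshold = w / np.sqrt(pca.n_genes)
    col = pca.loadings[f"PC{pc}"]
    hits = col[col.abs() > threshold]
    ordered = hits.reindex(hits.abs().sort_values(ascending=False, kind="stable").index)
    if ordered.empty:
        log.info("signature on PC%d at W=%.3g is empty", pc, w)
    return GeneSignature(
        source_pc=pc, w=w, threshold=float(threshold), members=dict(ordered)
    )


def pc_factor_association(
    pca: PCAResult, ann: pd.DataFrame, factor: str | pd.Series
) -> pd.Series:
    """Eta-squared of each PC's scores against a grouping factor.

    ``factor`` is an annotation column name (``cell_line`` or ``condition``)
    or an explicit per-sample label series. Eta-squared is the between-group
    sum of squares over the total sum of squares, in [0, 1]; the PC with the
    maximal value is the component that factor dominates.
    """
    if isinstance(factor, str):
        labels = ann.loc[pca.scores.index, factor]
    else:
        labels = factor.loc[pca.scores.index]
    labels = pd.Series(labels, index=pca.scores.index).astype(str)
    if labels.nunique() < 2:
        raise ValueError("factor must define at least 2 groups")

    out = {}
    for pc in pca.scores.columns:
        scores = pca.scores[pc]
        total = float(((scores - scores.mean()) ** 2).sum())
        if total == 0:
            out[pc] = 0.0
            continue
        between = sum(
            len(grp) * (grp.mean() - scores.mean()) ** 2
            for _, grp in scores.groupby(labels, observed=True)
        )
        out[pc] = float(between / total)
    return pd.Series(out, name="eta_squared")
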