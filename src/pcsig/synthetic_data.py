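"""Seeded generator of the two-cell-line x three-condition expression design.

The additive model on the log2 scale is

    x[g, s] = mu_g + L_g * [line(s) = LINE_B]
            + delta_g * [condition(s) = OVEREXPR]
            + Q_g * [line(s) = LINE_B and condition(s) = VECTOR]
            + eps[g, s]

with baseline mu_g ~ N(7, 1.5^2), a cell-line offset L_g ~ N(0,
line_effect_sd^2) on every gene (the dominant confounder), an overexpression
shift delta_g = de_effect on a planted subset of genes (the signal the
pipeline must recover), an optional empty-vector quirk Q_g on one line, and
noise eps ~ N(0, sigma2_g) with gene variances drawn from a scaled
inverse-chi-square prior sigma2_g ~ s2_0 * d0 / chi2_{d0} — the same family
the moderated t assumes.

Planted pathways contain a fixed fraction of their members from the planted
overexpression genes; the remaining pathways are random decoys. The returned
truth object is the oracle for every downstream recovery test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pcsig.io_formats import (
    GeneSet,
    GeneSetCollection,
    write_expression_matrix,
    write_gmt,
    write_sample_annotation,
)

LINES = ("LINE_A", "LINE_B")
CONDITIONS = ("WT", "VECTOR", "OVEREXPR")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment; defaults are the study-like
    conditions every acceptance simulation runs under."""

    n_genes: int = 5000
    n_reps: int = 3
    line_effect_sd: float = 1.2
    n_de_genes: int = 150
    de_effect: float = 2.0
    vector_quirk_sd: float = 0.0
    d0_true: float = 4.0
    s2_0_true: float = 0.05
    n_pathways: int = 51
    pathway_size: int = 40
    n_planted_pathways: int = 1
    planted_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (downstream variances undefined)")
        for name in ("line_effect_sd", "vector_quirk_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.n_planted_pathways > self.n_pathways:
            raise ValueError("n_planted_pathways cannot exceed n_pathways")


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    de_gene_ids: list[str]
    gene_variances: pd.Series
    line_offsets: pd.Series
    quirk_offsets: pd.Series
    planted_pathways: list[str]
    seed: int
    config: SimConfig = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "de_gene_ids": self.de_gene_ids,
            "gene_variances": self.gene_variances.round(10).to_dict(),
            "line_offsets": self.line_offsets.round(10).to_dict(),
            "quirk_offsets": self.quirk_offsets.round(10).to_dict(),
            "planted_pathways": self.planted_pathways,
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
        }


def generate_experiment(
    config: SimConfig = SimConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection, SyntheticTruth]:
    """Simulate the full bundle: matrix, annotation, gene sets, truth.

    Deterministic for a given config (all randomness flows through one
    generator seeded from ``config.seed``). Samples are named
    LINE_CONDITION_rep and ordered line-major, condition-minor.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    samples, line_of, cond_of = [], [], []
    for line in LINES:
        for cond in CONDITIONS:
            for rep in range(1, config.n_reps + 1):
                samples.append(f"{line}_{cond}_{rep}")
                line_of.append(line)
                cond_of.append(cond)
    ann = pd.DataFrame(
        {"cell_line": line_of, "condition": pd.Categorical(cond_of, categories=list(CONDITIONS))},
        index=pd.Index(samples, name="sample_id"),
    )

    mu = rng.normal(7.0, 1.5, config.n_genes)
    line_offset = rng.normal(0.0, config.line_effect_sd, config.n_genes)
    sigma2 = (
        config.s2_0_true
        * config.d0_true
        / rng.chisquare(config.d0_true, config.n_genes)
    )
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    delta = np.zeros(config.n_genes)
    delta[de_idx] = config.de_effect
    quirk = (
        rng.normal(0.0, config.vector_quirk_sd, config.n_genes)
        if config.vector_quirk_sd > 0
        else np.zeros(config.n_genes)
    )

    is_line_b = np.array([l == "LINE_B" for l in line_of])
    is_over = np.array([c == "OVEREXPR" for c in cond_of])
    is_quirk = is_line_b & np.array([c == "VECTOR" for c in cond_of])

    signal = (
        mu[:, None]
        + np.outer(line_offset, is_line_b)
        + np.outer(delta, is_over)
        + np.outer(quirk, is_quirk)
    )
    noise = rng.normal(0.0, np.sqrt(sigma2)[:, None], signal.shape)
    matrix = pd.DataFrame(signal + noise, index=genes, columns=samples)

    collection = _plant_pathways(rng, config, genes, de_idx)

    truth = SyntheticTruth(
        de_gene_ids=[genes[i] for i in sorted(de_idx)],
        gene_variances=pd.Series(sigma2, index=genes, name="sigma2"),
        line_offsets=pd.Series(line_offset, index=genes, name="line_offset"),
        quirk_offsets=pd.Series(quirk, index=genes, name="quirk_offset"),
        planted_pathways=[s.name for s in collection if s.name.startswith("PLANTED")],
        seed=config.seed,
        config=config,
    )
    return matrix, ann, collection, truth


def _plant_pathways(
    rng: np.random.Generator, config: SimConfig, genes: list[str], de_idx: np.ndarray
) -> GeneSetCollection:
    """Planted sets mix DE and background genes; decoys are pure background."""
    collection = GeneSetCollection()
    de_set = set(de_idx.tolist())
    background = np.array([i for i in range(config.n_genes) if i not in de_set])
    n_from_de = int(round(config.planted_fraction * config.pathway_size))
    n_from_de = min(n_from_de, len(de_idx))
    for p in range(config.n_pathways):
        if p < config.n_planted_pathways:
            de_part = rng.choice(de_idx, size=n_from_de, replace=False)
            bg_part = rng.choice(
                background, size=config.pathway_size - n_from_de, replace=False
            )
            members = np.concatenate([de_part, bg_part])
            name = f"PLANTED_PATHWAY_{p + 1}"
        else:
            members = rng.choice(background, size=config.pathway_size, replace=False)
            name = f"DECOY_PATHWAY_{p - config.n_planted_pathways + 1:03d}"
        collection.sets[name] = GeneSet(
            name=name,
            description="synthetic gene set",
            members=tuple(genes[i] for i in sorted(members)),
        )
    return collection


def write_fixture_bundle(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    collection: GeneSetCollection,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write expr.tsv, ann.tsv, sets.gmt and truth.json into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": write_expression_matrix(matrix, directory / "expr.tsv"),
        "ann": write_sample_annotation(ann, directory / "ann.tsv"),
        "gmt": write_gmt(collection, directory / "sets.gmt"),
        "truth": directory / "truth.json",
    }
    with open(paths["truth"], "w") as handle:
        json.dump(truth.to_json_dict(), handle, indent=1)
    return paths
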