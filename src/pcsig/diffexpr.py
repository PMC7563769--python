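"""Moderated two-sample t-tests with empirical-Bayes variance shrinkage.

With only a handful of arrays per group, gene-wise variances are noisy. The
moderated t replaces each gene's pooled variance s2_g by the posterior

    s2_post = (d0 * s2_0 + d_g * s2_g) / (d0 + d_g)

where the prior (d0, s2_0) is estimated from all genes by moment matching on
log variances (trigamma inversion), and refers the statistic to a
t-distribution with d0 + d_g degrees of freedom. d0 = 0 recovers the
classical pooled t-test; d0 = inf shrinks every variance to s2_0.

P-values are Benjamini-Hochberg adjusted; the default significance call is
adjusted p < 1e-4, and findings from the two cell lines are combined by set
intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA_ADJ = 1e-4
_TINY = np.nextafter(0.0, 1.0)


def genewise_stats(
    matrix: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Per-gene mean difference and pooled within-group variance.

    ``group_a`` and ``group_b`` are disjoint sample-id lists of size >= 2
    each (A is the overexpression group by convention, so mean_diff is
    overexpression minus control). Returns columns mean_diff, s2_g, d_g.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    d_g = na + nb - 2
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return pd.DataFrame(
        {
            "mean_diff": a.mean(axis=1) - b.mean(axis=1),
            "s2_g": (ssa + ssb) / d_g,
            "d_g": d_g,
            "n_a": na,
            "n_b": nb,
        },
        index=matrix.index,
    )


def estimate_eb_prior(s2: np.ndarray | pd.Series, d_g: int) -> tuple[float, float]:
    """Estimate the scaled-inverse-chi-square prior (d0, s2_0) for variances.

    Moment matching on z = log(s2): under the model, var(z) equals
    trigamma(d_g/2) + trigamma(d0/2), so d0 solves

        trigamma(d0/2) = var(z) - trigamma(d_g/2)

    (monotone bisection on d0 in (1e-4, 1e4)); s2_0 follows from mean(z)
    after removing both chi-square biases. When the observed spread of log
    variances does not exceed that implied by d_g alone, d0 = inf and s2_0
    is the bias-corrected geometric mean (complete shrinkage). Zero
    variances are excluded from estimation.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        raise ValueError("need at least 2 positive variances to estimate a prior")
    z = np.log(s2)
    mean_z = z.mean()
    if z.var(ddof=1) < 1e-15:
        # literally identical variances: complete shrinkage to the common value
        return float("inf"), float(np.exp(mean_z))
    # bias and spread of log s2_g given the true variance, chi-square algebra
    z_bias = special.digamma(d_g / 2.0) - np.log(d_g / 2.0)
    excess = z.var(ddof=1) - special.polygamma(1, d_g / 2.0)
    lo, hi = 1e-4, 1e4
    if excess <= special.polygamma(1, hi / 2.0):
        # spread fully explained by sampling noise: infinite prior df
        return float("inf"), float(np.exp(mean_z - z_bias))
    if excess >= special.polygamma(1, lo / 2.0):  # pragma: no cover - absurd spread
        d0 = lo
    else:
        d0 = optimize.brentq(
            lambda d: special.polygamma(1, d / 2.0) - excess, lo, hi, xtol=1e-12
        )
    # remove both log-scale biases: +z_bias(d_g) from sampling, -z_bias(d0)
    # from the inverse-chi-square prior draw
    s2_0 = np.exp(mean_z - z_bias + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s2_0)


@dataclass
class ModeratedTestResult:
    """Per-gene moderated-t table plus the shared prior.

    ``table`` columns: mean_diff, s2_g, d_g, s2_post, t_mod, df_total, p,
    adj_p. ``d0`` may be inf (complete shrinkage).
    """

    table: pd.DataFrame
    d0: float
    s2_0: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha_adj: float = DEFAULT_ALPHA_ADJ) -> set[str]:
        hits = self.table.index[self.table["adj_p"] < alpha_adj]
        return set(hits)


def moderated_t(
    stats_table: pd.DataFrame, d0: float, s2_0: float
) -> ModeratedTestResult:
    """Compute shrunken-variance t statistics and two-sided p-values.

    With d0 = 0 this is exactly the classical pooled two-sample t-test; with
    d0 = inf every posterior variance equals s2_0 and the reference
    distribution is normal. A zero posterior variance with a nonzero mean
    difference is guarded to the smallest positive p.
    """
    if d0 < 0 or s2_0 <= 0:
        raise ValueError("prior requires d0 >= 0 and s2_0 > 0")
    s2_g = stats_table["s2_g"].to_numpy(dtype=float)
    d_g = stats_table["d_g"].to_numpy(dtype=float)
    diff = stats_table["mean_diff"].to_numpy(dtype=float)
    inv_n = 1.0 / stats_table["n_a"].to_numpy() + 1.0 / stats_table["n_b"].to_numpy()

    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s2_0)
        df_total = np.full_like(s2_g, np.inf)
    else:
        s2_post = (d0 * s2_0 + d_g * s2_g) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * inv_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # degenerate genes: zero posterior variance but a real mean shift
    degenerate = (se == 0) & (diff != 0)
    p = np.where(degenerate, _TINY, np.clip(p, _TINY, 1.0))
    with np.errstate(invalid="ignore"):
        t_mod = np.where(degenerate, np.sign(diff) * np.inf, t_mod)

    table = stats_table.copy()
    table["s2_post"] = s2_post
    table["t_mod"] = t_mod
    table["df_total"] = df_total
    table["p"] = p
    table["adj_p"] = bh_adjust(p)
    return ModeratedTestResult(table=table, d0=float(d0), s2_0=float(s2_0))


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    cell_line: str,
    control: str = "VECTOR",
    prior: tuple[float, float] | None = None,
) -> ModeratedTestResult:
    """One per-cell-line model: overexpression versus one control type.

    Separate models per control type follow the study design; ``control`` is
    ``VECTOR`` (empty vector, the primary comparison) or ``WT``. The prior
    is estimated from this model's variances unless supplied.
    """
    sub = ann[ann["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"no samples for cell line {cell_line!r}")
    group_a = sub.index[sub["condition"] == "OVEREXPR"].tolist()
    group_b = sub.index[sub["condition"] == control].tolist()
    stats_table = genewise_stats(matrix, group_a, group_b)
    if prior is None:
        prior = estimate_eb_prior(stats_table["s2_g"], int(stats_table["d_g"].iloc[0]))
    return moderated_t(stats_table, *prior)


@dataclass
class SignificanceCall:
    """Per-model significant sets and their cross-cell-line intersection."""

    alpha_adj: float
    per_model: dict[str, set[str]]
    intersection: set[str]


def call_and_intersect(
    results: dict[str, ModeratedTestResult], alpha_adj: float = DEFAULT_ALPHA_ADJ
) -> SignificanceCall:
    """Apply the adjusted-p threshold per model and intersect across models.

    All models must cover the same gene universe (genes common to both cell
    lines' filtered matrices); a mismatch is an error naming the difference.
    """
    if len(results) < 1:
        raise ValueError("need at least one model")
    universes = [set(r.gene_ids) for r in results.values()]
    reference = universes[0]
    for name, uni in zip(results, universes):
        if uni != reference:
            diff = sorted(reference ^ uni)
            raise ValueError(
                f"gene universe of model {name!r} differs; symmetric difference: "
                f"{diff[:10]}{'...' if len(diff) > 10 else ''}"
            )
    per_model = {name: r.significant(alpha_adj) for name, r in results.items()}
    intersection = set.intersection(*per_model.values())
    return SignificanceCall(
        alpha_adj=alpha_adj, per_model=per_model, intersection=intersection
    )


def write_de_table(result: ModeratedTestResult, path, alpha_adj: float = DEFAULT_ALPHA_ADJ):
    """Persist a result as TSV: gene_id, mean_diff, t_mod, df, p, adj_p, significant."""
    out = result.table[["mean_diff", "t_mod", "df_total", "p", "adj_p"]].copy()
    out.columns = ["mean_diff", "t_mod", "df", "p", "adj_p"]
    out["significant"] = out["adj_p"] < alpha_adj
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    return path
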