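"""Over-representation analysis by the upper-tail hypergeometric test.

A gene signature of size n drawn from a universe of Nu genes overlaps a
pathway of (universe-restricted) size m in k genes; the ORA p-value is
P(X >= k) for X ~ Hypergeometric(Nu, m, n). The tail is summed in log space
from exact log-pmf terms, so minuscule p-values keep relative accuracy.
BH-adjusted values are reported informatively but the significance flag uses
the raw p at alpha (default 0.05), reflecting the exploratory use of ORA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from pcsig.diffexpr import bh_adjust
from pcsig.io_formats import GeneSetCollection

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

ORA_COLUMNS = [
    "rank",
    "pathway",
    "n_pathway",
    "n_pathway_universe",
    "n_overlap",
    "n_signature",
    "n_universe",
    "p_value",
    "adj_p",
    "significant",
]


def hypergeom_upper_tail(nu: int, m: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population nu, successes m, draws n).

    Feasibility requires max(0, m + n - nu) <= k <= min(m, n); k = 0 gives
    p = 1. The tail is accumulated from log-pmf terms via logsumexp.
    """
    if not (0 <= m <= nu and 0 <= n <= nu):
        raise ValueError(f"need 0 <= m, n <= Nu; got Nu={nu}, m={m}, n={n}")
    lo, hi = max(0, m + n - nu), min(m, n)
    if not lo <= k <= hi:
        raise ValueError(f"infeasible overlap k={k}; feasible range [{lo}, {hi}]")
    if k == 0:
        return 1.0
    support = np.arange(k, hi + 1)
    log_terms = stats.hypergeom.logpmf(support, nu, m, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def run_ora(
    signature: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test a signature against every gene set in a collection.

    The universe is the filtered gene list the signature was drawn from;
    signature members outside it are dropped with a logged count, and each
    pathway is restricted to the universe before testing (sets that do not
    intersect the universe are skipped). Rows are sorted by p ascending,
    ties by pathway name, and carry both the pathway's full parsed size
    (``n_pathway``) and the universe-restricted size actually tested
    (``n_pathway_universe``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature)
    outside = signature - universe
    if outside:
        log.warning("dropping %d signature gene(s) outside the universe", len(outside))
        signature &= universe

    nu, n = len(universe), len(signature)
    rows = []
    for gene_set in collection:
        members_in_universe = set(gene_set.members) & universe
        m = len(members_in_universe)
        if m == 0:
            continue
        k = len(members_in_universe & signature)
        rows.append(
            {
                "pathway": gene_set.name,
                "n_pathway": len(gene_set.members),
                "n_pathway_universe": m,
                "n_overlap": k,
                "n_signature": n,
                "n_universe": nu,
                "p_value": hypergeom_upper_tail(nu, m, n, k),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    table = pd.DataFrame(rows).sort_values(
        ["p_value", "pathway"], kind="stable", ignore_index=True
    )
    table["adj_p"] = bh_adjust(table["p_value"])
    table["significant"] = table["p_value"] < alpha
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table[ORA_COLUMNS]


def write_ora_table(table: pd.DataFrame, path) -> None:
    """Persist an ORA table as TSV in the documented column order."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
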