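"""Cross-array quantile normalization and the low-expression filter.

The filter keeps a gene when its signal reaches a threshold (default 5 on the
log2 scale) in strictly more than a minimum number of arrays (default 3).
Quantile normalization is a desk-scale stand-in for the cross-array step of
full RMA preprocessing; it is off by default for inputs that arrive already
normalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Low-expression filter constants.

    A gene is kept when ``count(values >= signal_threshold)`` exceeds
    ``min_arrays`` (strictly when ``strict_arrays``, the default reading of
    "present in more than 3 arrays").
    """

    signal_threshold: float = 5.0
    min_arrays: int = 3
    strict_arrays: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal_threshold) and self.signal_threshold > 0:
            raise ValueError("signal_threshold must be finite or -inf")
        if self.min_arrays < 0:
            raise ValueError("min_arrays must be non-negative")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the per-rank mean distribution.

    After normalization each column holds the same multiset of values (the
    mean of the input columns' order statistics); ties within a column get
    the mean of the reference values at the tied ranks.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average reference values over tied ranks so tied inputs stay tied
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        uniq, inverse = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inverse, weights=ranked)
            counts = np.bincount(inverse)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_low_expression(
    matrix: pd.DataFrame, spec: FilterSpec = FilterSpec()
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop genes with too few arrays at or above the signal threshold.

    Returns the surviving submatrix (row order preserved) and a boolean mask
    over the input genes. With ``min_arrays >= n_samples`` under the strict
    reading no gene can pass; that yields a warning and an empty result.
    """
    n_samples = matrix.shape[1]
    if spec.strict_arrays and spec.min_arrays >= n_samples:
        warnings.warn(
            f"min_arrays={spec.min_arrays} with strict comparison cannot be met "
            f"by {n_samples} samples; all genes removed",
            stacklevel=2,
        )
    present = (matrix.to_numpy(dtype=float) >= spec.signal_threshold).sum(axis=1)
    if spec.strict_arrays:
        keep = present > spec.min_arrays
    else:
        keep = present >= spec.min_arrays
    mask = pd.Series(keep, index=matrix.index, name="kept")
    log.info("low-expression filter: %d of %d genes kept", int(mask.sum()), len(mask))
    return matrix.loc[mask], mask


def mean_expression_histogram(
    matrix: pd.DataFrame, bins: int = 50
) -> pd.DataFrame:
    """Histogram of per-gene mean expression, as a table.

    Diagnostic support for choosing the filter constants from the data; it
    does not itself filter anything.
    """
    means = matrix.mean(axis=1).to_numpy()
    counts, edges = np.histogram(means, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
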