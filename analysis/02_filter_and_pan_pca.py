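"""Low-expression filtering and the pan-PCA over all samples.

Expected outcome under the simulated design: the cell-line difference
dominates PC1 (by far the largest variance fraction), while the
overexpression contrast surfaces on PC2 — the main confounding structure
this analysis exists to untangle.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pcsig.pca_signature import pc_factor_association, run_pca_svd, scale_center
from pcsig.preprocess import filter_low_expression
from pcsig.synthetic_data import SimConfig, generate_experiment

RESULTS = Path("results")
SEED = 1


def main() -> None:
    matrix, ann, _, _ = generate_experiment(SimConfig(seed=SEED))
    filtered, mask = filter_low_expression(matrix)
    print(f"filter (signal >= 5 in > 3 arrays): {mask.sum()} of {len(mask)} genes kept")

    pca = run_pca_svd(scale_center(filtered, unit_variance=False))
    over = pd.Series(
        np.where(ann["condition"] == "OVEREXPR", "OVEREXPR", "CONTROL"), index=ann.index
    )
    table = pd.DataFrame(
        {
            "variance_fraction": pca.variance_fraction.head(pca.k),
            "eta2_cell_line": pc_factor_association(pca, ann, "cell_line"),
            "eta2_overexpression": pc_factor_association(pca, ann, over),
        }
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "02_pan_pca.tsv", sep="\t", float_format="%.6g")
    print(table.head(4).round(4).to_string())
    print(
        f"\nPC1 carries {100 * table['variance_fraction'].iloc[0]:.1f}% of variance "
        f"and tracks the cell line (eta^2 = {table['eta2_cell_line'].iloc[0]:.3f}); "
        f"PC2 ({100 * table['variance_fraction'].iloc[1]:.1f}%) tracks overexpression "
        f"(eta^2 = {table['eta2_overexpression'].iloc[1]:.3f}). The cell-line "
        "difference is the dominant confounder, so the signature search moves "
        "to per-line analyses next."
    )


if __name__ == "__main__":
    main()
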