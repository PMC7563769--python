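"""Moderated-t differential expression per control type and per line.

Each model contrasts overexpressing samples against one control type within
one cell line, with empirical-Bayes variance shrinkage across genes; gene
sets significant in both lines are intersected. With three replicates per
group the posterior t has ~8 degrees of freedom, which bounds how small the
BH-adjusted p-values can get — the strict 1e-4 call is reported alongside
more attainable thresholds to make that power ceiling visible.
"""

from pathlib import Path

import pandas as pd

from pcsig.diffexpr import call_and_intersect, run_contrast
from pcsig.preprocess import filter_low_expression
from pcsig.synthetic_data import SimConfig, generate_experiment

RESULTS = Path("results")
SEED = 1


def main() -> None:
    matrix, ann, _, truth = generate_experiment(SimConfig(seed=SEED))
    filtered, _ = filter_low_expression(matrix)
    de = set(truth.de_gene_ids)
    lines = sorted(ann["cell_line"].unique())

    rows = []
    for control in ("VECTOR", "WT"):
        results = {
            line: run_contrast(filtered, ann, line, control=control)
            for line in lines
        }
        for alpha in (1e-4, 1e-3, 1e-2):
            call = call_and_intersect(results, alpha)
            inter = call.intersection
            rows.append(
                {
                    "control": control,
                    "alpha_adj": alpha,
                    **{f"n_{line}": len(call.per_model[line]) for line in lines},
                    "n_intersection": len(inter),
                    "recall_of_planted": len(inter & de) / len(de),
                    "false_positives": len(inter - set(truth.de_gene_ids)),
                }
            )
        for line in lines:
            r = results[line]
            print(f"{line} vs {control}: prior d0 = {r.d0:.2f}, s2_0 = {r.s2_0:.4f}")

    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "04_de_summary.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print()
    print(table.to_string(index=False))

    strict = table[(table["control"] == "VECTOR") & (table["alpha_adj"] == 1e-4)]
    relaxed = table[(table["control"] == "VECTOR") & (table["alpha_adj"] == 1e-2)]
    print(
        f"\nAt adj p < 1e-4 the cross-line intersection recovers "
        f"{100 * strict['recall_of_planted'].iloc[0]:.0f}% of planted genes: "
        "with n = 3 per group the moderated t has ~8 df, so even a noiseless "
        "gene cannot clear that threshold after BH correction at this effect "
        f"size. At adj p < 0.01 recovery is "
        f"{100 * relaxed['recall_of_planted'].iloc[0]:.0f}% with "
        f"{relaxed['false_positives'].iloc[0]} false positives — the ranking "
        "is sound; the strict cut is beyond the design's power."
    )


if __name__ == "__main__":
    main()
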