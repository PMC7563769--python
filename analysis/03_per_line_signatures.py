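"""Per-cell-line PCA, component attribution and signature recovery.

For each cell line separately: decompose the filtered matrix, select the
W = 3.5 loading signature of the first two components, cluster the samples
on each signature, and attribute a component to overexpression when the
clustering splits overexpressing samples from both control types. The
planted truth then scores how well the attributed signature recovers the
genes that actually respond.
"""

from pathlib import Path

import pandas as pd

from pcsig.pipeline import PipelineConfig, run_pipeline
from pcsig.pca_signature import run_pca_svd, scale_center, select_signature
from pcsig.preprocess import filter_low_expression
from pcsig.synthetic_data import SimConfig, generate_experiment

RESULTS = Path("results")
SEED = 1


def main() -> None:
    matrix, ann, collection, truth = generate_experiment(SimConfig(seed=SEED))
    report = run_pipeline(matrix, ann, collection, PipelineConfig())
    filtered, _ = filter_low_expression(matrix)
    de = set(truth.de_gene_ids)

    rows = []
    for line, per_line in report.per_line.items():
        for pc, entry in per_line["components"].items():
            cols = list(ann.index[ann["cell_line"] == line])
            pca = run_pca_svd(scale_center(filtered[cols], unit_variance=False))
            sig = set(select_signature(pca, pc).gene_ids)
            rows.append(
                {
                    "cell_line": line,
                    "pc": pc,
                    "signature_size": entry["signature_size"],
                    "concordance_overexpression": entry.get(
                        "concordance_overexpression"
                    ),
                    "attributed": report.overexpression_components.get(line) == pc,
                    "recall_of_planted": len(sig & de) / len(de),
                    "false_inclusion": len(sig - de) / max(1, len(sig)),
                }
            )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "03_signatures.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print(table.round(3).to_string(index=False))

    attributed = table[table["attributed"]]
    print(
        f"\nIn both lines the attributed component's clustering separates "
        f"overexpressing samples from both control types (concordance "
        f"{attributed['concordance_overexpression'].min():.2f}); its W=3.5 "
        f"signature recovers {100 * attributed['recall_of_planted'].mean():.1f}% "
        f"of the planted genes at {100 * attributed['false_inclusion'].mean():.1f}% "
        "false inclusion."
    )


if __name__ == "__main__":
    main()
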