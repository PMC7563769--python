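"""Readers and writers for the pipeline's external text formats.

Expression matrices travel as TSV with a sample-id header row and gene ids in
the first column; sample annotations as a three-column TSV; gene sets as GMT.
In memory an expression matrix is a :class:`pandas.DataFrame` (genes on the
index, samples on the columns, log2 intensities) and an annotation is a
DataFrame indexed by sample id with ``cell_line`` and ``condition`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("WT", "VECTOR", "OVEREXPR")

# accepted spellings, case-folded, for the three experimental conditions
_CONDITION_ALIASES = {
    "wt": "WT",
    "wild-type": "WT",
    "wildtype": "WT",
    "wild_type": "WT",
    "vector": "VECTOR",
    "empty-vector": "VECTOR",
    "empty_vector": "VECTOR",
    "overexpr": "OVEREXPR",
    "overexpression": "OVEREXPR",
    "oe": "OVEREXPR",
}


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad tokens, wrong field counts)."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {', '.join(map(str, dup))}")


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix.

    Requires unique gene and sample ids and all-finite float values.
    """
    _check_unique(matrix.index, "gene")
    _check_unique(matrix.columns, "sample")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = matrix.columns[
            [not np.issubdtype(dt, np.number) for dt in matrix.dtypes]
        ].tolist()
        raise FormatError(f"non-numeric expression column(s): {bad}")
    if not np.isfinite(values).all():
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite expression value at gene {matrix.index[g]!r}, "
            f"sample {matrix.columns[s]!r}"
        )
    return matrix


def read_expression_matrix(path: str | Path, *, linear_scale: bool = False) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    The first row holds sample ids, the first column gene ids; row and column
    order are preserved. With ``linear_scale=True`` the values are floored at
    1 and log2-transformed (RMA output is already log2, so the default leaves
    values untouched).
    """
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text suffices
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    _check_unique(matrix.index, "gene")
    _check_unique(matrix.columns, "sample")
    try:
        matrix = matrix.astype(float)
    except ValueError:
        for j, col in enumerate(matrix.columns):
            converted = pd.to_numeric(matrix[col], errors="coerce")
            if converted.isna().any():
                i = int(np.argmax(converted.isna().to_numpy()))
                raise FormatError(
                    f"non-numeric value {matrix.iloc[i, j]!r} at gene "
                    f"{matrix.index[i]!r} (row {i + 2}), sample {col!r} (column {j + 2})"
                ) from None
        raise  # pragma: no cover
    if linear_scale:
        matrix = np.log2(matrix.clip(lower=1.0))
    return validate_expression_matrix(matrix)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a genes x samples matrix as TSV; inverse of the reader."""
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    return path


def read_sample_annotation(
    path: str | Path, *, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read the sample annotation TSV (sample_id, cell_line, condition).

    Condition tokens are mapped case-insensitively onto WT / VECTOR /
    OVEREXPR. When ``matrix`` is given, the sample sets must match exactly
    and the annotation is reordered to the matrix's column order.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "condition"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing column(s): {sorted(missing)}")
    _check_unique(ann["sample_id"], "sample")
    ann = ann.set_index("sample_id")

    mapped = []
    for sid, token in ann["condition"].items():
        key = str(token).strip().casefold()
        if key not in _CONDITION_ALIASES:
            raise FormatError(
                f"unknown condition {token!r} for sample {sid!r}; accepted tokens "
                f"(case-insensitive): {sorted(set(_CONDITION_ALIASES))}"
            )
        mapped.append(_CONDITION_ALIASES[key])
    ann["condition"] = pd.Categorical(mapped, categories=list(CONDITIONS))
    ann["cell_line"] = ann["cell_line"].astype(str)

    if matrix is not None:
        ann = align_annotation(ann, matrix)
    return ann


def align_annotation(ann: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Reorder an annotation to the matrix sample order, erroring on mismatch."""
    ann_ids, mat_ids = set(ann.index), set(matrix.columns)
    if ann_ids != mat_ids:
        only_ann = sorted(ann_ids - mat_ids)
        only_mat = sorted(mat_ids - ann_ids)
        raise FormatError(
            "annotation/matrix sample mismatch; "
            f"annotation-only: {only_ann}, matrix-only: {only_mat}"
        )
    return ann.loc[list(matrix.columns)]


def write_sample_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ann.to_csv(path, sep="\t", index_label="sample_id")
    return path


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered, name-unique collection of gene sets parsed from GMT."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members.

    Duplicate members within a line are collapsed (first occurrence kept);
    file order of the sets is preserved.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected name, description and at least one member"
                )
            name, description, *members = fields
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = tuple(dict.fromkeys(m for m in members if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            collection.sets[name] = GeneSet(name, description, members)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for gene_set in collection:
            handle.write(
                "\t".join([gene_set.name, gene_set.description, *gene_set.members]) + "\n"
            )
    return path
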