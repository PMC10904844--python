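"""Shared TSV/JSON I/O conventions for all pipeline stages.

Expression matrices are genes x samples TSV with gene ids in the first
column; metadata is (sample_id, group) TSV with group in {tumor, normal};
survival tables are (id, time_months, event, expression) TSV; traces are
(well, assay, phase, timepoint, OCR, ECAR) TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .diffexp import ExpressionCohort

__all__ = [
    "write_expression", "read_expression",
    "write_de_table", "read_de_table",
    "write_survival", "read_survival",
    "write_gene_set", "read_gene_set",
    "write_json", "read_json",
]


def write_expression(cohort: ExpressionCohort, matrix_path, metadata_path) -> None:
    cohort.to_frame().to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample_id": cohort.sample_ids, "group": cohort.group}) \
        .to_csv(metadata_path, sep="\t", index=False)


def read_expression(matrix_path, metadata_path, cohort_id: str | None = None) -> ExpressionCohort:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    group = meta.set_index("sample_id").loc[mat.columns, "group"].tolist()
    return ExpressionCohort(cohort_id or Path(matrix_path).stem,
                            mat.index.tolist(), mat.columns.tolist(),
                            mat.to_numpy(), group)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path, cohort_id: str | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    if cohort_id:
        table.attrs["cohort_id"] = cohort_id
    return table


def write_survival(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_set(gene_ids, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_ids)) + "\n")


def read_gene_set(path) -> frozenset:
    return frozenset(line.strip() for line in Path(path).read_text().splitlines() if line.strip())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
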