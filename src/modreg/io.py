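"""Plain-text readers and writers for the pipeline's file formats.

All tables are tab-separated; the expression matrix carries gene ids in
the first column and sample ids in the header row. Floats are written
with ten significant digits so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import ExpressionData, WeightedNetwork

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(data: ExpressionData, matrix_path, annotation_path) -> None:
    mat = data.values.copy()
    mat.insert(0, "gene", mat.index)
    mat.to_csv(matrix_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    ann = pd.DataFrame({"sample": data.groups.index, "group": data.groups.to_numpy()})
    write_tsv(ann, annotation_path)


def read_expression(matrix_path, annotation_path, case: str) -> ExpressionData:
    mat = pd.read_csv(matrix_path, sep="\t")
    mat = mat.set_index(mat.columns[0])
    mat.index.name = "gene"
    ann = read_tsv(annotation_path).set_index("sample")["group"]
    if mat.isna().any().any():
        raise ValueError(f"missing values in expression matrix {matrix_path}")
    return ExpressionData(values=mat, groups=ann.reindex(mat.columns), case=case)


def read_probe_annotation(path) -> dict[str, str]:
    ann = read_tsv(path)
    return dict(zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str)))


def write_network(network: WeightedNetwork, path) -> None:
    write_tsv(network.edge_table(), path)


def read_edge_table(path) -> pd.DataFrame:
    return read_tsv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
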