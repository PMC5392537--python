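"""Beta-matrix container conventions and TSV round-trip.

The pipeline's central table is a pandas DataFrame indexed by sample id with
the annotation columns ``age`` (years), ``sex`` ("F"/"M"), ``dataset`` (study
label) and ``tissue``, followed by one column per CpG site (Illumina-style
``cg…`` ids) holding methylation beta values in [0, 1].
"""

from __future__ import annotations

import pandas as pd

META_COLUMNS = ["age", "sex", "dataset", "tissue"]

__all__ = ["META_COLUMNS", "beta_columns", "read_beta_matrix", "write_beta_matrix"]


def beta_columns(matrix: pd.DataFrame) -> list[str]:
    """CpG columns of a beta matrix, in table order."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")


def read_beta_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    missing = [c for c in META_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"beta matrix missing annotation columns: {missing}")
    return matrix
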