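"""Readers and writers for the tabular and tree interchange formats.

Count tables travel as TSV: a header row of feature identifiers, the
first column holding sample identifiers, samples as rows.  Metadata uses
the same convention (first column = sample identifier).  BIOM tables
(HDF5 or JSON dialect) are read through the ``biom`` package when it is
installed and converted to the same samples x features DataFrame.
Trees are newick, niche vectors two-column TSV, bases and regression
results TSV with labelled rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_table_tsv",
    "write_table_tsv",
    "read_metadata_tsv",
    "read_biom_table",
    "read_niche_tsv",
    "write_niche_tsv",
    "write_basis_tsv",
    "read_basis_tsv",
    "write_results_tsv",
]


def read_table_tsv(path) -> pd.DataFrame:
    """Read a samples x features abundance table from TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    if table.isna().any().any():
        raise ValueError(f"{path}: table contains missing values")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in abundance table")
    if (values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample or feature identifiers")
    return table


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read per-sample metadata (first column = sample identifier)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers in metadata")
    return meta


def read_biom_table(path) -> pd.DataFrame:
    """Read a BIOM table (HDF5 or JSON) as samples x features counts.

    Requires the optional ``biom`` dependency; BIOM stores observations
    (features) as rows, so the matrix is transposed on the way in.
    """
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading BIOM requires the biom-format package "
            "(pip install nichebalance[biom]); alternatively convert to TSV"
        ) from exc
    bt = biom.load_table(str(path))
    frame = bt.to_dataframe(dense=True).T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_niche_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].rename("mean_niche")


def write_niche_tsv(niche: pd.Series, path) -> None:
    niche.rename("mean_niche").to_csv(path, sep="\t", index_label="feature_id")


def write_basis_tsv(basis: pd.DataFrame, path) -> None:
    basis.to_csv(path, sep="\t", index_label="node")


def read_basis_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_results_tsv(result, path) -> None:
    """Write the per-(node, term) coefficient table of a RegressionResult."""
    result.summary_frame().to_csv(path, sep="\t", index=False)
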