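"""Readers and writers for the pipeline's table formats.

All tables are UTF-8 CSV/TSV with a mandatory header row and "." decimals;
sparse counts use MatrixMarket with gene/cell sidecar TSVs.  Readers
validate headers strictly so schema drift fails loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flow_readout import (
    COUNT_FIELDS,
    ColonyCall,
    ColonyReadout,
    EngraftmentRecord,
)
from .lda import LDACohort
from .scqc import CountsMatrix

__all__ = [
    "ParseError",
    "read_indexsort_csv", "write_indexsort_csv",
    "read_colony_counts_csv", "write_colony_counts_csv",
    "write_colony_calls_csv",
    "read_division_csv", "write_division_csv",
    "read_lda_csv", "write_lda_csv",
    "read_engraftment_csv", "write_engraftment_csv",
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "write_json",
]


class ParseError(ValueError):
    """A table did not match its expected schema."""


INDEX_META_COLUMNS = ("cell_id", "well", "sort_batch")


def read_indexsort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INDEX_META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"index-sort CSV missing columns: {missing}")
    return df


def write_indexsort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


_COLONY_COLUMNS = ("well_id", "assay") + COUNT_FIELDS


def read_colony_counts_csv(path) -> list[ColonyReadout]:
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in _COLONY_COLUMNS]
    if unknown:
        raise ParseError(f"unknown column(s) in colony counts CSV: {unknown}")
    missing = [c for c in ("well_id",) + COUNT_FIELDS if c not in df.columns]
    if missing:
        raise ParseError(f"colony counts CSV missing columns: {missing}")
    if "assay" not in df.columns:
        df["assay"] = "MS5_multilineage"
    return [
        ColonyReadout(
            well_id=str(row.well_id),
            assay=str(row.assay),
            **{f: int(getattr(row, f)) for f in COUNT_FIELDS},
        )
        for row in df.itertuples(index=False)
    ]


def write_colony_counts_csv(readouts: list[ColonyReadout], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in readouts]).to_csv(path, index=False)


def write_colony_calls_csv(calls: list[ColonyCall], path) -> None:
    rows = []
    for c in calls:
        d = dataclasses.asdict(c)
        d["lineages"] = "/".join(sorted(c.lineages))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_division_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("well_id", "time_hours") if c not in df.columns]
    if missing:
        raise ParseError(f"division CSV missing columns: {missing}")
    df["time_hours"] = pd.to_numeric(df["time_hours"], errors="coerce")
    return df


def write_division_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_lda_csv(path) -> list[LDACohort]:
    df = pd.read_csv(path)
    expected = ["group", "dose", "n", "k_engrafted"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"LDA cohort CSV missing columns: {missing}")
    return [LDACohort.from_dataframe(df, group=g) for g in df["group"].unique()]


def write_lda_csv(cohorts: list[LDACohort], path) -> None:
    pd.concat([c.to_dataframe() for c in cohorts]).to_csv(path, index=False)


_ENGRAFT_COLUMNS = (
    "mouse_id", "pct_CD45dd", "pct_GlyA", "n_human_cells", "n_CD33",
    "n_CD19dd", "n_GlyA_CD45neg", "n_CD71GlyA_CD45neg",
)


def read_engraftment_csv(path) -> list[EngraftmentRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _ENGRAFT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"engraftment CSV missing columns: {missing}")
    return [
        EngraftmentRecord(
            mouse_id=str(row.mouse_id),
            pct_CD45dd=float(row.pct_CD45dd),
            pct_GlyA=float(row.pct_GlyA),
            n_human_cells=int(row.n_human_cells),
            n_CD33=int(row.n_CD33),
            n_CD19dd=int(row.n_CD19dd),
            n_GlyA_CD45neg=int(row.n_GlyA_CD45neg),
            n_CD71GlyA_CD45neg=int(row.n_CD71GlyA_CD45neg),
        )
        for row in df.itertuples(index=False)
    ]


def write_engraftment_csv(records: list[EngraftmentRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_counts_tsv(path, **flags) -> CountsMatrix:
    """Genes x cells TSV, first column the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return CountsMatrix.from_counts(df, **flags)


def write_counts_tsv(matrix: CountsMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path, cells_path, **flags) -> CountsMatrix:
    """MatrixMarket triplet + gene/cell sidecar TSVs (one id per line)."""
    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(genes), len(cells)):
        raise ParseError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    df = pd.DataFrame(mat, index=genes.to_numpy(), columns=cells.to_numpy())
    return CountsMatrix.from_counts(df, **flags)


def write_counts_mtx(matrix: CountsMatrix, mtx_path, genes_path, cells_path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(mtx_path), coo_matrix(matrix.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, matrix.counts.index)) + "\n")
    Path(cells_path).write_text("\n".join(map(str, matrix.counts.columns)) + "\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
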