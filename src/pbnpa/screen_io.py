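"""Reading and writing sgRNA count tables and gene-level result tables.

The canonical input dialect is the MAGeCK-style count table: a UTF-8,
tab-delimited file with a header row, an ``sgRNA`` column, a ``Gene``
column, and one column of non-negative integer read counts per sample.
Replicates are expressed as explicit (control, treatment) column pairs;
pairing is never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenCountTable",
    "ScreenFormatError",
    "read_count_table",
    "write_gene_results",
]

SGRNA_COL = "sgRNA"
GENE_COL = "Gene"


class ScreenFormatError(ValueError):
    """Raised for malformed count tables (missing columns, bad cells, dupes)."""


@dataclass
class ScreenCountTable:
    """Per-sgRNA read counts for one control/treatment pair.

    Parameters
    ----------
    sgrna_ids : array of str
        Unique sgRNA identifiers, in input row order.
    gene_ids : array of str
        Gene label for each sgRNA (parallel to ``sgrna_ids``); the gene
        grouping partitions the sgRNA index set.
    control, treatment : array of int
        Raw read counts under the control (i = 0) and treatment (i = 1)
        conditions.
    replicate_id : int, optional
        1-based replicate index when the table is one of several replicate
        pairings from the same experiment.
    """

    sgrna_ids: np.ndarray
    gene_ids: np.ndarray
    control: np.ndarray
    treatment: np.ndarray
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.sgrna_ids = np.asarray(self.sgrna_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.control = np.asarray(self.control)
        self.treatment = np.asarray(self.treatment)
        n = len(self.sgrna_ids)
        if n < 1:
            raise ScreenFormatError("count table must contain at least one sgRNA")
        for name, arr in (("gene_ids", self.gene_ids), ("control", self.control),
                          ("treatment", self.treatment)):
            if len(arr) != n:
                raise ScreenFormatError(
                    f"{name} has length {len(arr)}, expected {n}"
                )
        for name, arr in (("control", self.control), ("treatment", self.treatment)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.asarray(arr) == np.floor(arr)):
                    raise ScreenFormatError(f"{name} counts must be integers")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ScreenFormatError(f"{name} counts must be non-negative")
            setattr(self, name, arr.astype(np.int64))
        if len(set(self.sgrna_ids)) != n:
            seen: set = set()
            dup = next(s for s in self.sgrna_ids if s in seen or seen.add(s))
            raise ScreenFormatError(f"duplicate sgRNA id: {dup!r}")

    @property
    def n_sgrnas(self) -> int:
        return len(self.sgrna_ids)

    @property
    def n_genes(self) -> int:
        return len(pd.unique(self.gene_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                SGRNA_COL: self.sgrna_ids,
                GENE_COL: self.gene_ids,
                "control": self.control,
                "treatment": self.treatment,
            }
        )


def read_count_table(
    path,
    control_cols: Sequence[str] | str,
    treatment_cols: Sequence[str] | str,
) -> list[ScreenCountTable]:
    """Read a MAGeCK-style count table into one table per replicate pairing.

    ``control_cols[k]`` is paired with ``treatment_cols[k]`` and becomes the
    table with ``replicate_id = k + 1``. Input row order is preserved, so
    sgRNA ``k`` of every returned table is row ``k`` of the file.

    Raises
    ------
    ScreenFormatError
        If a named column is missing, a count cell is negative or
        non-integer, or an sgRNA id is duplicated.
    """
    if isinstance(control_cols, str):
        control_cols = [control_cols]
    if isinstance(treatment_cols, str):
        treatment_cols = [treatment_cols]
    if len(control_cols) != len(treatment_cols):
        raise ScreenFormatError(
            f"{len(control_cols)} control columns cannot be paired with "
            f"{len(treatment_cols)} treatment columns"
        )
    if not control_cols:
        raise ScreenFormatError("at least one (control, treatment) pair is required")

    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in (SGRNA_COL, GENE_COL, *control_cols, *treatment_cols):
        if col not in df.columns:
            raise ScreenFormatError(
                f"column {col!r} not found in {path} "
                f"(available: {list(df.columns)})"
            )

    counts: dict[str, np.ndarray] = {}
    for col in {*control_cols, *treatment_cols}:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed)) | (parsed < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ScreenFormatError(
                f"column {col!r}, data row {row + 1}: "
                f"{raw.iloc[row]!r} is not a non-negative integer count"
            )
        counts[col] = parsed.to_numpy(dtype=np.int64)

    tables = []
    for k, (ctrl, treat) in enumerate(zip(control_cols, treatment_cols), start=1):
        tables.append(
            ScreenCountTable(
                sgrna_ids=df[SGRNA_COL].to_numpy(dtype=object),
                gene_ids=df[GENE_COL].to_numpy(dtype=object),
                control=counts[ctrl],
                treatment=counts[treat],
                replicate_id=k if len(control_cols) > 1 else None,
            )
        )
    return tables


def write_count_table(table: ScreenCountTable, path, *,
                      control_name: str = "control",
                      treatment_name: str = "treatment") -> None:
    """Write one replicate pairing back to the canonical TSV dialect."""
    df = table.to_frame().rename(
        columns={"control": control_name, "treatment": treatment_name}
    )
    df.to_csv(path, sep="\t", index=False)


_RESULT_COLUMNS = ("Gene", "R", "p.pos", "fdr.pos", "p.neg", "fdr.neg")


def write_gene_results(results: Iterable, path) -> None:
    """Write gene-level inference to a TSV with a fixed six-column header.

    Columns are ``Gene, R, p.pos, fdr.pos, p.neg, fdr.neg``; numeric fields
    are printed with 12 significant digits so a read-back round-trips at
    that precision. An empty result collection is an error.
    """
    rows = [
        (g.gene_id, g.R, g.p_pos, g.fdr_pos, g.p_neg, g.fdr_neg)
        for g in results
    ]
    if not rows:
        raise ValueError("cannot write an empty result set")
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gene_results(path) -> pd.DataFrame:
    """Read a gene-level result table written by :func:`write_gene_results`."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"result table missing columns {missing}")
    return df
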