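"""Pair-level data ingestion and aggregation into concordance tables.

Pair records are carried as a pandas DataFrame with columns ``pair_id``,
``group`` (one of ``same_sex``, ``opposite_sex``, ``sibling``), binary
``pheno_1`` / ``pheno_2``, and any number of extra stratification columns.
Aggregation reduces records to per-(group, stratum) 2x2 concordance
tables, the sufficient statistics for every downstream fit.

Twin order within a pair is arbitrary in registry-like data, so tables
are symmetrized: each pair contributes half a count to (y1, y2) and half
to (y2, y1).  This forces n01 == n10 and justifies a single shared
threshold in the liability model.  Fractional counts are kept in floating
point; the multinomial likelihood accepts non-integer weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GROUPS", "ConcordanceTable", "read_pairs", "aggregate", "tables_to_frame"]

GROUPS = ("same_sex", "opposite_sex", "sibling")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceTable:
    """Symmetrized 2x2 pair counts for one group and stratum level.

    Counts may be fractional (halves) because of symmetrization.
    """

    group: str
    stratum: str
    n00: float
    n01: float
    n10: float
    n11: float

    def __post_init__(self):
        for v in (self.n00, self.n01, self.n10, self.n11):
            if v < 0:
                raise ValueError("concordance counts must be non-negative")
        if self.n_total < 1:
            raise ValueError("concordance table must contain at least one pair")

    @property
    def n_total(self) -> float:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n00, self.n01, self.n10, self.n11])

    def scaled(self, factor: float) -> "ConcordanceTable":
        return ConcordanceTable(
            self.group, self.stratum,
            self.n00 * factor, self.n01 * factor,
            self.n10 * factor, self.n11 * factor,
        )


_DEFAULT_SCHEMA = {
    "pair_id": "pair_id",
    "group": "group",
    "pheno_1": "pheno_1",
    "pheno_2": "pheno_2",
}


def read_pairs(
    source,
    schema: Mapping[str, str] | None = None,
    strata_columns: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read and validate pair-level records from delimited text.

    Parameters
    ----------
    source : path or file-like
        Comma-separated text with a header row.
    schema : mapping, optional
        Maps canonical names (pair_id, group, pheno_1, pheno_2) to the
        column names present in the file.
    strata_columns : iterable of str, optional
        Extra columns to retain as stratifiers; by default every column
        beyond the four canonical ones is kept.

    Returns
    -------
    DataFrame with canonical column names.  Rows whose phenotype values
    are missing or not in {0, 1} are dropped; the drop count is logged
    and stored in ``df.attrs["n_dropped"]``.

    Raises
    ------
    ValueError
        On an empty file, a missing mapped column, or an unknown group
        label (the offending row is named).
    """
    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(source, dtype={colmap["pair_id"]: str})
    if df.empty:
        raise ValueError("input file contains no data rows")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"mapped columns not found in input: {missing}")

    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    if strata_columns is not None:
        keep = list(_DEFAULT_SCHEMA) + [c for c in strata_columns if c in df.columns]
        absent = [c for c in strata_columns if c not in df.columns]
        if absent:
            raise ValueError(f"strata columns not found in input: {absent}")
        df = df[keep]

    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = df.index[bad_group][0]
        raise ValueError(
            f"unknown group label {df.loc[row, 'group']!r} at row {row}; "
            f"expected one of {GROUPS}"
        )

    n_before = len(df)
    for c in ("pheno_1", "pheno_2"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    valid = df["pheno_1"].isin((0, 1)) & df["pheno_2"].isin((0, 1))
    dropped = int(n_before - valid.sum())
    if dropped:
        logger.info("dropped %d rows with missing/non-binary phenotypes", dropped)
    df = df.loc[valid].copy()
    if df.empty:
        raise ValueError("no valid pair records after filtering")
    df["pheno_1"] = df["pheno_1"].astype(np.int8)
    df["pheno_2"] = df["pheno_2"].astype(np.int8)
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise ValueError(f"duplicate pair_id {dup!r}")
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = dropped
    return df


def aggregate(
    records: pd.DataFrame,
    stratify_by: str | None = None,
) -> list[ConcordanceTable]:
    """Aggregate pair records into symmetrized concordance tables.

    One table per (group x stratum level); when ``stratify_by`` is None a
    single "all" stratum is used.  Each pair contributes 1/2 to cell
    (y1, y2) and 1/2 to (y2, y1), so n01 == n10 by construction and the
    total weight equals the number of contributing pairs.
    """
    if stratify_by is not None and stratify_by not in records.columns:
        available = [
            c for c in records.columns
            if c not in ("pair_id", "group", "pheno_1", "pheno_2")
        ]
        raise ValueError(
            f"stratifier {stratify_by!r} not in records; available: {available}"
        )

    tables = []
    if stratify_by is None:
        grouping = [("all", records)]
    else:
        grouping = [
            (str(level), sub)
            for level, sub in records.groupby(stratify_by, observed=True)
        ]
    for stratum, sub in grouping:
        for grp, gsub in sub.groupby("group", observed=True):
            y1 = gsub["pheno_1"].to_numpy()
            y2 = gsub["pheno_2"].to_numpy()
            # half-weight both orderings
            n11 = float(np.sum((y1 == 1) & (y2 == 1)))
            n00 = float(np.sum((y1 == 0) & (y2 == 0)))
            d12 = float(np.sum((y1 == 0) & (y2 == 1)))
            d21 = float(np.sum((y1 == 1) & (y2 == 0)))
            noff = 0.5 * (d12 + d21)
            tables.append(
                ConcordanceTable(str(grp), stratum, n00, noff, noff, n11)
            )
    return tables


def tables_to_frame(tables: Iterable[ConcordanceTable]) -> pd.DataFrame:
    """Tidy export of concordance tables."""
    return pd.DataFrame(
        [
            {
                "group": t.group,
                "stratum": t.stratum,
                "n00": t.n00,
                "n01": t.n01,
                "n10": t.n10,
                "n11": t.n11,
            }
            for t in tables
        ]
    )
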