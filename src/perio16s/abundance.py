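"""OTU count tables, sample metadata, and abundance transformations.

The analyses in this package operate on a table of 16S OTU read counts
(OTUs x samples) together with per-sample clinical metadata (periodontal
health status, average gingivitis score of the sampled teeth, age, sex).
This module provides the validated containers, TSV readers/writers, the
rare-OTU classification rule, and the proportion transforms used
downstream:

* raw proportions  ``c_ij / T_j``
* pseudo-count adjusted proportions ``(c_ij + 2) / (T_j + 4)`` --
  equivalent to adding two successes and two failures to every
  OTU/sample cell, which keeps logits finite when counts are zero
* pooled proportions ``100 * count / total`` for whole-study summaries

Rare-OTU rule: an OTU is *rare* when its mean raw proportion is below
``prop_threshold`` (default 0.05%) within **every** health-status group,
or it is detected (count > 0) in fewer than ``min_samples`` samples
overall.  Rare OTUs are pooled, per sample, into a single reserved
``RARE`` row so that read totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HEALTH_STATES = ("health", "gingivitis", "pd1")
RARE_ID = "RARE"

METADATA_COLUMNS = ("health_status", "avg_gingivitis_score", "age", "sex")


class TableValidationError(ValueError):
    """A count table or metadata table violates its contract."""


class DuplicateIdError(TableValidationError):
    """Sample or OTU identifiers are not unique."""


class NegativeCountError(TableValidationError):
    """A count cell is negative or non-integer."""


class SampleMismatchError(TableValidationError):
    """Metadata and count-table sample sets differ."""


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with unique identifiers.

    ``counts`` is a pandas DataFrame indexed by OTU id with sample ids as
    columns.  Cells must be non-negative integers and every sample total
    must be positive.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate OTU identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample identifiers: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise NegativeCountError("count cells must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if (values < 0).any():
            bad = df.columns[(values < 0).any(axis=0)].tolist()
            raise NegativeCountError(f"negative counts in samples: {bad}")
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            bad = df.columns[totals <= 0].tolist()
            raise TableValidationError(f"samples with zero total reads: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_rare_row(self) -> "OtuTable":
        """Return the table without the pooled ``RARE`` row (if present)."""
        if RARE_ID in self.counts.index:
            return OtuTable(self.counts.drop(index=RARE_ID))
        return self


@dataclass
class RareFiltered:
    """Result of the rare-OTU classification.

    ``retained`` holds the non-rare OTUs plus a pooled ``RARE`` row whose
    per-sample counts are the summed counts of all rare OTUs, so column
    sums reproduce the original sample totals exactly.
    """

    retained: OtuTable
    rare_otu_ids: list[str] = field(default_factory=list)


@dataclass
class ProportionMatrix:
    """Per-cell proportions with the transformation scheme recorded."""

    values: pd.DataFrame
    scheme: str  # "raw" | "adjusted"


def read_count_table(path: str | Path) -> OtuTable:
    """Read a TSV count table (first column ``otu_id``, then sample columns)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "otu_id":
        raise TableValidationError(
            f"first column must be 'otu_id', got {df.columns[0]!r}"
        )
    df = df.set_index("otu_id")
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise NegativeCountError(f"non-integer count cell: {exc}") from exc
    return OtuTable(df)


def write_count_table(table: OtuTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV indexed by ``sample_id``.

    Columns: ``health_status`` (health/gingivitis/pd1),
    ``avg_gingivitis_score`` (0-3), ``age``, ``sex``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise TableValidationError("metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateIdError(f"duplicate sample identifiers: {dups}")
    df = df.set_index("sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"metadata missing columns: {missing}")
    bad = sorted(set(df["health_status"]) - set(HEALTH_STATES))
    if bad:
        raise TableValidationError(f"unknown health status tokens: {bad}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def check_samples_match(table: OtuTable, metadata: pd.DataFrame) -> None:
    """Raise :class:`SampleMismatchError` unless sample sets are equal."""
    table_set = set(table.sample_ids)
    meta_set = set(metadata.index)
    missing_meta = sorted(table_set - meta_set)
    missing_table = sorted(meta_set - table_set)
    if missing_meta or missing_table:
        parts = []
        if missing_meta:
            parts.append(f"samples missing from metadata: {missing_meta}")
        if missing_table:
            parts.append(f"samples missing from count table: {missing_table}")
        raise SampleMismatchError("; ".join(parts))


def raw_proportions(table: OtuTable) -> ProportionMatrix:
    """Per-sample relative abundances ``c_ij / T_j``."""
    df = table.counts
    return ProportionMatrix(df / df.sum(axis=0), scheme="raw")


def adjusted_proportion(count: float, total: float) -> float:
    """Pseudo-count adjusted proportion ``(c + 2) / (T + 4)``."""
    return (count + 2.0) / (total + 4.0)


def adjusted_proportions(table: OtuTable) -> ProportionMatrix:
    """Pseudo-count adjusted proportions, strictly inside (0, 1)."""
    df = table.counts
    values = (df + 2.0) / (df.sum(axis=0) + 4.0)
    return ProportionMatrix(values, scheme="adjusted")


def pooled_proportion(count: int, total: int) -> float:
    """Percentage of ``total`` reads belonging to one OTU, unrounded.

    Presentation rounding (two decimals) is left to report code.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must satisfy 0 <= count <= total")
    return 100.0 * count / total


def group_mean_proportions(
    table: OtuTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean raw proportion of each OTU within each health-status group."""
    check_samples_match(table, metadata)
    props = raw_proportions(table).values
    out = {}
    for state in HEALTH_STATES:
        samples = metadata.index[metadata["health_status"] == state]
        if len(samples) == 0:
            raise TableValidationError(f"health group {state!r} has no samples")
        out[state] = props[samples].mean(axis=1)
    return pd.DataFrame(out)


def classify_rare(
    table: OtuTable,
    metadata: pd.DataFrame,
    prop_threshold: float = 0.0005,
    min_samples: int = 2,
) -> RareFiltered:
    """Apply the rare-OTU rule and pool rare counts into a ``RARE`` row.

    An OTU is rare iff its mean raw proportion is below ``prop_threshold``
    in every health-status group, or it has a positive count in fewer
    than ``min_samples`` samples overall.  The pooled ``RARE`` row is
    appended even when no OTU is rare, so downstream stages can rely on
    its presence.
    """
    if RARE_ID in table.counts.index:
        raise TableValidationError(f"input table already contains a {RARE_ID} row")
    means = group_mean_proportions(table, metadata)
    below_everywhere = (means < prop_threshold).all(axis=1)
    detected_in = (table.counts > 0).sum(axis=1)
    rare_mask = below_everywhere | (detected_in < min_samples)
    rare_ids = table.counts.index[rare_mask].tolist()
    retained_df = table.counts.loc[~rare_mask]
    rare_row = table.counts.loc[rare_mask].sum(axis=0).to_frame(RARE_ID).T
    rare_row.index.name = retained_df.index.name
    retained_df = pd.concat([retained_df, rare_row])
    return RareFiltered(retained=OtuTable(retained_df), rare_otu_ids=rare_ids)
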