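"""Count/taxonomy table I/O and relative-abundance normalisation.

Input contract: genus-by-sample count tables as TSV (taxon names in the first
column, sample IDs in the header row, non-negative integer counts) and a
two-column taxonomy TSV mapping each taxon to its parent-level category
(e.g. genus -> family).

Normalisation divides each sample column by its total count.  Taxa labelled
"unclassified" (the source data also uses the spelling "unclassifed") are
dropped *after* normalisation, so columns of the resulting abundance table
may sum to less than 1 — that order is part of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "AbundanceTable",
    "Taxonomy",
    "TableFormatError",
    "DEFAULT_UNCLASSIFIED_LABELS",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "to_relative_abundance",
    "drop_unclassified",
    "warn_on_sample_overlap",
]

logger = logging.getLogger(__name__)

#: Labels removed after normalisation (matched case-insensitively).  The
#: misspelling appears verbatim in real annotation tables.
DEFAULT_UNCLASSIFIED_LABELS = frozenset({"unclassified", "unclassifed"})


class TableFormatError(ValueError):
    """A count or taxonomy table violates the input contract."""


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts for one group."""

    group: str
    data: pd.DataFrame  # index: taxa, columns: samples, dtype int64

    def __post_init__(self) -> None:
        _validate_counts(self.data, source=f"group {self.group}")
        self.data = self.data.astype(np.int64)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AbundanceTable:
    """Taxa x samples matrix of relative abundances in [0, 1]."""

    group: str
    data: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def row(self, taxon: str) -> np.ndarray:
        """Abundance vector of one taxon across samples."""
        if taxon not in self.data.index:
            raise KeyError(f"taxon {taxon!r} not in abundance table")
        return self.data.loc[taxon].to_numpy()


@dataclass
class Taxonomy:
    """Mapping from taxon name to its parent-level category.

    The parent level is whatever sits one rank above the count-table labels
    (family for genus-level tables, genus for species-level tables, ...).
    """

    mapping: dict[str, str]

    def sup_category(self, taxon: str) -> str:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} missing from taxonomy") from None

    def require(self, taxa: Iterable[str]) -> None:
        """Raise listing every queried taxon absent from the taxonomy."""
        missing = sorted(t for t in taxa if t not in self.mapping)
        if missing:
            raise TableFormatError(
                "taxa present in counts but absent from taxonomy: "
                + ", ".join(missing)
            )

    def __len__(self) -> int:
        return len(self.mapping)


def _validate_counts(df: pd.DataFrame, source: str) -> None:
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise TableFormatError(f"{source}: duplicate taxon names: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise TableFormatError(f"{source}: duplicate sample IDs: {dups}")
    if df.shape[1] < 2:
        raise TableFormatError(
            f"{source}: at least 2 samples are required, got {df.shape[1]}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            ~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
        ]
        raise TableFormatError(
            f"{source}: non-numeric counts in column(s) {list(bad)}"
        )
    neg = np.argwhere(values < 0)
    if neg.size:
        i, k = neg[0]
        raise TableFormatError(
            f"{source}: negative count at taxon {df.index[i]!r}, "
            f"sample {df.columns[k]!r}"
        )
    frac = np.argwhere(values != np.floor(values))
    if frac.size:
        i, k = frac[0]
        raise TableFormatError(
            f"{source}: non-integer count at taxon {df.index[i]!r}, "
            f"sample {df.columns[k]!r}"
        )


def read_count_table(path: str | Path, group: str) -> CountTable:
    """Read and validate a genus-by-sample count TSV for one group."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise TableFormatError(f"cannot parse count table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _validate_counts(df, source=str(path))
    return CountTable(group=group, data=df)


def write_count_table(ct: CountTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index_label="taxon")


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a two-column taxon -> parent-level TSV (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError(
            f"taxonomy {path}: expected two tab-separated columns"
        )
    taxa, sup = df.iloc[:, 0], df.iloc[:, 1]
    if taxa.duplicated().any():
        dups = sorted(taxa[taxa.duplicated()].unique())
        raise TableFormatError(f"taxonomy {path}: duplicate taxa: {dups}")
    return Taxonomy(mapping=dict(zip(taxa, sup)))


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\tsup_category\n")
        for taxon, sup in tax.mapping.items():
            fh.write(f"{taxon}\t{sup}\n")


def to_relative_abundance(ct: CountTable) -> AbundanceTable:
    """Normalise each sample column by its total count.

    abundance[i, k] = count[i, k] / sum_h count[h, k]; every column of the
    result sums to 1.  An all-zero sample column is an error (the sample
    carries no information and the division is undefined).
    """
    totals = ct.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise TableFormatError(
            f"group {ct.group}: sample(s) with zero total count: "
            + ", ".join(map(str, zero.index))
        )
    return AbundanceTable(group=ct.group, data=ct.data / totals)


def drop_unclassified(
    at: AbundanceTable,
    labels: Iterable[str] = DEFAULT_UNCLASSIFIED_LABELS,
) -> AbundanceTable:
    """Remove unclassified taxa *after* normalisation.

    Matching is case-insensitive.  Absent labels are a no-op.  Remaining
    abundances are left unchanged, so sample columns may now sum to < 1.
    """
    lowered = {str(l).lower() for l in labels}
    keep = [t for t in at.data.index if str(t).lower() not in lowered]
    if len(keep) == len(at.data.index):
        return at
    return AbundanceTable(group=at.group, data=at.data.loc[keep])


def warn_on_sample_overlap(ct_x: CountTable, ct_y: CountTable) -> set[str]:
    """Log a warning if the two groups share sample IDs (likely a user error)."""
    overlap = set(ct_x.samples) & set(ct_y.samples)
    if overlap:
        logger.warning(
            "groups %s and %s share %d sample ID(s): %s",
            ct_x.group,
            ct_y.group,
            len(overlap),
            sorted(overlap)[:10],
        )
    return overlap
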