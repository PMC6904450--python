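"""Reading, validating, aggregating and ranking OTU abundance tables.

The on-disk dialect is a plain TSV: first column holds OTU identifiers
(header ``OTU_ID`` by default), remaining columns are integer read counts,
one column per sample.  Gzip is handled transparently by pandas.  Zero-total
OTUs are kept at read time and only dropped when samples are aggregated, so
subsetting is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "OTUTable",
    "AbundanceVector",
    "RankAbundance",
    "read_otu_table",
    "write_otu_table",
    "aggregate_counts",
    "rank_abundance",
    "read_abundance_vector",
    "write_abundance_vector",
]


@dataclass(frozen=True)
class OTUTable:
    """OTU x sample matrix of non-negative integer read counts."""

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_otus, n_samples), integer dtype

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ParseError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise ParseError("counts must be integers")
        if (counts < 0).any():
            bad = int(np.argwhere(counts < 0)[0][0])
            raise ParseError(f"negative count in row for OTU {self.otu_ids[bad]!r}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ParseError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample ids")
        if counts.sum() <= 0:
            raise ParseError("table has no OTU with a positive total")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.otu_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class AbundanceVector:
    """Aggregated reads per OTU: the x_i entering every distribution fit."""

    otu_ids: tuple[str, ...]
    x: np.ndarray  # positive integer reads per OTU

    def __post_init__(self):
        x = np.asarray(self.x)
        if x.ndim != 1 or len(x) != len(self.otu_ids):
            raise DomainError("otu_ids and x must have equal length")
        if len(x) == 0:
            raise DomainError("empty abundance vector")
        if not np.issubdtype(x.dtype, np.integer):
            if np.all(x == np.floor(x)):
                x = x.astype(np.int64)
            else:
                raise DomainError("abundances must be integers")
        if (x < 1).any():
            raise DomainError("every abundance must be >= 1")
        object.__setattr__(self, "x", x)

    @property
    def N(self) -> int:
        """Total reads."""
        return int(self.x.sum())

    @property
    def S(self) -> int:
        """Observed richness (number of OTUs)."""
        return len(self.x)

    @classmethod
    def from_counts(cls, x: Iterable[int], prefix: str = "otu") -> "AbundanceVector":
        x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x)
        width = max(5, len(str(len(x))))
        ids = tuple(f"{prefix}_{i:0{width}d}" for i in range(len(x)))
        return cls(ids, x)


@dataclass(frozen=True)
class RankAbundance:
    """Abundances sorted descending; rank r = 1..S, ties broken by OTU id."""

    otu_ids: tuple[str, ...]
    rank: np.ndarray
    x: np.ndarray

    @property
    def S(self) -> int:
        return len(self.x)

    @property
    def normalized_rank(self) -> np.ndarray:
        """r / S in (0, 1]; comparable to the empirical complementary CDF."""
        return self.rank / self.S


def _read_frame(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_otu_table(path, sep: str = "\t", id_column: str | None = None) -> OTUTable:
    """Read a TSV OTU table (first column OTU ids, header row sample ids).

    ``id_column`` defaults to the first column regardless of its header name;
    pass a name to enforce it.  Gzip-compressed files are read transparently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_frame(path, sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected an id column plus at least one sample column")
    first = df.columns[0]
    if id_column is not None and first != id_column:
        raise ParseError(f"{path}: first column is {first!r}, expected {id_column!r}")
    otu_ids = df[first].tolist()
    sample_ids = tuple(df.columns[1:])
    raw = df.iloc[:, 1:]
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        try:
            vals = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()].index[0]
            raise ParseError(
                f"{path}: non-numeric count at line {bad + 2}, sample {col!r}"
            ) from None
        arr = np.asarray(vals, dtype=float)
        if not np.all(arr == np.floor(arr)):
            bad = int(np.argwhere(arr != np.floor(arr))[0][0])
            raise ParseError(f"{path}: non-integer count at line {bad + 2}, sample {col!r}")
        if (arr < 0).any():
            bad = int(np.argwhere(arr < 0)[0][0])
            raise ParseError(f"{path}: negative count at line {bad + 2}, sample {col!r}")
        counts[:, j] = arr.astype(np.int64)
    seen: set[str] = set()
    for i, oid in enumerate(otu_ids):
        if oid in seen:
            raise ParseError(f"{path}: duplicate OTU id {oid!r} at line {i + 2}")
        seen.add(oid)
    return OTUTable(tuple(otu_ids), sample_ids, counts)


def write_otu_table(table: OTUTable, path, sep: str = "\t", id_column: str = "OTU_ID") -> None:
    """Write the same TSV dialect read by :func:`read_otu_table`."""
    df = table.to_frame()
    df.index.name = id_column
    df.to_csv(path, sep=sep)


def aggregate_counts(table: OTUTable, sample_subset: Sequence[str] | None = None) -> AbundanceVector:
    """Sum reads per OTU over a subset of samples, dropping zero-total OTUs."""
    if sample_subset is None:
        cols = np.arange(len(table.sample_ids))
    else:
        subset = list(sample_subset)
        if not subset:
            raise DomainError("sample subset must be non-empty")
        index = {s: i for i, s in enumerate(table.sample_ids)}
        missing = [s for s in subset if s not in index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        cols = np.array([index[s] for s in subset])
    sums = table.counts[:, cols].sum(axis=1)
    keep = sums > 0
    if not keep.any():
        raise DomainError("selected samples contain no reads")
    ids = tuple(oid for oid, k in zip(table.otu_ids, keep) if k)
    return AbundanceVector(ids, sums[keep].astype(np.int64))


def rank_abundance(v: AbundanceVector) -> RankAbundance:
    """Sort descending by abundance; ties broken lexicographically by OTU id."""
    ids = np.asarray(v.otu_ids)
    order = np.lexsort((ids, -v.x.astype(np.int64)))
    return RankAbundance(
        tuple(ids[order]),
        np.arange(1, v.S + 1),
        v.x[order],
    )


def write_abundance_vector(v: AbundanceVector, path, sep: str = "\t") -> None:
    pd.DataFrame({"otu_id": list(v.otu_ids), "reads": v.x}).to_csv(path, sep=sep, index=False)


def read_abundance_vector(path, sep: str = "\t") -> AbundanceVector:
    df = pd.read_csv(path, sep=sep)
    if not {"otu_id", "reads"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns otu_id, reads")
    return AbundanceVector(tuple(df["otu_id"].astype(str)), df["reads"].to_numpy())
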