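"""Assignment of mapped reads to restriction fragments.

A 4C read originates at a restriction site of the fragment it was
ligated to, so each read is credited to exactly one fragment: the one
containing its 5' position (``start`` on the + strand, ``end - 1`` on
the - strand).  Reads on chromosomes absent from the fragment map are
tallied as discarded; malformed reads (start >= end) are tallied as
rejected with a warning — nothing is dropped silently, so
``assigned + discarded + rejected`` always equals the input read count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .fragments import FragmentMap

__all__ = ["ReadInterval", "RawCounts", "assign_reads", "load_counts"]


class ReadInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class RawCounts:
    """Per-fragment read tally aligned to a :class:`FragmentMap`."""

    fmap: FragmentMap
    counts: np.ndarray  # int64, one entry per fragment row
    discarded: int = 0  # reads on chromosomes absent from the map
    rejected: int = 0  # malformed read records

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.fmap):
            raise ValueError("counts not aligned to fragment map")
        if (self.counts < 0).any():
            raise ValueError("negative fragment count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.fmap.df[["chrom", "start", "end", "frag_class"]].copy()
        out["count"] = self.counts
        return out


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads[["chrom", "start", "end", "strand"]].copy()
    rows = list(reads)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def assign_reads(reads: Iterable[ReadInterval] | pd.DataFrame, fmap: FragmentMap) -> RawCounts:
    """Credit each read to the fragment containing its 5' position.

    Input order never matters.  Reads whose 5' position falls beyond the
    tiled chromosome extent are counted as discarded.
    """
    df = _reads_frame(reads)
    counts = np.zeros(len(fmap), dtype=np.int64)
    if df.empty:
        return RawCounts(fmap=fmap, counts=counts)

    bad = df["start"].to_numpy() >= df["end"].to_numpy()
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} reads with start >= end", stacklevel=2)
    df = df.loc[~bad]

    n_discarded = 0
    frag = fmap.df
    for chrom, sub in df.groupby("chrom", sort=False):
        block = frag.index[frag["chrom"] == chrom]
        if len(block) == 0:
            n_discarded += len(sub)
            continue
        offset = int(block[0])
        starts = frag.loc[block, "start"].to_numpy()
        ends = frag.loc[block, "end"].to_numpy()
        pos5 = np.where(sub["strand"].to_numpy() == "-", sub["end"].to_numpy() - 1, sub["start"].to_numpy())
        idx = np.searchsorted(starts, pos5, side="right") - 1
        inside = (idx >= 0) & (pos5 < ends[np.minimum(idx, len(ends) - 1)])
        n_discarded += int((~inside).sum())
        np.add.at(counts, offset + idx[inside], 1)
    return RawCounts(fmap=fmap, counts=counts, discarded=n_discarded, rejected=n_rejected)


def load_counts(table: str | pd.DataFrame, fmap: FragmentMap) -> RawCounts:
    """Load precomputed per-fragment counts aligned by exact interval match.

    ``table`` is a tab-delimited file (or DataFrame) with columns
    chrom, start, end, count (a ``frag_class`` column, if present, is
    ignored).  Every row must match a fragment interval exactly; a row
    that does not is a hard error naming the row.  Fragments absent from
    the table get count 0.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t")
        if "chrom" not in df.columns:
            df = pd.read_csv(table, sep="\t", header=None)
            names = ["chrom", "start", "end", "count"]
            if df.shape[1] == 5:
                names = ["chrom", "start", "end", "frag_class", "count"]
            df.columns = names
    if "count" not in df.columns:
        raise ValueError("counts table lacks a 'count' column")
    if (df["count"] < 0).any():
        row = df.index[df["count"] < 0][0]
        raise ValueError(f"negative count at row {row}")

    key = {
        (c, int(s), int(e)): i
        for i, (c, s, e) in enumerate(zip(fmap.df["chrom"], fmap.df["start"], fmap.df["end"]))
    }
    counts = np.zeros(len(fmap), dtype=np.int64)
    for row in df.itertuples():
        k = (row.chrom, int(row.start), int(row.end))
        if k not in key:
            raise ValueError(
                f"row {row.Index}: interval {row.chrom}:{row.start}-{row.end} not in fragment map"
            )
        counts[key[k]] += int(row.count)
    return RawCounts(fmap=fmap, counts=counts)
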