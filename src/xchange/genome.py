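"""Genome model and interval arithmetic.

All coordinates are 0-based half-open (BED convention). Reports that mirror
cytogenetics tables render 1-based inclusive; that conversion lives in the
report writers, never here.

The workhorse data structure is a per-chromosome pair of sorted, merged
``(starts, ends)`` arrays with a running prefix of covered bases, which turns
"how many bases of [a, b) are covered by this track?" into two searchsorted
lookups. Every operation here is vectorized over fragment arrays because the
pipeline routinely queries 10^5-10^6 fragments per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "IntervalTrack",
    "merge_intervals",
    "overlap_fraction",
    "bins_overlapped",
    "union_coverage",
]


class UnknownChromosomeError(KeyError):
    """Raised when an interval references a chromosome absent from the model."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome name -> length (bp) map.

    The chromosome order is part of the model: pair canonicalization and all
    report ordering follow it, so it must be stable across runs.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome model needs at least one chromosome")
        object.__setattr__(self, "lengths", dict(self.lengths))
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def order(self, chrom: str) -> int:
        """Rank of a chromosome in the model's canonical order."""
        try:
            return self.chromosomes.index(chrom)
        except ValueError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeModel":
        """Read a two-column chrom-sizes text file (name, length)."""
        df = pd.read_csv(path, sep=r"\s+", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"].astype(int))))

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeModel) -> None:
        if self.chrom not in genome:
            raise UnknownChromosomeError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length(self.chrom)}"
            )


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, max_gap: int = 0):
    """Merge sorted interval arrays; intervals separated by <= max_gap coalesce."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running maximum of ends defines chain boundaries
    run_end = np.maximum.accumulate(e)
    new_chain = np.empty(len(s), dtype=bool)
    new_chain[0] = True
    new_chain[1:] = s[1:] > run_end[:-1] + max_gap
    chain = np.cumsum(new_chain) - 1
    out_s = s[new_chain]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_chain))
    del chain
    return out_s, out_e


class IntervalTrack:
    """A named set of labeled genomic intervals (repeats, genes, cytobands...).

    Backed by a DataFrame with columns chrom/start/end and optional
    label columns; merged per-chromosome indexes are built lazily and cached.
    """

    def __init__(self, name: str, intervals: pd.DataFrame,
                 label_vocabulary: Sequence[str] | None = None):
        df = intervals.reset_index(drop=True).copy()
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"empty/negative interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if label_vocabulary is not None and "label" in df.columns and len(df):
            unknown = set(df["label"]) - set(label_vocabulary)
            if unknown:
                raise ValueError(f"labels outside declared vocabulary: {sorted(unknown)}")
        self.name = name
        self.df = df
        self.label_vocabulary = tuple(label_vocabulary) if label_vocabulary else None
        self._merged_cache: dict[tuple, dict] = {}

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def subset(self, labels: Iterable[str], name: str | None = None) -> "IntervalTrack":
        """Restrict to intervals whose label is in ``labels``."""
        labels = set(labels)
        if "label" not in self.df.columns:
            raise ValueError(f"track {self.name!r} carries no labels")
        sub = self.df[self.df["label"].isin(labels)]
        return IntervalTrack(name or f"{self.name}[{','.join(sorted(labels))}]", sub)

    def _merged(self, max_gap: int = 0) -> dict:
        """chrom -> (starts, ends, prefix) with prefix[i] = covered bp before interval i."""
        key = (max_gap,)
        if key not in self._merged_cache:
            index = {}
            for chrom, grp in self.df.groupby("chrom", sort=False):
                s, e = _merge_arrays(grp["start"].to_numpy(np.int64),
                                     grp["end"].to_numpy(np.int64), max_gap)
                prefix = np.concatenate([[0], np.cumsum(e - s)])
                index[chrom] = (s, e, prefix)
            self._merged_cache[key] = index
        return self._merged_cache[key]

    def covered_bp(self, chrom: str, starts, ends) -> np.ndarray:
        """Bases of each query interval covered by the union of this track.

        Vectorized over parallel ``starts``/``ends`` arrays on one chromosome.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        entry = self._merged().get(chrom)
        if entry is None:
            return np.zeros(len(starts), dtype=np.int64)
        s, e, prefix = entry

        def cum(x):
            # covered bases in [0, x)
            i = np.searchsorted(s, x, side="right")
            base = prefix[i]
            # partial overlap with interval i-1 if x lands inside it
            inside = i > 0
            prev_e = np.where(inside, e[np.maximum(i - 1, 0)], 0)
            prev_s = np.where(inside, s[np.maximum(i - 1, 0)], 0)
            overshoot = np.where(inside, np.maximum(prev_e - np.maximum(x, prev_s), 0), 0)
            # base counted full interval i-1; subtract the part at/after x
            return base - np.minimum(overshoot, prev_e - prev_s)

        return cum(ends) - cum(starts)

    def overlaps_any(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean mask: does each query overlap >= 1 bp of the track union?"""
        return self.covered_bp(chrom, starts, ends) > 0

    def union_bp(self) -> int:
        return int(sum(entry[2][-1] for entry in self._merged().values()))

    def merged_track(self, max_gap: int = 0, name: str | None = None) -> "IntervalTrack":
        rows = []
        for chrom in self.chromosomes:
            s, e, _ = self._merged(max_gap).get(chrom, (np.array([]), np.array([]), None))
            for a, b in zip(s, e):
                rows.append((chrom, int(a), int(b)))
        return IntervalTrack(name or f"{self.name}.merged",
                             pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def merge_intervals(intervals: Iterable[GenomicInterval], max_gap: int = 0
                    ) -> list[GenomicInterval]:
    """Coalesce intervals whose separation is <= max_gap (per chromosome).

    At ``max_gap=0`` overlapping and abutting intervals merge ([0,10)+[10,20)
    -> [0,20)) while a 1-bp gap keeps them apart, so the union of covered
    bases is preserved.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for iv in intervals:
        if iv.chrom not in by_chrom:
            order.append(iv.chrom)
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in order:
        ivs = by_chrom[chrom]
        s = np.array([iv.start for iv in ivs], dtype=np.int64)
        e = np.array([iv.end for iv in ivs], dtype=np.int64)
        ms, me = _merge_arrays(s, e, max_gap)
        out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me))
    return out


def overlap_fraction(query: GenomicInterval, track: IntervalTrack) -> float:
    """Fraction of ``query`` bases covered by the union of the track."""
    covered = track.covered_bp(query.chrom, [query.start], [query.end])[0]
    return float(covered) / len(query)


def bins_overlapped(query: GenomicInterval, bin_size: int) -> list[tuple[str, int]]:
    """Fixed bins (bin i = [i*size, (i+1)*size)) overlapping >= 1 bp of the query."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    first = query.start // bin_size
    last = (query.end - 1) // bin_size  # end is exclusive
    return [(query.chrom, i) for i in range(first, last + 1)]


def union_coverage(intervals: Iterable[GenomicInterval], genome: GenomeModel) -> float:
    """Union of interval bases as a fraction of total genome size."""
    merged = merge_intervals(list(intervals), max_gap=0)
    covered = sum(len(iv) for iv in merged)
    return covered / genome.total_bp
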