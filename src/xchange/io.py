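"""Readers and writers for the external formats the pipeline touches.

BEDPE (7+ columns, subject id in the name column), BED 3-5 tracks, UCSC
cytoBand.txt, cohort TSV, catalog TSV and t(A;B)(bandA;bandB) notation.
All readers are gzip-transparent (by file extension) and reject malformed
rows into an explicit reject report instead of coercing or dropping them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, GenomicInterval, IntervalTrack

__all__ = [
    "TranslocationPair",
    "Cohort",
    "CatalogRecord",
    "PAIR_COLUMNS",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "read_cytoband",
    "read_cohort",
    "read_catalog",
    "parse_notation",
    "canonicalize_pairs",
    "pair_frame",
]

#: Canonical column layout of a pair table. ``kind`` is derived:
#: "intra" iff both fragments share a chromosome, else "inter".
PAIR_COLUMNS = ["subject", "chrom_a", "start_a", "end_a",
                "chrom_b", "start_b", "end_b", "kind"]

GIESTAIN_CLASSES = ("gpos100", "gpos75", "gpos50", "gpos25",
                    "gneg", "acen", "gvar", "stalk")
G_POSITIVE = ("gpos25", "gpos50", "gpos75", "gpos100")


@dataclass(frozen=True)
class TranslocationPair:
    """One called exchange: two genomic fragments observed in one subject."""

    subject: str
    fragment_a: GenomicInterval
    fragment_b: GenomicInterval

    @property
    def kind(self) -> str:
        return "intra" if self.fragment_a.chrom == self.fragment_b.chrom else "inter"

    def canonical(self, genome: GenomeModel | None = None) -> "TranslocationPair":
        a, b = self.fragment_a, self.fragment_b
        if genome is not None:
            key = lambda iv: (genome.order(iv.chrom), iv.start, iv.end)
        else:
            key = lambda iv: (iv.chrom, iv.start, iv.end)
        if key(b) < key(a):
            a, b = b, a
        return TranslocationPair(self.subject, a, b)


@dataclass
class Cohort:
    """Subject -> group / subgroup / gender assignment.

    The cohort size is the denominator of every detection rate in the
    pipeline, so unresolvable subjects are surfaced, never silently kept.
    """

    table: pd.DataFrame  # columns: subject, group, [subgroup], [gender]

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        if not {"subject", "group"}.issubset(df.columns):
            raise ValueError("cohort table needs 'subject' and 'group' columns")
        if df["subject"].duplicated().any():
            dups = df.loc[df["subject"].duplicated(), "subject"].tolist()
            raise ValueError(f"duplicate subject ids in cohort: {dups[:5]}")
        if "gender" not in df.columns:
            df["gender"] = "unknown"
        df["gender"] = df["gender"].fillna("unknown")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subjects(self) -> list[str]:
        return self.table["subject"].tolist()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group_sizes(self) -> dict[str, int]:
        counts = self.table["group"].value_counts()
        return {g: int(counts[g]) for g in self.groups}

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["subject"], self.table["group"]))

    def gender_of(self) -> dict[str, str]:
        return dict(zip(self.table["subject"], self.table["gender"]))

    def unresolved(self, pairs: pd.DataFrame) -> list[str]:
        """Subject ids present in the pair table but absent from the cohort."""
        known = set(self.subjects)
        return sorted(set(pairs["subject"]) - known)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CatalogRecord:
    """A known translocation: two loci, each a cytoband or a bp interval."""

    record_id: str
    source: str
    # exactly one of (band, interval) per locus
    chrom_a: str
    band_a: str | None
    interval_a: GenomicInterval | None
    chrom_b: str
    band_b: str | None
    interval_b: GenomicInterval | None

    def __post_init__(self) -> None:
        for side, band, iv in (("a", self.band_a, self.interval_a),
                               ("b", self.band_b, self.interval_b)):
            if (band is None) == (iv is None):
                raise ValueError(
                    f"catalog record {self.record_id}: locus_{side} needs exactly "
                    "one of band or bp interval"
                )


# --- pair tables -----------------------------------------------------------

def pair_frame(pairs) -> pd.DataFrame:
    """Build a canonical pair DataFrame from TranslocationPair records."""
    rows = [(p.subject,
             p.fragment_a.chrom, p.fragment_a.start, p.fragment_a.end,
             p.fragment_b.chrom, p.fragment_b.start, p.fragment_b.end,
             p.kind) for p in pairs]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def canonicalize_pairs(df: pd.DataFrame, genome: GenomeModel | None = None
                       ) -> pd.DataFrame:
    """Order each pair's fragments (chromosome order, then start, then end).

    With a genome model, chromosome order is the model's; otherwise
    lexicographic. Also (re)derives the ``kind`` column.
    """
    df = df.copy()
    if genome is not None:
        rank = {c: i for i, c in enumerate(genome.chromosomes)}
        oa = df["chrom_a"].map(rank)
        ob = df["chrom_b"].map(rank)
        for col, ser in (("chrom_a", oa), ("chrom_b", ob)):
            if ser.isna().any():
                bad = df.loc[ser.isna(), col].iloc[0]
                raise KeyError(f"unknown chromosome {bad!r} in pair table")
    else:
        cats = sorted(set(df["chrom_a"]) | set(df["chrom_b"]))
        rank = {c: i for i, c in enumerate(cats)}
        oa = df["chrom_a"].map(rank)
        ob = df["chrom_b"].map(rank)
    swap = (ob < oa) | ((ob == oa) & (df["start_b"] < df["start_a"])) | \
           ((ob == oa) & (df["start_b"] == df["start_a"]) & (df["end_b"] < df["end_a"]))
    swap = swap.to_numpy()
    if swap.any():
        a_cols = ["chrom_a", "start_a", "end_a"]
        b_cols = ["chrom_b", "start_b", "end_b"]
        tmp = df.loc[swap, a_cols].to_numpy()
        df.loc[swap, a_cols] = df.loc[swap, b_cols].to_numpy()
        df.loc[swap, b_cols] = tmp
    df["kind"] = np.where(df["chrom_a"] == df["chrom_b"], "intra", "inter")
    return df


def _open_kwargs(path):
    return {"compression": "gzip"} if str(path).endswith(".gz") else {}


def read_bedpe(path, genome: GenomeModel | None = None):
    """Parse a BEDPE file into a canonical pair table plus a reject report.

    Returns ``(pairs, rejects)``: ``pairs`` is a DataFrame with
    :data:`PAIR_COLUMNS`; ``rejects`` records each malformed row with its
    line number and reason. Rows are never silently dropped.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str,
                          comment="#", **_open_kwargs(path))
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty BEDPE file: {path}")
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        return empty, pd.DataFrame(columns=["line", "reason", "content"])
    if raw.shape[1] < 7:
        raise ValueError(f"BEDPE needs >= 7 columns, got {raw.shape[1]} in {path}")
    raw = raw.iloc[:, :7]
    raw.columns = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                   "subject"]
    rejects = []

    coords = raw[["start_a", "end_a", "start_b", "end_b"]].apply(
        pd.to_numeric, errors="coerce")
    bad_num = coords.isna().any(axis=1)
    neg = (coords < 0).any(axis=1)
    empty_a = coords["start_a"] >= coords["end_a"]
    empty_b = coords["start_b"] >= coords["end_b"]
    bad_chrom = pd.Series(False, index=raw.index)
    if genome is not None:
        known = set(genome.chromosomes)
        bad_chrom = ~(raw["chrom_a"].isin(known) & raw["chrom_b"].isin(known))
        too_long = pd.Series(False, index=raw.index)
        ok_chrom = ~bad_chrom & ~bad_num
        if ok_chrom.any():
            len_a = raw.loc[ok_chrom, "chrom_a"].map(genome.lengths)
            len_b = raw.loc[ok_chrom, "chrom_b"].map(genome.lengths)
            too_long.loc[ok_chrom] = ((coords.loc[ok_chrom, "end_a"] > len_a) |
                                      (coords.loc[ok_chrom, "end_b"] > len_b))
    else:
        too_long = pd.Series(False, index=raw.index)

    reason = pd.Series("", index=raw.index)
    reason[too_long] = "interval beyond chromosome end"
    reason[empty_b.fillna(False)] = "empty interval"
    reason[empty_a.fillna(False)] = "empty interval"
    reason[neg.fillna(False)] = "negative coordinate"
    reason[bad_chrom] = "unknown chromosome"
    reason[bad_num] = "unparseable coordinates"
    bad = reason != ""
    for idx in raw.index[bad]:
        rejects.append((int(idx) + 1, reason[idx],
                        "\t".join(str(v) for v in raw.loc[idx])))

    good = raw[~bad].copy()
    for col in ("start_a", "end_a", "start_b", "end_b"):
        good[col] = coords.loc[~bad, col].astype(np.int64)
    good = canonicalize_pairs(good, genome)
    good = good[PAIR_COLUMNS].reset_index(drop=True)
    rejects = pd.DataFrame(rejects, columns=["line", "reason", "content"])
    return good, rejects


def write_bedpe(pairs: pd.DataFrame, path) -> None:
    """Write a pair table as 7-column BEDPE (subject id in the name column)."""
    out = pairs[["chrom_a", "start_a", "end_a",
                 "chrom_b", "start_b", "end_b", "subject"]]
    out.to_csv(path, sep="\t", header=False, index=False, **_open_kwargs(path))


# --- tracks ----------------------------------------------------------------

def read_bed(path, name: str | None = None) -> IntervalTrack:
    """BED 3-5 reader; column 4 (name) becomes the ``label`` column if present."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         **_open_kwargs(path))
    except pd.errors.EmptyDataError:
        return IntervalTrack(name or Path(path).stem,
                             pd.DataFrame(columns=["chrom", "start", "end"]))
    ncol = min(df.shape[1], 5)
    df = df.iloc[:, :ncol]
    df.columns = ["chrom", "start", "end", "label", "score"][:ncol]
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise ValueError(f"unparseable coordinate at {path}:{line}")
        df[col] = vals.astype(np.int64)
    return IntervalTrack(name or Path(path).stem, df)


def write_bed(track: IntervalTrack, path) -> None:
    cols = ["chrom", "start", "end"]
    if "label" in track.df.columns:
        cols.append("label")
    track.df[cols].to_csv(path, sep="\t", header=False, index=False,
                          **_open_kwargs(path))


def read_cytoband(path) -> IntervalTrack:
    """UCSC cytoBand.txt reader (chrom, start, end, band, gieStain).

    Validates the Giemsa stain vocabulary and that bands tile each chromosome
    without overlap (gaps are tolerated; overlap is not).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["chrom", "start", "end", "band", "label"],
                     **_open_kwargs(path))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    unknown = ~df["label"].isin(GIESTAIN_CLASSES)
    if unknown.any():
        i = int(df.index[unknown][0])
        raise ValueError(
            f"unknown gieStain label {df.loc[i, 'label']!r} at {path} line {i + 1}")
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping cytobands on {chrom} in {path}")
    return IntervalTrack("cytoband", df, label_vocabulary=GIESTAIN_CLASSES)


def write_cytoband(track: IntervalTrack, path) -> None:
    track.df[["chrom", "start", "end", "band", "label"]].to_csv(
        path, sep="\t", header=False, index=False, **_open_kwargs(path))


# --- cohort ----------------------------------------------------------------

def read_cohort(path) -> Cohort:
    """Cohort TSV: subject, group, optional subgroup, optional gender columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, **_open_kwargs(path))
    lower = {c.lower(): c for c in df.columns}
    if "subject" not in lower or "group" not in lower:
        raise ValueError("cohort TSV needs header columns 'subject' and 'group'")
    rename = {lower[k]: k for k in ("subject", "group", "subgroup", "gender")
              if k in lower}
    return Cohort(df.rename(columns=rename))


# --- catalogs --------------------------------------------------------------

_NOTATION_RE = re.compile(
    r"^t\(\s*([0-9XYxy]+)\s*;\s*([0-9XYxy]+)\s*\)"
    r"\(\s*([pq][0-9.]*)\s*;\s*([pq][0-9.]*)\s*\)$"
)


def parse_notation(text: str, chrom_prefix: str = "chr"):
    """Parse translocation notation t(A;B)(bandA;bandB).

    >>> parse_notation("t(11;22)(q23;q11)")
    (('chr11', 'q23'), ('chr22', 'q11'))
    """
    m = _NOTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed translocation notation: {text!r}")
    ca, cb, ba, bb = m.groups()
    return (f"{chrom_prefix}{ca.upper() if ca.upper() in 'XY' else ca}", ba), \
           (f"{chrom_prefix}{cb.upper() if cb.upper() in 'XY' else cb}", bb)


def read_catalog(path) -> tuple[list[CatalogRecord], pd.DataFrame]:
    """Catalog TSV reader.

    Accepted layouts (header-driven):
      * ``record_id  source  notation``  — t(A;B)(bandA;bandB) strings, or
      * ``record_id  source  chrom_a  band_a|start_a,end_a  chrom_b  ...``
        with either ``band_x`` or both ``start_x``/``end_x`` per locus.
    Unparseable rows go to the reject report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, **_open_kwargs(path))
    records: list[CatalogRecord] = []
    rejects = []
    for i, row in df.iterrows():
        try:
            if "notation" in df.columns and isinstance(row.get("notation"), str):
                (ca, ba), (cb, bb) = parse_notation(row["notation"])
                rec = CatalogRecord(row["record_id"], row.get("source", "unknown"),
                                    ca, ba, None, cb, bb, None)
            else:
                def locus(side):
                    chrom = row[f"chrom_{side}"]
                    band = row.get(f"band_{side}")
                    if isinstance(band, str) and band:
                        return chrom, band, None
                    iv = GenomicInterval(chrom, int(row[f"start_{side}"]),
                                         int(row[f"end_{side}"]))
                    return chrom, None, iv
                ca, ba, iva = locus("a")
                cb, bb, ivb = locus("b")
                rec = CatalogRecord(row["record_id"], row.get("source", "unknown"),
                                    ca, ba, iva, cb, bb, ivb)
            records.append(rec)
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append((int(i) + 2, str(exc)))  # +2: header + 1-based
    return records, pd.DataFrame(rejects, columns=["line", "reason"])
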