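"""Cohort-level descriptive characterization of the surviving call set.

Fragment-size distribution, per-subject burden and genome coverage, and
overlap of fragments with annotation tracks (genic / CDS / Giemsa stain
classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, IntervalTrack, _merge_arrays
from .io import Cohort

__all__ = ["SizeSummary", "SubjectSummary", "size_summary", "subject_summary",
           "annotation_overlap", "fragment_table", "intra_fraction"]


@dataclass
class SizeSummary:
    """Distribution of translocated-fragment lengths.

    Each pair contributes both fragment lengths to the distribution; the
    large-size count is per *pair* (either fragment above the threshold).
    """

    count: int
    mean: float
    median: float
    min: int
    max: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    pairs_over_threshold: int
    large_threshold: int


@dataclass
class SubjectSummary:
    per_subject: pd.DataFrame  # subject, pair_count, coverage_fraction
    mean_pairs: float
    interval_95: tuple[float, float]  # central 2.5-97.5 percentile of counts
    mean_coverage: float
    pooled_coverage: float
    unresolved_subjects: list


def fragment_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Long-format table of individual fragments (two rows per pair)."""
    a = pairs[["subject", "chrom_a", "start_a", "end_a"]].rename(
        columns={"chrom_a": "chrom", "start_a": "start", "end_a": "end"})
    b = pairs[["subject", "chrom_b", "start_b", "end_b"]].rename(
        columns={"chrom_b": "chrom", "start_b": "start", "end_b": "end"})
    return pd.concat([a, b], ignore_index=True)


def size_summary(pairs: pd.DataFrame, large_threshold: int = 1000,
                 bin_width: int = 25) -> SizeSummary:
    """Fragment-length statistics plus histogram at ``bin_width`` granularity."""
    if len(pairs) == 0:
        raise ValueError("size_summary needs at least one pair")
    len_a = (pairs["end_a"] - pairs["start_a"]).to_numpy()
    len_b = (pairs["end_b"] - pairs["start_b"]).to_numpy()
    lengths = np.concatenate([len_a, len_b])
    hi = int(np.ceil(lengths.max() / bin_width)) * bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return SizeSummary(
        count=len(lengths),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        min=int(lengths.min()),
        max=int(lengths.max()),
        hist_edges=edges,
        hist_counts=counts,
        pairs_over_threshold=int(((len_a > large_threshold) |
                                  (len_b > large_threshold)).sum()),
        large_threshold=large_threshold,
    )


def intra_fraction(pairs: pd.DataFrame) -> float:
    """Share of pairs with both fragments on one chromosome."""
    if len(pairs) == 0:
        raise ValueError("intra_fraction needs at least one pair")
    return float((pairs["kind"] == "intra").mean())


def _union_bp_frame(frags: pd.DataFrame) -> int:
    total = 0
    for chrom, grp in frags.groupby("chrom", sort=False):
        s, e = _merge_arrays(grp["start"].to_numpy(np.int64),
                             grp["end"].to_numpy(np.int64))
        total += int((e - s).sum())
    return total


def subject_summary(pairs: pd.DataFrame, cohort: Cohort,
                    genome: GenomeModel) -> SubjectSummary:
    """Per-subject pair counts and genome-coverage fractions.

    Subjects in the pair table but not in the cohort are listed and excluded;
    cohort subjects with no pairs count 0.
    """
    unresolved = cohort.unresolved(pairs)
    known = pairs[pairs["subject"].isin(set(cohort.subjects))]
    counts = known["subject"].value_counts()
    counts = counts.reindex(cohort.subjects, fill_value=0)

    frags = fragment_table(known)
    g_total = genome.total_bp
    cov = {}
    for subject, grp in frags.groupby("subject", sort=False):
        cov[subject] = _union_bp_frame(grp) / g_total
    cov_series = pd.Series(cov).reindex(cohort.subjects, fill_value=0.0)

    per_subject = pd.DataFrame({
        "subject": cohort.subjects,
        "pair_count": counts.to_numpy(),
        "coverage_fraction": cov_series.to_numpy(),
    })
    lo, hi = np.percentile(per_subject["pair_count"], [2.5, 97.5])
    pooled = _union_bp_frame(frags) / g_total if len(frags) else 0.0
    return SubjectSummary(
        per_subject=per_subject,
        mean_pairs=float(per_subject["pair_count"].mean()),
        interval_95=(float(lo), float(hi)),
        mean_coverage=float(per_subject["coverage_fraction"].mean()),
        pooled_coverage=float(pooled),
        unresolved_subjects=unresolved,
    )


def annotation_overlap(pairs: pd.DataFrame, track: IntervalTrack,
                       labels=None) -> dict:
    """Overlap of translocated fragments with an annotation track.

    Returns both interpretations of "fraction in the annotation":

    * ``fragment_fraction`` — fragments with >= 1 bp overlap / all fragments
      (the default reading), and
    * ``base_fraction`` — covered fragment-union bases inside the annotation
      / all covered bases.

    ``labels`` restricts a labeled track to a class subset (e.g. the
    G-positive stain classes) before computing either fraction.
    """
    if labels is not None:
        track = track.subset(labels)
    frags = fragment_table(pairs)
    n_hit = 0
    covered_in = 0
    covered_all = 0
    for chrom, grp in frags.groupby("chrom", sort=False):
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        n_hit += int(track.overlaps_any(chrom, s, e).sum())
        ms, me = _merge_arrays(s, e)
        covered_all += int((me - ms).sum())
        covered_in += int(track.covered_bp(chrom, ms, me).sum())
    return {
        "fragment_fraction": n_hit / len(frags) if len(frags) else 0.0,
        "base_fraction": covered_in / covered_all if covered_all else 0.0,
        "fragments": int(len(frags)),
        "fragments_overlapping": int(n_hit),
    }
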