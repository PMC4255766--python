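"""Two-stage false-positive filtering of translocation calls.

Calls produced by discordant-read-pair SV callers are notoriously enriched
for alignment artifacts in simple repeats and low-mappability regions. The
pipeline removes, in a fixed order:

1. exact duplicate records within a subject,
2. pairs with either fragment touching a simple-repeat interval (any
   overlap), and
3. pairs whose worse fragment is covered by low-mappability regions at or
   above a kind-dependent threshold — 85% for intrachromosomal and 50% for
   interchromosomal pairs by default.

The removal predicates are mutually independent, so the surviving set does
not depend on stage order; the report attributes each removed pair to the
first applicable stage in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import IntervalTrack
from .io import PAIR_COLUMNS

__all__ = ["FilterConfig", "FilterReport", "dedupe", "repeat_filter",
           "mappability_filter", "run_filters", "fraction_removed"]


@dataclass
class FilterConfig:
    """Thresholds and switches for the filtering stage."""

    intra_lowmap_threshold: float = 0.85
    inter_lowmap_threshold: float = 0.50
    repeat_filter: bool = True
    mappability_filter: bool = True
    dedupe: bool = True

    def __post_init__(self) -> None:
        for name in ("intra_lowmap_threshold", "inter_lowmap_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class FilterReport:
    input_count: int
    removed_duplicate: int
    removed_repeat: int
    removed_mappability: int
    surviving: int

    @property
    def fraction_removed(self) -> float:
        if self.input_count == 0:
            return 0.0
        return 1.0 - self.surviving / self.input_count

    def validate(self) -> None:
        removed = self.removed_duplicate + self.removed_repeat + self.removed_mappability
        if self.input_count != self.surviving + removed:
            raise AssertionError("filter report does not balance")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_removed"] = self.fraction_removed
        return d


def fraction_removed(raw_count: int, surviving_count: int) -> float:
    """Share of input calls removed: (raw - surviving) / raw."""
    if raw_count <= 0:
        raise ValueError("raw_count must be positive")
    return (raw_count - surviving_count) / raw_count


def dedupe(pairs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop exact per-subject coordinate duplicates, keeping first occurrence.

    Identical coordinates in *different* subjects are independent
    observations and are kept.
    """
    keep = ~pairs.duplicated(subset=["subject", "chrom_a", "start_a", "end_a",
                                     "chrom_b", "start_b", "end_b"])
    return pairs[keep].reset_index(drop=True), int((~keep).sum())


def _fragment_mask(pairs: pd.DataFrame, fn) -> np.ndarray:
    """Apply a per-chromosome vectorized predicate to both fragments; OR them."""
    mask = np.zeros(len(pairs), dtype=bool)
    for side in ("a", "b"):
        chroms = pairs[f"chrom_{side}"]
        starts = pairs[f"start_{side}"].to_numpy()
        ends = pairs[f"end_{side}"].to_numpy()
        for chrom in chroms.unique():
            idx = (chroms == chrom).to_numpy()
            mask[idx] |= fn(chrom, starts[idx], ends[idx], side, idx)
    return mask


def repeat_filter(pairs: pd.DataFrame, repeat_track: IntervalTrack
                  ) -> tuple[pd.DataFrame, int]:
    """Remove pairs with >= 1 bp of either fragment inside a repeat interval."""
    hit = _fragment_mask(
        pairs, lambda chrom, s, e, side, idx: repeat_track.overlaps_any(chrom, s, e))
    return pairs[~hit].reset_index(drop=True), int(hit.sum())


def _lowmap_fractions(pairs: pd.DataFrame, lowmap_track: IntervalTrack) -> np.ndarray:
    """(n, 2) array of low-mappability coverage fractions per fragment."""
    out = np.zeros((len(pairs), 2))
    for j, side in enumerate(("a", "b")):
        chroms = pairs[f"chrom_{side}"]
        starts = pairs[f"start_{side}"].to_numpy()
        ends = pairs[f"end_{side}"].to_numpy()
        for chrom in chroms.unique():
            idx = (chroms == chrom).to_numpy()
            cov = lowmap_track.covered_bp(chrom, starts[idx], ends[idx])
            out[idx, j] = cov / (ends[idx] - starts[idx])
    return out


def mappability_filter(pairs: pd.DataFrame, lowmap_track: IntervalTrack,
                       config: FilterConfig | None = None
                       ) -> tuple[pd.DataFrame, int]:
    """Remove pairs heavily overlapping low-mappability regions.

    A pair is removed iff the larger of its two fragment coverage fractions
    reaches the threshold for its kind ("at least": inclusive >=) — 0.85 for
    intrachromosomal, 0.50 for interchromosomal pairs.
    """
    config = config or FilterConfig()
    frac = _lowmap_fractions(pairs, lowmap_track).max(axis=1)
    thresh = np.where(pairs["kind"].to_numpy() == "intra",
                      config.intra_lowmap_threshold,
                      config.inter_lowmap_threshold)
    hit = frac >= thresh
    return pairs[~hit].reset_index(drop=True), int(hit.sum())


def run_filters(pairs: pd.DataFrame,
                repeat_track: IntervalTrack | None = None,
                lowmap_track: IntervalTrack | None = None,
                config: FilterConfig | None = None
                ) -> tuple[pd.DataFrame, FilterReport]:
    """Run dedupe -> repeat -> mappability and return survivors plus report."""
    config = config or FilterConfig()
    n_in = len(pairs)
    n_dup = n_rep = n_map = 0
    out = pairs
    if config.dedupe:
        out, n_dup = dedupe(out)
    if config.repeat_filter:
        if repeat_track is None:
            raise ValueError("repeat filter enabled but no repeat track given")
        out, n_rep = repeat_filter(out, repeat_track)
    if config.mappability_filter:
        if lowmap_track is None:
            raise ValueError("mappability filter enabled but no low-mappability "
                             "track given")
        out, n_map = mappability_filter(out, lowmap_track, config)
    report = FilterReport(n_in, n_dup, n_rep, n_map, len(out))
    report.validate()
    return out, report
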