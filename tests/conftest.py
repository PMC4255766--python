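"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (per-base loops, full candidate
enumeration) and independent of the library's vectorized implementations;
equivalence tests pit the two against each other on randomized instances.
"""

import numpy as np
import pandas as pd
import pytest

from xchange import GenomeModel, IntervalTrack
from xchange.io import canonicalize_pairs, PAIR_COLUMNS


# --- brute-force oracles ----------------------------------------------------

def brute_covered_bp(intervals, start, end):
    """Per-base count of positions in [start, end) covered by any interval."""
    return sum(1 for p in range(start, end)
               if any(s <= p < e for s, e in intervals))


def brute_overlap_fraction(intervals, start, end):
    return brute_covered_bp(intervals, start, end) / (end - start)


def brute_union_bp(intervals):
    positions = set()
    for s, e in intervals:
        positions.update(range(s, e))
    return len(positions)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_planted_motifs(seqs, l, d):
    """Full 4^l enumeration of the planted (l, d) motif search."""
    from itertools import product
    out = []
    for cand in product("ACGT", repeat=l):
        cand = "".join(cand)
        if all(any(hamming(cand, s[i:i + l]) <= d
                   for i in range(len(s) - l + 1)) for s in seqs):
            out.append(cand)
    return out


# --- fixtures ---------------------------------------------------------------

@pytest.fixture
def toy_genome():
    return GenomeModel({"chr1": 100_000, "chr2": 100_000, "chr3": 100_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


def random_track(rng, genome, n=30, max_len=400, name="track"):
    rows = []
    for _ in range(n):
        chrom = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        length = int(rng.integers(10, max_len))
        start = int(rng.integers(0, genome.length(chrom) - length))
        rows.append((chrom, start, start + length))
    return IntervalTrack(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def random_pairs(rng, genome, n=50, n_subjects=5, max_len=300):
    rows = []
    chroms = genome.chromosomes
    for _ in range(n):
        rec = []
        for _ in range(2):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(20, max_len))
            start = int(rng.integers(0, genome.length(chrom) - length))
            rec += [chrom, start, start + length]
        rows.append([f"S{rng.integers(n_subjects)}"] + rec)
    df = pd.DataFrame(rows, columns=["subject", "chrom_a", "start_a", "end_a",
                                     "chrom_b", "start_b", "end_b"])
    return canonicalize_pairs(df, genome)[PAIR_COLUMNS]


@pytest.fixture(scope="session")
def small_sim():
    """A reduced end-to-end simulation shared across read-only tests."""
    import xchange as x
    cfg = x.default_desk_config(seed=7)
    cfg.group_sizes = {g: 10 for g in cfg.group_sizes}
    cfg.pairs_per_subject = 400
    for h in cfg.hot_regions:
        h.occurrence = 200
    return x.simulate(cfg)
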