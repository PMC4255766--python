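"""Motif occurrence scanning and brute-force planted (l, d) motif search.

The planted-motif problem: given sequences and parameters (l, d), find all
length-l strings that occur in *every* sequence within Hamming distance d.
The search here enumerates the d-neighborhoods of the observed l-mers —
exact and complete at desk scale (l <= 14, d <= 3), which is all the
pipeline needs to characterize a handful of hot-region sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = ["motif_occurrence", "planted_motif_search", "reverse_complement",
           "read_fasta", "write_fasta"]

_ALPHABET = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid DNA character {exc.args[0]!r}") from None


def _window_matrix(seq: str, l: int) -> np.ndarray:
    """(n_windows, l) int8 matrix of all l-mers of a sequence."""
    arr = _encode(seq)
    if len(arr) < l:
        return np.empty((0, l), dtype=np.int8)
    return np.lib.stride_tricks.sliding_window_view(arr, l)


def motif_occurrence(sequences: dict[str, str], motif: str,
                     max_mismatch: int = 0, both_strands: bool = True) -> dict:
    """Scan sequences for a motif, allowing mismatches and both strands.

    N positions never match. Returns per-sequence hit tables (offset,
    strand, mismatches) and the fraction of sequences with at least one hit.
    """
    motif = motif.upper()
    if set(motif) - set(_ALPHABET):
        raise ValueError(f"motif contains invalid characters: {motif!r}")
    l = len(motif)
    if any(len(s) < l for s in sequences.values()):
        short = [n for n, s in sequences.items() if len(s) < l]
        raise ValueError(f"motif longer than sequence(s): {short}")
    targets = [( "+", _encode(motif))]
    if both_strands:
        targets.append(("-", _encode(reverse_complement(motif))))
    rows = []
    for name, seq in sequences.items():
        windows = _window_matrix(seq, l)
        for strand, enc in targets:
            # N (code 4) differs from every target code, so it never matches
            mism = (windows != enc).sum(axis=1)
            for off in np.flatnonzero(mism <= max_mismatch):
                rows.append((name, int(off), strand, int(mism[off])))
    hits = pd.DataFrame(rows, columns=["sequence", "offset", "strand",
                                       "mismatches"])
    n_with = hits["sequence"].nunique() if len(hits) else 0
    return {"hits": hits,
            "fraction_with_hit": n_with / len(sequences) if sequences else 0.0,
            "sequences_with_hit": int(n_with),
            "n_sequences": len(sequences)}


def _decode(codes) -> str:
    return "".join(_ALPHABET[c] for c in codes)


def _neighborhood(word: tuple, d: int):
    """All l-mers within Hamming distance d of ``word`` (codes 0-3)."""
    l = len(word)
    out = set()
    for k in range(d + 1):
        for pos in combinations(range(l), k):
            for repl in product(range(4), repeat=k):
                w = list(word)
                ok = True
                for p, r in zip(pos, repl):
                    if w[p] == r:
                        ok = False  # substitution must change the letter
                        break
                    w[p] = r
                if ok or k == 0:
                    out.add(tuple(w))
    return out


def planted_motif_search(sequences: dict[str, str] | list[str], l: int, d: int
                         ) -> list[str]:
    """All l-mers present within Hamming distance d in every sequence.

    Candidates are the union of d-neighborhoods of the first sequence's
    l-mers (any solution must be within d of some window of every sequence,
    so the smallest neighborhood suffices); each candidate is then verified
    against every sequence. Output is lexicographically sorted.

    Guarded to l <= 14 and d <= 3: beyond that the neighborhood enumeration
    is no longer a desk-scale computation and a specialized solver is the
    right tool.
    """
    if l > 14 or d > 3 or l < 1 or d < 0:
        raise ValueError(
            f"planted_motif_search supports 1 <= l <= 14 and 0 <= d <= 3, "
            f"got l={l}, d={d}")
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    window_sets = []
    for s in seqs:
        w = _window_matrix(s, l)
        if len(w) == 0:
            raise ValueError("sequence shorter than motif length")
        window_sets.append(w)

    if d >= l:  # saturation: every candidate matches every window
        return sorted(_decode(c) for c in product(range(4), repeat=l))

    # seed from the sequence with the fewest windows
    seed = min(window_sets, key=len)
    candidates = set()
    for row in seed:
        npos = np.flatnonzero(row == 4)
        word = tuple(int(x) for x in row)
        if len(npos) == 0:
            candidates |= _neighborhood(word, d)
            continue
        # every N position is a forced mismatch against any ACGT candidate
        if len(npos) > d:
            continue
        budget = d - len(npos)
        for repl in product(range(4), repeat=len(npos)):
            w = list(word)
            for p, r in zip(npos, repl):
                w[p] = r
            candidates |= _neighborhood(tuple(w), budget)

    result = []
    for cand in candidates:
        enc = np.array(cand, dtype=np.int8)
        if all(((w != enc).sum(axis=1) <= d).any() for w in window_sets):
            result.append(_decode(cand))
    return sorted(result)
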