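"""Enrichment and cohort statistics.

* chromosome-pair enrichment scores for interchromosomal exchange,
* Pearson chi-square homogeneity test of carrier rates across groups,
* Giemsa-stain-class enrichment of fragments (Fisher exact),
* gender effect on per-subject burden (Welch t),
* hypergeometric gene-set enrichment with Benjamini-Hochberg adjustment.

The enrichment score for chromosomes i and j is the observed
interchromosomal pair count N_ij divided by its expectation under
independent marginals:

    score_ij = N_ij / (N_i/N * N_j/N * N) = N_ij * N / (N_i * N_j)

with N_i the number of inter pairs involving chromosome i and N the total
inter pair count. Scores above 1 mark chromosome pairs exchanging more
material than their overall activities predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, IntervalTrack
from .io import Cohort, G_POSITIVE
from .landscape import fragment_table

__all__ = ["EnrichmentMatrix", "enrichment_matrix", "group_rate_test",
           "stain_enrichment", "gender_test", "gene_set_enrichment"]


@dataclass
class EnrichmentMatrix:
    """Observed/expected interchromosomal exchange per chromosome pair."""

    chromosomes: list
    observed: pd.DataFrame   # symmetric N_ij, zero diagonal
    scores: pd.DataFrame     # symmetric score_ij; NaN where undefined
    marginals: pd.Series     # N_i
    total: int               # N

    def flat_scores(self) -> np.ndarray:
        """Upper-triangle scores (defined entries only), histogram-ready."""
        vals = []
        chroms = self.chromosomes
        for i in range(len(chroms)):
            for j in range(i + 1, len(chroms)):
                v = self.scores.iloc[i, j]
                if not np.isnan(v):
                    vals.append(v)
        return np.array(vals)

    def top_pairs(self, k: int = 3) -> list[tuple[str, str, float]]:
        flat = []
        chroms = self.chromosomes
        for i in range(len(chroms)):
            for j in range(i + 1, len(chroms)):
                v = self.scores.iloc[i, j]
                if not np.isnan(v):
                    flat.append((chroms[i], chroms[j], float(v)))
        flat.sort(key=lambda t: -t[2])
        return flat[:k]


def enrichment_matrix(pairs: pd.DataFrame,
                      genome: GenomeModel | None = None) -> EnrichmentMatrix:
    """Chromosome-pair enrichment scores from interchromosomal pairs.

    Intra pairs are excluded. Chromosomes with no inter pairs have undefined
    scores (reported NaN, never 0).
    """
    inter = pairs[pairs["kind"] == "inter"]
    if len(inter) == 0:
        raise ValueError("enrichment_matrix needs at least one inter pair")
    if genome is not None:
        chroms = genome.chromosomes
    else:
        chroms = sorted(set(inter["chrom_a"]) | set(inter["chrom_b"]))
    idx = {c: i for i, c in enumerate(chroms)}
    n = len(chroms)
    obs = np.zeros((n, n), dtype=np.int64)
    counts = inter.groupby(["chrom_a", "chrom_b"], sort=False).size()
    for (ca, cb), c in counts.items():
        obs[idx[ca], idx[cb]] += c
        obs[idx[cb], idx[ca]] += c
    marg = obs.sum(axis=1)  # N_i
    total = int(marg.sum() // 2)  # each pair counted once per involved chromosome
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.outer(marg, marg) / total
        scores = np.where(expected > 0, obs * 1.0 / np.where(expected > 0, expected, 1),
                          np.nan)
    np.fill_diagonal(scores, np.nan)
    return EnrichmentMatrix(
        chromosomes=list(chroms),
        observed=pd.DataFrame(obs, index=chroms, columns=chroms),
        scores=pd.DataFrame(scores, index=chroms, columns=chroms),
        marginals=pd.Series(marg, index=chroms),
        total=total,
    )


def group_rate_test(carriers, sizes) -> dict:
    """Pearson chi-square homogeneity test of carrier rates across k groups.

    Closed-form Pearson statistic on the 2 x k carriers/non-carriers table,
    df = k - 1, no continuity correction.
    """
    carriers = np.asarray(carriers, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(carriers) < 2:
        raise ValueError("need at least two groups")
    if (sizes <= 0).any():
        raise ValueError("every group must be non-empty")
    if (carriers > sizes).any() or (carriers < 0).any():
        raise ValueError("carriers must satisfy 0 <= carriers <= size")
    table = np.vstack([carriers, sizes - carriers])  # 2 x k observed
    col = table.sum(axis=0)
    rowsum = table.sum(axis=1)
    total = table.sum()
    expected = np.outer(rowsum, col) / total
    if (expected == 0).any():
        # all carriers or all non-carriers: rates identical by construction
        return {"statistic": 0.0, "df": len(carriers) - 1, "p_value": 1.0}
    stat = float(((table - expected) ** 2 / expected).sum())
    df = len(carriers) - 1
    return {"statistic": stat, "df": df,
            "p_value": float(stats.chi2.sf(stat, df))}


def stain_enrichment(pairs: pd.DataFrame, cytoband: IntervalTrack,
                     classes=G_POSITIVE,
                     genome: GenomeModel | None = None) -> dict:
    """Fisher exact test of fragment enrichment in a stain-class subset.

    Contingency construction: fragments overlapping the class union vs not,
    against the genome's base composition rescaled to fragment-equivalent
    units (class bp and non-class bp each divided by the mean fragment
    length, rounded). The full 2 x 2 table is returned so callers can
    substitute their own background counts.
    """
    classes = tuple(classes)
    sub = cytoband.subset(classes)
    if len(sub) == 0:
        raise ValueError(f"classes {classes} absent from track {cytoband.name!r}")
    frags = fragment_table(pairs)
    n_in = 0
    for chrom, grp in frags.groupby("chrom", sort=False):
        n_in += int(sub.overlaps_any(chrom, grp["start"].to_numpy(np.int64),
                                     grp["end"].to_numpy(np.int64)).sum())
    n_out = len(frags) - n_in
    mean_len = float((frags["end"] - frags["start"]).mean())
    class_bp = sub.union_bp()
    if genome is not None:
        total_bp = genome.total_bp
    else:
        total_bp = cytoband.union_bp()
    bg_in = int(round(class_bp / mean_len))
    bg_out = int(round((total_bp - class_bp) / mean_len))
    table = np.array([[n_in, n_out], [bg_in, bg_out]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
            "p_value": float(p), "classes": classes}


def gender_test(per_subject_counts: pd.Series | dict, cohort: Cohort) -> dict:
    """Welch two-sample t-test of per-subject pair counts by gender.

    Subjects with unknown gender are excluded.
    """
    counts = pd.Series(per_subject_counts)
    gender = pd.Series(cohort.gender_of())
    merged = pd.DataFrame({"count": counts, "gender": gender}).dropna()
    males = merged.loc[merged["gender"] == "M", "count"].to_numpy(float)
    females = merged.loc[merged["gender"] == "F", "count"].to_numpy(float)
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need >= 2 subjects of each gender with counts")
    res = stats.ttest_ind(males, females, equal_var=False)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_male": len(males), "n_female": len(females),
            "mean_male": float(males.mean()), "mean_female": float(females.mean())}


def gene_set_enrichment(query: set, term_genes: dict, reference: set,
                        min_term_size: int = 15, max_term_size: int = 250
                        ) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in annotation terms.

    Per term (restricted to ``min_term_size <= C <= max_term_size`` reference
    genes): C reference genes in the term, O query genes in the term,
    expectation E = C*k/M (k query size, M reference size), enrichment ratio
    R = O/E, rawP = P[X >= O] for X ~ Hypergeom(M, C, k), and
    Benjamini-Hochberg adjP across the surviving terms. Sorted by rawP.
    """
    if not query:
        raise ValueError("empty query gene set")
    reference = set(reference)
    query = set(query)
    if not query <= reference:
        missing = sorted(query - reference)
        raise ValueError(f"query genes missing from reference: {missing[:5]}")
    M, k = len(reference), len(query)
    rows = []
    for term, genes in term_genes.items():
        genes = set(genes) & reference
        C = len(genes)
        if not (min_term_size <= C <= max_term_size):
            continue
        O = len(genes & query)
        E = C * k / M
        rawp = float(stats.hypergeom.sf(O - 1, M, C, k))
        rows.append((term, C, O, E, O / E if E > 0 else np.nan, rawp))
    df = pd.DataFrame(rows, columns=["term", "C", "O", "E", "R", "rawP"])
    if len(df):
        from statsmodels.stats.multitest import multipletests
        df["adjP"] = multipletests(df["rawP"], method="fdr_bh")[1]
        df = df.sort_values("rawP", kind="stable").reset_index(drop=True)
    else:
        df["adjP"] = []
    return df
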