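"""Chromosome-pair enrichment, group/gender statistics, gene-set
over-representation, and motif scanning.

Enrichment scores are observed/expected interchromosomal pair counts under
independent chromosome marginals; with no planted chromosome preference
they concentrate at n/(2(n-1)). The gene-set block reproduces the O/E
ratio convention of over-representation tools; the motif block scans
hot-region sequences for the planted 10-mer.
"""

import numpy as np

import xchange as x

cfg = x.default_desk_config(seed=5)
cfg.group_sizes = {g: 12 for g in cfg.group_sizes}
cfg.pairs_per_subject = 500
for h in cfg.hot_regions:
    h.occurrence = 250
sim = x.simulate(cfg)
pairs, _ = x.run_filters(sim.pairs.drop(columns="provenance"),
                         sim.repeats, sim.lowmap)

m = x.enrichment_matrix(pairs, sim.genome)
n = len(m.chromosomes)
print(f"inter pairs: {m.total}; enrichment scores mean "
      f"{m.flat_scores().mean():.3f} (uniform expectation "
      f"{n / (2 * (n - 1)):.3f})")
print("top pairs:", [(a, b, round(s, 3)) for a, b, s in m.top_pairs(3)])

counts = pairs["subject"].value_counts().reindex(sim.cohort.subjects,
                                                 fill_value=0)
g = x.gender_test(counts, sim.cohort)
print(f"gender effect on burden: t={g['statistic']:.2f}, p={g['p_value']:.3f} "
      f"(no effect planted)")

se = x.stain_enrichment(pairs, sim.cytoband, genome=sim.genome)
print(f"G-positive enrichment: OR={se['odds_ratio']:.2f}, "
      f"p={se['p_value']:.2g} (fragments placed uniformly)")

# gene-set over-representation on a synthetic annotation
rng = np.random.default_rng(0)
reference = {f"g{i}" for i in range(2000)}
terms = {f"T{t}": set(rng.choice(sorted(reference), 60, replace=False))
         for t in range(8)}
query = set(rng.choice(sorted(terms["T0"]), 12, replace=False)) | \
        set(rng.choice(sorted(reference), 48, replace=False))
enr = x.gene_set_enrichment(query, terms, reference)
top = enr.iloc[0]
print(f"gene-set: top term {top['term']} C={top['C']} O={top['O']} "
      f"E={top['E']:.2f} R={top['R']:.1f} rawP={top['rawP']:.2g} "
      f"adjP={top['adjP']:.2g}")

occ = x.motif_occurrence(sim.sequences, cfg.motif)
print(f"motif {cfg.motif} found in {occ['sequences_with_hit']}/"
      f"{occ['n_sequences']} hot-region sequences")
motifs = x.planted_motif_search(list(sim.sequences.values()), l=10, d=0)
print(f"planted (10,0) motif search over the same sequences: {motifs}")
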