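# xchange

Genome-wide characterization of chromosomal material exchange from
population-scale translocation call sets.

Discordant-read-pair SV callers applied to low-coverage whole-genome
sequencing emit, per subject, millions of *translocated fragment pairs* —
two genomic intervals (usually on different chromosomes, ~100 bp each)
called as exchanged material. `xchange` turns such call sets (BEDPE, one
record per fragment pair) into a population-level picture:

* **Filtering** — removal of per-subject duplicate records, of pairs with a
  fragment touching a simple-repeat interval, and of pairs whose worse
  fragment is covered by low-mappability regions at ≥ 85% (intrachromosomal)
  or ≥ 50% (interchromosomal), the standard false-positive controls for
  alignment-artifact calls.
* **Landscape** — fragment-size distribution, per-subject burden and genome
  coverage, overlap with gene/CDS/Giemsa-stain annotation.
* **Recurrence** — per-subject carrier detection rates for arbitrary region
  pairs (e.g. the cytoband loci of known constitutional translocations such
  as t(11;22)(q23;q11)); a genome-wide scan of 200-bp bin pairs ranked by
  cohort detection rate; hot regions located by pooled fragment occurrence
  with partner-location profiles.
* **Enrichment** — chromosome-pair enrichment scores

  `score_ij = N_ij / (N_i/N · N_j/N · N) = N_ij · N / (N_i · N_j)`

  where `N_ij` is the observed interchromosomal pair count between
  chromosomes *i* and *j*, `N_i` the inter count involving *i* and `N` the
  total inter count; Pearson chi-square homogeneity tests of carrier rates
  across cohort groups; Fisher-exact stain-class enrichment; Welch *t* for
  gender effects; and hypergeometric gene-set over-representation
  (`E = C·k/M`, `R = O/E`, Benjamini–Hochberg adjustment, term size
  bounded to 15–250 genes).
* **Catalog comparison** — cytoband→bp conversion (hierarchical band-name
  prefix matching against a UCSC-style cytoband table) and per-record
  carrier rates for external translocation catalogs.
* **Motif** — both-strand motif occurrence scanning over hot-region
  sequences and an exact brute-force planted (l, d) motif search
  (all l-mers within Hamming distance d of a window in every sequence).
* **Synthetic data** — a ground-truthed generator for every input the
  pipeline consumes: per-subject BEDPE with a truncated-lognormal fragment
  size model (mean ≈102 bp, median ≈101 bp, rare >1 kb tail), ~0.11%
  intrachromosomal share, planted hot regions, recurrent region pairs with
  per-group carrier probabilities, track-overlapping false positives,
  duplicates, and a planted sequence motif.

## Worked example

```python
import xchange as x

cfg = x.default_desk_config(seed=42)
cfg.group_sizes = {g: 12 for g in cfg.group_sizes}   # 60 subjects
cfg.pairs_per_subject = 500
for h in cfg.hot_regions:
    h.occurrence = 250

sim = x.simulate(cfg)
pairs, report = x.run_filters(sim.pairs.drop(columns="provenance"),
                              sim.repeats, sim.lowmap)
```

Running `python examples/01_simulate_and_filter.py` (the same code with
reporting) prints:

```
simulated 30703 fragment pairs for 60 subjects
  planted to be filtered: 5400 track-overlapping + 150 duplicates
filter removed 5550 pairs (18.1%):
  duplicates 150, repeat overlap 2827, low-mappability 2573
every removed pair was planted: True
```

i.e. the two-stage filter removes exactly the planted false-positive share
(the generator places genuine calls clear of both tracks, so nothing else
dies). `examples/03_recurrence_hotspots.py` then recovers the planted
structure from the surviving calls:

```
bin pairs at detection rate >= 20%: 6; top 3:
  chr2:5000000-5000200 <-> chr4:3000000-3000200  rate 78.0% (78 subjects)
  ...
hot regions (occurrence > 400): 3
  chr1:2000000-2000299 occurrence 577, top partner share 0.04 -> spread
  chr2:5000000-5000298 occurrence 572, top partner share 1.00 -> concentrated
  chr4:3000000-3000300 occurrence 572, top partner share 1.00 -> concentrated
```

The concentrated hot region and its reciprocal partner locus show partner
share ≈ 1 (all exchange flows between the two loci), while the spread
region's partners scatter genome-wide; the top bin pairs are the planted
reciprocal exchange carried by ~77% of subjects.

The remaining examples cover the landscape summaries
(`02_landscape.py`) and the enrichment/gene-set/motif statistics
(`04_enrichment_and_motif.py`). A thin CLI wraps the same pipeline:
`xchange all --seed 3 --out run/` simulates and runs every stage;
`xchange filter --bedpe calls.bedpe --chrom-sizes genome.sizes
--repeats repeats.bed --lowmap lowmap.bed --out filtered.bedpe` filters an
existing call set; `xchange run ...` analyses existing files.

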