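# Methods

## Data model and coordinates

All intervals are 0-based half-open (the BED/BEDPE convention); tables
that mirror cytogenetics reports render begins 1-based inclusive at write
time only. A *translocated fragment pair* is one subject's called exchange:
two intervals, canonically ordered by (genome chromosome order, start,
end) so duplicates are well defined; `kind` is `intra` iff both fragments
share a chromosome. Pair collections are pandas DataFrames; interval
tracks keep per-chromosome sorted merged arrays with a prefix sum of
covered bases, so coverage queries over 10^5–10^6 fragments are two
`searchsorted` calls per chromosome. Randomized per-base brute-force
equivalence tests guard this machinery.

## Filtering

Three removal predicates, applied dedupe → repeat → mappability:

* **Duplicates** — identical (subject, fragment_a, fragment_b) after
  canonicalization; first occurrence kept. Identical coordinates in
  different subjects are independent observations.
* **Repeat filter** — a pair dies if *either* fragment overlaps a
  simple-repeat interval by ≥ 1 bp (threshold-free by design; repeats are
  where spurious discordant mappings concentrate).
* **Low-mappability filter** — per fragment, the fraction of bases covered
  by the low-mappability track; the pair dies if the larger of its two
  fractions is ≥ 0.85 (intra) or ≥ 0.50 (inter). "At least" is inclusive:
  an inter pair at exactly 0.50 is removed. The per-fragment /
  either-fragment reading is the conservative resolution of an ambiguous
  convention (the alternatives — summed-over-pair, both-fragment — remove
  fewer dubious calls); thresholds are config keys.

The predicates are mutually independent, so the surviving set is
order-invariant; the report attributes each removal to the first
applicable stage and satisfies `input = surviving + Σ removed` exactly.

## Recurrence

Carrier semantics are per-subject presence/absence everywhere: a subject
either contributes ≥ 1 qualifying pair or does not, so one subject's pair
multiplicity never inflates a detection rate.

* **Region pairs** — a subject carries (A, B) iff some pair has one
  fragment overlapping A and the other overlapping B, either orientation;
  membership is any-overlap (fragments are tiny relative to cytobands).
  Rates are reported per cohort group and pooled; the pooled rate is
  identically the size-weighted mean of group rates.
* **Bin pairs** — the genome is tiled with fixed 200-bp bins (about twice
  the mean fragment size); a fragment contributes to every bin it touches,
  but each subject counts once per canonical bin pair. Same-bin self pairs
  are excluded. Records at or above the rate threshold are returned sorted
  by rate, ties in genomic order. As bin size → ∞ this degenerates to
  per-chromosome-pair carrier rates (asserted in tests).
* **Hot regions** — located by an occupancy scan: fragments pooled over
  all subjects are counted per fixed `scan_bin` (default 100 bp) window
  via any-overlap; windows strictly above `min_occurrence` (default 1,000)
  are hot; hot windows separated by ≤ `merge_gap` (default 0) coalesce;
  each region is reported with the [min start, max end) extent of its
  member fragments and their count as the occurrence. A naive
  single-linkage merge of raw fragments is not usable here: at realistic
  densities (fragment bases ≈ 0.5–2× the genome) uniform background
  chain-merges entire chromosomes into one cluster, drowning genuine
  stacks. The occupancy scan only surfaces loci where fragments actually
  pile beyond the threshold, and reproduces data-driven (non-round) region
  spans. The cost is that stacks closer than one scan bin cannot be
  resolved apart; `scan_bin` trades resolution against noise.
* **Partner profiles** — for every pair with one fragment in a region, the
  partner fragment is assigned to a 1-Mb bin; the modal bin's share
  separates "concentrated" regions (share ≈ 1, reciprocal exchange with one
  locus) from "spread" regions (share ≈ 1/k over k occupied bins).

## Enrichment and statistics

* **Chromosome-pair scores** — `score_ij = N_ij·N/(N_i·N_j)` over inter
  pairs only. Scores for chromosomes with `N_i = 0` are reported missing,
  never 0. Two exact identities are tested: uniform counts over n
  chromosomes give every score `n/(2(n−1))` (23 chromosomes → 23/44), and
  `Σ_{i<j} score_ij·N_i·N_j/N = N`. Note the score's null is *not* 1: a
  preference-free allocation concentrates at `n/(2(n−1))`.
* **Group homogeneity** — closed-form Pearson chi-square on the 2×k
  carriers/non-carriers table, df = k−1, no continuity correction (also
  for k = 2, for consistency); cross-checked against
  `scipy.stats.chi2_contingency`.
* **Stain enrichment** — Fisher exact on (fragments in/out of the stain
  class union) vs the genome's base composition rescaled to
  fragment-equivalent units (class bp and complement bp each divided by
  the mean fragment length, rounded). This 2×2 construction is a package
  definition — the background could equally be drawn in other ways — so
  the full table is returned for callers who substitute their own counts.
* **Gender** — Welch two-sample t on per-subject pair counts; subjects of
  unknown gender excluded.
* **Gene sets** — per term with 15 ≤ C ≤ 250 reference genes: E = C·k/M,
  R = O/E, rawP = upper-tail hypergeometric (scipy, verified against
  exhaustive enumeration for M ≤ 25), Benjamini–Hochberg adjP across
  surviving terms. BH is the concrete choice for the generic "multiple
  test adjustment" of over-representation tools.

## Catalogs and motifs

Band designations are converted to bp as the union of all bands whose name
starts with the query (so "q11" covers q11.1/q11.21, and "p1" an arm
prefix) — catalogs mix band resolutions, and the union is the faithful bp
rendering of a coarse designation. A catalog record "overlaps the results"
when ≥ 1 subject (configurable) carries a qualifying pair between its
loci; per-record carrier rates are reported alongside.

Motif occurrence scans both strands by default (reverse-complement hits
count; a single-strand flag exists), N never matches. The planted (l, d)
search enumerates the d-neighborhoods of one sequence's windows (the
smallest window set suffices for completeness: a solution must be within d
of a window of *every* sequence) and verifies candidates everywhere;
windows containing N seed via forced substitution at the N positions. It
is guarded to l ≤ 14, d ≤ 3 — an exact desk-scale computation, with a
specialized solver the right tool beyond that — and is verified against
full 4^l enumeration for small l.

## Synthetic data generator

The generator emulates a population study's inputs; its defaults are the
study conditions the package is tested under, not tuning knobs.

* **Fragment sizes** — lognormal(μ=4.61499, σ=0.13920) truncated to
  [65, 2000] bp, solved numerically so the truncated mean is 102 and
  median 101; a log-uniform [1000, 1886] component at 3.2×10⁻⁴ mirrors the
  observed rare >1 kb fragments. Realized mean ≈ 102.4.
* **Intra share** — 0.11% of background pairs, allocated per subject as
  floor + Bernoulli remainder so the realized share concentrates tightly
  at the target rather than wandering with per-pair Bernoulli noise.
* **Tracks** — random intervals to a target base density (repeats 4%
  mean length 300 bp; low-mappability 5%, 500 bp; genes 40%, 50 kb with
  CDS sub-intervals at 35% of gene length). Synthetic cytobands tile each
  chromosome with named p/q sub-bands and a centromeric `acen` band.
* **Planted structure** — a configured fraction (default 18%) of
  background pairs is relocated (fragment a only, same chromosome —
  preserving the pair's intra/inter kind) fully inside a repeat or
  low-mappability interval, guaranteeing removal; 0.5% are duplicated
  verbatim. All other pairs are rejection-sampled clear of both tracks and
  planted loci are carved out of the tracks, so removed = planted exactly
  and filter attribution is assertable. Hot regions stack `occurrence`
  fragments in a locus with partners either spread (uniform,
  interchromosomal) or concentrated at a fixed partner locus; concentrated
  regions with a carrier probability first draw Bernoulli carriers (fixing
  the detection rate) and distribute the occurrence over them. Recurrent
  region pairs are single 200-bp bin-aligned loci with per-group Bernoulli
  carriers, one pair per carrier. Realizations are recorded as ground
  truth next to the targets.
* **Determinism** — one `numpy` Generator seeded from the config; two runs
  at one seed are byte-identical including all written files.

What the generator does *not* emulate: read-level noise and breakpoint
uncertainty, chromosome-length and GC heterogeneity, linkage between
nearby calls, population structure beyond group-specific carrier
probabilities, and real repeat/mappability landscapes. Passing recovery
tests therefore demonstrate the pipeline's arithmetic and detection logic
under controlled truth, not caller accuracy on real alignments.

## Problem sizes and defaults

The desk-scale configuration — 5 chromosomes × 10 Mb, 200 subjects in 5
groups, ~2,000 background pairs/subject (~4×10⁵ pairs), 2 hot regions at
occurrence 1,500, 3 recurrent pairs (one near-universal at p = 0.769, two
group-varying) — runs the full pipeline in well under a minute on one CPU
and is the size at which parameter-recovery checks are stated. Unit and
property tests use smaller cohorts; the determinism sweep uses a 60-subject
reduction. Analysis thresholds default to: low-mappability 0.85/0.50,
recurrence bins 200 bp, hot-region occurrence 1,000 (scan bin 100 bp,
merge gap 0), large-fragment threshold 1 kb, gene-set term size 15–250,
bin-pair rate threshold 20%.

## Known limitations

* Hot regions closer than one scan bin merge; sub-bin localization is not
  attempted.
* The stain-enrichment background construction is one of several
  defensible 2×2 choices; compare odds ratios across tools with care.
* Group homogeneity tests on published group-rate tables reconstruct
  carrier counts by rounding rate×size; reconstructed p-values can differ
  from originally published ones when the original test used a finer group
  structure.
* `read_bedpe` accepts only the 7+ column dialect with the subject id in
  the name column; VCF BND import is out of scope.
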