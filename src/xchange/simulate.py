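"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the inputs a population-scale translocation study
consumes — per-subject BEDPE call sets with a realistic fragment-size
distribution, repeat / low-mappability / gene / CDS / cytoband tracks, a
cohort table, and FASTA sequences for hot regions — and plants structures
(hot regions, recurrent region pairs, track-overlapping false positives,
duplicates, a sequence motif) whose parameters are recorded as ground truth
so every downstream stage can be tested for recovery.

Emulation targets built into the defaults: fragment sizes with mean ~102 bp
and median ~101 bp on [65, 2000] with a rare >1 kb heavy tail; ~0.11%
intrachromosomal pairs; recurrent pairs with per-group carrier
probabilities; hot regions whose partners are either spread genome-wide or
concentrated at one reciprocal locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, GenomicInterval, IntervalTrack
from .io import (Cohort, GIESTAIN_CLASSES, canonicalize_pairs, pair_frame,
                 write_bedpe, write_bed, write_cytoband, PAIR_COLUMNS)
from .motif import reverse_complement, write_fasta

__all__ = ["SimulationConfig", "PlantedHotRegion", "PlantedRecurrentPair",
           "GroundTruth", "SimulationResult", "simulate", "default_desk_config"]

# Fragment-size model: lognormal(mu, sigma) truncated to [size_min, size_max],
# solved numerically for mean 102 / median 101 bp, plus a rare log-uniform
# heavy-tail component on [1000, 1886] matching the observed >1 kb share.
SIZE_MU = 4.61499
SIZE_SIGMA = 0.13920
TAIL_FRACTION = 3.2e-4
TAIL_RANGE = (1000, 1886)


@dataclass
class PlantedHotRegion:
    chrom: str
    start: int
    end: int
    occurrence: int            # number of fragments to stack in the locus
    mode: str = "spread"       # "spread" | "concentrated"
    partner_chrom: str | None = None   # for concentrated mode
    partner_start: int | None = None
    partner_end: int | None = None
    carrier_probability: float | None = None
    # concentrated mode with carrier_probability set plants one pair per
    # Bernoulli-carrier subject (a recurrent reciprocal exchange); otherwise
    # ``occurrence`` pairs go to uniformly drawn subjects.


@dataclass
class PlantedRecurrentPair:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    group_probability: dict    # group label -> carrier probability


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 5
    chromosome_length: int = 10_000_000
    group_sizes: dict = field(default_factory=lambda: {
        "AFR": 40, "AMR": 40, "ASN": 40, "EUR": 40, "SAN": 40})
    male_fraction: float = 0.5
    pairs_per_subject: float = 2000.0      # Poisson mean of background pairs
    intra_fraction: float = 0.0011
    size_min: int = 65
    size_max: int = 2000
    repeat_density: float = 0.04           # fraction of genome in simple repeats
    lowmap_density: float = 0.05           # fraction in low-mappability regions
    track_overlap_fraction: float = 0.18   # background pairs planted to be filtered
    duplicate_fraction: float = 0.005      # background pairs duplicated verbatim
    gene_density: float = 0.40
    cds_within_gene: float = 0.35
    hot_regions: list = field(default_factory=list)
    recurrent_pairs: list = field(default_factory=list)
    motif: str = "CCCAGGCTGG"
    motif_fraction: float = 0.75           # share of hot regions carrying the motif
    bin_size: int = 200

    def validate(self, genome: GenomeModel) -> None:
        for name in ("male_fraction", "intra_fraction", "repeat_density",
                     "lowmap_density", "track_overlap_fraction",
                     "duplicate_fraction", "gene_density", "cds_within_gene",
                     "motif_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for hr in self.hot_regions:
            GenomicInterval(hr.chrom, hr.start, hr.end).validate(genome)
            if hr.mode == "concentrated":
                GenomicInterval(hr.partner_chrom, hr.partner_start,
                                hr.partner_end).validate(genome)
        for rp in self.recurrent_pairs:
            GenomicInterval(rp.chrom_a, rp.start_a, rp.end_a).validate(genome)
            GenomicInterval(rp.chrom_b, rp.start_b, rp.end_b).validate(genome)
            for g, p in rp.group_probability.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"carrier probability {p} for group {g}")

    def genome(self) -> GenomeModel:
        return GenomeModel({f"chr{i + 1}": self.chromosome_length
                            for i in range(self.n_chromosomes)})


@dataclass
class GroundTruth:
    hot_regions: list          # dicts: locus, mode, target/realized occurrence
    recurrent_pairs: list      # dicts: loci, per-group target p and realized carriers
    intra_fraction_target: float
    intra_fraction_realized: float
    n_pairs: int
    n_duplicates: int
    n_track_overlap: int
    motif: str
    motif_regions: list        # hot-region sequence names carrying the motif

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


@dataclass
class SimulationResult:
    genome: GenomeModel
    cohort: Cohort
    pairs: pd.DataFrame            # canonical pair table + provenance column
    repeats: IntervalTrack
    lowmap: IntervalTrack
    genes: IntervalTrack
    cds: IntervalTrack
    cytoband: IntervalTrack
    sequences: dict                # hot-region name -> DNA string
    ground_truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> dict:
        """Write every standard-format input file; returns name -> path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["bedpe"] = out / "pairs.bedpe"
        write_bedpe(self.pairs, paths["bedpe"])
        paths["chrom_sizes"] = out / "genome.chrom.sizes"
        self.genome.to_chrom_sizes(paths["chrom_sizes"])
        for name, track in (("repeats", self.repeats), ("lowmap", self.lowmap),
                            ("genes", self.genes), ("cds", self.cds)):
            paths[name] = out / f"{name}.bed"
            write_bed(track, paths[name])
        paths["cytoband"] = out / "cytoband.txt"
        write_cytoband(self.cytoband, paths["cytoband"])
        paths["cohort"] = out / "cohort.tsv"
        self.cohort.to_tsv(paths["cohort"])
        paths["fasta"] = out / "hot_regions.fasta"
        write_fasta(self.sequences, paths["fasta"])
        paths["ground_truth"] = out / "ground_truth.json"
        self.ground_truth.to_json(paths["ground_truth"])
        return paths


# --- internals -------------------------------------------------------------

def _sample_sizes(rng: np.random.Generator, n: int, cfg: SimulationConfig
                  ) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while len(todo):
        draw = rng.lognormal(SIZE_MU, SIZE_SIGMA, len(todo))
        ok = (draw >= cfg.size_min) & (draw <= cfg.size_max)
        out[todo[ok]] = np.round(draw[ok]).astype(np.int64)
        todo = todo[~ok]
    tail = rng.random(n) < TAIL_FRACTION
    if tail.any():
        lo, hi = np.log(TAIL_RANGE[0]), np.log(TAIL_RANGE[1])
        out[tail] = np.round(np.exp(rng.uniform(lo, hi, tail.sum()))).astype(np.int64)
    return np.clip(out, cfg.size_min, cfg.size_max)


def _random_track(rng, genome: GenomeModel, density: float, mean_len: int,
                  name: str, exclusions: list | None = None,
                  labels: tuple | None = None) -> IntervalTrack:
    """Random intervals reaching ~density of each chromosome, avoiding exclusions."""
    rows = []
    for chrom in genome.chromosomes:
        L = genome.length(chrom)
        target = density * L
        got = 0
        while got < target:
            length = max(50, int(rng.exponential(mean_len)))
            start = int(rng.integers(0, max(1, L - length)))
            iv = (start, start + length)
            if exclusions and any(c == chrom and iv[0] < e and iv[1] > s
                                  for c, s, e in exclusions):
                continue
            label = labels[rng.integers(len(labels))] if labels else None
            rows.append((chrom, iv[0], iv[1], label))
            got += length
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    if labels is None:
        df = df.drop(columns="label")
    return IntervalTrack(name, df)


def _make_cytoband(genome: GenomeModel) -> IntervalTrack:
    """Synthetic banding: 3 p sub-bands, a centromere, 4 q sub-bands per chromosome."""
    stains = ["gneg", "gpos25", "gpos50", "gpos75", "gpos100", "gneg", "gvar",
              "stalk"]
    rows = []
    si = 0
    for chrom in genome.chromosomes:
        L = genome.length(chrom)
        mid = L // 2
        cen_half = L // 50
        p_edges = np.linspace(0, mid - cen_half, 4).astype(np.int64)
        # p bands are numbered outward from the centromere, so genomic order
        # on the p arm runs p12, p11.2, p11.1
        for i, nm in enumerate(["p12", "p11.2", "p11.1"]):
            rows.append((chrom, int(p_edges[i]), int(p_edges[i + 1]), nm,
                         stains[si % len(stains)]))
            si += 1
        rows.append((chrom, int(mid - cen_half), int(mid + cen_half), "q10", "acen"))
        q_edges = np.linspace(mid + cen_half, L, 5).astype(np.int64)
        for i, nm in enumerate(["q11.1", "q11.2", "q12", "q13"]):
            rows.append((chrom, int(q_edges[i]), int(q_edges[i + 1]), nm,
                         stains[si % len(stains)]))
            si += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "label"])
    return IntervalTrack("cytoband", df, label_vocabulary=GIESTAIN_CLASSES)


def _place_fragments(rng, genome: GenomeModel, n: int, sizes: np.ndarray,
                     repeats: IntervalTrack, lowmap: IntervalTrack,
                     avoid_tracks: bool, chroms=None):
    """Uniform fragment placement, optionally rejection-sampled to survive filters.

    A fragment is "clean" when it overlaps no repeat interval and has
    low-mappability coverage below 0.5 (the stricter of the two kind
    thresholds), so pairs built from clean fragments always survive.
    """
    names = np.array(genome.chromosomes)
    lens = np.array([genome.length(c) for c in names], dtype=np.int64)
    if chroms is None:
        probs = lens / lens.sum()
        chrom_idx = rng.choice(len(names), size=n, p=probs)
    else:
        rank = {c: i for i, c in enumerate(names)}
        chrom_idx = np.array([rank[c] for c in chroms])
    starts = (rng.random(n) * (lens[chrom_idx] - sizes)).astype(np.int64)
    if avoid_tracks:
        for _ in range(200):
            bad = np.zeros(n, dtype=bool)
            ends = starts + sizes
            for ci in np.unique(chrom_idx):
                m = chrom_idx == ci
                c = names[ci]
                rep = repeats.covered_bp(c, starts[m], ends[m]) > 0
                low = lowmap.covered_bp(c, starts[m], ends[m]) / sizes[m] >= 0.5
                bad[m] = rep | low
            if not bad.any():
                break
            starts[bad] = (rng.random(bad.sum()) *
                           (lens[chrom_idx[bad]] - sizes[bad])).astype(np.int64)
        else:
            raise RuntimeError("could not place fragments clear of tracks")
    return names[chrom_idx], starts, starts + sizes


def _random_sequence(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate all pipeline inputs plus ground truth, bit-reproducibly."""
    genome = config.genome()
    config.validate(genome)
    rng = np.random.default_rng(config.seed)

    # cohort
    subjects, groups = [], []
    i = 0
    for g, size in config.group_sizes.items():
        for _ in range(size):
            subjects.append(f"S{i:05d}")
            groups.append(g)
            i += 1
    gender = np.where(rng.random(len(subjects)) < config.male_fraction, "M", "F")
    cohort = Cohort(pd.DataFrame({"subject": subjects, "group": groups,
                                  "gender": gender}))

    # tracks avoid every planted locus so planted pairs survive filtering
    margin = 2000
    exclusions = []
    for hr in config.hot_regions:
        exclusions.append((hr.chrom, hr.start - margin, hr.end + margin))
        if hr.mode == "concentrated":
            exclusions.append((hr.partner_chrom, hr.partner_start - margin,
                               hr.partner_end + margin))
    for rp in config.recurrent_pairs:
        exclusions.append((rp.chrom_a, rp.start_a - margin, rp.end_a + margin))
        exclusions.append((rp.chrom_b, rp.start_b - margin, rp.end_b + margin))
    repeats = _random_track(rng, genome, config.repeat_density, 300,
                            "simple_repeats", exclusions)
    lowmap = _random_track(rng, genome, config.lowmap_density, 500,
                           "low_mappability", exclusions)
    genes = _random_track(rng, genome, config.gene_density, 50_000, "genes")
    genes.df["label"] = [f"GENE{i:05d}" for i in range(len(genes.df))]
    # CDS: sub-intervals of genes
    cds_rows = []
    for row in genes.df.itertuples(index=False):
        glen = row.end - row.start
        c_len = int(glen * config.cds_within_gene)
        if c_len >= 10:
            off = int(rng.integers(0, glen - c_len + 1))
            cds_rows.append((row.chrom, row.start + off, row.start + off + c_len,
                             f"CDS_{row.label}"))
    cds = IntervalTrack("cds", pd.DataFrame(
        cds_rows, columns=["chrom", "start", "end", "label"]))
    cytoband = _make_cytoband(genome)

    frames = []

    # background pairs (track-overlap planting and duplicates included)
    n_bg = rng.poisson(config.pairs_per_subject, len(subjects))
    total_bg = int(n_bg.sum())
    subj_col = np.repeat(subjects, n_bg)

    # intra allocation: floor + Bernoulli remainder per subject
    intra_f = config.intra_fraction
    n_intra = (np.floor(n_bg * intra_f) +
               (rng.random(len(n_bg)) < (n_bg * intra_f) % 1)).astype(np.int64)
    is_intra = np.zeros(total_bg, dtype=bool)
    off = 0
    for k, ni in zip(n_bg, n_intra):
        is_intra[off:off + ni] = True
        off += k

    sizes_a = _sample_sizes(rng, total_bg, config)
    sizes_b = _sample_sizes(rng, total_bg, config)
    chrom_a, start_a, end_a = _place_fragments(
        rng, genome, total_bg, sizes_a, repeats, lowmap, avoid_tracks=True)
    # partner chromosome: same as side a for intra, a different one for inter
    names = np.array(genome.chromosomes)
    chroms_b = chrom_a.copy()
    inter_mask = ~is_intra
    draw = names[rng.integers(0, len(names), int(inter_mask.sum()))]
    same = draw == chrom_a[inter_mask]
    while same.any():
        draw[same] = names[rng.integers(0, len(names), int(same.sum()))]
        same = draw == chrom_a[inter_mask]
    chroms_b[inter_mask] = draw
    chrom_b, start_b, end_b = _place_fragments(
        rng, genome, total_bg, sizes_b, repeats, lowmap, avoid_tracks=True,
        chroms=chroms_b)

    bg = pd.DataFrame({
        "subject": subj_col, "chrom_a": chrom_a, "start_a": start_a,
        "end_a": end_a, "chrom_b": chrom_b, "start_b": start_b, "end_b": end_b,
    })
    bg["provenance"] = "background"

    # plant track-overlapping (to-be-filtered) pairs among the background:
    # fragment a is relocated fully inside a repeat interval (any-overlap
    # removal) or a low-mappability interval (coverage 1 >= both thresholds)
    n_overlap = int(round(config.track_overlap_fraction * total_bg))
    if n_overlap:
        which = rng.choice(total_bg, size=n_overlap, replace=False)
        half = n_overlap // 2
        chrom_a_all = bg["chrom_a"].to_numpy()
        for track, idxs in ((repeats, which[:half]), (lowmap, which[half:])):
            if len(idxs) == 0:
                continue
            # relocate within the fragment's own chromosome so the pair's
            # intra/inter kind (and the intra share) is untouched
            per_chrom = dict(tuple(track.df.groupby("chrom", sort=False)))
            chroms_of = chrom_a_all[idxs]
            for c in np.unique(chroms_of):
                sub = idxs[chroms_of == c]
                tdf = per_chrom[c]
                r = rng.integers(0, len(tdf), len(sub))
                t_start = tdf["start"].to_numpy()[r]
                t_end = tdf["end"].to_numpy()[r]
                frag_len = (bg["end_a"].to_numpy() - bg["start_a"].to_numpy())[sub]
                size = np.minimum(frag_len, t_end - t_start)
                start = t_start + (rng.random(len(sub)) *
                                   (t_end - t_start - size + 1)).astype(np.int64)
                bg.loc[sub, "start_a"] = start
                bg.loc[sub, "end_a"] = start + size
        bg.loc[which, "provenance"] = "track-overlap"

    # duplicates: verbatim copies of clean background rows (same subject)
    n_dup = int(round(config.duplicate_fraction * total_bg))
    if n_dup:
        clean = np.flatnonzero((bg["provenance"] == "background").to_numpy())
        dup_idx = rng.choice(clean, size=min(n_dup, len(clean)), replace=False)
        n_dup = len(dup_idx)
        frames.append(bg.iloc[dup_idx].copy())
    frames.insert(0, bg)

    # planted hot regions
    gt_hot = []
    seq_names = []
    for hi, hr in enumerate(config.hot_regions, start=1):
        locus_len = hr.end - hr.start
        realized_carriers = None
        if hr.mode == "concentrated" and hr.carrier_probability is not None:
            # Bernoulli carriers set the detection rate; extra pairs are
            # spread over the carriers to reach the occurrence target
            draws = rng.random(len(subjects)) < hr.carrier_probability
            carriers = np.array([s for s, c in zip(subjects, draws) if c])
            realized_carriers = len(carriers)
            if len(carriers) == 0:
                n_pairs = 0
                subj = carriers
            else:
                n_pairs = max(hr.occurrence, len(carriers))
                extra = rng.choice(carriers, n_pairs - len(carriers)) \
                    if n_pairs > len(carriers) else np.array([], dtype=carriers.dtype)
                subj = np.concatenate([carriers, extra])
        else:
            n_pairs = hr.occurrence
            subj = np.array(subjects)[rng.integers(0, len(subjects), n_pairs)]
        sizes_h = np.minimum(_sample_sizes(rng, n_pairs, config), locus_len)
        s_h = hr.start + (rng.random(n_pairs) * (locus_len - sizes_h)).astype(np.int64)
        if hr.mode == "concentrated":
            plen = hr.partner_end - hr.partner_start
            sizes_p = np.minimum(_sample_sizes(rng, n_pairs, config), plen)
            ps = hr.partner_start + (rng.random(n_pairs) *
                                     (plen - sizes_p)).astype(np.int64)
            pc = np.full(n_pairs, hr.partner_chrom)
            pe = ps + sizes_p
        else:
            sizes_p = _sample_sizes(rng, n_pairs, config)
            # spread partners are interchromosomal: same-chromosome partners
            # would be intra pairs, which the intra allocation already governs
            others = np.array([c for c in genome.chromosomes if c != hr.chrom])
            pchroms = others[rng.integers(0, len(others), n_pairs)]
            pc, ps, pe = _place_fragments(rng, genome, n_pairs, sizes_p,
                                          repeats, lowmap, avoid_tracks=True,
                                          chroms=pchroms)
        hot = pd.DataFrame({
            "subject": subj, "chrom_a": np.full(n_pairs, hr.chrom),
            "start_a": s_h, "end_a": s_h + sizes_h,
            "chrom_b": pc, "start_b": ps, "end_b": pe,
        })
        hot["provenance"] = "hot"
        frames.append(hot)
        gt_hot.append({"name": f"hot_{hi}", "chrom": hr.chrom, "start": hr.start,
                       "end": hr.end, "mode": hr.mode,
                       "target_occurrence": hr.occurrence,
                       "realized_pairs": int(n_pairs),
                       "realized_carriers": realized_carriers,
                       "carrier_probability": hr.carrier_probability,
                       "partner": (hr.partner_chrom, hr.partner_start,
                                   hr.partner_end)
                       if hr.mode == "concentrated" else None})
        seq_names.append(f"hot_{hi}")

    # planted recurrent region pairs
    gt_rec = []
    group_of = cohort.group_of()
    for ri, rp in enumerate(config.recurrent_pairs, start=1):
        carriers = []
        for s in subjects:
            p = rp.group_probability.get(group_of[s], 0.0)
            if rng.random() < p:
                carriers.append(s)
        n_pairs = len(carriers)
        la, lb = rp.end_a - rp.start_a, rp.end_b - rp.start_b
        sz_a = np.minimum(_sample_sizes(rng, n_pairs, config), la)
        sz_b = np.minimum(_sample_sizes(rng, n_pairs, config), lb)
        sa = rp.start_a + (rng.random(n_pairs) * (la - sz_a)).astype(np.int64)
        sb = rp.start_b + (rng.random(n_pairs) * (lb - sz_b)).astype(np.int64)
        rec = pd.DataFrame({
            "subject": carriers, "chrom_a": np.full(n_pairs, rp.chrom_a),
            "start_a": sa, "end_a": sa + sz_a,
            "chrom_b": np.full(n_pairs, rp.chrom_b), "start_b": sb,
            "end_b": sb + sz_b,
        })
        rec["provenance"] = "recurrent"
        frames.append(rec)
        realized_by_group = {}
        for g in cohort.groups:
            members = [s for s in subjects if group_of[s] == g]
            realized_by_group[g] = sum(1 for s in carriers if group_of[s] == g)
        gt_rec.append({"name": f"recurrent_{ri}",
                       "locus_a": (rp.chrom_a, rp.start_a, rp.end_a),
                       "locus_b": (rp.chrom_b, rp.start_b, rp.end_b),
                       "group_probability": dict(rp.group_probability),
                       "realized_carriers": realized_by_group,
                       "realized_rate": n_pairs / len(subjects)})

    pairs = pd.concat(frames, ignore_index=True)
    prov = pairs.pop("provenance")
    pairs = canonicalize_pairs(pairs, genome)
    pairs["provenance"] = prov.to_numpy()
    pairs = pairs[PAIR_COLUMNS + ["provenance"]]

    realized_intra = float((pairs["kind"] == "intra").mean())

    # hot-region FASTA with the motif planted in a fixed share of regions
    sequences = {}
    n_regions = len(config.hot_regions)
    n_motif = int(round(config.motif_fraction * n_regions))
    motif_regions = []
    rc = reverse_complement(config.motif)
    for j, hr in enumerate(config.hot_regions):
        name = seq_names[j]
        length = max(hr.end - hr.start, len(config.motif) + 10)
        while True:
            seq = _random_sequence(rng, length)
            if config.motif not in seq and rc not in seq:
                break
        if j < n_motif:
            off = int(rng.integers(0, length - len(config.motif) + 1))
            seq = seq[:off] + config.motif + seq[off + len(config.motif):]
            motif_regions.append(name)
        sequences[name] = seq

    gt = GroundTruth(
        hot_regions=gt_hot,
        recurrent_pairs=gt_rec,
        intra_fraction_target=config.intra_fraction,
        intra_fraction_realized=realized_intra,
        n_pairs=len(pairs),
        n_duplicates=n_dup,
        n_track_overlap=int((pairs["provenance"] == "track-overlap").sum()),
        motif=config.motif,
        motif_regions=motif_regions,
    )
    return SimulationResult(genome, cohort, pairs, repeats, lowmap, genes, cds,
                            cytoband, sequences, gt, config)


def default_desk_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale study conditions: 5 x 10 Mb genome, 200 subjects in 5 groups,
    ~2,000 background pairs per subject, 2 planted hot regions and 3 planted
    recurrent region pairs; a full pipeline run takes minutes on one CPU.

    The planted recurrent carrier probabilities mirror the detection-rate
    patterns a population cohort exhibits for known constitutional
    exchanges: one near-universal reciprocal exchange (p = 0.769 in every
    group) and two with group-specific rates.
    """
    hot = [
        # spread: partners land uniformly across the genome
        PlantedHotRegion("chr1", 2_000_000, 2_000_300, occurrence=1500,
                         mode="spread"),
        # concentrated: a reciprocal partner locus, carried by 76.9% of subjects
        PlantedHotRegion("chr2", 5_000_000, 5_000_300, occurrence=1500,
                         mode="concentrated",
                         partner_chrom="chr4", partner_start=3_000_000,
                         partner_end=3_000_300, carrier_probability=0.769),
    ]
    rec = [
        PlantedRecurrentPair("chr1", 4_000_000, 4_000_200,
                             "chr3", 6_000_000, 6_000_200,
                             {"AFR": 0.1807, "AMR": 0.2054, "ASN": 0.1588,
                              "EUR": 0.1661, "SAN": 0.1818}),
        PlantedRecurrentPair("chr2", 7_000_000, 7_000_200,
                             "chr5", 1_000_000, 1_000_200,
                             {"AFR": 0.5336, "AMR": 0.4598, "ASN": 0.3676,
                              "EUR": 0.3671, "SAN": 0.3506}),
        PlantedRecurrentPair("chr3", 2_500_000, 2_500_200,
                             "chr4", 8_000_000, 8_000_200,
                             {"AFR": 0.25, "AMR": 0.25, "ASN": 0.25,
                              "EUR": 0.25, "SAN": 0.25}),
    ]
    return SimulationConfig(seed=seed, hot_regions=hot, recurrent_pairs=rec)
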