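"""End-to-end orchestration: simulate/load -> filter -> landscape ->
recurrence -> enrichment -> catalog comparison -> motif, with a report
bundle written as deterministic TSV/JSON files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeModel, GenomicInterval, IntervalTrack
from .io import (Cohort, G_POSITIVE, read_bed, read_bedpe, read_cohort,
                 read_cytoband, write_bedpe)
from .filtering import FilterConfig, run_filters
from .landscape import annotation_overlap, size_summary, subject_summary
from .recurrence import (annotate_hot_regions, bin_pair_detection, hot_regions,
                         partner_profile, region_pair_detection)
from .enrichment import (enrichment_matrix, gender_test, group_rate_test,
                         stain_enrichment)
from .compare import catalog_overlap
from .motif import motif_occurrence, read_fasta
from .simulate import SimulationConfig, SimulationResult, simulate

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Stage switches and thresholds for a full run.

    Thresholds default to the values a population-scale study would use:
    low-mappability removal at 85% (intra) / 50% (inter) fragment coverage,
    200-bp recurrence bins, hot regions above 1,000 pooled occurrences, 1-kb
    large-fragment threshold.
    """

    filter: FilterConfig = field(default_factory=FilterConfig)
    bin_size: int = 200
    min_bin_rate: float = 0.2
    hot_min_occurrence: int = 1000
    hot_merge_gap: int = 0
    hot_scan_bin: int = 100
    large_threshold: int = 1000
    motif: str = "CCCAGGCTGG"
    partner_bin: int = 1_000_000


@dataclass
class PipelineResult:
    pairs: pd.DataFrame
    reports: dict              # stage name -> python object (dict / DataFrame)

    def write(self, outdir) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, obj in self.reports.items():
            if isinstance(obj, pd.DataFrame):
                p = out / f"{name}.tsv"
                obj.to_csv(p, sep="\t", index=False)
            else:
                p = out / f"{name}.json"
                with open(p, "w") as fh:
                    json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
            paths[name] = p
        write_bedpe(self.pairs, out / "filtered.bedpe")
        paths["filtered_bedpe"] = out / "filtered.bedpe"
        return paths

    def checksums(self, outdir) -> dict:
        """SHA-256 of every written report file, for determinism sweeps."""
        sums = {}
        for p in sorted(Path(outdir).iterdir()):
            if p.is_file():
                sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return sums


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return str(obj)


def run_pipeline(sim: SimulationResult | None = None,
                 config: PipelineConfig | None = None,
                 inputs: dict | None = None) -> PipelineResult:
    """Run every stage on a simulation result or on loaded file inputs.

    ``inputs`` (alternative to ``sim``) maps names to paths: bedpe,
    chrom_sizes, repeats, lowmap, genes, cds, cytoband, cohort, optional
    fasta. Stage reports carry per-stage counts; no stage mutates its
    inputs.
    """
    cfg = config or PipelineConfig()
    if sim is not None:
        genome, cohort = sim.genome, sim.cohort
        pairs = sim.pairs.drop(columns=["provenance"], errors="ignore")
        repeats, lowmap = sim.repeats, sim.lowmap
        genes, cds, cytoband = sim.genes, sim.cds, sim.cytoband
        sequences = sim.sequences
    elif inputs is not None:
        missing = [k for k in ("bedpe", "chrom_sizes", "repeats", "lowmap",
                               "cytoband", "cohort") if k not in inputs]
        if missing:
            raise ValueError(f"missing pipeline inputs: {missing}")
        genome = GenomeModel.from_chrom_sizes(inputs["chrom_sizes"])
        pairs, rejects = read_bedpe(inputs["bedpe"], genome)
        cohort = read_cohort(inputs["cohort"])
        repeats = read_bed(inputs["repeats"], "simple_repeats")
        lowmap = read_bed(inputs["lowmap"], "low_mappability")
        genes = read_bed(inputs["genes"], "genes") if "genes" in inputs else None
        cds = read_bed(inputs["cds"], "cds") if "cds" in inputs else None
        cytoband = read_cytoband(inputs["cytoband"])
        sequences = read_fasta(inputs["fasta"]) if "fasta" in inputs else {}
    else:
        raise ValueError("run_pipeline needs a simulation result or file inputs")

    reports: dict = {"meta": {"version": __version__,
                              "config": _config_dict(cfg),
                              "n_input_pairs": int(len(pairs))}}

    # filtering
    filtered, freport = run_filters(pairs, repeats, lowmap, cfg.filter)
    reports["filter_report"] = freport.to_dict()

    # landscape
    ss = size_summary(filtered, cfg.large_threshold)
    reports["size_summary"] = {
        "fragments": ss.count, "mean": ss.mean, "median": ss.median,
        "min": ss.min, "max": ss.max,
        "pairs_over_threshold": ss.pairs_over_threshold,
        "hist_edges": ss.hist_edges, "hist_counts": ss.hist_counts,
    }
    subj = subject_summary(filtered, cohort, genome)
    reports["subject_summary"] = {
        "mean_pairs": subj.mean_pairs, "interval_95": list(subj.interval_95),
        "mean_coverage": subj.mean_coverage,
        "pooled_coverage": subj.pooled_coverage,
        "unresolved_subjects": subj.unresolved_subjects,
        "intra_fraction": float((filtered["kind"] == "intra").mean()),
    }
    reports["per_subject"] = subj.per_subject
    if genes is not None:
        reports["genic_overlap"] = annotation_overlap(filtered, genes)
    if cds is not None:
        reports["cds_overlap"] = annotation_overlap(filtered, cds)
    reports["gpos_overlap"] = annotation_overlap(filtered, cytoband, G_POSITIVE)

    # recurrence
    bin_records = bin_pair_detection(filtered, cohort, cfg.bin_size,
                                     cfg.min_bin_rate, genome)
    reports["bin_pairs"] = pd.DataFrame([
        {"chrom_a": r.bin_a[0], "begin_a": r.interval_a.start + 1,
         "end_a": r.interval_a.end, "chrom_b": r.bin_b[0],
         "begin_b": r.interval_b.start + 1, "end_b": r.interval_b.end,
         "carriers": len(r.carriers), "detection_rate": r.detection_rate}
        for r in bin_records])
    hot = hot_regions(filtered, cfg.hot_min_occurrence, cfg.hot_merge_gap,
                      cfg.hot_scan_bin)
    hot_table = annotate_hot_regions(hot, cytoband, genes, cds, repeats)
    if len(hot_table):
        hot_table["begin"] = hot_table["begin"] + 1  # render 1-based inclusive
    reports["hot_regions"] = hot_table
    partner = {}
    for i, region in enumerate(hot, start=1):
        prof = partner_profile(region, filtered, cfg.partner_bin)
        partner[f"region_{i}"] = {
            "top_partner_bin": list(prof["top_partner_bin"]),
            "top_partner_share": prof["top_partner_share"],
            "total_pairs": prof["total_pairs"],
        }
    reports["partner_profiles"] = partner

    # enrichment
    try:
        mat = enrichment_matrix(filtered, genome)
        reports["enrichment_scores"] = mat.scores.reset_index(
            names="chrom")
        reports["enrichment_top_pairs"] = {"top": mat.top_pairs(3),
                                           "total_inter": mat.total}
    except ValueError:
        reports["enrichment_top_pairs"] = {"top": [], "total_inter": 0}
    counts = filtered["subject"].value_counts().reindex(cohort.subjects,
                                                        fill_value=0)
    try:
        reports["gender_test"] = gender_test(counts, cohort)
    except ValueError as exc:
        reports["gender_test"] = {"error": str(exc)}
    reports["stain_enrichment"] = {
        k: v for k, v in stain_enrichment(filtered, cytoband,
                                          genome=genome).items()}

    # group-difference chi-square per top bin pair
    group_tests = []
    group_of = cohort.group_of()
    sizes = cohort.group_sizes()
    for r in bin_records:
        per_group = {g: 0 for g in cohort.groups}
        for s in r.carriers:
            per_group[group_of[s]] += 1
        res = group_rate_test([per_group[g] for g in cohort.groups],
                              [sizes[g] for g in cohort.groups])
        group_tests.append({"bin_a": list(r.bin_a), "bin_b": list(r.bin_b),
                            "rate": r.detection_rate, **res})
    reports["bin_pair_group_tests"] = group_tests

    # catalog comparison against planted truth (simulation runs only)
    if sim is not None and sim.ground_truth.recurrent_pairs:
        from .io import CatalogRecord
        catalog = []
        for rp in sim.ground_truth.recurrent_pairs:
            ca, sa, ea = rp["locus_a"]
            cb, sb, eb = rp["locus_b"]
            catalog.append(CatalogRecord(
                rp["name"], "planted", ca, None, GenomicInterval(ca, sa, ea),
                cb, None, GenomicInterval(cb, sb, eb)))
        comp = catalog_overlap(filtered, cohort, catalog, cytoband)
        reports["catalog_comparison"] = comp["records"]
        reports["catalog_summary"] = {
            "overlap_fraction": comp["overlap_fraction"],
            "mean_rate": comp["mean_rate"]}

    # motif occurrence over hot-region sequences
    if sequences:
        occ = motif_occurrence(sequences, cfg.motif)
        reports["motif_occurrence"] = {
            "motif": cfg.motif,
            "fraction_with_hit": occ["fraction_with_hit"],
            "sequences_with_hit": occ["sequences_with_hit"],
            "n_sequences": occ["n_sequences"],
        }

    return PipelineResult(pairs=filtered, reports=reports)


def _config_dict(cfg: PipelineConfig) -> dict:
    from dataclasses import asdict
    return asdict(cfg)
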