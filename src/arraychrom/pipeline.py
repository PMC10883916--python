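"""End-to-end demo pipeline: simulate -> normalize -> tss/footprint/peaks ->
enrichment statistics, with a machine-readable run report.

Every stage consumes the synthetic genome's planted truth, so a fixed seed
gives byte-identical outputs and the report records every parameter used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (NormalizationParams, bin_coverage, combine_replicates,
                       correlate_binned, fragments_to_coverage,
                       normalize_to_input, resample_fragments)
from .footprint import AnchorSet, aggregate_profile, detect_borders
from .genome import GenomeConfig, build_genome, simulate_end_coverage, \
    simulate_fragments
from .io import (write_bed6, write_clusters, write_fasta, write_gff3,
                 write_report, write_stranded_bedgraph)
from .peaks import Peak, filter_peaks, link_tss_to_summits, match_summits
from .stats import (CIDAnnotation, assign_operons_to_cids,
                    cid_operon_enrichment, tss_binding_enrichment)
from .tss import TSSCallParams, call_tss, classify_tss, differential_tss_stub


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration of the whole pipeline."""

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    norm: NormalizationParams = field(default_factory=NormalizationParams)
    tss: TSSCallParams = field(default_factory=TSSCallParams)
    seed: int = 0
    outdir: str = "arraychrom_out"
    chip_fragments: int = 50_000
    cappable_depth: int = 80_000
    cappable_jitter: int = 1
    cappable_background: float = 0.02
    exo_depth: int = 80_000
    exo_background: float = 0.01
    flank: int = 60
    min_enrichment: float = 5.0
    max_summit_dist: int = 40
    link_dist: int = 50
    inputs: dict = field(default_factory=dict)  # optional external files

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("genome", GenomeConfig), ("norm",
                         NormalizationParams), ("tss", TSSCallParams)):
            if key in kwargs:
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def validate(self) -> None:
        """Fail fast, before any stage runs."""
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"configured input {name!r} not found: {path}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = iter(master.integers(2**31, size=64).tolist())
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": config.to_dict(), "stages": {},
                    "outputs": []}

    def record(path):
        report["outputs"].append(str(path))

    # ---------------- simulate ----------------
    genome = _stage("simulate")(build_genome)(
        replace(config.genome, seed=config.seed))
    write_fasta(out / "genome.fasta", genome.sequence, genome.replicon)
    write_gff3(out / "genome.gff3", genome.features, genome.replicon,
               genome.length)
    write_bed6(out / "tss_truth.bed",
               [(genome.replicon, t.pos, t.pos + 1, t.kind, t.weight, t.strand)
                for t in genome.tss_truth])
    for p in ("genome.fasta", "genome.gff3", "tss_truth.bed"):
        record(out / p)
    report["stages"]["simulate"] = {
        "genome_length": genome.length,
        "n_features": len(genome.features),
        "n_planted_tss": len(genome.tss_truth),
        "n_repeats": len(genome.footprint_truth)}

    # ---------------- normalize (ChIP-seq) ----------------
    @_stage("normalize")
    def _normalize():
        reps = []
        for _ in range(2):
            frags = simulate_fragments(genome, n=config.chip_fragments,
                                       seed=next(seeds))
            reps.append(resample_fragments(frags, config.norm,
                                           seed=next(seeds)))
        inp = simulate_fragments(genome, occupancy=np.ones(genome.length),
                                 n=config.chip_fragments, seed=next(seeds))
        inp = resample_fragments(inp, config.norm, seed=next(seeds))
        inp_bin = bin_coverage(fragments_to_coverage(inp, genome.length),
                               config.norm.bin_width)
        norm_bins = []
        for i, frags in enumerate(reps, 1):
            cov = fragments_to_coverage(frags, genome.length)
            write_stranded_bedgraph(out / f"chip_rep{i}", cov)
            record(out / f"chip_rep{i}.plus.bedgraph")
            record(out / f"chip_rep{i}.minus.bedgraph")
            norm_bins.append(normalize_to_input(
                bin_coverage(cov, config.norm.bin_width), inp_bin,
                config.norm.pseudocount))
        combined = combine_replicates(norm_bins, method="arithmetic")
        r = correlate_binned(norm_bins[0], norm_bins[1], "pearson")
        return reps, combined, r

    reps, combined, rep_corr = _normalize()
    report["stages"]["normalize"] = {
        "retained_fragments": [len(f) for f in reps],
        "retained_mean_length": [float(f.lengths.mean()) for f in reps],
        "replicate_pearson_r": rep_corr}

    # ---------------- tss (Cappable-seq) ----------------
    @_stage("tss")
    def _tss():
        def truth_for(condition):
            pts = []
            for t in genome.tss_truth:
                w = t.weight
                if t.kind == "cryptic":
                    w *= 0.15 if condition == "wt" else 1.0
                elif t.kind == "leader":
                    w *= 1.0 if condition == "wt" else 0.35
                pts.append((t.pos, t.strand, w))
            return pts

        samples = {}
        conditions = {}
        for cond in ("wt", "dcbp1"):
            for r in (1, 2):
                name = f"{cond}_{r}"
                samples[name] = simulate_end_coverage(
                    genome.length, truth_for(cond), config.cappable_depth,
                    jitter=config.cappable_jitter,
                    background_rate=config.cappable_background,
                    seed=next(seeds), replicon=genome.replicon)
                conditions[name] = cond
        clusters = call_tss(samples, config.tss)
        classify_tss(clusters, genome.features_of("operon"),
                     genome.features_of("CDS"), config.tss)
        counts = pd.DataFrame(
            {s: [cl.counts[s] for cl in clusters] for s in samples})
        diff = differential_tss_stub(counts, conditions)
        write_clusters(out / "tss_clusters.tsv", clusters)
        record(out / "tss_clusters.tsv")
        return clusters, diff

    clusters, diff = _tss()
    class_counts = pd.Series([c.tss_class for c in clusters]) \
        .value_counts().to_dict()
    report["stages"]["tss"] = {
        "n_clusters": len(clusters), "classes": class_counts,
        "n_differential": int(diff["significant"].sum())}

    # ---------------- footprint (ChIP-exo) ----------------
    @_stage("footprint")
    def _footprint():
        stops = genome.exo_stop_truth(weight=1.0)
        covs = [simulate_end_coverage(
            genome.length, stops, config.exo_depth, jitter=0,
            background_rate=config.exo_background, seed=next(seeds),
            replicon=genome.replicon) for _ in range(2)]
        anchors = AnchorSet([(pos, strand) for _, pos, strand
                             in genome.footprint_truth], flank=config.flank,
                            replicon=genome.replicon)
        profile = aggregate_profile(covs, anchors)
        borders = detect_borders(profile)
        pd.DataFrame({"position": profile.positions, "sense": profile.sense,
                      "antisense": profile.antisense}) \
            .to_csv(out / "footprint_profile.tsv", sep="\t", index=False)
        record(out / "footprint_profile.tsv")
        return borders

    borders = _footprint()
    report["stages"]["footprint"] = {
        "upstream_border": borders[0], "downstream_border": borders[1],
        "planted_borders": list(genome.footprint_borders)}

    # ---------------- peaks ----------------
    @_stage("peaks")
    def _peaks():
        rng = np.random.default_rng(next(seeds))
        site_enrich = {f.id: float(rng.lognormal(2.3, 0.6))
                       for f in genome.features_of("noncanonical_site")}
        rep_lists = []
        for _ in range(2):
            plist = []
            for f in genome.features_of("noncanonical_site"):
                summit = (f.start + f.end) // 2 + int(rng.integers(-8, 9))
                enrich = site_enrich[f.id] * float(rng.lognormal(0, 0.1))
                plist.append(Peak(genome.replicon, summit - 100, summit + 100,
                                  summit, enrich))
            for f in genome.features_of("array"):
                summit = (f.start + f.end) // 2 + int(rng.integers(-8, 9))
                plist.append(Peak(genome.replicon, summit - 200, summit + 200,
                                  summit, float(rng.lognormal(2.5, 0.3))))
            rep_lists.append(plist)
        matched = match_summits(rep_lists[0], rep_lists[1],
                                config.max_summit_dist)
        arrays = [(f.start, f.end) for f in genome.features_of("array")]
        kept = filter_peaks(matched, config.min_enrichment, arrays)
        summits = [m.summit for m in kept]
        links = link_tss_to_summits(clusters, summits, config.link_dist)
        write_bed6(out / "peaks.bed",
                   [(genome.replicon, m.rep1.start, m.rep1.end,
                     f"peak{i + 1}", m.enrichment, "+")
                    for i, m in enumerate(kept)])
        record(out / "peaks.bed")
        return matched, kept, links

    matched, kept, links = _peaks()
    report["stages"]["peaks"] = {
        "n_matched": len(matched), "n_filtered": len(kept),
        "n_linked_tss": sum(1 for ln in links if ln.linked)}

    # ---------------- enrich ----------------
    @_stage("enrich")
    def _enrich():
        arrays = [(f.start, f.end) for f in genome.features_of("array")]
        in_array = np.array([any(s <= cl.centre < e for s, e in arrays)
                             for cl in clusters])
        up = (diff["significant"] & (diff["log2fc"] > 0)).to_numpy()
        res_array = tss_binding_enrichment(in_array, up, family_size=2) \
            if in_array.any() else None
        linked = np.array([ln.linked for ln in links])
        res_linked = tss_binding_enrichment(linked, up, family_size=2) \
            if linked.any() else None
        # CID-level: flag operons whose primary TSS moved down
        down_ops = set()
        for cl, sig, fc in zip(clusters, diff["significant"], diff["log2fc"]):
            if cl.tss_class == "primary" and sig and fc < 0:
                down_ops.add(cl.operon)
        cids = [(f.start, f.end, f.id) for f in genome.features_of("CID")]
        ops = genome.features_of("operon")
        ann = CIDAnnotation(
            cids, assign_operons_to_cids(cids, ops),
            {o.id: ("down" if o.id in down_ops else "ns") for o in ops})
        cid_df = cid_operon_enrichment(ann, "down")
        cid_df.to_csv(out / "cid_enrichment.tsv", sep="\t", index=False)
        record(out / "cid_enrichment.tsv")
        return res_array, res_linked

    res_array, res_linked = _enrich()
    report["stages"]["enrich"] = {
        "array_tss_up": None if res_array is None else
        {"pvalue": res_array.pvalue, "padj": res_array.padj,
         "odds_ratio": res_array.odds_ratio},
        "summit_linked_tss_up": None if res_linked is None else
        {"pvalue": res_linked.pvalue, "padj": res_linked.padj}}

    write_report(out / "report.json", report)
    record(out / "report.json")
    return report
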