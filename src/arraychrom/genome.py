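"""Synthetic genomes, annotations and sequencing-like data.

This module emulates the downstream products of the real experiments — mapped
ChIP fragments, Cappable-seq / ChIP-exo 5'-end counts — on a small circular
archaeal-style chromosome carrying CRISPR arrays (direct repeats interleaved
with spacers, preceded by a leader), protein-coding operons, non-canonical
binding sites, and chromosomal interaction domains (CIDs). Ground truth
(planted transcription start sites, per-repeat protection footprints, and
per-feature occupancy levels) is recorded so that every downstream analysis
stage can be tested for recovery of known signal.

It also contains the in vitro run-off template designer used for cell-free
transcription arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracks import FragmentSet, StrandedCoverage

#: default protected interval on a repeat, relative to the repeat 5' start:
#: upstream protection border at -5, downstream border at +16.
DEFAULT_FOOTPRINT_BORDERS = (-5, 16)


class LayoutError(ValueError):
    """Requested features do not fit into the genome."""


@dataclass
class GenomeConfig:
    """Parameters of the synthetic chromosome.

    Defaults describe a small but structurally faithful chromosome: a few
    multi-repeat CRISPR arrays with 25 bp repeats and 38 bp spacers, each with
    an upstream leader carrying the array's cognate promoter, a set of
    operons, non-canonical binding sites, and a CID partition.
    """

    n_arrays: int = 2
    repeats_per_array: int = 10
    repeat_length: int = 25
    spacer_length: int = 38
    leader_length: int = 150
    n_noncanonical_sites: int = 5
    n_operons: int = 20
    n_cids: int = 4
    cryptic_promoter_fraction: float = 0.3
    seed: int = 0
    genome_length: int | None = None
    footprint_borders: tuple[int, int] = DEFAULT_FOOTPRINT_BORDERS
    gap: int = 200  # spacing between placed feature blocks

    def __post_init__(self) -> None:
        for name in ("n_arrays", "repeats_per_array", "n_noncanonical_sites",
                     "n_operons", "n_cids"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("repeat_length", "spacer_length", "leader_length", "gap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.cryptic_promoter_fraction <= 1.0:
            raise ValueError("cryptic_promoter_fraction must lie in [0, 1]")


@dataclass
class Feature:
    """One annotated interval, 0-based half-open, with a strand."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    id: str = ""
    parent: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' start (genomic coordinate of the first base)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PlantedTSS:
    pos: int
    strand: str
    weight: float
    kind: str  # leader | cryptic | primary
    feature_id: str | None = None


@dataclass
class SyntheticGenome:
    """Circular chromosome with annotation and planted truth tables."""

    sequence: str
    features: list[Feature]
    tss_truth: list[PlantedTSS]
    footprint_truth: list[tuple[str, int, str]]  # (repeat id, anchor pos, strand)
    footprint_borders: tuple[int, int]
    occupancy_levels: dict[str, float]
    config: GenomeConfig
    replicon: str = "synchrom"
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def occupancy_track(self, background: float = 1.0) -> np.ndarray:
        """Per-base relative occupancy built from planted per-feature levels."""
        occ = np.full(self.length, background, dtype=float)
        for f in self.features:
            level = self.occupancy_levels.get(f.id)
            if level is None:
                level = self.occupancy_levels.get(f.kind)
            if level is not None:
                occ[f.start:f.end] = np.maximum(occ[f.start:f.end], level)
        return occ

    def exo_stop_truth(self, weight: float = 1.0) -> list[tuple[int, str, float]]:
        """Exonuclease stop points at the planted protection borders.

        The 5'->3' exonuclease halts at the upstream edge of the protected
        interval on the repeat's sense strand and at the downstream edge on
        the antisense strand; both positions are relative to the repeat start
        in the repeat's own orientation.
        """
        up, down = self.footprint_borders
        stops = []
        for _rid, anchor, strand in self.footprint_truth:
            if strand == "+":
                stops.append(((anchor + up) % self.length, "+", weight))
                stops.append(((anchor + down) % self.length, "-", weight))
            else:
                stops.append(((anchor - up) % self.length, "-", weight))
                stops.append(((anchor - down) % self.length, "+", weight))
        return stops


def build_genome(config: GenomeConfig) -> SyntheticGenome:
    """Lay out a synthetic chromosome deterministically from ``config.seed``.

    Arrays alternate strand so that minus-strand anchor handling is exercised.
    Raises :class:`LayoutError` if an explicit ``genome_length`` cannot hold
    the requested features.
    """
    rng = np.random.default_rng(config.seed)
    features: list[Feature] = []
    tss_truth: list[PlantedTSS] = []
    footprint_truth: list[tuple[str, int, str]] = []
    occupancy_levels: dict[str, float] = {
        "repeat": 10.0, "spacer": 10.0, "leader": 3.0,
        "noncanonical_site": 5.0,
    }
    cursor = config.gap

    # --- CRISPR arrays: leader then repeat (spacer repeat)* on '+';
    #     mirrored for '-' arrays (leader at the high-coordinate end).
    for ai in range(config.n_arrays):
        strand = "+" if ai % 2 == 0 else "-"
        aid = f"array{ai + 1}"
        n_rep = config.repeats_per_array
        n_spc = max(n_rep - 1, 0)
        body_len = n_rep * config.repeat_length + n_spc * config.spacer_length
        if n_rep == 0:
            continue
        if strand == "+":
            leader = Feature("leader", cursor, cursor + config.leader_length,
                             strand, f"{aid}_leader", aid)
            body_start = leader.end
        else:
            body_start = cursor
            leader = Feature("leader", body_start + body_len,
                             body_start + body_len + config.leader_length,
                             strand, f"{aid}_leader", aid)
        array = Feature("array", body_start, body_start + body_len, strand,
                        aid)
        features.append(array)
        features.append(leader)
        # leader TSS: at the strand-aware junction of leader and array body
        leader_tss = body_start if strand == "+" else body_start + body_len - 1
        tss_truth.append(PlantedTSS(leader_tss, strand,
                                    float(rng.lognormal(5.0, 0.3)),
                                    "leader", aid))
        # repeats and spacers; repeat indexing follows the strand direction
        unit = config.repeat_length + config.spacer_length
        for ri in range(n_rep):
            s = body_start + ri * unit
            rep = Feature("repeat", s, s + config.repeat_length, strand,
                          f"{aid}_repeat{ri + 1}", aid)
            features.append(rep)
            footprint_truth.append((rep.id, rep.five_prime, strand))
            if ri < n_spc:
                sp = Feature("spacer", rep.end, rep.end + config.spacer_length,
                             strand, f"{aid}_spacer{ri + 1}", aid)
                features.append(sp)
                if rng.random() < config.cryptic_promoter_fraction:
                    pos = int(rng.integers(sp.start + 2, sp.end - 2))
                    tss_strand = "+" if rng.random() < 0.5 else "-"
                    tss_truth.append(PlantedTSS(
                        pos, tss_strand, float(rng.lognormal(4.0, 0.6)),
                        "cryptic", sp.id))
        cursor = max(array.end, leader.end) + config.gap

    # --- non-canonical binding sites (repeat-like 21 bp motifs), half of
    #     them with a nearby cryptic promoter
    for si in range(config.n_noncanonical_sites):
        f = Feature("noncanonical_site", cursor, cursor + 21,
                    "+" if rng.random() < 0.5 else "-", f"ncsite{si + 1}")
        features.append(f)
        if rng.random() < 0.5:
            pos = (f.start + f.end) // 2 + int(rng.integers(-30, 31))
            tss_truth.append(PlantedTSS(
                pos, "+" if rng.random() < 0.5 else "-",
                float(rng.lognormal(4.0, 0.6)), "cryptic", f.id))
        cursor = f.end + config.gap

    # --- operons with 1-3 CDS each; one planted primary TSS per operon
    for oi in range(config.n_operons):
        strand = "+" if rng.random() < 0.5 else "-"
        oid = f"operon{oi + 1}"
        n_cds = int(rng.integers(1, 4))
        cds_len = int(rng.integers(300, 900))
        op_start = cursor
        pos = op_start
        cds_list = []
        for ci in range(n_cds):
            cds = Feature("CDS", pos, pos + cds_len, strand,
                          f"{oid}_cds{ci + 1}", oid)
            cds_list.append(cds)
            pos = cds.end + 20
        op_end = cds_list[-1].end
        features.append(Feature("operon", op_start, op_end, strand, oid))
        features.extend(cds_list)
        # ~60% leaderless starts (5'-UTR < 4 nt), the rest up to 50 nt
        utr = int(rng.integers(0, 4)) if rng.random() < 0.6 else \
            int(rng.integers(4, 51))
        if strand == "+":
            tss_pos = op_start - utr
        else:
            tss_pos = op_end - 1 + utr
        tss_truth.append(PlantedTSS(tss_pos, strand,
                                    float(rng.lognormal(4.5, 0.5)),
                                    "primary", oid))
        cursor = op_end + config.gap

    required = cursor + config.gap
    length = config.genome_length if config.genome_length is not None else required
    if length < required:
        raise LayoutError(
            f"features need {required} bp but genome_length={length}")

    # --- CID partition of the whole replicon
    if config.n_cids > 0:
        edges = np.linspace(0, length, config.n_cids + 1).astype(int)
        for ci in range(config.n_cids):
            features.append(Feature("CID", int(edges[ci]), int(edges[ci + 1]),
                                    "+", f"cid{ci + 1}"))

    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    for f in features:
        if f.end > length and f.kind != "CID":
            raise LayoutError(f"feature {f.id} exceeds genome length")
    for t in tss_truth:
        t.pos %= length

    return SyntheticGenome(seq, features, tss_truth, footprint_truth,
                           config.footprint_borders, occupancy_levels, config)


def simulate_fragments(genome: SyntheticGenome,
                       occupancy: np.ndarray | None = None,
                       n: int = 10_000,
                       length_law: tuple = ("uniform", 40, 300),
                       seed: int | None = None) -> FragmentSet:
    """Draw ``n`` mapped fragments with start density ~ planted occupancy.

    ``length_law`` is ``("uniform", lo, hi)`` (inclusive bounds, bp) or
    ``("normal", mean, sd)``; drawn lengths are integers clipped to >= 1.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if genome.length == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    occ = genome.occupancy_track() if occupancy is None else \
        np.asarray(occupancy, dtype=float)
    if occ.size != genome.length:
        raise ValueError("occupancy track length mismatch")
    if (occ < 0).any() or occ.sum() <= 0:
        raise ValueError("occupancy must be non-negative with positive total")
    starts = rng.choice(genome.length, size=n, p=occ / occ.sum())
    kind = length_law[0]
    if kind == "uniform":
        lengths = rng.integers(int(length_law[1]), int(length_law[2]) + 1,
                               size=n)
    elif kind == "normal":
        lengths = np.maximum(
            np.rint(rng.normal(length_law[1], length_law[2], size=n)), 1
        ).astype(np.int64)
    else:
        raise ValueError(f"unknown length law {kind!r}")
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype("<U1")
    return FragmentSet(genome.replicon, starts, starts + lengths, strands)


def simulate_end_coverage(length: int,
                          point_truth: list[tuple[int, str, float]],
                          n: int,
                          jitter: int = 0,
                          background_rate: float = 0.0,
                          seed: int | None = None,
                          circular: bool = True,
                          replicon: str = "synchrom") -> StrandedCoverage:
    """Multinomial 5'-end counts: planted points plus uniform background.

    Each base on each strand carries weight ``background_rate``; every truth
    point ``(pos, strand, weight)`` spreads its weight uniformly over
    ``pos - jitter .. pos + jitter``. Exactly ``n`` counts are distributed in
    proportion to the resulting weights, so the track total is conserved.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    w = {s: np.full(length, background_rate, dtype=float) for s in "+-"}
    for pos, strand, weight in point_truth:
        if weight < 0:
            raise ValueError("truth weights must be >= 0")
        share = weight / (2 * jitter + 1)
        for off in range(-jitter, jitter + 1):
            p = pos + off
            if circular:
                p %= length
            elif not 0 <= p < length:
                continue
            w[strand][p] += share
    flat = np.concatenate([w["+"], w["-"]])
    total = flat.sum()
    if total <= 0:
        if n > 0:
            raise ValueError("no probability mass to place counts on")
        counts = np.zeros(2 * length)
    else:
        counts = np.random.default_rng(seed).multinomial(n, flat / total)
    return StrandedCoverage(replicon, counts[:length].astype(float),
                            counts[length:].astype(float), circular)


@dataclass
class TemplateDesign:
    """Geometry of a linear in vitro transcription template.

    Promoter-relative coordinates are 1-based with no zero: the TSS is +1 and
    the base immediately upstream is -1. ``clamp_length`` G/C base pairs are
    appended at each end of the covered region; the run-off transcript extends
    from the TSS to the downstream template end.
    """

    tss_rel_start: int
    tss_rel_end: int
    clamp_length: int = 5

    def __post_init__(self) -> None:
        if self.tss_rel_start == 0 or self.tss_rel_end == 0:
            raise ValueError("promoter-relative coordinates have no position 0"
                             " (TSS is +1)")
        if not self.tss_rel_start < 0 < self.tss_rel_end:
            raise ValueError("need tss_rel_start < 0 < tss_rel_end")
        if self.clamp_length < 0:
            raise ValueError("clamp_length must be >= 0")

    @property
    def runoff_length(self) -> int:
        """Run-off transcript length in nt (TSS to downstream template end)."""
        return self.tss_rel_end + self.clamp_length

    @property
    def template_length(self) -> int:
        return abs(self.tss_rel_start) + self.tss_rel_end + 2 * self.clamp_length


def design_template(tss_rel_start: int, tss_rel_end: int,
                    clamp_length: int = 5) -> TemplateDesign:
    """Build a :class:`TemplateDesign`; see the class docstring for units."""
    return TemplateDesign(tss_rel_start, tss_rel_end, clamp_length)
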