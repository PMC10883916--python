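"""Transcription start site (TSS) discovery from 5'-end coverage.

Cappable-seq selects 5'-triphosphorylated RNA, so per-base 5'-end counts mark
genuine initiation events. A position is a candidate TSS when its count rises
sharply over the position immediately upstream (in the strand's 5'->3'
reading direction): an absolute increase of more than ``abs_min`` read
5'-ends and more than ``fold_min``-fold relative increase. Candidates
reproducible at the exact position in at least ``min_samples`` samples are
kept, neighbouring candidates (< ``cluster_gap`` bp apart) are merged into
clusters represented by their centre, signal is quantified over an odd,
centred window, and clusters are classified against operon/CDS annotation as
primary, internal sense, antisense or intergenic, with primary TSSs flagged
leaderless when the 5'-UTR is shorter than 4 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import Feature
from .tracks import StrandedCoverage

TSS_CLASSES = ("primary", "internal_sense", "antisense", "intergenic")


@dataclass
class TSSCallParams:
    """Thresholds of the TSS discovery procedure.

    ``count_mode`` selects the reading of the absolute criterion:
    ``"increase"`` (default) requires the count *difference* versus the
    preceding position to exceed ``abs_min``; ``"absolute"`` requires the
    position's own count to exceed it.
    """

    abs_min: float = 20.0
    fold_min: float = 5.0
    min_samples: int = 2
    cluster_gap: int = 5
    window: int = 11
    leaderless_max_utr: int = 4
    primary_upstream: int = 300
    primary_downstream: int = 3
    count_mode: str = "increase"

    def __post_init__(self) -> None:
        if min(self.abs_min, self.fold_min) <= 0 or self.cluster_gap <= 0 \
                or self.min_samples <= 0 or self.window <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.window % 2 == 0:
            raise ValueError("window must be odd (centred on the TSS)")
        if self.count_mode not in ("increase", "absolute"):
            raise ValueError("count_mode must be 'increase' or 'absolute'")


@dataclass
class TSSCluster:
    """A called start site: centre of a chain of candidate positions."""

    replicon: str
    centre: int
    strand: str
    members: tuple[int, ...]
    counts: dict[str, float] = field(default_factory=dict)
    tss_class: str | None = None
    leaderless: bool | None = None
    utr_length: int | None = None
    operon: str | None = None


def call_candidates(cov5p: StrandedCoverage,
                    params: TSSCallParams) -> dict[str, np.ndarray]:
    """Per-strand candidate TSS positions for one sample.

    Position ``i`` is a candidate iff ``c_i - c_prev > abs_min`` (or
    ``c_i > abs_min`` in absolute mode) *and* either the preceding position
    has zero counts or ``c_i / c_prev > fold_min``. ``prev`` is the adjacent
    upstream position in the strand's 5'->3' direction; on a circular
    replicon it wraps around the origin.
    """
    out = {}
    for s, shift in (("+", 1), ("-", -1)):
        c = cov5p.strand(s)
        if cov5p.circular:
            prev = np.roll(c, shift)
        else:
            prev = np.empty_like(c)
            if s == "+":
                prev[1:], prev[0] = c[:-1], 0.0
            else:
                prev[:-1], prev[-1] = c[1:], 0.0
        if params.count_mode == "increase":
            abs_ok = (c - prev) > params.abs_min
        else:
            abs_ok = c > params.abs_min
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_ok = (prev == 0) | (c / np.where(prev == 0, 1.0, prev)
                                     > params.fold_min)
        out[s] = np.flatnonzero(abs_ok & fold_ok)
    return out


def keep_reproducible(candidate_sets: list[dict[str, np.ndarray]],
                      min_samples: int = 2) -> dict[str, np.ndarray]:
    """Exact-position, strand-matched intersection across samples.

    A position survives when it is a candidate in at least ``min_samples``
    of the per-sample sets (samples may come from different conditions).
    """
    if len(candidate_sets) < min_samples:
        raise ValueError(f"need >= {min_samples} candidate sets, got "
                         f"{len(candidate_sets)}")
    out = {}
    for s in "+-":
        all_pos = np.concatenate([np.asarray(cs.get(s, []), dtype=np.int64)
                                  for cs in candidate_sets])
        pos, counts = np.unique(all_pos, return_counts=True)
        out[s] = pos[counts >= min_samples]
    return out


def cluster_candidates(positions: np.ndarray, cluster_gap: int = 5
                       ) -> list[tuple[int, tuple[int, ...]]]:
    """Chain positions closer than ``cluster_gap`` bp into maximal clusters.

    Consecutive sorted positions join a chain when their gap is strictly
    smaller than ``cluster_gap``. The cluster centre is the median member;
    for an even member count the centre rounds toward the lower coordinate.
    Returns ``(centre, members)`` pairs; every input position belongs to
    exactly one cluster.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if pos.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) >= cluster_gap) + 1
    clusters = []
    for chunk in np.split(pos, breaks):
        centre = int(np.floor(np.median(chunk)))
        clusters.append((centre, tuple(int(p) for p in chunk)))
    return clusters


def build_clusters(positions: dict[str, np.ndarray], replicon: str,
                   cluster_gap: int = 5) -> list[TSSCluster]:
    """Cluster per-strand reproducible positions into :class:`TSSCluster`."""
    clusters = []
    for s in "+-":
        for centre, members in cluster_candidates(positions.get(s, []),
                                                  cluster_gap):
            clusters.append(TSSCluster(replicon, centre, s, members))
    clusters.sort(key=lambda c: (c.centre, c.strand))
    return clusters


def quantify_windows(samples: dict[str, StrandedCoverage],
                     clusters: list[TSSCluster],
                     window: int = 11) -> list[TSSCluster]:
    """Sum 5'-end counts over an odd window centred on each cluster.

    The window wraps around the origin on circular replicons and is truncated
    at the ends of linear ones. Counts are stored per sample on the cluster.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    for name, cov in samples.items():
        for cl in clusters:
            sig = cov.strand(cl.strand)
            idx = np.arange(cl.centre - half, cl.centre + half + 1)
            if cov.circular:
                idx %= cov.length
            else:
                idx = idx[(idx >= 0) & (idx < cov.length)]
            cl.counts[name] = float(sig[idx].sum())
    return clusters


def classify_tss(clusters: list[TSSCluster], operons: list[Feature],
                 cds_features: list[Feature],
                 params: TSSCallParams | None = None) -> list[TSSCluster]:
    """Assign each cluster exactly one class and, for primaries, a UTR.

    For every operon, same-strand clusters whose centre lies within
    ``primary_upstream`` bp upstream to ``primary_downstream`` bp downstream
    of the first CDS start compete; the strongest total window count wins
    (ties: closest to the start, then lower coordinate). Remaining clusters
    inside a CDS body are internal sense or antisense by strand; everything
    else is intergenic. ``utr_length`` is the strand-aware distance from the
    cluster centre to the CDS start (negative when the TSS sits inside the
    codon); a primary TSS is leaderless when the UTR is shorter than 4 nt.
    """
    params = params or TSSCallParams()
    for cl in clusters:
        if cl.strand not in "+-":
            raise ValueError(f"unknown strand {cl.strand!r}")
        cl.tss_class = None
        cl.leaderless = None
        cl.utr_length = None
        cl.operon = None

    first_cds: dict[str, Feature] = {}
    for cds in cds_features:
        if cds.parent is None:
            continue
        cur = first_cds.get(cds.parent)
        if cur is None:
            first_cds[cds.parent] = cds
        elif (cds.strand == "+" and cds.start < cur.start) or \
                (cds.strand == "-" and cds.end > cur.end):
            first_cds[cds.parent] = cds

    for op in operons:
        cds = first_cds.get(op.id)
        start = cds.five_prime if cds is not None else op.five_prime
        if op.strand == "+":
            lo, hi = start - params.primary_upstream, \
                start + params.primary_downstream
        else:
            lo, hi = start - params.primary_downstream, \
                start + params.primary_upstream
        hits = [cl for cl in clusters
                if cl.strand == op.strand and lo <= cl.centre <= hi]
        if not hits:
            continue
        best = max(hits, key=lambda cl: (sum(cl.counts.values()),
                                         -abs(cl.centre - start),
                                         -cl.centre))
        utr = start - best.centre if op.strand == "+" else best.centre - start
        if best.tss_class == "primary" and best.utr_length is not None \
                and abs(best.utr_length) <= abs(utr):
            continue  # already primary for a closer operon
        best.tss_class = "primary"
        best.utr_length = int(utr)
        best.leaderless = utr < params.leaderless_max_utr
        best.operon = op.id

    for cl in clusters:
        if cl.tss_class == "primary":
            continue
        sense = any(c.contains(cl.centre) and c.strand == cl.strand
                    for c in cds_features)
        anti = any(c.contains(cl.centre) and c.strand != cl.strand
                   for c in cds_features)
        if sense:
            cl.tss_class = "internal_sense"
        elif anti:
            cl.tss_class = "antisense"
        else:
            cl.tss_class = "intergenic"
    return clusters


def mask_region(clusters: list[TSSCluster],
                intervals: list[tuple[int, int]]) -> list[TSSCluster]:
    """Drop clusters whose centre falls inside any half-open interval."""
    return [cl for cl in clusters
            if not any(s <= cl.centre < e for s, e in intervals)]


def call_tss(samples: dict[str, StrandedCoverage],
             params: TSSCallParams | None = None,
             mask: list[tuple[int, int]] | None = None) -> list[TSSCluster]:
    """Full discovery pipeline: candidates -> reproducibility -> clusters ->
    window quantification (classification is separate)."""
    params = params or TSSCallParams()
    covs = list(samples.values())
    if not covs:
        raise ValueError("need at least one sample")
    cand = [call_candidates(c, params) for c in covs]
    repro = keep_reproducible(cand, params.min_samples)
    clusters = build_clusters(repro, covs[0].replicon, params.cluster_gap)
    if mask:
        clusters = mask_region(clusters, mask)
    return quantify_windows(samples, clusters, params.window)


def differential_tss_stub(counts: pd.DataFrame, conditions: dict[str, str],
                          alpha: float = 0.01) -> pd.DataFrame:
    """Minimal two-condition differential test on per-cluster window counts.

    ``counts`` has one row per cluster and one column per sample;
    ``conditions`` maps sample name to one of exactly two condition labels.
    Log2 fold change is computed on condition-mean CPM with a +1 pseudocount.
    The p-value comes from a two-sided binomial test of the condition-A count
    against the pooled library-size proportion; a Benjamini-Hochberg flag at
    ``alpha`` is reported separately from the raw p-value.
    """
    labels = sorted(set(conditions.values()))
    if len(labels) != 2:
        raise ValueError("need exactly two condition labels")
    a_cols = [s for s in counts.columns if conditions[s] == labels[0]]
    b_cols = [s for s in counts.columns if conditions[s] == labels[1]]
    if not a_cols or not b_cols:
        raise ValueError("each condition needs at least one sample")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm = counts / lib * 1e6
    mean_a, mean_b = cpm[a_cols].mean(axis=1), cpm[b_cols].mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    p0 = float(lib[a_cols].sum() / lib.sum())
    pvals = np.ones(len(counts))
    k_a = counts[a_cols].sum(axis=1).round().astype(int).to_numpy()
    k_tot = counts.sum(axis=1).round().astype(int).to_numpy()
    for i, (k, n) in enumerate(zip(k_a, k_tot)):
        if n > 0:
            pvals[i] = stats.binomtest(k, n, p0).pvalue
    significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals,
                         "significant": significant}, index=counts.index)
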