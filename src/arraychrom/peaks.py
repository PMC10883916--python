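"""Peak reproducibility matching, filtering, and TSS-to-summit linking.

Peak lists come from an external narrow-peak caller (one list per biological
replicate, each peak with a summit position and a fold enrichment over
input). Reproducible binding sites are defined by matching summits between
replicates within a maximal distance, filtering on mean enrichment, and
excluding summits inside regions where enrichment is trivially expected
(CRISPR arrays, rRNA loci). Called TSSs are then linked to the nearest
reproducible summit to test for binding-associated transcription changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tss import TSSCluster


@dataclass
class Peak:
    replicon: str
    start: int
    end: int
    summit: int
    enrichment: float
    score: float | None = None  # -log10 p, optional

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie within the peak interval")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")


@dataclass
class MatchedPeak:
    rep1: Peak
    rep2: Peak
    distance: int

    @property
    def summit(self) -> int:
        """Consensus summit: mean of the two replicate summits (rounded down)."""
        return (self.rep1.summit + self.rep2.summit) // 2

    @property
    def enrichment(self) -> float:
        """Replicate-mean enrichment."""
        return (self.rep1.enrichment + self.rep2.enrichment) / 2.0


def match_summits(peaks_rep1: list[Peak], peaks_rep2: list[Peak],
                  max_dist: int = 40) -> list[MatchedPeak]:
    """Greedy nearest-summit matching between two replicates.

    Candidate pairs with summit distance <= ``max_dist`` (inclusive) are
    accepted closest-first; each peak joins at most one pair. Distance ties
    are broken toward the lower-coordinate partner.
    """
    pairs = []
    for i, p1 in enumerate(peaks_rep1):
        for j, p2 in enumerate(peaks_rep2):
            if p1.replicon != p2.replicon:
                continue
            d = abs(p1.summit - p2.summit)
            if d <= max_dist:
                pairs.append((d, p1.summit, p2.summit, i, j))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    matches = []
    for d, _, _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matches.append(MatchedPeak(peaks_rep1[i], peaks_rep2[j], d))
    matches.sort(key=lambda m: m.summit)
    return matches


def filter_peaks(peaks: list, min_enrichment: float = 5.0,
                 excluded_regions: list[tuple[int, int]] = ()) -> list:
    """Keep peaks with enrichment strictly above the threshold and the summit
    outside every excluded half-open region."""
    out = []
    for p in peaks:
        if p.enrichment <= min_enrichment:
            continue
        if any(s <= p.summit < e for s, e in excluded_regions):
            continue
        out.append(p)
    return out


@dataclass
class TSSLink:
    cluster: TSSCluster
    summit: int | None
    distance: int | None

    @property
    def linked(self) -> bool:
        return self.summit is not None


def link_tss_to_summits(clusters: list[TSSCluster], summits: list[int],
                        max_dist: int = 50) -> list[TSSLink]:
    """Annotate each TSS with its nearest summit within ``max_dist`` bp.

    Distance is strand-agnostic, from the cluster centre to the summit,
    with an inclusive bound; TSSs with no summit in range stay unlinked.
    """
    s = np.sort(np.asarray(summits, dtype=np.int64))
    links = []
    for cl in clusters:
        if s.size == 0:
            links.append(TSSLink(cl, None, None))
            continue
        i = int(np.searchsorted(s, cl.centre))
        best = min((int(s[j]) for j in (i - 1, i) if 0 <= j < s.size),
                   key=lambda x: (abs(x - cl.centre), x))
        d = abs(best - cl.centre)
        if d <= max_dist:
            links.append(TSSLink(cl, best, d))
        else:
            links.append(TSSLink(cl, None, None))
    return links
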