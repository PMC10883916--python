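"""Exact enrichment statistics: Fisher's test, Bonferroni, regional tests.

The two-sided Fisher exact p-value uses the probability-mass convention:
with all margins fixed, it sums the hypergeometric probabilities of every
table no more probable than the observed one (with a small relative slack to
absorb floating-point ties), evaluated in log space for stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

_SLACK = 1e-7  # relative tie tolerance on the observed table's probability


@dataclass
class ContingencyTable2x2:
    """Counts (rows: in-category / not; columns: flagged / not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    ``table`` is a :class:`ContingencyTable2x2`, a 2x2 array, or a flat
    ``(a, b, c, d)`` sequence. Returns p in (0, 1].
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        arr = np.asarray(table).ravel()
        if arr.size != 4:
            raise ValueError("need a 2x2 table")
        a, b, c, d = (int(v) for v in arr)
        ContingencyTable2x2(a, b, c, d)  # validates
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margins: a single attainable table
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    logp = (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    log_obs = logp[a - kmin]
    keep = logp <= log_obs + np.log1p(_SLACK)
    return float(min(np.exp(logsumexp(logp[keep])), 1.0))


def adjust_bonferroni(pvals, m: int) -> np.ndarray:
    """Bonferroni adjustment over a family of ``m`` tests: min(1, m*p)."""
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than {p.size} tests")
    return np.minimum(1.0, m * p)


@dataclass
class CIDAnnotation:
    """Chromosomal interaction domains with operon membership and flags.

    ``cids`` are non-overlapping half-open intervals with ids; each operon is
    assigned to at most one CID by its midpoint; ``operon_flags`` maps operon
    id to ``'up'``, ``'down'`` or ``'ns'`` (an operon is flagged when at
    least one of its genes carries that differential flag).
    """

    cids: list[tuple[int, int, str]]
    operon_cid: dict[str, str | None]
    operon_flags: dict[str, str]

    def __post_init__(self) -> None:
        ivs = sorted((s, e) for s, e, _ in self.cids)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("CIDs must be non-overlapping")


def assign_operons_to_cids(cids: list[tuple[int, int, str]],
                           operons: list) -> dict[str, str | None]:
    """Map each operon to the CID containing its midpoint (or None)."""
    out = {}
    for op in operons:
        mid = (op.start + op.end) // 2
        out[op.id] = next((cid for s, e, cid in cids if s <= mid < e), None)
    return out


def cid_operon_enrichment(annotation: CIDAnnotation,
                          direction: str = "down") -> pd.DataFrame:
    """Per-CID Fisher test of flagged-operon enrichment.

    For each CID the 2x2 table crosses operon membership (in the CID or not)
    with the differential flag (``direction`` or not). The Bonferroni family
    is fixed at (number of CIDs) x 2, covering both regulation directions.
    CIDs containing no operons are excluded with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rows = []
    n_flagged = sum(1 for f in annotation.operon_flags.values()
                    if f == direction)
    n_total = len(annotation.operon_flags)
    for s, e, cid in annotation.cids:
        members = [o for o, c in annotation.operon_cid.items() if c == cid]
        if not members:
            warnings.warn(f"CID {cid} contains no operons; excluded")
            continue
        a = sum(1 for o in members if annotation.operon_flags[o] == direction)
        b = len(members) - a
        c = n_flagged - a
        d = (n_total - len(members)) - c
        t = ContingencyTable2x2(a, b, c, d)
        rows.append({"cid": cid, "start": s, "end": e, "n_operons":
                     len(members), "n_flagged": a, "odds_ratio": t.odds_ratio,
                     "pvalue": fisher_exact_2x2(t)})
    df = pd.DataFrame(rows)
    m = max(len(annotation.cids) * 2, 1)
    if len(df):
        df["padj"] = adjust_bonferroni(df["pvalue"].to_numpy(), m)
    return df


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    pvalue: float
    padj: float


def tss_binding_enrichment(in_category: np.ndarray, up_flag: np.ndarray,
                           family_size: int = 1) -> EnrichmentResult:
    """Fisher test of differential-TSS enrichment in a category of TSSs.

    ``in_category`` marks TSSs inside CRISPR arrays (or linked to binding
    site summits); ``up_flag`` marks TSSs called differentially transcribed.
    Bonferroni adjusts over the declared family of such tests.
    """
    cat = np.asarray(in_category, dtype=bool)
    up = np.asarray(up_flag, dtype=bool)
    if cat.shape != up.shape:
        raise ValueError("flag vectors must have equal length")
    if not cat.any():
        raise ValueError("empty category")
    t = ContingencyTable2x2(int((cat & up).sum()), int((cat & ~up).sum()),
                            int((~cat & up).sum()), int((~cat & ~up).sum()))
    p = fisher_exact_2x2(t)
    padj = float(adjust_bonferroni([p], family_size)[0])
    return EnrichmentResult(t, t.odds_ratio, p, padj)
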