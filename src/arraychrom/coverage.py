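"""ChIP-seq fragment-length resampling normalization and track arithmetic.

The central operation is :func:`resample_fragments`: ChIP libraries from
different samples carry different fragment-length distributions, which biases
occupancy comparisons; thinning each library so that the retained lengths
follow a common target normal distribution (mean 120 bp, sd 18 bp for
*S. solfataricus* P2 data; 150/20 for *S. islandicus* LAL14/1) removes that
bias. The remaining operations build per-base coverage from fragments, bin
tracks, normalize immunoprecipitation (IP) signal to input, combine
replicates, and correlate binned tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import BinnedTrack, FragmentSet, GridMismatchError, StrandedCoverage


class NormalizationImpossibleError(ValueError):
    """No input fragment lies near the target length distribution."""


class InsufficientDataError(ValueError):
    """Too few surviving bins to compute a statistic."""


@dataclass
class NormalizationParams:
    """Target length distribution and track grid for ChIP-seq normalization."""

    target_mean: float = 120.0
    target_sd: float = 18.0
    bin_width: int = 30
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


#: defaults used for the two chromosomes the analysis targets
P2_PARAMS = NormalizationParams(target_mean=120.0, target_sd=18.0)
LAL14_PARAMS = NormalizationParams(target_mean=150.0, target_sd=20.0)


def length_acceptance(lengths: np.ndarray, params: NormalizationParams
                      ) -> tuple[int, np.ndarray]:
    """Per-length acceptance probabilities of the density-ratio thinning.

    The empirical length density is estimated on a 1 bp histogram spanning
    the observed length range (floored at one count per length); the
    acceptance probability of length ``l`` is proportional to
    ``target_pdf(l) / empirical_density(l)`` with the proportionality
    constant chosen as large as possible such that all probabilities stay
    <= 1 (maximal yield). Returns the histogram origin ``lo`` and the
    acceptance array for lengths ``lo .. lo + len(accept) - 1``.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    lo, hi = int(lengths.min()), int(lengths.max())
    hist = np.bincount(lengths - lo, minlength=hi - lo + 1).astype(float)
    hist = np.maximum(hist, 1.0)
    emp = hist / hist.sum()
    target = stats.norm.pdf(np.arange(lo, hi + 1), params.target_mean,
                            params.target_sd)
    ratio = target / emp
    return lo, np.minimum(ratio / ratio.max(), 1.0)


def resample_fragments(frags: FragmentSet, params: NormalizationParams,
                       seed: int | None = None) -> FragmentSet:
    """Thin a fragment set so retained lengths follow the target normal.

    Density-ratio thinning with the per-length acceptance probabilities of
    :func:`length_acceptance`. The output is always a subset of the input;
    it raises :class:`NormalizationImpossibleError` when no input fragment
    length lies within four target standard deviations of the target mean.
    """
    if len(frags) == 0:
        raise ValueError("cannot resample an empty fragment set")
    lengths = frags.lengths
    mu, sd = params.target_mean, params.target_sd
    if not ((lengths >= mu - 4 * sd) & (lengths <= mu + 4 * sd)).any():
        raise NormalizationImpossibleError(
            f"no fragment length within {mu} +/- 4*{sd} bp")
    lo, accept = length_acceptance(lengths, params)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < accept[lengths - lo]
    return frags.subset(keep)


def fragments_to_coverage(frags: FragmentSet, length: int,
                          circular: bool = True) -> StrandedCoverage:
    """Per-base, per-strand count of fragments overlapping each base.

    The sum over all bases and strands equals the summed fragment lengths.
    Fragments extending past the end of a circular replicon wrap around.
    """
    fwd = np.zeros(length)
    rev = np.zeros(length)
    for track, s in ((fwd, "+"), (rev, "-")):
        sel = frags.strands == s
        starts, ends = frags.starts[sel], frags.ends[sel]
        if circular:
            starts = starts % length
            ends = starts + (frags.ends[sel] - frags.starts[sel])
        diff = np.zeros(length + 1)
        wraps = ends > length
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, np.minimum(ends, length), -1.0)
        track += np.cumsum(diff[:-1])
        if circular and wraps.any():
            wdiff = np.zeros(length + 1)
            np.add.at(wdiff, np.zeros(wraps.sum(), dtype=int), 1.0)
            np.add.at(wdiff, ends[wraps] - length, -1.0)
            track += np.cumsum(wdiff[:-1])
        elif not circular and (ends > length).any():
            raise ValueError("fragment exceeds linear replicon")
    return StrandedCoverage(frags.replicon, fwd, rev, circular)


def bin_coverage(cov: StrandedCoverage, bin_width: int) -> BinnedTrack:
    """Sum strand-collapsed per-base signal over consecutive bins.

    The last bin is truncated when the replicon length is not a multiple of
    the bin width, so bins always tile the replicon exactly.
    """
    sig = cov.combined()
    edges = np.arange(0, sig.size, bin_width)
    return BinnedTrack(cov.replicon, bin_width, np.add.reduceat(sig, edges))


def window_fragment_counts(frags: FragmentSet, length: int,
                           bin_width: int = 30) -> BinnedTrack:
    """Count fragments overlapping each consecutive window.

    This is the counting step of window-based differential binding: a
    fragment contributes one count to every window it overlaps.
    """
    n_bins = int(np.ceil(length / bin_width))
    diff = np.zeros(n_bins + 1)
    first = (frags.starts % length) // bin_width
    # the tail of an origin-wrapping fragment is clipped at the grid end
    last = np.maximum((np.minimum(frags.ends, length) - 1) // bin_width, first)
    np.add.at(diff, first, 1.0)
    np.add.at(diff, last + 1, -1.0)
    return BinnedTrack(frags.replicon, bin_width, np.cumsum(diff[:-1]))


def normalize_to_input(ip: BinnedTrack, input_: BinnedTrack,
                       pseudocount: float = 1.0) -> BinnedTrack:
    """Per-bin IP / input enrichment ratio after counts-per-million scaling.

    Both tracks are scaled to counts per million, then the ratio
    ``(ip_cpm + pseudocount) / (input_cpm + pseudocount)`` is taken. Scaling
    first makes the ratio invariant to sequencing depth.
    """
    ip.require_same_grid(input_)
    for t in (ip, input_):
        if t.values.sum() <= 0:
            raise ValueError("cannot CPM-scale a track with zero total")
    ip_cpm = ip.values / ip.values.sum() * 1e6
    in_cpm = input_.values / input_.values.sum() * 1e6
    return BinnedTrack(ip.replicon, ip.bin_width,
                       (ip_cpm + pseudocount) / (in_cpm + pseudocount))


def _combine_arrays(arrs: list[np.ndarray], method: str,
                    pseudocount: float) -> np.ndarray:
    stacked = np.stack(arrs)
    if method not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown method {method!r}")
    if len(arrs) == 1:
        return stacked[0].copy()
    if method == "arithmetic":
        return stacked.mean(axis=0)
    with np.errstate(divide="ignore"):
        logs = np.log(stacked + pseudocount)
    out = np.exp(logs.mean(axis=0)) - pseudocount
    return np.maximum(out, 0.0)


def combine_replicates(tracks: list, method: str = "arithmetic",
                       scale: str = "none", pseudocount: float = 0.0):
    """Per-position mean of replicate tracks (arithmetic or geometric).

    ``scale='cpm'`` divides each track by its total / 1e6 before combining.
    A positive ``pseudocount`` is added inside the log for the geometric mean
    (and subtracted afterwards) to tolerate zero-heavy 5'-end tracks.
    Accepts :class:`StrandedCoverage` or :class:`BinnedTrack` inputs, all on
    the same grid, and returns the same type.
    """
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    if any(type(t) is not type(first) for t in tracks):
        raise GridMismatchError("mixed track types")
    if isinstance(first, StrandedCoverage):
        if any(not first.same_grid(t) for t in tracks):
            raise GridMismatchError("replicate tracks on different grids")
        scales = [t.total() / 1e6 if scale == "cpm" else 1.0 for t in tracks]
        fwd = _combine_arrays([t.fwd / s for t, s in zip(tracks, scales)],
                              method, pseudocount)
        rev = _combine_arrays([t.rev / s for t, s in zip(tracks, scales)],
                              method, pseudocount)
        return StrandedCoverage(first.replicon, fwd, rev, first.circular)
    if isinstance(first, BinnedTrack):
        for t in tracks:
            first.require_same_grid(t)
        scales = [t.values.sum() / 1e6 if scale == "cpm" else 1.0
                  for t in tracks]
        vals = _combine_arrays([t.values / s for t, s in zip(tracks, scales)],
                               method, pseudocount)
        return BinnedTrack(first.replicon, first.bin_width, vals)
    raise TypeError(f"unsupported track type {type(first).__name__}")


def correlate_binned(a: BinnedTrack, b: BinnedTrack, method: str = "pearson",
                     min_value: float = 0.0) -> float:
    """Correlation of two binned tracks over informative bins.

    Bins whose value falls below ``min_value`` in *both* tracks are excluded
    before computing the coefficient.
    """
    a.require_same_grid(b)
    keep = (a.values >= min_value) | (b.values >= min_value)
    x, y = a.values[keep], b.values[keep]
    if x.size < 3:
        raise InsufficientDataError(
            f"only {x.size} bins survive min_value={min_value}")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
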