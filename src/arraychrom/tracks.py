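"""Core in-memory containers: stranded per-base tracks, mapped fragments, binned tracks.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based inclusive convention happens only at the GFF3 boundary (see
:mod:`arraychrom.io`). Replicons are circular by default (archaeal chromosome),
so intervals may wrap: a wrapping fragment is stored unwrapped with
``end > replicon length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")


class GridMismatchError(ValueError):
    """Two tracks do not share replicon, length or bin width."""


@dataclass
class StrandedCoverage:
    """Per-base, per-strand non-negative signal over one replicon.

    Holds either 5'-end counts (Cappable-seq, ChIP-exo) or fragment coverage
    (ChIP-seq), depending on how it was produced.
    """

    replicon: str
    fwd: np.ndarray
    rev: np.ndarray
    circular: bool = True

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 1:
            raise ValueError("fwd/rev must be 1-D arrays of equal length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("coverage must be non-negative")

    @property
    def length(self) -> int:
        return self.fwd.size

    def strand(self, s: str) -> np.ndarray:
        if s == "+":
            return self.fwd
        if s == "-":
            return self.rev
        raise ValueError(f"unknown strand {s!r}")

    def total(self) -> float:
        """Library size: summed signal over both strands."""
        return float(self.fwd.sum() + self.rev.sum())

    def combined(self) -> np.ndarray:
        """Strand-collapsed per-base signal."""
        return self.fwd + self.rev

    def copy(self) -> "StrandedCoverage":
        return StrandedCoverage(self.replicon, self.fwd.copy(), self.rev.copy(),
                                self.circular)

    def same_grid(self, other: "StrandedCoverage") -> bool:
        return (self.replicon == other.replicon and self.length == other.length)


@dataclass
class FragmentSet:
    """Mapped paired-end fragments on one replicon, as half-open intervals.

    ``ends`` may exceed the replicon length for fragments wrapping the origin
    of a circular replicon; ``ends > starts`` always holds after unwrapping.
    """

    replicon: str
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.strands is None:
            self.strands = np.full(self.starts.size, "+", dtype="<U1")
        else:
            self.strands = np.asarray(self.strands, dtype="<U1")
        if not (self.starts.shape == self.ends.shape == self.strands.shape):
            raise ValueError("starts/ends/strands must have equal shapes")
        if self.starts.size and (self.ends <= self.starts).any():
            raise ValueError("fragment ends must exceed starts (unwrap circular"
                             " fragments first)")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.replicon, self.starts[mask], self.ends[mask],
                           self.strands[mask])


@dataclass
class BinnedTrack:
    """Per-bin values (counts or ratios) on a fixed grid tiling one replicon."""

    replicon: str
    bin_width: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("bin values must be finite")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (self.replicon == other.replicon
                and self.bin_width == other.bin_width
                and self.n_bins == other.n_bins)

    def require_same_grid(self, other: "BinnedTrack") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"bin grids differ: ({self.replicon}, w={self.bin_width}, "
                f"n={self.n_bins}) vs ({other.replicon}, w={other.bin_width}, "
                f"n={other.n_bins})")
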