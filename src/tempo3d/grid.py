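"""Genome coordinate model: binned grids, intervals, gene annotations.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package.  Readers converting from 1-based conventions (GTF-style TSS) do so
at the parsing boundary, so nothing downstream ever sees mixed conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["GenomeGrid", "Interval", "AnnotatedGene", "overlaps", "overlap_length"]


@dataclass(frozen=True)
class GenomeGrid:
    """A fixed-resolution binning of a genome.

    Bin ``b`` of a chromosome covers the half-open interval
    ``[b * binsize, (b + 1) * binsize)``; the last bin may be partial.

    Parameters
    ----------
    chromsizes
        Mapping of chromosome name to length in base pairs.
    binsize
        Bin width in base pairs (e.g. 100_000 for compartment calling,
        50_000 for TAD-border calling).
    """

    chromsizes: Mapping[str, int]
    binsize: int

    def __post_init__(self) -> None:
        if self.binsize <= 0:
            raise ValueError(f"binsize must be positive, got {self.binsize}")
        for chrom, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "chromsizes", dict(self.chromsizes))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromsizes)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chromsizes[chrom] / self.binsize)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing base-pair position ``pos`` (0-based)."""
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chromsizes[chrom]})")
        return pos // self.binsize

    def bin_interval(self, chrom: str, b: int) -> "Interval":
        n = self.n_bins(chrom)
        if not 0 <= b < n:
            raise ValueError(f"bin {b} out of range for {chrom} ({n} bins)")
        start = b * self.binsize
        end = min((b + 1) * self.binsize, self.chromsizes[chrom])
        return Interval(chrom, start, end)


@dataclass(frozen=True)
class Interval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    signal: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class AnnotatedGene:
    """A gene reduced to the fields promoter definition needs."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS {self.tss}")


def overlap_length(a: Interval, b: Interval) -> int:
    """Length in bp of the intersection of two half-open intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: Interval, b: Interval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` base pairs.

    Half-open semantics: abutting intervals ([0,10) vs [10,20)) do not overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp
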