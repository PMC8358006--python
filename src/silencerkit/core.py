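"""Core domain types shared by every stage.

All coordinates are 0-based, half-open ``[start, end)``.  Conversions to and
from file conventions happen only at the I/O boundary (:mod:`silencerkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "CoverageTrack",
    "GeneModel",
    "ChromatinLoop",
]


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str = "", line_number: int | None = None):
        loc = f"{path}:{line_number}: " if line_number is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line_number = line_number


class ValidationError(ValueError):
    """Data violated an invariant (bad coordinates, out-of-bounds value...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval.

    Sort order is (chrom, start, end) so a list of intervals sorts
    genomically with plain ``sorted``.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """Stranded gene; TSS/TES carry orientation, ``body`` is the span."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if self.tss == self.tes:
            raise ValidationError(f"gene {self.gene_id}: zero-length body")
        if self.strand == "+" and self.tss > self.tes:
            raise ValidationError(
                f"gene {self.gene_id}: + strand requires tss < tes"
            )
        if self.strand == "-" and self.tss < self.tes:
            raise ValidationError(
                f"gene {self.gene_id}: - strand requires tss > tes"
            )

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(self.tss, self.tes),
            max(self.tss, self.tes),
            name=self.gene_id,
            strand=self.strand,
        )


@dataclass(frozen=True)
class ChromatinLoop:
    """Unordered pair of anchors; ``score`` optional, kept for provenance."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None

    @property
    def inter_chromosomal(self) -> bool:
        return self.anchor1.chrom != self.anchor2.chrom

    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor1, self.anchor2)


class CoverageTrack:
    """Run-length coverage: per chromosome, sorted non-overlapping runs.

    Gaps between runs have value 0 by convention — this matters for RPKM
    and methylation means.  ``total_mapped`` is the library size used for
    RPKM scaling of read-derived tracks; value-style tracks (methylation
    betas) leave it at None and set ``value_bounds=(0, 1)``.
    """

    def __init__(
        self,
        total_mapped: Optional[int] = None,
        value_bounds: Optional[tuple[float, float]] = None,
    ):
        self.total_mapped = total_mapped
        self.value_bounds = value_bounds
        # chrom -> (starts, ends, values, prefix) with prefix[i] = cumulative
        # sum of value*length over runs [0, i)
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self._building: dict[str, list[tuple[int, int, float]]] = {}

    # -- construction -----------------------------------------------------
    def add_run(self, chrom: str, start: int, end: int, value: float) -> None:
        if not (0 <= start < end):
            raise ValidationError(f"bad run {chrom}:{start}-{end}")
        if not np.isfinite(value):
            raise ValidationError(f"non-finite value at {chrom}:{start}-{end}")
        if self.value_bounds is not None:
            lo, hi = self.value_bounds
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"value {value} at {chrom}:{start}-{end} outside "
                    f"bounds [{lo}, {hi}]"
                )
        self._building.setdefault(chrom, []).append((start, end, float(value)))
        self._runs.pop(chrom, None)

    def _finalize(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if chrom in self._runs:
            return self._runs[chrom]
        raw = sorted(self._building.get(chrom, []))
        starts = np.array([r[0] for r in raw], dtype=np.int64)
        ends = np.array([r[1] for r in raw], dtype=np.int64)
        values = np.array([r[2] for r in raw], dtype=np.float64)
        if len(raw) > 1 and np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValidationError(
                f"overlapping runs on {chrom} near position {starts[i + 1]}"
            )
        prefix = np.concatenate(([0.0], np.cumsum(values * (ends - starts))))
        self._runs[chrom] = (starts, ends, values, prefix)
        return self._runs[chrom]

    # -- queries ----------------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return sorted(set(self._building) | set(self._runs))

    def runs(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        starts, ends, values, _ = self._finalize(chrom)
        for s, e, v in zip(starts, ends, values):
            yield int(s), int(e), float(v)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x overlap-length over [start, end); gaps contribute 0."""
        if end <= start:
            raise ValidationError(f"zero-length query {chrom}:{start}-{end}")
        if chrom not in self._building and chrom not in self._runs:
            return 0.0
        starts, ends, values, prefix = self._finalize(chrom)
        if len(starts) == 0:
            return 0.0
        # runs fully inside: first index with start >= query start etc.
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            # at most one run can straddle the query
            k = i - 1
            if 0 <= k < len(starts):
                ov = min(ends[k], end) - max(starts[k], start)
                if ov > 0:
                    return float(values[k] * ov)
            return 0.0
        total = float(prefix[j] - prefix[i])
        # trim partial overlap at both edges
        if starts[i] < start:
            total -= float(values[i] * (start - starts[i]))
        if ends[j - 1] > end:
            total -= float(values[j - 1] * (ends[j - 1] - end))
        return total

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        return self.sum_over(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean value over ``n_bins`` equal-width bins of [start, end).

        Bin edges are computed in float so unequal remainders are spread
        evenly; each bin mean treats gaps as zero.
        """
        if n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        edges = np.linspace(start, end, n_bins + 1)
        out = np.empty(n_bins, dtype=np.float64)
        for b in range(n_bins):
            lo = int(np.floor(edges[b]))
            hi = max(lo + 1, int(np.ceil(edges[b + 1])))
            out[b] = self.mean_over(chrom, lo, hi)
        return out

    def rpkm(self, chrom: str, start: int, end: int) -> float:
        """Reads-per-kilobase-per-million over a region.

        Run values are per-base read depth, so reads-in-region is the
        depth-weighted overlap sum.
        """
        if self.total_mapped is None or self.total_mapped <= 0:
            raise ValidationError("rpkm requires total_mapped > 0")
        reads = self.sum_over(chrom, start, end)
        length_kb = (end - start) / 1000.0
        millions = self.total_mapped / 1e6
        return reads / (length_kb * millions)
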