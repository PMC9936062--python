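"""Genomic-interval algebra underlying every stage of the pipeline.

Coordinates are half-open ``[start, end)`` throughout, so the length of an
interval is simply ``end - start`` and two intervals that merely touch
(``end == start``) do not overlap.  Copy-number events are unstranded, so no
strand field exists anywhere in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CnvType",
    "RegionType",
    "GenomicInterval",
    "TypedInterval",
    "MergedRegion",
    "interval_length",
    "overlap_length",
    "union_length",
    "overlap_fraction",
    "merge_overlapping",
    "coverage_fraction",
]


class CnvType(str, enum.Enum):
    """Copy-number event class: deletion (loss) or duplication (gain)."""

    DEL = "DEL"
    DUP = "DUP"


class RegionType(str, enum.Enum):
    """Type of a merged multi-sample region; BOTH when members disagree."""

    DEL = "DEL"
    DUP = "DUP"
    BOTH = "BOTH"


class IntervalError(ValueError):
    """Raised for malformed intervals (``end <= start``, negative start...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    ``length == end - start``; zero-length intervals are rejected.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start coordinate: {self!r}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TypedInterval:
    """An interval carrying a DEL/DUP label."""

    interval: GenomicInterval
    cnv_type: CnvType

    def __post_init__(self) -> None:
        object.__setattr__(self, "cnv_type", CnvType(self.cnv_type))


@dataclass
class MergedRegion:
    """A maximal union of overlapping typed intervals (a CNVR precursor).

    ``region_type`` is DEL or DUP when every member agrees, BOTH otherwise.
    ``member_indices`` records which inputs were absorbed.
    """

    interval: GenomicInterval
    region_type: RegionType
    member_indices: list[int] = field(default_factory=list)


def interval_length(iv: GenomicInterval) -> int:
    """Base-pair length of *iv* (``end - start``)."""
    return iv.length


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by *a* and *b*; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _merged_spans(ivs: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome union of intervals as sorted disjoint (start, end) runs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged: list[tuple[int, int]] = []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # touching runs coalesce in a plain union
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        out[chrom] = merged
    return out


def union_length(ivs: Iterable[GenomicInterval]) -> int:
    """Total number of distinct bases covered by *ivs*."""
    return sum(
        e - s for spans in _merged_spans(ivs).values() for s, e in spans
    )


def overlap_fraction(
    query: GenomicInterval, refs: Iterable[GenomicInterval]
) -> float:
    """Fraction of *query* covered by the union of *refs* (query-anchored).

    The denominator is the query length; the numerator is the number of
    query bases covered by at least one reference.  An empty reference set
    yields 0.0.
    """
    covered = 0
    spans = _merged_spans(r for r in refs if r.chrom == query.chrom)
    for s, e in spans.get(query.chrom, []):
        covered += max(0, min(e, query.end) - max(s, query.start))
    return covered / query.length


def merge_overlapping(
    ivs: Sequence[TypedInterval], min_overlap_bp: int = 1
) -> list[MergedRegion]:
    """Aggregate typed intervals into maximal regions chained by overlap.

    Two intervals belong to the same region when they overlap by at least
    ``min_overlap_bp`` bases (default 1 bp), directly or through a chain of
    intermediates.  Under half-open coordinates, adjacent intervals
    (``a.end == b.start``) share 0 bp and are NOT merged.  Output regions are
    pairwise non-overlapping and sorted by (chrom, start); each carries the
    consensus type (DEL/DUP if unanimous, else BOTH) and the indices of its
    member inputs.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    order = sorted(
        range(len(ivs)),
        key=lambda i: (ivs[i].interval.chrom, ivs[i].interval.start, ivs[i].interval.end),
    )
    regions: list[MergedRegion] = []
    cur: MergedRegion | None = None
    cur_types: set[CnvType] = set()
    for idx in order:
        ti = ivs[idx]
        iv = ti.interval
        if (
            cur is not None
            and iv.chrom == cur.interval.chrom
            and min(iv.end, cur.interval.end) - max(iv.start, cur.interval.start)
            >= min_overlap_bp
        ):
            cur.interval = GenomicInterval(
                iv.chrom, cur.interval.start, max(cur.interval.end, iv.end)
            )
            cur.member_indices.append(idx)
            cur_types.add(ti.cnv_type)
            cur.region_type = (
                RegionType(next(iter(cur_types)).value)
                if len(cur_types) == 1
                else RegionType.BOTH
            )
        else:
            cur = MergedRegion(iv, RegionType(ti.cnv_type.value), [idx])
            cur_types = {ti.cnv_type}
            regions.append(cur)
    return regions


def coverage_fraction(
    ivs: Iterable[GenomicInterval], chrom_length: int
) -> float:
    """Fraction of a chromosome of length *chrom_length* covered by *ivs*.

    All intervals must lie on a single chromosome and within its bounds.
    """
    ivs = list(ivs)
    if not ivs:
        return 0.0
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise IntervalError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    bad = [iv for iv in ivs if iv.end > chrom_length]
    if bad:
        raise IntervalError(
            f"interval {bad[0]} extends beyond chromosome length {chrom_length}"
        )
    return union_length(ivs) / chrom_length
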