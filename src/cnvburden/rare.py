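"""Common-vs-rare classification of CNV calls by reference overlap.

A call is "common" when the union of matching reference intervals — a
common-CNV catalogue plus, optionally, the control cohort's own calls —
covers strictly more than ``overlap_threshold`` of its length (the default
threshold is 0.5 with strictly-greater semantics, so exactly 50% coverage
is retained as rare).  Matching is type-aware by default: deletions are
only masked by deletion references and duplications by duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import (
    CnvType,
    GenomicInterval,
    TypedInterval,
    overlap_fraction,
    overlap_length,
)
from .io import CnvCall

__all__ = ["RareFilterConfig", "FilterResult", "filter_rare", "split_by_type",
           "control_reference_intervals"]


@dataclass(frozen=True)
class RareFilterConfig:
    """Overlap rule for excluding common CNVs.

    overlap_threshold
        Exclusive fraction; a call is removed when its covered fraction is
        strictly greater than this (default 0.5).
    type_matched
        When true (default), DEL calls are compared only against DEL
        references and DUP against DUP.
    min_control_carriers
        A genomic segment from the control cohort joins the reference set
        only when at least this many distinct control samples carry an
        overlapping call of the same type (default 1).
    anchor
        What the overlap fraction is measured against: ``"query"``
        (default; union of references over the call's length),
        ``"reference"`` (best single reference's covered fraction) or
        ``"reciprocal"`` (best single reference's min of both fractions).
    """

    overlap_threshold: float = 0.5
    type_matched: bool = True
    min_control_carriers: int = 1
    anchor: str = "query"

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.min_control_carriers < 1:
            raise ValueError("min_control_carriers must be >= 1")
        if self.anchor not in ("query", "reference", "reciprocal"):
            raise ValueError("anchor must be query, reference or reciprocal")


@dataclass
class FilterResult:
    """Partition of the input calls: ``rare + removed`` is the input."""

    rare: list[CnvCall]
    removed: list[CnvCall]
    removed_fractions: list[float] = field(default_factory=list)


def _merge_sample_spans(
    spans: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    spans.sort()
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def control_reference_intervals(
    control_calls: Iterable[CnvCall], min_carriers: int = 1
) -> list[TypedInterval]:
    """Collapse control-cohort calls into reference intervals.

    For each chromosome and CNV type, per-sample calls are first merged, and
    genomic segments covered by at least ``min_carriers`` distinct control
    samples are emitted.
    """
    by_key: dict[tuple[str, CnvType], dict[str, list[tuple[int, int]]]] = {}
    for c in control_calls:
        by_key.setdefault((c.interval.chrom, c.cnv_type), {}).setdefault(
            c.sample_id, []
        ).append((c.interval.start, c.interval.end))
    refs: list[TypedInterval] = []
    for (chrom, ctype), per_sample in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        events: list[tuple[int, int]] = []  # (pos, +1/-1) sweep
        for spans in per_sample.values():
            for s, e in _merge_sample_spans(spans):
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        depth = 0
        seg_start: int | None = None
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < min_carriers <= depth:
                seg_start = pos
            elif prev >= min_carriers > depth and seg_start is not None:
                if pos > seg_start:
                    refs.append(
                        TypedInterval(GenomicInterval(chrom, seg_start, pos), ctype)
                    )
                seg_start = None
    return refs


def filter_rare(
    calls: Sequence[CnvCall],
    common_map: Sequence[TypedInterval] = (),
    control_calls: Sequence[CnvCall] = (),
    cfg: RareFilterConfig | None = None,
) -> FilterResult:
    """Partition *calls* into rare and removed-as-common.

    A call is removed iff the union of matching references covers strictly
    more than ``cfg.overlap_threshold`` of its length.
    """
    cfg = cfg or RareFilterConfig()
    refs = list(common_map) + control_reference_intervals(
        control_calls, cfg.min_control_carriers
    )
    by_type: dict[CnvType | None, list[GenomicInterval]] = {}
    for r in refs:
        by_type.setdefault(r.cnv_type, []).append(r.interval)
    all_refs = [r.interval for r in refs]
    result = FilterResult([], [])
    for call in calls:
        pool = by_type.get(call.cnv_type, []) if cfg.type_matched else all_refs
        if cfg.anchor == "query":
            frac = overlap_fraction(call.interval, pool)
        else:
            frac = 0.0
            for ref in pool:
                ov = overlap_length(call.interval, ref)
                if ov == 0:
                    continue
                ref_frac = ov / ref.length
                if cfg.anchor == "reciprocal":
                    ref_frac = min(ref_frac, ov / call.interval.length)
                frac = max(frac, ref_frac)
        if frac > cfg.overlap_threshold:
            result.removed.append(call)
            result.removed_fractions.append(frac)
        else:
            result.rare.append(call)
    return result


def split_by_type(
    calls: Iterable[CnvCall],
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Split a call table into (duplications, deletions)."""
    dups = [c for c in calls if c.cnv_type is CnvType.DUP]
    dels = [c for c in calls if c.cnv_type is CnvType.DEL]
    return dups, dels
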