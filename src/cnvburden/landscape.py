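"""Descriptive statistics of a rare-CNV call set.

Covers the cohort-level summaries a rare-CNV study reports: per-individual
call counts, per-chromosome burden normalized by chromosome length with the
deletion/duplication (loss/gain) ratio, size-class histograms, aggregation
of per-sample calls into multi-sample CNV regions (CNVRs) with chromosome
coverage, matching against curated pathogenic regions, and the Spearman
test of chromosome length against call count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    CnvType,
    GenomicInterval,
    RegionType,
    coverage_fraction,
    merge_overlapping,
    overlap_fraction,
)
from .io import CnvCall

__all__ = [
    "CnvRegion",
    "PathogenicMatch",
    "per_sample_counts",
    "chromosome_enrichment",
    "size_bins",
    "DEFAULT_BIN_EDGES_BP",
    "build_cnvrs",
    "match_pathogenic",
    "length_count_correlation",
    "percent_str",
    "write_landscape_tables",
]

DEFAULT_BIN_EDGES_BP = (10_000, 50_000, 100_000, 250_000, 500_000)


@dataclass
class CnvRegion:
    """A CNVR: maximal union of >=1bp-overlapping calls across samples."""

    interval: GenomicInterval
    region_type: RegionType
    member_calls: list[CnvCall]

    @property
    def n_samples(self) -> int:
        return len({c.sample_id for c in self.member_calls})


@dataclass(frozen=True)
class PathogenicMatch:
    """A call/CNVR matching a curated pathogenic region at >= threshold."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    region_name: str
    fraction: float


def per_sample_counts(
    calls: Iterable[CnvCall], sample_ids: Iterable[str] | None = None
) -> dict[str, int]:
    """Rare-call count per sample; *sample_ids* adds explicit zero entries."""
    counts: dict[str, int] = {s: 0 for s in (sample_ids or [])}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    return counts


def chromosome_enrichment(
    calls: Sequence[CnvCall], chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome count, count per Mb and loss/gain (DEL/DUP) ratio.

    Chromosomes with zero duplications get ``NaN`` in ``loss_gain_ratio``
    (an undefined marker, not an exception).  Count per Mb divides by the
    chromosome length in megabases.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        here = [c for c in calls if c.interval.chrom == chrom]
        n_del = sum(1 for c in here if c.cnv_type is CnvType.DEL)
        n_dup = len(here) - n_del
        rows.append(
            {
                "chrom": chrom,
                "length_bp": length,
                "count": len(here),
                "count_per_mb": len(here) / (length / 1e6),
                "n_del": n_del,
                "n_dup": n_dup,
                "loss_gain_ratio": n_del / n_dup if n_dup else math.nan,
            }
        )
    unplaced = {c.interval.chrom for c in calls} - set(chrom_lengths)
    if unplaced:
        raise ValueError(f"calls on chromosomes without lengths: {sorted(unplaced)}")
    return pd.DataFrame(rows)


def size_bins(
    calls: Sequence[CnvCall],
    edges_bp: Sequence[int] = DEFAULT_BIN_EDGES_BP,
) -> pd.DataFrame:
    """Histogram of call lengths over ``len(edges_bp) + 1`` size classes.

    Bins are half-open on the left and closed on the right:
    ``(0, e1], (e1, e2], ..., (e_k, inf)``, so a call of exactly 10 kb falls
    in the first bin under the default edges.  Columns ``all``, ``gain``
    and ``loss`` satisfy gain + loss = all per bin.
    """
    edges = [0, *edges_bp, math.inf]
    labels = []
    for lo, hi in itertools.pairwise(edges):
        labels.append(f">{lo:g}bp" if hi == math.inf else f"({lo:g}, {hi:g}]bp")
    table = pd.DataFrame(
        0, index=pd.Index(labels, name="size_bin"), columns=["all", "gain", "loss"]
    )
    for c in calls:
        size = c.interval.length
        for (lo, hi), lab in zip(itertools.pairwise(edges), labels):
            if lo < size <= hi:
                table.loc[lab, "all"] += 1
                table.loc[lab, "gain" if c.cnv_type is CnvType.DUP else "loss"] += 1
                break
    return table


def build_cnvrs(
    calls: Sequence[CnvCall],
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[CnvRegion], dict[str, float]]:
    """Aggregate calls into CNVRs and report per-chromosome coverage.

    Calls chained by at least 1 bp of overlap merge into one region whose
    type is DEL or DUP when all members agree and BOTH otherwise.  Coverage
    fractions are computed only when *chrom_lengths* is given (chromosomes
    without any CNVR report 0.0).
    """
    merged = merge_overlapping([c.typed for c in calls], min_overlap_bp=1)
    regions = [
        CnvRegion(m.interval, m.region_type, [calls[i] for i in m.member_indices])
        for m in merged
    ]
    coverage: dict[str, float] = {}
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            ivs = [r.interval for r in regions if r.interval.chrom == chrom]
            coverage[chrom] = coverage_fraction(ivs, length) if ivs else 0.0
    return regions, coverage


def match_pathogenic(
    items: Sequence[CnvCall] | Sequence[CnvRegion],
    curated: Sequence[tuple[GenomicInterval, str]],
    threshold: float = 0.5,
    anchor: str = "item",
) -> list[PathogenicMatch]:
    """Match calls or CNVRs against curated pathogenic regions.

    A match requires the overlap fraction to be at least *threshold*
    (inclusive).  ``anchor`` selects the fraction's denominator: ``"item"``
    (default) anchors on the query call/CNVR, ``"region"`` on the curated
    region.
    """
    if anchor not in ("item", "region"):
        raise ValueError("anchor must be 'item' or 'region'")
    matches: list[PathogenicMatch] = []
    for item in items:
        iv = item.interval
        sample = getattr(item, "sample_id", "")
        ctype = getattr(item, "cnv_type", getattr(item, "region_type", ""))
        ctype = getattr(ctype, "value", str(ctype))
        for region, name in curated:
            if anchor == "item":
                frac = overlap_fraction(iv, [region])
            else:
                frac = overlap_fraction(region, [iv])
            if frac >= threshold:
                matches.append(PathogenicMatch(sample, iv, ctype, name, frac))
    return matches


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def length_count_correlation(
    per_chrom_counts: Mapping[str, int], chrom_lengths: Mapping[str, int]
) -> tuple[float, float]:
    """Spearman correlation of chromosome length against CNV count.

    Returns ``(rho, p)`` with mid-ranks for ties.  The two-sided p-value is
    exact by full permutation enumeration when n <= 9 and uses the
    t-distribution approximation otherwise.
    """
    chroms = list(chrom_lengths)
    x = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    y = np.array([per_chrom_counts.get(c, 0) for c in chroms], dtype=float)
    n = len(chroms)
    if n < 3:
        raise ValueError("need at least 3 chromosomes")
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return rho, math.nan
    if n <= 9:
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x, ry[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, p)


def percent_str(n: int, total: int, decimals: int = 1) -> str:
    """Share of *n* in *total* formatted as a percentage string."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{100.0 * n / total:.{decimals}f}%"


def write_landscape_tables(
    calls: Sequence[CnvCall],
    chrom_lengths: Mapping[str, int],
    out_dir: str | Path,
    curated: Sequence[tuple[GenomicInterval, str]] = (),
    bin_edges_bp: Sequence[int] = DEFAULT_BIN_EDGES_BP,
    pathogenic_threshold: float = 0.5,
) -> dict[str, Path]:
    """Emit the landscape summary TSVs into *out_dir*; returns the paths.

    Files: per_sample_counts.tsv, chromosome_summary.tsv, size_bins.tsv,
    cnvr.tsv, spearman.tsv and, when curated regions are given,
    pathogenic_matches.tsv with the columns Sample, Chr, Start, End,
    Region size, Region name, CNV type.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    counts = per_sample_counts(calls)
    df = pd.DataFrame(
        sorted(counts.items()), columns=["sample", "n_rare_cnvs"]
    )
    paths["per_sample_counts"] = out_dir / "per_sample_counts.tsv"
    df.to_csv(paths["per_sample_counts"], sep="\t", index=False)

    chrom_df = chromosome_enrichment(calls, chrom_lengths)
    paths["chromosome_summary"] = out_dir / "chromosome_summary.tsv"
    chrom_df.to_csv(paths["chromosome_summary"], sep="\t", index=False)

    bins = size_bins(calls, bin_edges_bp)
    paths["size_bins"] = out_dir / "size_bins.tsv"
    bins.to_csv(paths["size_bins"], sep="\t")

    regions, coverage = build_cnvrs(calls, chrom_lengths)
    cnvr_df = pd.DataFrame(
        [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "type": r.region_type.value,
                "n_calls": len(r.member_calls),
                "n_samples": r.n_samples,
            }
            for r in regions
        ]
    )
    paths["cnvr"] = out_dir / "cnvr.tsv"
    cnvr_df.to_csv(paths["cnvr"], sep="\t", index=False)
    cov_df = pd.DataFrame(
        sorted(coverage.items()), columns=["chrom", "cnvr_coverage_fraction"]
    )
    paths["cnvr_coverage"] = out_dir / "cnvr_coverage.tsv"
    cov_df.to_csv(paths["cnvr_coverage"], sep="\t", index=False)

    per_chrom = {
        row["chrom"]: int(row["count"]) for _, row in chrom_df.iterrows()
    }
    if len(chrom_lengths) >= 3:
        rho, p = length_count_correlation(per_chrom, chrom_lengths)
    else:  # correlation undefined on fewer than 3 chromosomes
        rho, p = math.nan, math.nan
    paths["spearman"] = out_dir / "spearman.tsv"
    with open(paths["spearman"], "w", encoding="utf-8") as fh:
        fh.write("statistic\tvalue\nrho\t%.6g\np\t%.6g\n" % (rho, p))

    if curated:
        matches = match_pathogenic(calls, curated, pathogenic_threshold)
        match_df = pd.DataFrame(
            [
                {
                    "Sample": m.sample_id,
                    "Chr": m.interval.chrom,
                    "Start": m.interval.start,
                    "End": m.interval.end,
                    "Region size": m.interval.length,
                    "Region name": m.region_name,
                    "CNV type": m.cnv_type,
                }
                for m in matches
            ],
            columns=[
                "Sample", "Chr", "Start", "End",
                "Region size", "Region name", "CNV type",
            ],
        )
        paths["pathogenic_matches"] = out_dir / "pathogenic_matches.tsv"
        match_df.to_csv(paths["pathogenic_matches"], sep="\t", index=False)
    return paths
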