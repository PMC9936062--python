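"""Gene-level case-control CNV burden testing.

The unit of burden is the carrier subject: a sample carries a gene when at
least one of its rare CNVs overlaps the gene interval by >= 1 bp, counted
once per gene no matter how many calls hit it.  Per gene, carrier counts in
cases and controls form a 2x2 table tested with a two-sided Fisher exact
test (point-probability rule); genes with p below the significance level
are candidate genes.  No multiple-testing correction is applied to the
candidate flag; a Benjamini-Hochberg column is emitted for information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .intervals import CnvType, GenomicInterval
from .io import CnvCall

__all__ = [
    "BurdenRecord",
    "annotate_genes",
    "fisher_exact_two_sided",
    "burden_table",
]

# relative tolerance on the "point probability <= observed" comparison, so
# tables that are equal up to float rounding are counted as ties
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class BurdenRecord:
    """Per-gene carrier counts and Fisher p-value."""

    gene: str
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    p_value: float
    n_del_carriers: int
    n_dup_carriers: int
    candidate: bool


def _annotate(
    calls: Sequence[CnvCall], genes: Mapping[str, GenomicInterval]
) -> tuple[dict[str, set[str]], dict[str, dict[str, set[CnvType]]]]:
    """One sweep over calls: gene -> carriers, and gene -> sample -> types."""
    trees: dict[str, IntervalTree] = {}
    for name, iv in genes.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, name)
    carriers: dict[str, set[str]] = {}
    types: dict[str, dict[str, set[CnvType]]] = {}
    for call in calls:
        tree = trees.get(call.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(call.interval.start, call.interval.end):
            gene = hit.data
            carriers.setdefault(gene, set()).add(call.sample_id)
            types.setdefault(gene, {}).setdefault(call.sample_id, set()).add(
                call.cnv_type
            )
    return carriers, types


def annotate_genes(
    calls: Sequence[CnvCall], genes: Mapping[str, GenomicInterval]
) -> dict[str, set[str]]:
    """Map each gene to the set of samples with >= 1 overlapping rare call.

    Overlap is half-open: a call merely touching a gene boundary does not
    make a carrier.  Genes hit by no call are absent from the result.
    """
    return _annotate(calls, genes)[0]


def _log_hypergeom_pmf(k: np.ndarray, row1: int, row2: int, col1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom: k successes of col1 draws in row1."""

    def logc(n: int | np.ndarray, r: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logc(row1, k) + logc(row2, col1 - k) - logc(row1 + row2, np.full_like(k, col1, dtype=float))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed one
    (within a small relative tolerance); computed in log space.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    row1, row2 = a + b, c + d
    col1 = a + c
    if row1 + row2 == 0 or (row1 == 0 or row2 == 0) or (col1 == 0 or b + d == 0):
        # a zero margin leaves a degenerate, single-table space
        if row1 + row2 == 0:
            raise ValueError("all-zero table")
        return 1.0
    k = np.arange(max(0, col1 - row2), min(col1, row1) + 1, dtype=float)
    logp = _log_hypergeom_pmf(k, row1, row2, col1)
    log_obs = _log_hypergeom_pmf(np.array([float(a)]), row1, row2, col1)[0]
    include = logp <= log_obs + np.log1p(_TIE_RTOL)
    total = np.exp(logp[include]).sum()
    return float(min(1.0, total))


def burden_table(
    calls: Sequence[CnvCall],
    genes: Mapping[str, GenomicInterval],
    labels: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher burden test for every gene with at least one carrier.

    *labels* maps each sample to CASE or CONTROL; every sample in *calls*
    must be labelled.  Rows are sorted by ascending p, ties broken by gene
    name; ``candidate`` is ``p < alpha`` (strict).  A ``p_bh`` column holds
    Benjamini-Hochberg adjusted values for information only.
    """
    unlabelled = {c.sample_id for c in calls} - set(labels)
    if unlabelled:
        raise ValueError(f"samples without labels: {sorted(unlabelled)[:5]}")
    n_cases = sum(1 for v in labels.values() if v == "CASE")
    n_controls = sum(1 for v in labels.values() if v == "CONTROL")
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both cohorts must be non-empty")
    carriers, type_by_sample_gene = _annotate(calls, genes)
    records = []
    for gene, samples in carriers.items():
        case_c = sum(1 for s in samples if labels[s] == "CASE")
        ctrl_c = len(samples) - case_c
        p = fisher_exact_two_sided(
            case_c, n_cases - case_c, ctrl_c, n_controls - ctrl_c
        )
        types = type_by_sample_gene.get(gene, {})
        n_del = sum(1 for s in samples if CnvType.DEL in types.get(s, ()))
        n_dup = sum(1 for s in samples if CnvType.DUP in types.get(s, ()))
        records.append(
            BurdenRecord(
                gene, case_c, ctrl_c, n_cases, n_controls, p,
                n_del, n_dup, p < alpha,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.gene))
    columns = [
        "gene", "case_carriers", "control_carriers", "n_cases", "n_controls",
        "p_value", "n_del_carriers", "n_dup_carriers", "candidate",
    ]
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "case_carriers": r.case_carriers,
                "control_carriers": r.control_carriers,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "p_value": r.p_value,
                "n_del_carriers": r.n_del_carriers,
                "n_dup_carriers": r.n_dup_carriers,
                "candidate": r.candidate,
            }
            for r in records
        ],
        columns=columns,
    )
    if len(df):
        df["p_bh"] = false_discovery_control(df["p_value"], method="bh")
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df


def candidate_genes(burden: pd.DataFrame) -> list[str]:
    """Genes flagged as candidates in a burden table."""
    return list(burden.loc[burden["candidate"], "gene"])
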