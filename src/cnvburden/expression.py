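"""CPM quantification and the "high and dynamic" developmental screen.

Bulk time-course expression (e.g. embryonic heart from 4 to 19 weeks
post-conception) is normalized to counts per million (CPM) and screened for
genes that are both highly expressed (peak CPM at or above a floor) and
dynamic (max/min fold change, with a pseudocount of 1 on CPM, at or above a
threshold).  Both components are reported so users can re-threshold.
Per-cluster single-cell summaries (mean CPM, fraction of expressing cells)
support spatial-expression readouts; clustering itself is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "cpm_normalize",
    "screen_dynamic",
    "cluster_summary",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the high-and-dynamic screen.

    high_threshold
        CPM floor on the per-gene maximum (default 10).
    dynamic_fold
        Minimum ``(max + 1) / (min + 1)`` fold change on CPM (default 2).
    """

    high_threshold: float = 10.0
    dynamic_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.high_threshold <= 0 or self.dynamic_fold <= 0:
            raise ValueError("thresholds must be positive")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each condition (column) to counts per million.

    Every column must have a positive total; the output's columns each sum
    to 1e6.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-sum condition column(s): {list(zero.index)[:5]}")
    return counts / totals * 1e6


def screen_dynamic(
    cpm: pd.DataFrame, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Flag genes with high and dynamic expression across the time course.

    Returns one row per gene with ``max_cpm``, ``min_cpm``, ``fold``
    (pseudocount 1) and the boolean ``dynamic`` flag:
    ``max_cpm >= high_threshold AND fold >= dynamic_fold``.
    """
    cfg = cfg or ScreenConfig()
    mx = cpm.max(axis=1)
    mn = cpm.min(axis=1)
    fold = (mx + 1.0) / (mn + 1.0)
    return pd.DataFrame(
        {
            "max_cpm": mx,
            "min_cpm": mn,
            "fold": fold,
            "dynamic": (mx >= cfg.high_threshold) & (fold >= cfg.dynamic_fold),
        }
    )


def cluster_summary(
    cells: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cluster mean CPM and expressing-cell fraction for every gene.

    *cells* is genes x cells; *labels* maps each cell (column) to a cluster
    name.  Every column must be labelled and every cluster non-empty.
    Returns a frame indexed by gene with a two-level column index
    (cluster, {mean_cpm, frac_expressing}).
    """
    missing = [c for c in cells.columns if c not in labels]
    if missing:
        raise ValueError(f"cells without cluster labels: {missing[:5]}")
    clusters = sorted(set(labels[c] for c in cells.columns))
    pieces: dict[tuple[str, str], pd.Series] = {}
    for cl in clusters:
        members = [c for c in cells.columns if labels[c] == cl]
        if not members:
            raise ValueError(f"cluster {cl!r} has no cells")
        sub = cells[members]
        pieces[(cl, "mean_cpm")] = sub.mean(axis=1)
        pieces[(cl, "frac_expressing")] = (sub > 0).mean(axis=1)
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cluster", "stat"])
    return out
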