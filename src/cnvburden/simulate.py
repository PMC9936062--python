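"""Synthetic case-control exome cohorts with known ground truth.

The generator emulates the statistical structure a read-depth CNV pipeline
assumes, so every downstream stage can be exercised without real data:

* a 150-case / 100-control cohort (configurable) of per-target mean read
  depths, drawn negative-binomially around a base depth and modulated by
  low-rank multiplicative confounders (batch/capture structure for the PCA
  step to remove);
* implanted deletions (x0.5 depth) and duplications (x1.5 depth) spanning
  consecutive exon targets, recorded in a :class:`TruthSet`;
* a common-CNV reference map built by jittering a chosen subset of the
  implants (plus non-overlapping decoy records), so the rare/common label
  of every implant is known;
* genes tiled over the targets, a subset of which carry a planted
  case-enriched carrier burden and are shielded from background implants so
  their case/control carrier counts are exactly the configured values;
* curated "pathogenic" regions placed over planted events;
* an Erdos-Renyi protein-interaction graph with planted cliques through
  designated hub nodes;
* bulk developmental time-course expression with planted dynamic genes.

All randomness flows from a single ``rng_seed``; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CnvType, GenomicInterval, TypedInterval, overlap_fraction
from .io import CnvCall, DepthMatrix

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_ppi",
    "simulate_expression",
    "simulate_single_cell",
    "recovery_stats",
]


class ConfigError(ValueError):
    """Raised for impossible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Depth noise: the negative-binomial dispersion (size) of 150 gives a
    ~11.5% coefficient of variation at the default base depth of 100 —
    typical of exome target coverage — and is calibrated so that, after
    PCA normalization (which slightly inflates residual variance and
    absorbs part of any single-sample deviation), a half-dosage deletion
    (x0.5) or a 1.5x duplication shifts the standardized depth by about
    3 units: the regime the caller's default emission shift expects.
    """

    n_cases: int = 150
    n_controls: int = 100
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    n_targets_per_chrom: int = 250
    target_length_bp: int = 150
    base_depth: float = 100.0
    nb_dispersion: float = 150.0
    n_confounders: int = 3
    confounder_sd: float = 0.15
    cnv_rate: float = 1.0
    cnv_length_min_bp: int = 80_000
    cnv_length_max_bp: int = 480_000
    del_multiplier: float = 0.5
    dup_multiplier: float = 1.5
    common_map_overlap_fraction: float = 0.3
    common_map_jitter: float = 0.1
    n_decoy_common: int = 20
    n_genes: int = 200
    gene_span_targets: int = 2
    n_burden_genes: int = 3
    burden_case_carriers: int = 8
    burden_control_carriers: int = 0
    burden_span_targets: int = 6
    n_pathogenic_regions: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "n_cases", "n_chromosomes", "chrom_length_bp",
            "n_targets_per_chrom", "target_length_bp", "base_depth",
            "nb_dispersion", "n_genes", "gene_span_targets",
            "burden_span_targets",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        if not self.del_multiplier < 1.0 < self.dup_multiplier:
            raise ConfigError("need del_multiplier < 1 < dup_multiplier")
        if self.cnv_rate < 0:
            raise ConfigError("cnv_rate must be >= 0")
        if not 0 <= self.common_map_overlap_fraction <= 1:
            raise ConfigError("common_map_overlap_fraction must be in [0, 1]")
        if not 0 <= self.common_map_jitter < 0.25:
            # jitter beyond a quarter-length could push overlap below 50%
            raise ConfigError("common_map_jitter must be in [0, 0.25)")
        if self.cnv_length_min_bp > self.cnv_length_max_bp:
            raise ConfigError("cnv_length_min_bp > cnv_length_max_bp")
        if self.cnv_length_max_bp > self.chrom_length_bp:
            raise ConfigError("implanted CNV longer than chromosome")
        spacing = self.chrom_length_bp // self.n_targets_per_chrom
        if self.target_length_bp > spacing:
            raise ConfigError("targets longer than their spacing")
        if self.burden_span_targets > self.n_targets_per_chrom:
            raise ConfigError("burden implant longer than chromosome")
        if self.burden_case_carriers > self.n_cases:
            raise ConfigError("more burden carriers than cases")
        if self.burden_control_carriers > self.n_controls:
            raise ConfigError("more burden carriers than controls")

    @property
    def target_spacing_bp(self) -> int:
        return self.chrom_length_bp // self.n_targets_per_chrom


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort.

    ``implanted`` are the true events as call records (quality 99);
    ``is_common[i]`` says whether implant ``i`` is covered >50% (same-type,
    query-anchored) by the emitted common map; ``burden_truth`` maps each
    planted burden gene to its (case, control) carrier counts.
    """

    implanted: list[CnvCall] = field(default_factory=list)
    is_common: list[bool] = field(default_factory=list)
    burden_truth: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def rare_implants(self) -> list[CnvCall]:
        return [c for c, com in zip(self.implanted, self.is_common) if not com]


@dataclass
class SimulatedCohort:
    """Everything one simulated study emits, plus its truth."""

    config: SimulationConfig
    depth: DepthMatrix
    labels: dict[str, str]
    chrom_lengths: dict[str, int]
    genes: dict[str, GenomicInterval]
    common_map: list[TypedInterval]
    pathogenic: list[tuple[GenomicInterval, str]]
    truth: TruthSet


def _make_targets(cfg: SimulationConfig) -> list[GenomicInterval]:
    targets = []
    spacing = cfg.target_spacing_bp
    offset = (spacing - cfg.target_length_bp) // 2
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(cfg.n_targets_per_chrom):
            s = i * spacing + offset
            targets.append(GenomicInterval(chrom, s, s + cfg.target_length_bp))
    return targets


def _span_interval(
    targets: Sequence[GenomicInterval], lo: int, hi: int
) -> GenomicInterval:
    """Interval from the first to the last target of a global index span."""
    return GenomicInterval(targets[lo].chrom, targets[lo].start, targets[hi].end)


def simulate_cohort(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate one synthetic case-control cohort (see module docstring)."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n_samples = cfg.n_cases + cfg.n_controls
    n_targets = cfg.n_chromosomes * cfg.n_targets_per_chrom
    per_chrom = cfg.n_targets_per_chrom
    targets = _make_targets(cfg)
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"C{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    labels = {
        sid: ("CASE" if i < cfg.n_cases else "CONTROL")
        for i, sid in enumerate(sample_ids)
    }
    chrom_lengths = {
        f"chr{c + 1}": cfg.chrom_length_bp for c in range(cfg.n_chromosomes)
    }

    # --- genes tiled over targets; burden genes first, far apart ---------
    genes: dict[str, GenomicInterval] = {}
    gene_starts = np.linspace(
        0, n_targets - cfg.gene_span_targets, cfg.n_genes
    ).astype(int)
    # keep every gene inside one chromosome
    gene_starts = np.minimum(
        gene_starts,
        (gene_starts // per_chrom) * per_chrom + per_chrom - cfg.gene_span_targets,
    )
    for g, s in enumerate(gene_starts):
        genes[f"G{g + 1:04d}"] = _span_interval(
            targets, int(s), int(s) + cfg.gene_span_targets - 1
        )
    if cfg.n_burden_genes > cfg.n_genes:
        raise ConfigError("n_burden_genes exceeds n_genes")
    burden_idx = np.linspace(
        0, cfg.n_genes - 1, cfg.n_burden_genes
    ).astype(int) if cfg.n_burden_genes else np.array([], dtype=int)
    burden_names = [f"G{i + 1:04d}" for i in burden_idx]

    # target windows reserved for burden genes (background implants avoid
    # them, so planted carrier counts stay exact)
    reserved: set[int] = set()
    burden_spans: dict[str, tuple[int, int]] = {}
    for name, gi in zip(burden_names, burden_idx):
        g_start = int(gene_starts[gi])
        chrom_base = (g_start // per_chrom) * per_chrom
        pad = (cfg.burden_span_targets - cfg.gene_span_targets + 1) // 2
        lo = max(chrom_base, g_start - pad)
        hi = min(chrom_base + per_chrom - 1, lo + cfg.burden_span_targets - 1)
        lo = max(chrom_base, hi - cfg.burden_span_targets + 1)
        burden_spans[name] = (lo, hi)
        reserved.update(range(lo, hi + 1))

    truth = TruthSet()
    multiplier = np.ones((n_samples, n_targets))

    def implant(sample_idx: int, lo: int, hi: int, ctype: CnvType) -> CnvCall:
        mult = (
            cfg.del_multiplier if ctype is CnvType.DEL else cfg.dup_multiplier
        )
        multiplier[sample_idx, lo : hi + 1] = mult
        return CnvCall(
            sample_ids[sample_idx],
            _span_interval(targets, lo, hi),
            ctype,
            quality=99.0,
            n_targets=hi - lo + 1,
        )

    # --- planted burden carriers ----------------------------------------
    for g_i, name in enumerate(burden_names):
        lo, hi = burden_spans[name]
        ctype = CnvType.DEL if g_i % 2 == 0 else CnvType.DUP
        case_pick = rng.choice(
            cfg.n_cases, size=cfg.burden_case_carriers, replace=False
        )
        ctrl_pick = rng.choice(
            cfg.n_controls, size=cfg.burden_control_carriers, replace=False
        )
        for s in case_pick:
            truth.implanted.append(implant(int(s), lo, hi, ctype))
        for s in ctrl_pick:
            truth.implanted.append(implant(cfg.n_cases + int(s), lo, hi, ctype))
        truth.burden_truth[name] = (
            cfg.burden_case_carriers, cfg.burden_control_carriers
        )
    n_burden_implants = len(truth.implanted)

    # --- background implants --------------------------------------------
    spacing = cfg.target_spacing_bp
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_samples)}
    common_flags: list[bool] = [False] * n_burden_implants
    for s_idx in range(n_samples):
        for _ in range(rng.poisson(cfg.cnv_rate)):
            length = math.exp(
                rng.uniform(
                    math.log(cfg.cnv_length_min_bp),
                    math.log(cfg.cnv_length_max_bp),
                )
            )
            span = max(1, int(round(length / spacing)))
            span = min(span, per_chrom)
            for _try in range(40):
                chrom_i = rng.integers(cfg.n_chromosomes)
                lo = int(
                    chrom_i * per_chrom + rng.integers(per_chrom - span + 1)
                )
                hi = lo + span - 1
                if any(lo <= i <= hi for i in reserved):
                    continue
                if any(not (hi < a or lo > b) for a, b in occupied[s_idx]):
                    continue
                occupied[s_idx].append((lo, hi))
                ctype = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
                truth.implanted.append(implant(s_idx, lo, hi, ctype))
                common_flags.append(
                    bool(rng.random() < cfg.common_map_overlap_fraction)
                )
                break

    # --- common-CNV map: jittered copies of flagged implants + decoys ----
    common_map: list[TypedInterval] = []
    for call, flagged in zip(truth.implanted, common_flags):
        if not flagged:
            continue
        iv = call.interval
        j = int(cfg.common_map_jitter * iv.length)
        start = max(0, iv.start + int(rng.integers(-j, j + 1)) if j else iv.start)
        end = min(
            cfg.chrom_length_bp,
            iv.end + int(rng.integers(-j, j + 1)) if j else iv.end,
        )
        if end <= start:
            start, end = iv.start, iv.end
        common_map.append(
            TypedInterval(GenomicInterval(iv.chrom, start, end), call.cnv_type)
        )
    implanted_ivs = [c.interval for c in truth.implanted]
    decoys = 0
    for _try in range(cfg.n_decoy_common * 20):
        if decoys >= cfg.n_decoy_common:
            break
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        length = int(rng.integers(20_000, 200_000))
        start = int(rng.integers(cfg.chrom_length_bp - length))
        iv = GenomicInterval(chrom, start, start + length)
        if any(
            iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end
            for o in implanted_ivs
        ):
            continue
        common_map.append(
            TypedInterval(iv, CnvType.DEL if rng.random() < 0.5 else CnvType.DUP)
        )
        decoys += 1

    # truth label: covered >50% by same-type map records (the rare filter's
    # default semantics)
    by_type = {
        CnvType.DEL: [t.interval for t in common_map if t.cnv_type is CnvType.DEL],
        CnvType.DUP: [t.interval for t in common_map if t.cnv_type is CnvType.DUP],
    }
    truth.is_common = [
        overlap_fraction(c.interval, by_type[c.cnv_type]) > 0.5
        for c in truth.implanted
    ]

    # --- pathogenic regions over the first planted events ----------------
    pathogenic: list[tuple[GenomicInterval, str]] = []
    for r in range(cfg.n_pathogenic_regions):
        if r < len(truth.implanted):
            iv = truth.implanted[r].interval
            pathogenic.append((iv, f"PATHO_{r + 1}"))

    # --- depth matrix -----------------------------------------------------
    u = rng.normal(0.0, cfg.confounder_sd, size=(n_samples, cfg.n_confounders))
    v = rng.normal(0.0, 1.0, size=(cfg.n_confounders, n_targets))
    mean = cfg.base_depth * np.exp(u @ v) * multiplier
    size = cfg.nb_dispersion
    p = size / (size + mean)
    values = rng.negative_binomial(size, p).astype(float)
    depth = DepthMatrix(sample_ids, targets, values)

    return SimulatedCohort(
        cfg, depth, labels, chrom_lengths, genes, common_map, pathogenic, truth
    )


def recovery_stats(
    truth: TruthSet,
    calls: Sequence[CnvCall],
    targets: Sequence[GenomicInterval],
    n_samples: int,
    min_target_overlap: float = 0.5,
) -> tuple[float, float]:
    """Sensitivity and false-call rate of a call set against the truth.

    An implant counts as recovered when a same-sample, same-type call
    covers at least ``min_target_overlap`` of the implant's targets; a call
    is false when it shares no such coverage (on its own targets) with any
    same-sample implant of either type.  Returns
    ``(recall, false_calls_per_sample)``.
    """
    def covered_targets(region: GenomicInterval) -> list[GenomicInterval]:
        return [
            t for t in targets
            if t.chrom == region.chrom
            and t.start < region.end and t.end > region.start
        ]

    def target_frac(call_iv: GenomicInterval, base: list[GenomicInterval]) -> float:
        hit = sum(
            1 for t in base
            if t.chrom == call_iv.chrom
            and t.start < call_iv.end and t.end > call_iv.start
        )
        return hit / len(base) if base else 0.0

    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    recovered = 0
    for imp in truth.implanted:
        base = covered_targets(imp.interval)
        if any(
            c.cnv_type is imp.cnv_type
            and target_frac(c.interval, base) >= min_target_overlap
            for c in by_sample.get(imp.sample_id, [])
        ):
            recovered += 1
    truth_by_sample: dict[str, list[CnvCall]] = {}
    for imp in truth.implanted:
        truth_by_sample.setdefault(imp.sample_id, []).append(imp)
    false_calls = 0
    for c in calls:
        base = covered_targets(c.interval)
        if not any(
            target_frac(i.interval, base) >= min_target_overlap
            for i in truth_by_sample.get(c.sample_id, [])
        ):
            false_calls += 1
    recall = recovered / len(truth.implanted) if truth.implanted else 1.0
    return recall, false_calls / n_samples


def simulate_ppi(
    n_nodes: int,
    node_names: Sequence[str] | None = None,
    hub_nodes: Sequence[str] | int = 3,
    clique_size: int = 5,
    edge_prob: float = 0.02,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Erdos-Renyi background plus planted cliques through hub nodes.

    Returns ``(edges, hub_names)``.  ``hub_nodes`` may be explicit names or
    a count (taken from the start of the node list).  ``n_nodes=1`` (or 0)
    yields an empty edge list.
    """
    rng = np.random.default_rng(seed)
    names = (
        list(node_names)
        if node_names is not None
        else [f"N{i + 1:04d}" for i in range(n_nodes)]
    )
    if len(names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    if isinstance(hub_nodes, int):
        hubs = names[: min(hub_nodes, n_nodes)]
    else:
        hubs = [h for h in hub_nodes if h in set(names)]
    edges: set[frozenset[str]] = set()
    if n_nodes >= 2:
        mask = rng.random((n_nodes, n_nodes)) < edge_prob
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if mask[i, j]:
                    edges.add(frozenset((names[i], names[j])))
        non_hubs = [nm for nm in names if nm not in hubs]
        for h in hubs:
            k = min(clique_size - 1, len(non_hubs))
            if k < 1:
                continue
            partners = list(rng.choice(len(non_hubs), size=k, replace=False))
            members = [h] + [non_hubs[int(i)] for i in partners]
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    edges.add(frozenset((members[a_i], members[b_i])))
    ordered = sorted(tuple(sorted(e)) for e in edges)
    return [tuple(e) for e in ordered], hubs


def simulate_expression(
    n_genes: int = 500,
    timepoints: Sequence[int] = tuple(range(4, 20)),
    n_dynamic: int = 50,
    fold_range: tuple[float, float] = (6.0, 16.0),
    gene_names: Sequence[str] | None = None,
    dynamic_genes: Sequence[str] | None = None,
    nb_dispersion: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Bulk developmental time-course counts with planted dynamic genes.

    Dynamic genes follow a smooth Gaussian-bump trajectory whose peak/trough
    mean ratio is drawn log-uniformly from ``fold_range`` (the default lower
    bound of 6 leaves ample margin over the screen's fold-2 threshold under
    counting noise); flat genes have a constant mean.  Counts are
    negative-binomial.  Returns the counts matrix (genes x timepoints, CPM
    screening is the caller's job) and the list of dynamic gene names.
    """
    rng = np.random.default_rng(seed)
    names = (
        list(gene_names)
        if gene_names is not None
        else [f"G{i + 1:04d}" for i in range(n_genes)]
    )
    if len(names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    if dynamic_genes is not None:
        dyn = [g for g in dynamic_genes if g in set(names)]
    else:
        dyn = names[:n_dynamic]
    t = np.asarray(timepoints, dtype=float)
    mean = np.empty((n_genes, t.size))
    dyn_set = set(dyn)
    for i, name in enumerate(names):
        if name in dyn_set:
            base = math.exp(rng.uniform(math.log(20.0), math.log(200.0)))
            fold = math.exp(
                rng.uniform(math.log(fold_range[0]), math.log(fold_range[1]))
            )
            peak = rng.uniform(t.min(), t.max())
            width = rng.uniform(2.0, 5.0)
            mean[i] = base * (
                1.0 + (fold - 1.0) * np.exp(-((t - peak) ** 2) / (2 * width**2))
            )
        else:
            mean[i] = math.exp(rng.uniform(math.log(1.0), math.log(1000.0)))
    p = nb_dispersion / (nb_dispersion + mean)
    counts = rng.negative_binomial(nb_dispersion, p).astype(float)
    df = pd.DataFrame(
        counts, index=pd.Index(names, name="gene"),
        columns=[f"wpc{int(w)}" for w in timepoints],
    )
    return df, dyn


def simulate_single_cell(
    gene_names: Sequence[str],
    cluster_sizes: Mapping[str, int],
    marker_genes: Mapping[str, Sequence[str]] | None = None,
    base_cpm: float = 20.0,
    marker_boost: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Toy single-cell CPM matrix with cluster labels.

    Marker genes of a cluster get ``marker_boost`` times the base mean in
    that cluster's cells.  Returns (genes x cells CPM frame, cell -> cluster
    labels).
    """
    rng = np.random.default_rng(seed)
    marker_genes = marker_genes or {}
    cells: list[str] = []
    labels: dict[str, str] = {}
    cols: list[np.ndarray] = []
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for cl, n in cluster_sizes.items():
        boost = np.ones(len(gene_names))
        for g in marker_genes.get(cl, []):
            if g in gene_index:
                boost[gene_index[g]] = marker_boost
        for k in range(n):
            cell = f"{cl}_cell{k + 1}"
            cells.append(cell)
            labels[cell] = cl
            lam = base_cpm * boost
            cols.append(rng.poisson(lam).astype(float))
    raw = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(gene_names), 0)),
        index=pd.Index(list(gene_names), name="gene"),
        columns=cells,
    )
    return raw, labels
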