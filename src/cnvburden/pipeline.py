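"""Single-process orchestration of the full analysis chain.

Stage order: simulate -> call -> rarefilter -> landscape -> burden ->
hubs -> exprscreen.  A pipeline run either starts from a synthetic cohort
(the default; the seed fixes every stochastic stage) or from user-provided
input files.  Case calls are filtered against the common-CNV map plus the
control cohort's calls; control calls against the map alone.  Every emitted
file is recorded in a manifest with its SHA-256 hash, so reruns under the
same configuration can be checked for byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as cio
from .burden import burden_table, candidate_genes
from .caller import HmmParams, NormalizationParams, call_cohort
from .expression import ScreenConfig, cpm_normalize, screen_dynamic
from .landscape import DEFAULT_BIN_EDGES_BP, write_landscape_tables
from .network import build_graph, rank_hubs
from .rare import RareFilterConfig, filter_rare
from .simulate import SimulationConfig, simulate_cohort, simulate_expression, simulate_ppi

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cnvburden")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``inputs`` may map the keys depth/labels/genes/common/pathogenic/
    lengths (and optionally ppi, expr) to existing files; when absent, the
    simulate stage generates them from ``simulation`` with ``seed``.
    """

    out_dir: str = "cnvburden_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    hmm: HmmParams = field(default_factory=HmmParams)
    min_quality: float = 60.0
    rare_filter: RareFilterConfig = field(default_factory=RareFilterConfig)
    bin_edges_bp: tuple[int, ...] = DEFAULT_BIN_EDGES_BP
    pathogenic_threshold: float = 0.5
    alpha: float = 0.05
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    top_hubs: int = 8
    inputs: dict[str, str] = field(default_factory=dict)

    _SECTIONS = {
        "simulation": SimulationConfig,
        "normalization": NormalizationParams,
        "hmm": HmmParams,
        "rare_filter": RareFilterConfig,
        "screen": ScreenConfig,
    }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key in cls._SECTIONS:
                section_cls = cls._SECTIONS[key]
                fields = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - fields
                if bad:
                    raise PipelineError(
                        f"config: unknown key(s) {sorted(bad)} in section {key!r}"
                    )
                kwargs[key] = section_cls(**value)
            elif key == "bin_edges_bp":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["bin_edges_bp"] = list(self.bin_edges_bp)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(cfg: PipelineConfig) -> None:
    if cfg.inputs:
        required = ["depth", "labels", "genes", "common", "pathogenic", "lengths"]
        missing_keys = [k for k in required if k not in cfg.inputs]
        if missing_keys:
            raise PipelineError(
                f"config: inputs section lacks {missing_keys}; either provide "
                "all required inputs or none (to simulate)"
            )
        for key, path in cfg.inputs.items():
            if not Path(path).exists():
                raise PipelineError(f"config: input file missing: {key} = {path}")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all stages; returns the manifest (also written to manifest.json).

    The manifest maps every emitted file (relative to ``out_dir``) to its
    SHA-256 hash and records per-stage timings.  Any stage failure raises
    :class:`PipelineError` naming the stage; configuration problems are
    detected before any stage runs.
    """
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emitted: dict[str, str] = {}
    timings: dict[str, float] = {}

    def track(path: Path) -> None:
        emitted[str(path.relative_to(out))] = _sha256(path)

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name}: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    simulated = not cfg.inputs
    with stage("simulate"):
        if simulated:
            sim_cfg = dataclasses.replace(cfg.simulation, rng_seed=cfg.seed)
            cohort = simulate_cohort(sim_cfg)
            cio.write_depth_matrix(cohort.depth, out / "depth.tsv")
            cio.write_labels(cohort.labels, out / "labels.tsv")
            cio.write_bed(
                [(iv, name) for name, iv in cohort.genes.items()],
                out / "genes.bed",
            )
            cio.write_bed(
                [(t.interval, t.cnv_type.value) for t in cohort.common_map],
                out / "common_cnvs.bed",
            )
            cio.write_bed(cohort.pathogenic, out / "pathogenic.bed")
            cio.write_chrom_lengths(cohort.chrom_lengths, out / "lengths.tsv")
            cio.write_cnv_calls(cohort.truth.implanted, out / "truth_calls.tsv")
            gene_names = list(cohort.genes)
            burden_genes = list(cohort.truth.burden_truth)
            ppi_edges, _ = simulate_ppi(
                n_nodes=len(gene_names),
                node_names=gene_names,
                hub_nodes=burden_genes,
                seed=cfg.seed + 1,
            )
            cio.write_edge_list(ppi_edges, out / "ppi.edges")
            expr, _ = simulate_expression(
                n_genes=len(gene_names),
                gene_names=gene_names,
                dynamic_genes=burden_genes,
                seed=cfg.seed + 2,
            )
            cio.write_expression_tsv(expr, out / "expr.tsv")
            for f in (
                "depth.tsv", "labels.tsv", "genes.bed", "common_cnvs.bed",
                "pathogenic.bed", "lengths.tsv", "truth_calls.tsv",
                "ppi.edges", "expr.tsv",
            ):
                track(out / f)
            paths = {k: out / v for k, v in {
                "depth": "depth.tsv", "labels": "labels.tsv",
                "genes": "genes.bed", "common": "common_cnvs.bed",
                "pathogenic": "pathogenic.bed", "lengths": "lengths.tsv",
                "ppi": "ppi.edges", "expr": "expr.tsv",
            }.items()}
        else:
            paths = {k: Path(v) for k, v in cfg.inputs.items()}

    with stage("call"):
        depth = cio.read_depth_matrix(paths["depth"])
        labels = cio.read_labels(paths["labels"])
        calls = call_cohort(depth, cfg.normalization, cfg.hmm, cfg.min_quality)
        case_calls = [c for c in calls if labels.get(c.sample_id) == "CASE"]
        control_calls = [c for c in calls if labels.get(c.sample_id) == "CONTROL"]
        cio.write_cnv_calls(case_calls, out / "calls_cases.tsv")
        cio.write_cnv_calls(control_calls, out / "calls_controls.tsv")
        track(out / "calls_cases.tsv")
        track(out / "calls_controls.tsv")

    with stage("rarefilter"):
        common_map = cio.read_typed_bed(paths["common"])
        case_rare = filter_rare(
            case_calls, common_map, control_calls, cfg.rare_filter
        ).rare
        control_rare = filter_rare(
            control_calls, common_map, (), cfg.rare_filter
        ).rare
        cio.write_cnv_calls(case_rare, out / "rare_cases.tsv")
        cio.write_cnv_calls(control_rare, out / "rare_controls.tsv")
        track(out / "rare_cases.tsv")
        track(out / "rare_controls.tsv")

    with stage("landscape"):
        lengths = cio.read_chrom_lengths(paths["lengths"])
        curated = cio.read_region_bed(paths["pathogenic"])
        for p in write_landscape_tables(
            case_rare, lengths, out / "landscape", curated,
            cfg.bin_edges_bp, cfg.pathogenic_threshold,
        ).values():
            track(p)

    with stage("burden"):
        genes = cio.read_gene_bed(paths["genes"])
        bt = burden_table(case_rare + control_rare, genes, labels, cfg.alpha)
        bt.to_csv(out / "burden.tsv", sep="\t", index=False)
        track(out / "burden.tsv")
        candidates = candidate_genes(bt)

    with stage("hubs"):
        if "ppi" in paths:
            g = build_graph(cio.read_edge_list(paths["ppi"]))
            ranking = rank_hubs(g, candidates or None, cfg.top_hubs)
            with open(out / "hubs.tsv", "w", encoding="utf-8") as fh:
                fh.write("node\tmcc\tdegree\tin_graph\n")
                for e in ranking:
                    fh.write(f"{e.node}\t{e.mcc}\t{e.degree}\t{e.in_graph}\n")
            track(out / "hubs.tsv")

    with stage("exprscreen"):
        if "expr" in paths:
            counts = cio.read_expression_tsv(paths["expr"])
            cpm = cpm_normalize(counts)
            screen = screen_dynamic(cpm, cfg.screen)
            screen.to_csv(out / "screen.tsv", sep="\t", index_label="gene")
            track(out / "screen.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "files": emitted,
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
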