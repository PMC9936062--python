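import numpy as np
import pytest

from cnvburden.expression import ScreenConfig, cpm_normalize, screen_dynamic
from cnvburden.intervals import CnvType
from cnvburden.network import build_graph, mcc_scores
from cnvburden.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_expression,
    simulate_ppi,
)

SMALL = dict(
    n_cases=15, n_controls=10, n_chromosomes=2, chrom_length_bp=2_000_000,
    n_targets_per_chrom=80, n_genes=40, n_burden_genes=1,
    cnv_length_min_bp=100_000, cnv_length_max_bp=300_000,
)


def test_same_seed_identical_outputs():
    a = simulate_cohort(SimulationConfig(rng_seed=5, **SMALL))
    b = simulate_cohort(SimulationConfig(rng_seed=5, **SMALL))
    np.testing.assert_array_equal(a.depth.values, b.depth.values)
    assert a.truth.implanted == b.truth.implanted
    assert a.common_map == b.common_map
    assert a.genes == b.genes
    c = simulate_cohort(SimulationConfig(rng_seed=6, **SMALL))
    assert not np.array_equal(a.depth.values, c.depth.values)


def test_zero_cnv_rate_no_implants():
    cfg = SimulationConfig(
        rng_seed=1, cnv_rate=0.0, **{**SMALL, "n_burden_genes": 0}
    )
    cohort = simulate_cohort(cfg)
    assert cohort.truth.implanted == []
    # no dosage effect anywhere: grand mean close to base depth
    assert cohort.depth.values.mean() == pytest.approx(cfg.base_depth, rel=0.1)


def test_implanted_deletion_halves_depth():
    cfg = SimulationConfig(rng_seed=3, **SMALL)
    cohort = simulate_cohort(cfg)
    dels = [c for c in cohort.truth.implanted if c.cnv_type is CnvType.DEL]
    assert dels, "expected at least one implanted deletion"
    srows = {s: i for i, s in enumerate(cohort.depth.sample_ids)}
    ratios = []
    for call in dels:
        idx = [
            k for k, t in enumerate(cohort.depth.targets)
            if t.chrom == call.interval.chrom
            and t.start < call.interval.end and t.end > call.interval.start
        ]
        carrier = cohort.depth.values[srows[call.sample_id], idx].mean()
        others = np.delete(cohort.depth.values[:, idx], srows[call.sample_id], axis=0).mean()
        ratios.append(carrier / others)
    # mean dosage ratio ~= 0.5 within 3 standard errors
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios)) if len(ratios) > 1 else 0.05
    assert abs(np.mean(ratios) - 0.5) < max(3 * se, 0.05)


def test_truth_common_labels_respect_map_construction(small_cohort):
    # implants flagged common are covered >50% by same-type map records
    from cnvburden.intervals import overlap_fraction

    by_type = {
        t: [r.interval for r in small_cohort.common_map if r.cnv_type is t]
        for t in CnvType
    }
    for call, is_common in zip(
        small_cohort.truth.implanted, small_cohort.truth.is_common
    ):
        frac = overlap_fraction(call.interval, by_type[call.cnv_type])
        assert (frac > 0.5) == is_common


def test_burden_truth_counts_are_exact(small_cohort):
    from cnvburden.burden import annotate_genes

    carriers = annotate_genes(small_cohort.truth.implanted, small_cohort.genes)
    for gene, (n_case, n_ctrl) in small_cohort.truth.burden_truth.items():
        got = carriers.get(gene, set())
        cases = sum(1 for s in got if small_cohort.labels[s] == "CASE")
        assert (cases, len(got) - cases) == (n_case, n_ctrl)


def test_config_validation():
    with pytest.raises(ConfigError, match="longer than chromosome"):
        SimulationConfig(cnv_length_max_bp=20_000_000)
    with pytest.raises(ConfigError, match="del_multiplier"):
        SimulationConfig(del_multiplier=1.2)
    with pytest.raises(ConfigError, match="carriers"):
        SimulationConfig(n_cases=5, burden_case_carriers=10)


def test_ppi_planted_hub_scores_high():
    edges, hubs = simulate_ppi(30, hub_nodes=2, clique_size=4, seed=9)
    scores = mcc_scores(build_graph(edges))
    for h in hubs:
        assert scores[h] >= 6  # a planted K4 alone contributes 3! = 6


def test_ppi_degenerate_and_deterministic():
    edges, _ = simulate_ppi(1, seed=0)
    assert edges == []
    a, _ = simulate_ppi(25, seed=4)
    b, _ = simulate_ppi(25, seed=4)
    assert a == b


def test_expression_flat_when_no_dynamic():
    counts, dyn = simulate_expression(n_genes=30, n_dynamic=0, seed=2)
    assert dyn == []
    cpm = cpm_normalize(counts)
    # flat genes: observed fold stays far below a planted-dynamic fold
    folds = (cpm.max(axis=1) + 1) / (cpm.min(axis=1) + 1)
    assert folds.median() < 3


def test_expression_planted_dynamic_recovered():
    counts, dyn = simulate_expression(n_genes=120, n_dynamic=15, seed=8)
    screen = screen_dynamic(cpm_normalize(counts), ScreenConfig())
    assert set(dyn) <= set(screen.index[screen["dynamic"]])
    a, _ = simulate_expression(n_genes=40, seed=3)
    b, _ = simulate_expression(n_genes=40, seed=3)
    assert a.equals(b)
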