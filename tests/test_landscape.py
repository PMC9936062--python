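import math

import numpy as np
import pytest

from cnvburden.intervals import CnvType, GenomicInterval, RegionType
from cnvburden.io import CnvCall
from cnvburden.landscape import (
    build_cnvrs,
    chromosome_enrichment,
    length_count_correlation,
    match_pathogenic,
    per_sample_counts,
    percent_str,
    size_bins,
    write_landscape_tables,
)
from oracles import spearman_permutation_p


def _call(sample, chrom, start, end, ctype="DEL"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), CnvType(ctype), 99.0, 1)


def test_per_sample_counts():
    calls = [_call("a", "chr1", i * 10, i * 10 + 5) for i in range(3)]
    calls += [_call("b", "chr1", i * 10, i * 10 + 5) for i in range(5)]
    counts = per_sample_counts(calls, sample_ids=["a", "b", "c"])
    assert counts == {"a": 3, "b": 5, "c": 0}
    assert sum(counts.values()) == len(calls)


def test_chromosome_enrichment_ratios():
    calls = [_call("s", "chr1", i * 100, i * 100 + 50, "DEL") for i in range(4)]
    calls += [_call("s", "chr1", 5_000 + i * 100, 5_000 + i * 100 + 50, "DUP") for i in range(2)]
    df = chromosome_enrichment(calls, {"chr1": 50_000_000, "chr2": 10_000_000})
    row = df.set_index("chrom").loc["chr1"]
    assert row["count"] == 6
    # 10 calls on 50 Mb would be 0.2/Mb; here 6 -> 0.12
    assert row["count_per_mb"] == pytest.approx(6 / 50.0)
    assert row["loss_gain_ratio"] == pytest.approx(2.0)
    assert math.isnan(df.set_index("chrom").loc["chr2", "loss_gain_ratio"])


def test_size_bins_boundaries_and_totals():
    calls = [
        _call("s", "chr1", 0, 97),  # the smallest observable events
        _call("s", "chr1", 0, 10_000),  # right-closed first bin
        _call("s", "chr1", 0, 10_001),  # just over the first edge
        _call("s", "chr1", 0, 21_000_000, "DUP"),  # multi-Mb event
    ]
    table = size_bins(calls)
    assert table["all"].iloc[0] == 2
    assert table["all"].iloc[1] == 1
    assert table["all"].iloc[5] == 1
    assert table["all"].sum() == len(calls)
    assert (table["gain"] + table["loss"]).equals(table["all"])


def test_build_cnvrs_types_and_sample_counts():
    same = [_call("a", "chr1", 0, 100), _call("b", "chr1", 0, 100)]
    regions, _ = build_cnvrs(same)
    assert len(regions) == 1
    assert regions[0].region_type is RegionType.DEL
    assert regions[0].n_samples == 2

    mixed = [_call("a", "chr1", 0, 100, "DEL"), _call("b", "chr1", 50, 150, "DUP")]
    regions, _ = build_cnvrs(mixed)
    assert regions[0].region_type is RegionType.BOTH

    disjoint = [_call("a", "chr1", 0, 100), _call("b", "chr1", 200, 300)]
    regions, coverage = build_cnvrs(disjoint, {"chr1": 1_000})
    assert len(regions) == 2
    assert coverage["chr1"] == pytest.approx(0.2)


def test_cnvr_coverage_never_decreases_when_call_added(small_cohort_calls):
    calls = list(small_cohort_calls)
    lengths = {"chr1": 2_000_000, "chr2": 2_000_000}
    _, cov_all = build_cnvrs(calls, lengths)
    _, cov_fewer = build_cnvrs(calls[:-1], lengths)
    for chrom in lengths:
        assert cov_all[chrom] >= cov_fewer[chrom] - 1e-12


def test_match_pathogenic_inclusive_boundary():
    items = [_call("s", "chr9", 1400, 2600)]
    curated = [(GenomicInterval("chr9", 1000, 2000), "region_A")]
    matches = match_pathogenic(items, curated, threshold=0.5)
    assert len(matches) == 1  # 600/1200 = exactly 0.5, inclusive
    assert matches[0].fraction == pytest.approx(0.5)

    inside = [_call("s", "chr9", 1200, 1300)]
    assert match_pathogenic(inside, curated)[0].fraction == 1.0

    elsewhere = [_call("s", "chr8", 1400, 2600)]
    assert match_pathogenic(elsewhere, curated) == []


def test_match_pathogenic_region_anchoring():
    items = [_call("s", "chr9", 0, 10_000)]
    curated = [(GenomicInterval("chr9", 1000, 2000), "region_A")]
    assert match_pathogenic(items, curated, anchor="item") == []  # 10% of item
    assert len(match_pathogenic(items, curated, anchor="region")) == 1


def test_spearman_perfect_correlations():
    lengths = {f"c{i}": (i + 1) * 1000 for i in range(5)}
    up = {f"c{i}": i + 1 for i in range(5)}
    rho, _ = length_count_correlation(up, lengths)
    assert rho == pytest.approx(1.0)
    down = {f"c{i}": 5 - i for i in range(5)}
    rho, _ = length_count_correlation(down, lengths)
    assert rho == pytest.approx(-1.0)


def test_spearman_matches_permutation_oracle():
    rng = np.random.default_rng(5)
    lengths = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1000, 9999, 6))}
    counts = {f"c{i}": int(v) for i, v in enumerate(rng.integers(0, 30, 6))}
    rho, p = length_count_correlation(counts, lengths)
    o_rho, o_p = spearman_permutation_p(
        [lengths[c] for c in lengths], [counts[c] for c in lengths]
    )
    assert rho == pytest.approx(o_rho, abs=1e-12)
    assert p == pytest.approx(o_p, abs=1e-12)


def test_large_n_uses_t_approximation():
    rng = np.random.default_rng(2)
    lengths = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1_000, 9_999, 24))}
    counts = {f"c{i}": int(v) for i, v in enumerate(rng.integers(0, 500, 24))}
    rho, p = length_count_correlation(counts, lengths)
    from scipy.stats import spearmanr

    ref = spearmanr(
        [lengths[c] for c in lengths], [counts[c] for c in lengths]
    )
    assert rho == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_percent_formatting():
    assert percent_str(1, 3) == "33.3%"
    assert percent_str(1, 3, 2) == "33.33%"
    with pytest.raises(ValueError):
        percent_str(1, 0)


def test_landscape_tables_written(tmp_path, small_cohort, small_cohort_calls):
    paths = write_landscape_tables(
        small_cohort_calls,
        small_cohort.chrom_lengths,
        tmp_path,
        curated=small_cohort.pathogenic,
    )
    for p in paths.values():
        assert p.exists() and p.stat().st_size > 0
    assert "pathogenic_matches" in paths
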