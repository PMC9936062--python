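import numpy as np
import pytest
from scipy.stats import fisher_exact

from cnvburden.burden import (
    annotate_genes,
    burden_table,
    fisher_exact_two_sided,
)
from cnvburden.intervals import CnvType, GenomicInterval
from cnvburden.io import CnvCall
from oracles import fisher_two_sided_exact


def _call(sample, chrom, start, end, ctype="DEL"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), CnvType(ctype), 99.0, 1)


GENES = {
    "GA": GenomicInterval("chr1", 1_000, 2_000),
    "GB": GenomicInterval("chr1", 1_800, 3_000),
    "GC": GenomicInterval("chr2", 0, 500),
}


def test_one_call_spanning_two_genes():
    carriers = annotate_genes([_call("s1", "chr1", 900, 2_500)], GENES)
    assert carriers == {"GA": {"s1"}, "GB": {"s1"}}


def test_sample_counted_once_per_gene():
    calls = [_call("s1", "chr1", 900, 1_100), _call("s1", "chr1", 1_500, 1_700)]
    carriers = annotate_genes(calls, GENES)
    assert carriers["GA"] == {"s1"}


def test_touching_call_is_not_a_carrier():
    carriers = annotate_genes([_call("s1", "chr1", 500, 1_000)], GENES)
    assert "GA" not in carriers


# ------------------------------------------------------------------- Fisher


def test_fisher_degenerate_and_table_examples():
    assert fisher_exact_two_sided(0, 150, 0, 100) == 1.0
    p = fisher_exact_two_sided(8, 142, 0, 100)
    assert p == pytest.approx(float(fisher_two_sided_exact(8, 142, 0, 100)), abs=1e-12)

    p_sym = fisher_exact_two_sided(2, 8, 8, 2)
    assert p_sym == pytest.approx(float(fisher_two_sided_exact(2, 8, 8, 2)), abs=1e-12)
    # invariant under transposing the table
    assert p_sym == pytest.approx(fisher_exact_two_sided(2, 8, 8, 2), abs=1e-15)
    assert fisher_exact_two_sided(8, 2, 2, 8) == pytest.approx(p_sym, abs=1e-12)

    with pytest.raises(ValueError):
        fisher_exact_two_sided(0, 0, 0, 0)


@pytest.mark.parametrize("seed", range(10))
def test_fisher_matches_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    ours = fisher_exact_two_sided(a, b, c, d)
    ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_row_column_swap_symmetry():
    for (a, b, c, d) in [(3, 7, 1, 9), (5, 0, 2, 4), (6, 144, 0, 100)]:
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-12)


def test_adding_control_carrier_never_decreases_p():
    # a case-skewed gene: moving one subject from control-non-carrier to
    # control-carrier should weaken the association
    last = 0.0
    for ctrl_carriers in range(0, 5):
        p = fisher_exact_two_sided(8, 142, ctrl_carriers, 100 - ctrl_carriers)
        assert p >= last - 1e-12
        last = p


# ------------------------------------------------------------------- table


def _labels(n_cases=150, n_controls=100):
    lab = {f"S{i:04d}": "CASE" for i in range(n_cases)}
    lab.update({f"C{i:04d}": "CONTROL" for i in range(n_controls)})
    return lab


def test_burden_table_flag_decided_by_exact_p():
    # six case carriers, no control carriers: the oracle p decides the flag
    calls = [_call(f"S{i:04d}", "chr2", 10, 400) for i in range(6)]
    table = burden_table(calls, GENES, _labels())
    row = table.set_index("gene").loc["GC"]
    oracle_p = float(fisher_two_sided_exact(6, 144, 0, 100))
    assert row["p_value"] == pytest.approx(oracle_p, abs=1e-12)
    assert bool(row["candidate"]) == (oracle_p < 0.05)


def test_burden_table_equal_rates_not_candidate():
    calls = [_call(f"S{i:04d}", "chr2", 10, 400) for i in range(15)]
    calls += [_call(f"C{i:04d}", "chr2", 10, 400) for i in range(10)]
    table = burden_table(calls, GENES, _labels())
    row = table.set_index("gene").loc["GC"]
    assert row["p_value"] == pytest.approx(1.0)
    assert not row["candidate"]


def test_genes_without_carriers_absent_and_sorted():
    calls = [_call(f"S{i:04d}", "chr1", 1_100, 1_200) for i in range(10)]
    calls += [_call("S0099", "chr2", 10, 400)]
    table = burden_table(calls, GENES, _labels())
    assert set(table["gene"]) == {"GA", "GC"}
    assert list(table["p_value"]) == sorted(table["p_value"])
    assert "p_bh" in table.columns


def test_unlabelled_sample_rejected():
    with pytest.raises(ValueError, match="without labels"):
        burden_table([_call("mystery", "chr2", 10, 400)], GENES, _labels())


def test_del_dup_carrier_direction_counts():
    calls = [
        _call("S0001", "chr2", 10, 400, "DEL"),
        _call("S0002", "chr2", 10, 400, "DUP"),
        _call("S0003", "chr2", 10, 400, "DUP"),
    ]
    row = burden_table(calls, GENES, _labels()).set_index("gene").loc["GC"]
    assert (row["n_del_carriers"], row["n_dup_carriers"]) == (1, 2)


def test_planted_burden_genes_become_candidates(small_cohort):
    table = burden_table(
        small_cohort.truth.implanted, small_cohort.genes, small_cohort.labels
    )
    flagged = set(table.loc[table["candidate"], "gene"])
    assert set(small_cohort.truth.burden_truth) <= flagged
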