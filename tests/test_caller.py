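import numpy as np
import pytest

from cnvburden.caller import (
    DEL,
    DIP,
    DUP,
    HmmParams,
    NormalizationParams,
    _viterbi_states,
    call_cohort,
    call_quality,
    normalize_depth,
    posterior_matrix,
    viterbi_segment,
)
from cnvburden.intervals import CnvType, GenomicInterval
from cnvburden.io import DepthMatrix
from oracles import exhaustive_best_path


def _targets(n, spacing=40_000, chrom="chr1", length=150):
    return [
        GenomicInterval(chrom, i * spacing + 100, i * spacing + 100 + length)
        for i in range(n)
    ]


# ------------------------------------------------------------ normalization


def test_identical_rows_center_to_zero_without_component_removal():
    dm = DepthMatrix(
        ["a", "b", "c"], _targets(4), np.tile([10.0, 20.0, 30.0, 40.0], (3, 1))
    )
    with pytest.warns(UserWarning, match="zero-variance"):
        zm = normalize_depth(dm)
    assert zm.n_components_removed == 0
    assert zm.n_targets == 0  # every centered column is exactly zero
    assert len(zm.dropped_targets) == 4


def test_rank_one_batch_effect_removed():
    rng = np.random.default_rng(0)
    a = rng.uniform(0.5, 2.0, size=50)  # per-sample batch factor
    b = rng.uniform(50, 150, size=80)  # per-target baseline
    noise = rng.normal(0, 1.0, size=(50, 80))
    dm = DepthMatrix(
        [f"s{i}" for i in range(50)], _targets(80), np.outer(a, b) + noise + 200
    )
    centered = dm.values - dm.values.mean(axis=0)
    pre_var = centered.var(axis=0).mean()
    zm = normalize_depth(dm)
    assert zm.n_components_removed >= 1
    # re-apply the dropped scaling to compare residual variance fairly:
    # after standardization variance is 1 by construction, so instead check
    # that the dominant component explained almost everything
    assert pre_var > 50  # batch structure dominates before removal
    assert zm.values.var(axis=0).mean() == pytest.approx(1.0, rel=1e-6)


def test_implanted_deletion_visible_in_z(small_cohort):
    zm = normalize_depth(small_cohort.depth)
    srows = {s: i for i, s in enumerate(zm.sample_ids)}
    shifts = []
    for call in small_cohort.truth.implanted:
        if call.cnv_type is not CnvType.DEL:
            continue
        idx = [
            k for k, t in enumerate(zm.targets)
            if t.chrom == call.interval.chrom
            and t.start < call.interval.end and t.end > call.interval.start
        ]
        shifts.append(zm.values[srows[call.sample_id], idx].mean())
    assert np.mean(shifts) < -2


def test_normalize_requires_two_samples():
    dm = DepthMatrix(["only"], _targets(3), np.ones((1, 3)))
    with pytest.raises(ValueError, match="2 samples"):
        normalize_depth(dm)


# ----------------------------------------------------------------- decoding


def test_all_zero_z_yields_no_calls():
    assert viterbi_segment(np.zeros(15), _targets(15)) == []


def test_six_target_shift_called_exactly_once():
    z = np.zeros(15)
    z[4:10] = -3.0
    calls = viterbi_segment(z, _targets(15), sample_id="s")
    assert len(calls) == 1
    call = calls[0]
    assert call.cnv_type is CnvType.DEL and call.n_targets == 6
    assert call.interval.start == _targets(15)[4].start
    assert call.interval.end == _targets(15)[9].end

    dup = viterbi_segment(np.where(z < 0, 3.0, 0.0), _targets(15))
    assert dup[0].cnv_type is CnvType.DUP


def test_single_isolated_shift_not_called():
    z = np.zeros(15)
    z[7] = 3.0
    assert viterbi_segment(z, _targets(15)) == []


def test_unsorted_targets_rejected():
    t = _targets(5)
    t[1], t[2] = t[2], t[1]
    with pytest.raises(ValueError, match="sorted"):
        viterbi_segment(np.zeros(5), t)


@pytest.mark.parametrize("seed", range(20))
def test_viterbi_equals_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    z = rng.normal(0, 2.5, size=n)
    hp = HmmParams()
    targets = _targets(n, spacing=int(rng.integers(10_000, 90_000)))
    mine = _viterbi_states(z, np.abs(np.diff(
        np.array([(t.start + t.end) / 2 for t in targets]))), hp)
    best, score, runner = exhaustive_best_path(z, targets, hp)
    assert score - runner > 1e-9  # unique argmax on continuous z
    np.testing.assert_array_equal(mine, best)


def test_monotonicity_stronger_shift_keeps_call():
    targets = _targets(15)
    for mag in (3.0, 3.5, 4.0, 5.0, 8.0):
        z = np.zeros(15)
        z[4:10] = -mag
        calls = viterbi_segment(z, targets)
        assert len(calls) == 1 and calls[0].n_targets == 6


# ------------------------------------------------- posteriors and qualities


def test_posteriors_sum_to_one():
    rng = np.random.default_rng(1)
    z = rng.normal(0, 2, size=30)
    targets = _targets(20) + _targets(10, chrom="chr2")
    post = posterior_matrix(z, targets)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_quality_strong_call_high_zero_call_low():
    targets = _targets(15)
    z = np.zeros(15)
    z[4:10] = -5.0
    call = viterbi_segment(z, targets, sample_id="s")[0]
    assert call_quality(z, targets, call) >= 60

    weak = call_quality(np.zeros(15), targets, call)
    assert weak < 1  # no evidence of a CNV in flat data


def test_quality_unchanged_by_other_chromosome_targets():
    targets = _targets(12)
    z = np.zeros(12)
    z[3:9] = -4.0
    call = viterbi_segment(z, targets, sample_id="s")[0]
    q1 = call_quality(z, targets, call)
    extended = targets + _targets(6, chrom="chr9")
    z2 = np.concatenate([z, np.zeros(6)])
    q2 = call_quality(z2, extended, call)
    assert q1 == pytest.approx(q2, abs=1e-9)


# ------------------------------------------------------------------- cohort


def test_call_cohort_empty_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        call_cohort(DepthMatrix([], [], np.empty((0, 0))))


def test_call_cohort_quality_threshold_filters(small_cohort):
    lax = call_cohort(small_cohort.depth, min_quality=0.0)
    strict = call_cohort(small_cohort.depth, min_quality=40.0)
    assert len(strict) <= len(lax)
    assert all(c.quality >= 40 for c in strict)


def test_noise_only_cohort_has_few_false_calls():
    from cnvburden.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_cases=25, n_controls=0, n_chromosomes=2, chrom_length_bp=2_000_000,
        n_targets_per_chrom=100, cnv_rate=0.0, n_burden_genes=0, rng_seed=13,
    )
    cohort = simulate_cohort(cfg)
    calls = call_cohort(cohort.depth, min_quality=0.0)
    assert len(calls) / 25 <= 0.5
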