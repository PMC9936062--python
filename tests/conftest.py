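import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cnvburden.caller import call_cohort
from cnvburden.simulate import SimulationConfig, simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small, dense-target cohort with implanted CNVs and burden genes.

    20 kb target spacing keeps inter-target attenuation mild; 6-target
    events sit at the caller's design point (|z| ~ 3).
    """
    cfg = SimulationConfig(
        n_cases=30,
        n_controls=20,
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        n_targets_per_chrom=100,
        cnv_length_min_bp=120_000,
        cnv_length_max_bp=120_000,
        n_genes=60,
        n_burden_genes=2,
        burden_case_carriers=8,
        rng_seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    """Discovery-level calls (no quality filtering) on the small cohort."""
    return call_cohort(small_cohort.depth, min_quality=0.0)
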