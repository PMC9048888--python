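"""Shared fixtures: a small simulated pedigree dataset with detection run.

The test-scale configuration keeps the per-chromosome genetic length modest
(75-100 cM) so that crossovers are well separated relative to the 100 kb
switch-back threshold; the defaults of SimConfig describe the full study
scale and are not suitable for fast tests.
"""

import numpy as np
import pytest

from pedrec.pipeline import PipelineConfig, detect_events
from pedrec.simulate import SimConfig, simulate_pedigree

TEST_SIM = dict(
    n_chromosomes=2,
    chrom_length_bp=30_000_000,
    marker_density=3e-4,
    male_map_cM=150.0,
    female_map_cM=200.0,
    nco_rate_per_bp=7.52e-6,
    genotype_error_rate=0.0,
    offspring_counts=(6, 5),
)


@pytest.fixture(scope="session")
def small_sim():
    """(table, pedigree, truth) for a clean, zero-error dataset."""
    return simulate_pedigree(SimConfig(**TEST_SIM, seed=42))


@pytest.fixture(scope="session")
def small_report(small_sim):
    """Detection output on the clean dataset (default thresholds)."""
    table, pedigree, _ = small_sim
    return detect_events(table, pedigree, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
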