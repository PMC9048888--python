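"""Simulator tests: determinism, validation, ground-truth consistency."""

import numpy as np
import pytest

from pedrec.simulate import (AnomalySpec, ConfigError, SimConfig,
                             inject_assembly_error, sample_tract_length,
                             simulate_pedigree, simulate_tract_observations)
from pedrec.tractmodel import TractLengthModel
from tests.conftest import TEST_SIM


def small_config(**over):
    kw = dict(TEST_SIM, n_chromosomes=1, chrom_length_bp=5_000_000, seed=7)
    kw.update(over)
    return SimConfig(**kw)


def test_deterministic_under_seed():
    t1, p1, g1 = simulate_pedigree(small_config())
    t2, p2, g2 = simulate_pedigree(small_config())
    assert t1.sites.equals(t2.sites)
    assert np.array_equal(t1.gt, t2.gt)
    assert p1.table.equals(p2.table)
    assert len(g1.meioses) == len(g2.meioses)
    t3, _, _ = simulate_pedigree(small_config(seed=8))
    assert not t3.sites.equals(t1.sites)


def test_config_validation():
    with pytest.raises(ConfigError, match="n_chromosomes"):
        small_config(n_chromosomes=0)
    with pytest.raises(ConfigError, match="marker_density"):
        small_config(marker_density=2.0)
    with pytest.raises(ConfigError, match="offspring_counts"):
        small_config(offspring_counts=(6, 3))
    with pytest.raises(ConfigError, match="map_cM"):
        small_config(male_map_cM=-1.0)


def test_pedigree_structure(small_sim):
    _, pedigree, _ = small_sim
    subs = pedigree.sub_pedigrees()
    assert sorted(len(kids) for _, _, kids in subs) == sorted(
        TEST_SIM["offspring_counts"])
    for f, m, kids in subs:
        assert pedigree.sex_of(f) == 1 and pedigree.sex_of(m) == 2
        for k in kids:
            assert pedigree.parents_of(k) == (f, m)


def test_no_mendel_violations_without_errors(small_sim):
    table, pedigree, _ = small_sim
    for f, m, kids in pedigree.sub_pedigrees():
        fi, mi = table.sample_index(f), table.sample_index(m)
        for k in kids:
            ki = table.sample_index(k)
            # one allele from each parent (columns are ordered father, mother)
            pat, mat = table.gt[:, ki, 0], table.gt[:, ki, 1]
            assert np.all((pat == table.gt[:, fi, 0])
                          | (pat == table.gt[:, fi, 1]))
            assert np.all((mat == table.gt[:, mi, 0])
                          | (mat == table.gt[:, mi, 1]))


def test_ground_truth_consistency(small_sim):
    table, pedigree, truth = small_sim
    n_expected = (sum(TEST_SIM["offspring_counts"]) * 2
                  * TEST_SIM["n_chromosomes"])
    assert len(truth.meioses) == n_expected
    for m in truth.meioses:
        assert np.all(np.diff(m.co_positions) >= 0)
        for t in m.tracts:
            assert t.realized_length <= t.drawn_length
            assert all(t.start <= p <= t.end for p in t.converted_sites)
    # the filter helper narrows correctly
    one = truth.meioses_for(parent="sire1", offspring="off1_1", chrom="chr1")
    assert len(one) == 1


def test_co_count_near_expectation(small_sim):
    _, pedigree, truth = small_sim
    total = sum(len(m.co_positions) for m in truth.meioses)
    n_off = sum(TEST_SIM["offspring_counts"])
    lam = n_off * (TEST_SIM["male_map_cM"] + TEST_SIM["female_map_cM"]) / 100
    assert abs(total - lam) < 5 * np.sqrt(lam)


def test_genotype_errors_recorded():
    table, _, truth = simulate_pedigree(
        small_config(genotype_error_rate=1e-3))
    assert len(truth.error_sites) > 0
    n_cells = table.n_sites * len(table.samples)
    assert abs(len(truth.error_sites) - 1e-3 * n_cells) \
        < 5 * np.sqrt(1e-3 * n_cells)


def test_sample_tract_length_bounds(rng):
    model = TractLengthModel()
    for _ in range(100):
        assert 1 <= sample_tract_length(model, rng) <= model.truncation


def test_inject_assembly_error_roundtrip(small_sim):
    table, _, _ = small_sim
    from pedrec.simulate import GroundTruth
    truth = GroundTruth()
    spec = AnomalySpec("inversion", "chr1", start=5_000_000, end=9_000_000)
    new_table, truth = inject_assembly_error(table, truth, spec)
    assert len(truth.anomalies) == 1
    # positions inside the segment are reflected, everything else unchanged
    chr1 = table.sites["chrom"].to_numpy() == "chr1"
    old = table.sites["pos"].to_numpy()
    inside = chr1 & (old >= 5_000_000) & (old <= 9_000_000)
    want = old.copy()
    want[inside] = 5_000_000 + 9_000_000 - old[inside]
    assert np.array_equal(
        np.sort(new_table.sites.loc[new_table.sites["chrom"] == "chr1",
                                    "pos"].to_numpy()),
        np.sort(want[chr1]))
    assert np.array_equal(
        new_table.sites.loc[new_table.sites["chrom"] == "chr2",
                            "pos"].to_numpy(),
        old[~chr1])
    with pytest.raises(ValueError, match="overlapping"):
        inject_assembly_error(new_table, truth, AnomalySpec(
            "inversion", "chr1", start=8_000_000, end=10_000_000))
    with pytest.raises(ValueError, match="unknown anomaly"):
        inject_assembly_error(table, GroundTruth(),
                              AnomalySpec("blend", "chr1", 1, 2))


def test_simulate_tract_observations(rng):
    model = TractLengthModel(alpha=0.99, m1=30, m2=1500, truncation=4000)
    data = simulate_tract_observations(model, rng, marker_density=5e-3,
                                       min_tracts=50,
                                       chrom_length=2_000_000,
                                       rate_per_bp=5e-4)
    assert len(data.tracts) >= 50
    assert all(t.span <= model.truncation for t in data.tracts)
    assert data.t_max == model.truncation
    assert np.all(data.e_total >= 0) and data.e_total[-1] > 0
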