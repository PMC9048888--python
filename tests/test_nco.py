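"""Noncrossover tract calling, filtering and classification tests."""

import numpy as np
import pandas as pd
import pytest

from pedrec.core import GenotypeTable, Pedigree
from pedrec.crossovers import COEvent
from pedrec.markers import InformativeSites
from pedrec.nco import (NCOTract, call_nco_tracts, classify_events,
                        filter_nco, long_tract_report)
from pedrec.phasing import InheritanceVector


def vec(positions, states, offspring="o") -> InheritanceVector:
    return InheritanceVector("p", offspring, "chr1",
                             np.asarray(positions, dtype=np.int64),
                             np.asarray(states, dtype=np.int8))


def test_simple_tract_called():
    pos = [100_000, 120_000, 200_000, 203_000, 240_000, 260_000]
    v = vec(pos, [0, 0, 1, 1, 0, 0])
    tracts = call_nco_tracts(v)
    assert len(tracts) == 1
    t = tracts[0]
    assert t.converted == (200_000, 203_000)
    assert (t.left_flank, t.right_flank) == (120_000, 240_000)
    assert t.cls == "simple"
    assert t.min_length == 3001 and t.n_sites == 2


def test_flank_with_too_few_sites_rejected():
    # only one concordant site on the left flank
    pos = [120_000, 200_000, 203_000, 240_000, 260_000]
    v = vec(pos, [0, 1, 1, 0, 0])
    assert call_nco_tracts(v) == []


def test_flank_spanning_too_little_rejected():
    # two left-flank sites but spanning only 5 kb < 10 kb
    pos = [195_000, 199_000, 200_000, 203_000, 240_000, 260_000]
    v = vec(pos, [0, 0, 1, 1, 0, 0])
    assert call_nco_tracts(v) == []


def test_long_tract_class():
    pos = [100_000, 120_000, 200_000, 250_000, 300_000, 320_000]
    v = vec(pos, [0, 0, 1, 1, 0, 0])  # 50 kb span: "long" class
    tracts = call_nco_tracts(v)
    assert len(tracts) == 1 and tracts[0].cls == "long"


def test_beyond_long_threshold_not_a_tract():
    pos = [100_000, 120_000, 200_000, 350_000, 500_000, 520_000]
    v = vec(pos, [0, 0, 1, 1, 0, 0])  # 150 kb: crossover territory
    assert call_nco_tracts(v) == []


def test_gbgc_tally():
    pos = np.array([100_000, 120_000, 200_000, 203_000, 240_000, 260_000],
                   dtype=np.int64)
    states = [0, 0, 1, 1, 0, 0]
    # site 200000: A->G conversion (to strong); 203000: C->T (to weak)
    info = InformativeSites(
        chrom="chr1", focal_parent="p", co_parent="q", offspring=("o",),
        positions=pos,
        ref=np.array(["A", "A", "A", "C", "A", "A"]),
        alt=np.array(["G", "G", "G", "T", "G", "G"]),
        co_allele=np.zeros(6, dtype=np.int8),
        transmitted=np.array([[0], [0], [1], [1], [0], [0]], dtype=np.int8))
    tracts = call_nco_tracts(vec(pos, states), info)
    assert len(tracts) == 1
    assert tracts[0].gc_to_strong == 1 and tracts[0].gc_to_weak == 1


def test_tract_invariants():
    with pytest.raises(ValueError):
        NCOTract("p", "o", "chr1", (), 1, 10)
    with pytest.raises(ValueError):
        NCOTract("p", "o", "chr1", (5,), 5, 10)


def make_tract(offspring, converted, parent="p", chrom="chr1"):
    return NCOTract(parent, offspring, chrom, tuple(converted),
                    min(converted) - 15_000, max(converted) + 15_000)


def test_filter_removes_sibling_shared_sites():
    a = make_tract("o1", [200_000, 203_000])
    b = make_tract("o2", [203_000])
    c = make_tract("o3", [900_000])
    out = filter_nco([a, b, c])
    assert [t.offspring for t in out] == ["o3"]


def test_filter_strips_multiallelic_sites():
    a = make_tract("o1", [200_000, 203_000])
    out = filter_nco([a], multiallelic={("chr1", 203_000)})
    assert out[0].converted == (200_000,)
    # tract vanishes when all its sites are multiallelic
    b = make_tract("o2", [400_000])
    assert filter_nco([b], multiallelic={("chr1", 400_000)}) == []


def test_mendel_flagging():
    samples = ["p", "q", "o1", "r", "g1"]
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [200_000],
                          "ref": ["A"], "alt": ["G"]})
    gt = np.zeros((1, 5, 2), dtype=np.int8)
    gt[0, samples.index("o1")] = (1, 1)   # converted homozygote
    gt[0, samples.index("g1")] = (0, 0)   # grandchild carries neither allele
    table = GenotypeTable(samples, sites, gt,
                          np.full((1, 5), 99, dtype=np.int16),
                          {"chr1": 1_000_000})
    ped = Pedigree(pd.DataFrame(
        [("p", "0", "0", 1), ("q", "0", "0", 2), ("o1", "p", "q", 1),
         ("r", "0", "0", 2), ("g1", "o1", "r", 1)],
        columns=["iid", "father", "mother", "sex"]))
    out = filter_nco([make_tract("o1", [200_000])], ped, table)
    assert len(out) == 1 and out[0].mendel_flagged


def test_classify_complex_and_co_associated():
    t1 = make_tract("o1", [200_000])
    t2 = make_tract("o1", [260_000])      # within 100 kb of t1: complex
    t3 = make_tract("o1", [2_000_000])    # near a CO: co_associated
    t4 = make_tract("o2", [200_000])      # different meiosis: simple
    cos = [COEvent("p", "o1", "chr1", 2_040_000, 2_060_000)]
    out, groups = classify_events([t1, t2, t3, t4], cos)
    by_off = {(t.offspring, t.first): t for t in out}
    assert by_off[("o1", 200_000)].cls == "complex_member"
    assert by_off[("o1", 260_000)].cls == "complex_member"
    assert by_off[("o1", 2_000_000)].cls == "co_associated"
    assert by_off[("o1", 2_000_000)].co_associated
    assert by_off[("o2", 200_000)].cls == "simple"
    assert sorted(len(g) for g in groups) == [1, 1, 2]


def test_long_tract_report():
    long_t = NCOTract("p", "o1", "chr1", (200_000, 230_000),
                      180_000, 260_000, cls="long")
    short_t = make_tract("o1", [500_000])

    class A:
        chrom, start, end = "chr1", 190_000, 240_000

    df = long_tract_report([long_t, short_t], [A()])
    assert len(df) == 1
    assert df.iloc[0]["overlaps_anomaly"] == "Yes"
    df2 = long_tract_report([long_t], [])
    assert df2.iloc[0]["overlaps_anomaly"] == "No"
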