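"""Coordinate-map and assembly-error-detection tests."""

import numpy as np
import pytest

from pedrec.anomalies import (AnomalyError, SegmentMap, apply_corrections,
                              detect_inversions, detect_misplaced_contigs,
                              detect_single_breaks, expected_break_overlap,
                              link_translocations, remap_table)
from pedrec.crossovers import COEvent

LENGTHS = {"chr1": 1_000_000, "chr2": 800_000}


def roundtrip(smap, chrom, positions):
    for p in positions:
        c2, p2 = smap.to_assembly(chrom, int(p))
        c3, p3 = smap.to_true(c2, p2)
        assert (c3, p3) == (chrom, int(p))


def test_identity_map():
    smap = SegmentMap.identity(LENGTHS)
    assert smap.to_assembly("chr1", 12345) == ("chr1", 12345)
    roundtrip(smap, "chr2", [1, 800_000])


def test_inversion_map(rng):
    smap = SegmentMap.inversion(LENGTHS, "chr1", 100_000, 200_000)
    # interior order is reversed
    assert smap.to_assembly("chr1", 100_000) == ("chr1", 200_000)
    assert smap.to_assembly("chr1", 200_000) == ("chr1", 100_000)
    assert smap.to_assembly("chr1", 99_999) == ("chr1", 99_999)
    assert smap.to_assembly("chr1", 200_001) == ("chr1", 200_001)
    roundtrip(smap, "chr1", rng.integers(1, 1_000_001, 200))
    with pytest.raises(AnomalyError):
        SegmentMap.inversion(LENGTHS, "chr1", 0, 10)


def test_misplaced_contig_map_is_bijective(rng):
    for dest in (500_000, 50_000):  # move right and move left
        smap = SegmentMap.misplaced_contig(LENGTHS, "chr1",
                                           100_000, 200_000, dest)
        pos = rng.integers(1, 1_000_001, 300)
        roundtrip(smap, "chr1", pos)
        # assembly positions cover 1..L exactly once
        mapped = sorted(smap.to_assembly("chr1", int(p))[1]
                        for p in range(99_990, 100_011))
        assert len(set(mapped)) == len(mapped)
    with pytest.raises(AnomalyError):
        SegmentMap.misplaced_contig(LENGTHS, "chr1", 100, 200, 150)


def test_tail_swap_map():
    smap = SegmentMap.tail_swap(LENGTHS, "chr1", 600_000, "chr2", 300_000)
    assert smap.asm_lengths["chr1"] == 600_000 + 500_000
    assert smap.asm_lengths["chr2"] == 300_000 + 400_000
    assert smap.to_assembly("chr1", 600_001) == ("chr2", 300_001)
    assert smap.to_assembly("chr2", 300_001) == ("chr1", 600_001)
    roundtrip(smap, "chr1", [1, 600_000, 600_001, 1_000_000])
    roundtrip(smap, "chr2", [1, 300_000, 300_001, 800_000])


def test_split_map():
    smap = SegmentMap.split(LENGTHS, "chr1", 400_000)
    assert smap.to_assembly("chr1", 400_000) == ("chr1A", 400_000)
    assert smap.to_assembly("chr1", 400_001) == ("chr1B", 1)
    assert smap.asm_lengths == {"chr2": 800_000, "chr1A": 400_000,
                                "chr1B": 600_000}


def test_uncovered_position_raises():
    smap = SegmentMap([], {"chr1": 100})
    with pytest.raises(AnomalyError):
        smap.to_assembly("chr1", 5)


def test_remap_and_correct_restore_table(small_sim):
    table, _, _ = small_sim
    smap = SegmentMap.inversion(dict(table.chrom_lengths), "chr1",
                                5_000_000, 9_000_000)
    remapped = remap_table(table, smap)
    assert not remapped.sites["pos"].equals(table.sites["pos"])
    restored = apply_corrections(remapped, [smap])
    assert restored.sites["pos"].tolist() == table.sites["pos"].tolist()
    assert restored.sites["chrom"].tolist() == table.sites["chrom"].tolist()
    assert np.array_equal(restored.gt, table.gt)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def co(parent, off, left, right, chrom="chr1"):
    return COEvent(parent, off, chrom, left, right)


def test_detect_inversions_triple():
    cos = [co("p", "o1", 1_000_000, 1_010_000),
           co("p", "o1", 3_000_000, 3_010_000),
           co("p", "o1", 5_000_000, 5_010_000),
           co("p", "o2", 40_000_000, 40_010_000)]
    calls = detect_inversions(cos)
    assert len(calls) == 1
    assert calls[0].kind == "inversion"
    assert calls[0].start <= 1_010_000 and calls[0].end >= 5_000_000
    # overlapping candidates from two meioses merge
    cos += [co("p", "o3", 1_500_000, 1_510_000),
            co("p", "o3", 3_000_000, 3_010_000),
            co("p", "o3", 5_500_000, 5_510_000)]
    merged = detect_inversions(cos)
    assert len(merged) == 1 and merged[0].n_meioses == 2


def test_detect_inversions_needs_proximity():
    cos = [co("p", "o1", 1_000_000, 1_010_000),
           co("p", "o1", 30_000_000, 30_010_000),
           co("p", "o1", 60_000_000, 60_010_000)]
    assert detect_inversions(cos) == []


def test_detect_misplaced_contigs():
    pair = [(2_000_000, 2_010_000), (2_400_000, 2_410_000)]
    cos = []
    for off in ("o1", "o2"):
        for l, r in pair:
            cos.append(co("p", off, l, r))
    calls = detect_misplaced_contigs(cos)
    assert len(calls) == 1
    assert calls[0].kind == "misplaced_contig"
    assert calls[0].detail["intervals"] == (pair[0], pair[1])
    # one meiosis only: no call
    assert detect_misplaced_contigs(cos[:2]) == []


def test_link_translocations():
    a = detect_misplaced_contigs(
        [co("p", o, l, r) for o in ("o1", "o2")
         for l, r in ((1_000_000, 1_010_000), (1_200_000, 1_210_000))])
    b = detect_misplaced_contigs(
        [co("p", o, l, r, chrom="chr2") for o in ("o1", "o2")
         for l, r in ((5_000_000, 5_010_000), (5_300_000, 5_310_000))])
    linked = link_translocations(a + b)
    assert len(linked) == 1 and linked[0].kind == "translocation"


def test_detect_single_breaks():
    cos = [co(p, o, 7_000_000 + i * 10_000, 7_001_000 + i * 10_000)
           for i, (p, o) in enumerate([("p1", "a"), ("p2", "b"), ("p3", "c")])]
    calls = detect_single_breaks(cos)
    assert len(calls) == 1
    assert calls[0].kind == "single_break" and calls[0].n_meioses == 3
    assert detect_single_breaks(cos[:2]) == []


def test_expected_break_overlap():
    windows = [("chr1", 1, 100), ("chr1", 50, 200), ("chr2", 1, 100)]
    # merged: 200 + 100 bases of 10,000
    assert expected_break_overlap(50, windows, 10_000) == pytest.approx(1.5)
    with pytest.raises(AnomalyError):
        expected_break_overlap(1, windows, 0)
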