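"""Assembly-error signatures in linkage data, and coordinate corrections.

A break of synteny in the genome assembly shows up in pedigree data as
spurious crossover (CO) clusters: an inverted segment containing a real CO
yields three apparent COs in that meiosis; a misplaced contig yields a pair
of tightly linked COs at identical marker intervals in every meiosis with a
CO between the contig's true and placed locations; a single synteny break
collects COs from many meioses into one small region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .crossovers import COEvent


class AnomalyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate maps (true <-> assembly)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A syntenic block: true interval mapped into an assembly chromosome."""

    true_chrom: str
    true_start: int  # 1-based inclusive
    true_end: int
    asm_chrom: str
    asm_start: int
    strand: int = 1  # +1 forward, -1 inverted

    @property
    def length(self) -> int:
        return self.true_end - self.true_start + 1

    @property
    def asm_end(self) -> int:
        return self.asm_start + self.length - 1


class SegmentMap:
    """Bijection between true and assembly coordinates over covered bases."""

    def __init__(self, segments: Sequence[Segment],
                 true_lengths: dict[str, int],
                 asm_lengths: dict[str, int] | None = None):
        self.segments = list(segments)
        self.true_lengths = dict(true_lengths)
        if asm_lengths is None:
            asm_lengths = {}
            for s in self.segments:
                asm_lengths[s.asm_chrom] = max(
                    asm_lengths.get(s.asm_chrom, 0), s.asm_end)
        self.asm_lengths = dict(asm_lengths)

    def to_assembly(self, chrom: str, pos: int) -> tuple[str, int]:
        for s in self.segments:
            if s.true_chrom == chrom and s.true_start <= pos <= s.true_end:
                off = pos - s.true_start if s.strand == 1 else s.true_end - pos
                return s.asm_chrom, s.asm_start + off
        raise AnomalyError(f"position {chrom}:{pos} not covered by map")

    def to_true(self, chrom: str, pos: int) -> tuple[str, int]:
        for s in self.segments:
            if s.asm_chrom == chrom and s.asm_start <= pos <= s.asm_end:
                off = pos - s.asm_start
                if s.strand == 1:
                    return s.true_chrom, s.true_start + off
                return s.true_chrom, s.true_end - off
        raise AnomalyError(f"assembly position {chrom}:{pos} not covered")

    def invert(self) -> "SegmentMap":
        inv = []
        for s in self.segments:
            if s.strand == 1:
                inv.append(Segment(s.asm_chrom, s.asm_start, s.asm_end,
                                   s.true_chrom, s.true_start, 1))
            else:
                inv.append(Segment(s.asm_chrom, s.asm_start, s.asm_end,
                                   s.true_chrom, s.true_start, -1))
        return SegmentMap(inv, self.asm_lengths, self.true_lengths)

    # -- builders ---------------------------------------------------------

    @classmethod
    def identity(cls, lengths: dict[str, int]) -> "SegmentMap":
        segs = [Segment(c, 1, n, c, 1, 1) for c, n in lengths.items()]
        return cls(segs, lengths, dict(lengths))

    @classmethod
    def inversion(cls, lengths: dict[str, int], chrom: str,
                  start: int, end: int) -> "SegmentMap":
        L = lengths[chrom]
        if not 1 <= start <= end <= L:
            raise AnomalyError("inversion segment outside chromosome")
        segs = [Segment(c, 1, n, c, 1, 1)
                for c, n in lengths.items() if c != chrom]
        if start > 1:
            segs.append(Segment(chrom, 1, start - 1, chrom, 1, 1))
        segs.append(Segment(chrom, start, end, chrom, start, -1))
        if end < L:
            segs.append(Segment(chrom, end + 1, L, chrom, end + 1, 1))
        return cls(segs, lengths, dict(lengths))

    @classmethod
    def misplaced_contig(cls, lengths: dict[str, int], chrom: str,
                         start: int, end: int, dest: int) -> "SegmentMap":
        """Contig [start, end] removed and re-inserted after true pos dest."""
        L = lengths[chrom]
        if not 1 <= start <= end <= L:
            raise AnomalyError("contig outside chromosome")
        if start <= dest <= end:
            raise AnomalyError("destination inside the moved contig")
        pieces: list[tuple[int, int]] = []  # true intervals in assembly order
        if dest > end:
            if start > 1:
                pieces.append((1, start - 1))
            pieces.append((end + 1, dest))
            pieces.append((start, end))
            if dest < L:
                pieces.append((dest + 1, L))
        else:
            if dest >= 1:
                pieces.append((1, dest))
            pieces.append((start, end))
            if dest + 1 <= start - 1:
                pieces.append((dest + 1, start - 1))
            if end < L:
                pieces.append((end + 1, L))
        segs = [Segment(c, 1, n, c, 1, 1)
                for c, n in lengths.items() if c != chrom]
        off = 1
        for a, b in pieces:
            if a > b:
                continue
            segs.append(Segment(chrom, a, b, chrom, off, 1))
            off += b - a + 1
        return cls(segs, lengths, dict(lengths))

    @classmethod
    def tail_swap(cls, lengths: dict[str, int], chrom1: str, break1: int,
                  chrom2: str, break2: int) -> "SegmentMap":
        """Join chrom1[1..b1] to chrom2[b2+1..] and vice versa.

        Creates a single break of synteny on each assembly chromosome.
        """
        L1, L2 = lengths[chrom1], lengths[chrom2]
        if not (1 <= break1 < L1 and 1 <= break2 < L2):
            raise AnomalyError("breakpoints outside chromosomes")
        segs = [Segment(c, 1, n, c, 1, 1)
                for c, n in lengths.items() if c not in (chrom1, chrom2)]
        segs.append(Segment(chrom1, 1, break1, chrom1, 1, 1))
        segs.append(Segment(chrom2, break2 + 1, L2, chrom1, break1 + 1, 1))
        segs.append(Segment(chrom2, 1, break2, chrom2, 1, 1))
        segs.append(Segment(chrom1, break1 + 1, L1, chrom2, break2 + 1, 1))
        asm = dict(lengths)
        asm[chrom1] = break1 + (L2 - break2)
        asm[chrom2] = break2 + (L1 - break1)
        return cls(segs, lengths, asm)

    @classmethod
    def split(cls, lengths: dict[str, int], chrom: str,
              pos: int) -> "SegmentMap":
        """Split a chromosome at pos into suffixed fragments A and B."""
        L = lengths[chrom]
        if not 1 <= pos < L:
            raise AnomalyError("split position outside chromosome")
        segs = [Segment(c, 1, n, c, 1, 1)
                for c, n in lengths.items() if c != chrom]
        segs.append(Segment(chrom, 1, pos, chrom + "A", 1, 1))
        segs.append(Segment(chrom, pos + 1, L, chrom + "B", 1, 1))
        asm = {c: n for c, n in lengths.items() if c != chrom}
        asm[chrom + "A"] = pos
        asm[chrom + "B"] = L - pos
        return cls(segs, lengths, asm)


def remap_table(table, segmap: SegmentMap):
    """Return a genotype table with site coordinates pushed through the map."""
    from .core import GenotypeTable
    chroms = table.sites["chrom"].to_numpy()
    poss = table.sites["pos"].to_numpy()
    new_c = []
    new_p = np.empty_like(poss)
    for i in range(len(poss)):
        c, p = segmap.to_assembly(str(chroms[i]), int(poss[i]))
        new_c.append(c)
        new_p[i] = p
    sites = table.sites.copy()
    sites["chrom"] = new_c
    sites["pos"] = new_p
    out = GenotypeTable(samples=list(table.samples), sites=sites,
                        gt=table.gt.copy(), gq=table.gq.copy(),
                        chrom_lengths=dict(segmap.asm_lengths))
    return out.sort()


def apply_corrections(table, segment_maps: Sequence[SegmentMap]):
    """Undo injected/declared assembly errors by inverting their maps.

    Maps are inverted and applied in reverse order of application, restoring
    true coordinates; the composite lift is a bijection on covered bases.
    """
    out = table
    for m in reversed(list(segment_maps)):
        out = remap_table(out, m.invert())
    return out


# ---------------------------------------------------------------------------
# detection from CO calls
# ---------------------------------------------------------------------------

@dataclass
class AnomalyCall:
    kind: str  # inversion | misplaced_contig | translocation | single_break
    chrom: str
    start: int
    end: int
    meioses: tuple[tuple[str, str], ...]
    detail: dict = field(default_factory=dict)

    @property
    def n_meioses(self) -> int:
        return len(set(self.meioses))


def _by_meiosis(cos: Iterable[COEvent]) -> dict[tuple[str, str, str],
                                                list[COEvent]]:
    groups: dict[tuple[str, str, str], list[COEvent]] = {}
    for co in cos:
        groups.setdefault((co.parent, co.offspring, co.chrom), []).append(co)
    for v in groups.values():
        v.sort(key=lambda c: c.midpoint)
    return groups


def _merge_calls(cands: list[AnomalyCall]) -> list[AnomalyCall]:
    """Merge candidates on the same chromosome with overlapping regions."""
    out: list[AnomalyCall] = []
    for c in sorted(cands, key=lambda a: (a.chrom, a.start)):
        if out and out[-1].chrom == c.chrom and c.start <= out[-1].end:
            last = out[-1]
            out[-1] = AnomalyCall(last.kind, last.chrom, last.start,
                                  max(last.end, c.end),
                                  tuple(set(last.meioses) | set(c.meioses)),
                                  last.detail)
        else:
            out.append(c)
    return out


def detect_inversions(cos: Iterable[COEvent],
                      window_bp: int = 10_000_000) -> list[AnomalyCall]:
    """Flag triples of COs within window_bp in one meiosis.

    Candidates from different meioses whose regions overlap are merged,
    since an assembly error produces the same breakpoints in every meiosis.
    """
    cands = []
    for (parent, child, chrom), colist in _by_meiosis(cos).items():
        mids = [c.midpoint for c in colist]
        for i in range(len(colist) - 2):
            if mids[i + 2] - mids[i] <= window_bp:
                cands.append(AnomalyCall(
                    "inversion", chrom, colist[i].left, colist[i + 2].right,
                    ((parent, child),)))
    return _merge_calls(cands)


def detect_misplaced_contigs(cos: Iterable[COEvent], min_meioses: int = 2,
                             max_pair_span: int = 10_000_000
                             ) -> list[AnomalyCall]:
    """Flag CO pairs with identical marker intervals in >= min_meioses."""
    seen: dict[tuple, list[tuple[str, str]]] = {}
    for (parent, child, chrom), colist in _by_meiosis(cos).items():
        for a, b in zip(colist, colist[1:]):
            if b.right - a.left > max_pair_span:
                continue
            key = (chrom, a.left, a.right, b.left, b.right)
            seen.setdefault(key, []).append((parent, child))
    out = []
    for (chrom, l1, r1, l2, r2), meioses in seen.items():
        if len(set(meioses)) >= min_meioses:
            out.append(AnomalyCall("misplaced_contig", chrom, l1, r2,
                                   tuple(meioses),
                                   {"intervals": ((l1, r1), (l2, r2))}))
    out.sort(key=lambda a: (a.chrom, a.start))
    return out


def link_translocations(calls: list[AnomalyCall]) -> list[AnomalyCall]:
    """Pair misplaced-contig calls that share supporting meioses.

    When a contig's correct location is revealed by a second CO cluster,
    the two misplaced-contig calls describe one translocated segment.
    """
    mis = [c for c in calls if c.kind == "misplaced_contig"]
    linked: list[AnomalyCall] = []
    used: set[int] = set()
    for i, a in enumerate(mis):
        if i in used:
            continue
        for j in range(i + 1, len(mis)):
            if j in used:
                continue
            b = mis[j]
            if set(a.meioses) & set(b.meioses):
                linked.append(AnomalyCall(
                    "translocation", a.chrom, a.start, a.end,
                    tuple(set(a.meioses) | set(b.meioses)),
                    {"partner": (b.chrom, b.start, b.end)}))
                used.update((i, j))
                break
    return linked


def detect_single_breaks(cos: Iterable[COEvent], window_bp: int = 50_000,
                         k_min: int = 3) -> list[AnomalyCall]:
    """Flag windows where COs from >= k_min distinct meioses co-localize."""
    per_chrom: dict[str, list[tuple[int, tuple[str, str]]]] = {}
    for co in cos:
        per_chrom.setdefault(co.chrom, []).append(
            (co.midpoint, (co.parent, co.offspring)))
    cands = []
    for chrom, items in per_chrom.items():
        items.sort()
        mids = [m for m, _ in items]
        lo = 0
        for hi in range(len(items)):
            while mids[hi] - mids[lo] > window_bp:
                lo += 1
            meioses = {m for _, m in items[lo:hi + 1]}
            if len(meioses) >= k_min:
                cands.append(AnomalyCall(
                    "single_break", chrom, mids[lo], mids[hi],
                    tuple(m for _, m in items[lo:hi + 1])))
    return _merge_calls(cands)


def expected_break_overlap(n_contig_breaks: int,
                           anomaly_windows: Sequence[tuple[str, int, int]],
                           genome_length: int) -> float:
    """Expected number of contig breaks falling in anomaly windows at random."""
    if genome_length <= 0:
        raise AnomalyError("genome_length must be positive")
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in sorted(anomaly_windows):
        ivs = merged.setdefault(chrom, [])
        if ivs and s <= ivs[-1][1] + 1:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], e))
        else:
            ivs.append((s, e))
    total = sum(e - s + 1 for ivs in merged.values() for s, e in ivs)
    return n_contig_breaks * total / genome_length
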