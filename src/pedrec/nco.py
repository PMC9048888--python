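"""Noncrossover gene-conversion tract calling, filtering, classification.

An NCO tract appears in an inheritance vector as a short run of sites from
one parental haplotype surrounded on both sides by much larger stretches of
the other haplotype.  Runs spanning at most ``max_span`` (10 kb) are called
tracts; runs of 10-100 kb are kept as a separate "long" class (in practice
often assembly artifacts); anything longer is treated as a genuine pair of
crossovers and left to the CO caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeTable, Pedigree, STRONG
from .crossovers import COEvent, LONG_NCO_MAX_SPAN, NCO_MAX_SPAN, _runs
from .markers import InformativeSites
from .phasing import InheritanceVector

log = logging.getLogger(__name__)

DEFAULT_COMPLEX_WINDOW = 100_000
DEFAULT_CO_WINDOW = 100_000
DEFAULT_FLANK_SITES = 2


@dataclass(frozen=True)
class NCOTract:
    """A called conversion tract: converted sites pinned between flanks."""

    parent: str
    offspring: str
    chrom: str
    converted: tuple[int, ...]       # positions of converted informative sites
    left_flank: int                  # nearest nonconverted site to the left
    right_flank: int                 # nearest nonconverted site to the right
    cls: str = "simple"  # simple | complex_member | co_associated | long
    co_associated: bool = False
    gc_to_strong: int = 0            # AT->GC informative conversions
    gc_to_weak: int = 0
    mendel_flagged: bool = False

    def __post_init__(self) -> None:
        if not self.converted:
            raise ValueError("tract needs >= 1 converted site")
        if not (self.left_flank < min(self.converted)
                and max(self.converted) < self.right_flank):
            raise ValueError("converted sites must lie strictly between "
                             "the flanking nonconverted sites")

    @property
    def first(self) -> int:
        return self.converted[0]

    @property
    def last(self) -> int:
        return self.converted[-1]

    @property
    def min_length(self) -> int:
        """Observable lower bound on the latent tract length."""
        return self.last - self.first + 1

    @property
    def n_sites(self) -> int:
        return len(self.converted)

    @property
    def midpoint(self) -> int:
        return (self.first + self.last) // 2

    @property
    def meiosis(self) -> tuple[str, str]:
        return (self.parent, self.offspring)


def call_nco_tracts(vector: InheritanceVector,
                    info: InformativeSites | None = None,
                    max_span: int = NCO_MAX_SPAN,
                    long_max: int = LONG_NCO_MAX_SPAN,
                    flank_sites: int = DEFAULT_FLANK_SITES,
                    flank_span: int | None = None) -> list[NCOTract]:
    """Call conversion tracts from one offspring's inheritance vector.

    A candidate run becomes a tract only when flanked on both sides by
    concordant runs of >= flank_sites sites spanning >= flank_span bp
    (default: max_span), which separates conversion from double crossovers
    at the 10 kb scale.  Passing ``info`` adds the gBGC tally (which allele
    class each A/T-G/C conversion resolved to).
    """
    if flank_span is None:
        flank_span = max_span
    pos = vector.positions
    runs = _runs(np.asarray(vector.states))
    out: list[NCOTract] = []
    for i in range(1, len(runs) - 1):
        s, e = runs[i]
        span = int(pos[e] - pos[s] + 1)
        if span > long_max:
            continue  # a real segment: boundaries are crossovers
        ok = True
        for fs, fe in (runs[i - 1], runs[i + 1]):
            n_f = fe - fs + 1
            span_f = int(pos[fe] - pos[fs] + 1)
            if n_f < flank_sites or span_f < flank_span:
                ok = False
        if not ok:
            log.info("discordant run at %s:%d-%d lacks qualifying flanks; "
                     "dropped", vector.chrom, pos[s], pos[e])
            continue
        tract = NCOTract(
            parent=vector.parent, offspring=vector.offspring,
            chrom=vector.chrom,
            converted=tuple(int(p) for p in pos[s:e + 1]),
            left_flank=int(pos[s - 1]), right_flank=int(pos[e + 1]),
            cls="long" if span > max_span else "simple")
        if info is not None:
            tract = _tally_gbgc(tract, info)
        out.append(tract)
    return out


def _tally_gbgc(tract: NCOTract, info: InformativeSites) -> NCOTract:
    j = info.offspring.index(tract.offspring)
    to_s = to_w = 0
    for p in tract.converted:
        i = int(np.searchsorted(info.positions, p))
        if i >= info.n_sites or info.positions[i] != p:
            continue
        ref, alt = str(info.ref[i]), str(info.alt[i])
        if (ref in STRONG) == (alt in STRONG):
            continue  # not informative on gBGC
        base = alt if info.transmitted[i, j] == 1 else ref
        if base in STRONG:
            to_s += 1
        else:
            to_w += 1
    return replace(tract, gc_to_strong=to_s, gc_to_weak=to_w)


def filter_nco(tracts: Sequence[NCOTract],
               pedigree: Pedigree | None = None,
               genotypes: GenotypeTable | None = None,
               multiallelic: set[tuple[str, int]] | None = None
               ) -> list[NCOTract]:
    """Apply artifact filters to called tracts.

    Tracts sharing any converted site with a tract in another offspring of
    the same parent are removed (a shared "conversion" is a genotyping
    artifact in the parent, not independent recombination).  Converted
    sites at multiallelic positions are stripped.  Tracts whose converted
    alleles create Mendelian inconsistencies in the next generation are
    flagged, not removed.
    """
    # strip multiallelic converted sites
    work: list[NCOTract] = []
    for t in tracts:
        conv = tuple(p for p in t.converted
                     if not (multiallelic and (t.chrom, p) in multiallelic))
        if not conv:
            continue
        if conv != t.converted:
            t = replace(t, converted=conv)
        work.append(t)

    # shared-site removal across offspring of the same parent
    seen: dict[tuple[str, str, int], set[str]] = {}
    for t in work:
        for p in t.converted:
            seen.setdefault((t.parent, t.chrom, p), set()).add(t.offspring)
    out = []
    for t in work:
        shared = any(len(seen[(t.parent, t.chrom, p)]) > 1
                     for p in t.converted)
        if shared:
            log.info("removed tract %s:%d-%d shared across siblings",
                     t.chrom, t.first, t.last)
            continue
        if pedigree is not None and genotypes is not None:
            t = replace(t, mendel_flagged=_mendel_inconsistent(
                t, pedigree, genotypes))
        out.append(t)
    return out


def _mendel_inconsistent(tract: NCOTract, pedigree: Pedigree,
                         genotypes: GenotypeTable) -> bool:
    """Check converted sites against the offspring's own children, if any."""
    children = pedigree.offspring_of(tract.offspring)
    if not children:
        return False
    oi = genotypes.sample_index(tract.offspring)
    cmask = genotypes.chrom_mask(tract.chrom)
    pos = genotypes.sites["pos"].to_numpy()
    for p in tract.converted:
        hit = np.flatnonzero(cmask & (pos == p))
        if hit.size == 0:
            continue
        row = int(hit[0])
        off = set(int(a) for a in genotypes.gt[row, oi] if a >= 0)
        for child in children:
            ci = genotypes.sample_index(child)
            cg = set(int(a) for a in genotypes.gt[row, ci] if a >= 0)
            if cg and off and not (cg & off):
                return True
    return False


def classify_events(tracts: Sequence[NCOTract], cos: Sequence[COEvent],
                    complex_window: int = DEFAULT_COMPLEX_WINDOW,
                    co_window: int = DEFAULT_CO_WINDOW
                    ) -> tuple[list[NCOTract], list[list[int]]]:
    """Group nearby tracts into complex events and mark CO association.

    Non-contiguous tracts of the same meiosis within ``complex_window`` of
    each other form one complex event; a tract within ``co_window`` of a CO
    of the same meiosis is CO-associated.  Returns the relabelled tracts
    and the event groups as lists of tract indexes.
    """
    tracts = list(tracts)
    order = sorted(range(len(tracts)),
                   key=lambda i: (tracts[i].meiosis, tracts[i].chrom,
                                  tracts[i].midpoint))
    groups: list[list[int]] = []
    for i in order:
        t = tracts[i]
        if groups:
            last_grp = groups[-1]
            prev = tracts[last_grp[-1]]
            if (prev.meiosis == t.meiosis and prev.chrom == t.chrom
                    and t.midpoint - prev.midpoint <= complex_window):
                last_grp.append(i)
                continue
        groups.append([i])

    co_mids: dict[tuple[str, str, str], np.ndarray] = {}
    for co in cos:
        key = (co.parent, co.offspring, co.chrom)
        co_mids.setdefault(key, [])
    for co in cos:
        co_mids[(co.parent, co.offspring, co.chrom)].append(co.midpoint)

    out = list(tracts)
    for grp in groups:
        for i in grp:
            t = out[i]
            mids = co_mids.get((t.parent, t.offspring, t.chrom), [])
            near_co = any(abs(t.midpoint - m) <= co_window for m in mids)
            cls = t.cls
            if cls != "long":
                if len(grp) > 1:
                    cls = "complex_member"
                elif near_co:
                    cls = "co_associated"
                else:
                    cls = "simple"
            out[i] = replace(t, cls=cls, co_associated=near_co)
    return out, groups


def long_tract_report(tracts: Iterable[NCOTract],
                      anomalies: Iterable) -> pd.DataFrame:
    """Cross-reference long (>10 kb) apparent tracts with anomaly regions."""
    regions = [(a.chrom, a.start, a.end) for a in anomalies]
    rows = []
    for t in tracts:
        if t.cls != "long":
            continue
        hit = any(c == t.chrom and s <= t.last and t.first <= e
                  for c, s, e in regions)
        rows.append({"chrom": t.chrom, "parent": t.parent,
                     "offspring": t.offspring,
                     "min_tract_length": t.min_length,
                     "n_nco_sites": t.n_sites,
                     "overlaps_anomaly": "Yes" if hit else "No"})
    return pd.DataFrame(rows, columns=["chrom", "parent", "offspring",
                                       "min_tract_length", "n_nco_sites",
                                       "overlaps_anomaly"])
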