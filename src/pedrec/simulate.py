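"""Synthetic pedigree genotypes with fully known recombination ground truth.

The generator emulates the observation process of a multi-generation
pedigree sequencing study: two (or more) mated pairs with large sib-ships,
dense biallelic SNPs informative for one focal parent each, sex-specific
crossover counts, gene-conversion tracts initiated per bp with
mixture-distributed lengths, GC-biased resolution of A/T-G/C heterozygotes
inside tracts, per-genotype miscalls, and (optionally) injected genome
assembly errors that scramble marker coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .anomalies import SegmentMap, remap_table
from .core import GenotypeTable, Pedigree, STRONG
from .tractmodel import TractLengthModel

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pedigree.

    Defaults mirror a large-mammal study design: a ~2.6 Gb genome in 20
    chromosomes, informative-marker density giving ~1.2M sites per meiosis
    genome, male/female map lengths of 2,080/2,506 cM, tract initiation at
    7.52e-6 per bp per meiosis with the fitted two-component length mixture,
    and a 57.6% transmission bias toward G/C inside conversion tracts.
    """

    n_chromosomes: int = 20
    chrom_length_bp: int = 130_000_000
    marker_density: float = 4.3e-4
    male_map_cM: float = 2080.0
    female_map_cM: float = 2506.0
    nco_rate_per_bp: float = 7.52e-6
    tract_model: TractLengthModel = field(default_factory=TractLengthModel)
    gbgc_bias: float = 0.576
    genotype_error_rate: float = 0.0
    offspring_counts: tuple[int, ...] = (12, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes: must be >= 1")
        if self.chrom_length_bp <= 0:
            raise ConfigError("chrom_length_bp: must be > 0")
        for name in ("marker_density", "nco_rate_per_bp", "gbgc_bias",
                     "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        if self.male_map_cM < 0 or self.female_map_cM < 0:
            raise ConfigError("map_cM: genetic lengths must be >= 0")
        if any(n < 5 for n in self.offspring_counts):
            raise ConfigError(
                "offspring_counts: each sub-pedigree needs >= 5 offspring")


@dataclass
class TrueTract:
    """An initiated gene-conversion tract and its observable footprint."""

    parent: str
    offspring: str
    chrom: str
    start: int
    drawn_length: int
    realized_length: int
    converted_sites: list[int] = field(default_factory=list)
    gc_resolution: dict[int, bool] = field(default_factory=dict)  # pos->to G/C

    @property
    def end(self) -> int:
        return self.start + self.realized_length - 1


@dataclass
class TrueMeiosis:
    parent: str
    offspring: str
    chrom: str
    start_hap: int
    co_positions: np.ndarray  # breakpoint after this bp
    tracts: list[TrueTract]


@dataclass
class AnomalySpec:
    """Description of an assembly error to inject (true coordinates)."""

    kind: str  # inversion | misplaced_contig | single_break
    chrom: str
    start: int = 0
    end: int = 0
    dest: int = 0          # misplaced_contig: insert after this position
    chrom2: str = ""       # single_break: partner chromosome
    break2: int = 0


@dataclass
class GroundTruth:
    meioses: list[TrueMeiosis] = field(default_factory=list)
    anomalies: list[tuple[AnomalySpec, SegmentMap]] = field(
        default_factory=list)
    error_sites: list[tuple[str, str, int]] = field(default_factory=list)

    def meioses_for(self, parent: str | None = None,
                    offspring: str | None = None,
                    chrom: str | None = None) -> list[TrueMeiosis]:
        out = []
        for m in self.meioses:
            if parent is not None and m.parent != parent:
                continue
            if offspring is not None and m.offspring != offspring:
                continue
            if chrom is not None and m.chrom != chrom:
                continue
            out.append(m)
        return out


def sample_tract_length(model: TractLengthModel,
                        rng: np.random.Generator) -> int:
    """One tract length drawn from the (truncated) length distribution."""
    return int(model.sample(rng, 1)[0])


def simulate_tract_observations(model: TractLengthModel,
                                rng: np.random.Generator,
                                marker_density: float = 4.3e-4,
                                min_tracts: int = 1000,
                                chrom_length: int = 100_000_000,
                                rate_per_bp: float | None = None):
    """Simulate the tract observation process at the marker level.

    Generates meiosis-chromosome panels (uniform informative markers at
    ``marker_density`` per bp, Poisson tract initiations at intensity
    ``rate_per_bp / mean(model)`` per bp -- the same convention as
    :meth:`~pedrec.tractmodel.TractLengthModel.initiation_probs`, where
    ``rate_per_bp`` is converted bp per bp per meiosis -- with lengths from
    ``model``) until at least ``min_tracts`` tracts convert >= 1 marker.
    Whole panels are kept so the exclusion summaries match the observed
    tracts exactly.  Returns likelihood-ready
    :class:`~pedrec.tractmodel.KmerData`.
    """
    from .tractmodel import KmerData, TractObservation

    rate = model.rate_per_bp if rate_per_bp is None else rate_per_bp
    init_rate = rate / model.mean()
    L = int(chrom_length)
    obs: list[TractObservation] = []
    nonconv: list[tuple[np.ndarray, int]] = []
    panel = 0
    while len(obs) < min_tracts:
        panel += 1
        pos = np.unique(rng.integers(1, L + 1,
                                     size=rng.poisson(L * marker_density)))
        n_init = rng.poisson(L * init_rate)
        starts = rng.integers(1, L + 1, size=n_init)
        lens = model.sample(rng, n_init)
        conv = np.zeros(pos.size, dtype=bool)
        for s, ln in zip(starts, lens):
            e = min(int(s) + int(ln) - 1, L)
            lo, hi = np.searchsorted(pos, [int(s), e + 1])
            conv[lo:hi] = True
        nonconv.append((pos[~conv], L))
        # maximal converted runs with nonconverted flanking markers
        idx = np.flatnonzero(conv)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1) + 1
            for run in np.split(idx, breaks):
                lo, hi = run[0], run[-1]
                if lo == 0 or hi == pos.size - 1:
                    continue  # no flanking marker on one side
                span = int(pos[hi] - pos[lo] + 1)
                if span > model.truncation:
                    continue
                obs.append(TractObservation(
                    int(pos[lo - 1]), int(pos[lo]), int(pos[hi]),
                    int(pos[hi + 1]), meiosis=f"panel{panel}"))
    return KmerData.build(obs, nonconv, t_max=model.truncation,
                          rate_per_bp=rate)


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None
                      ) -> tuple[GenotypeTable, Pedigree, GroundTruth]:
    """Simulate genotypes for mated pairs with known COs and NCO tracts.

    Each informative site is designed for exactly one (sub-pedigree, focal
    parent) combination at density ``marker_density`` per focal parent per
    bp; other parents are homozygous there.  Crossover counts per meiosis
    are Poisson with mean map_cM / 100 split evenly over chromosomes (no
    interference); tract initiations are Poisson per bp.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sub = len(config.offspring_counts)
    sires = [f"sire{i + 1}" for i in range(n_sub)]
    dams = [f"dam{i + 1}" for i in range(n_sub)]
    kids = [[f"off{i + 1}_{j + 1}" for j in range(n)]
            for i, n in enumerate(config.offspring_counts)]
    samples = []
    rows = []
    for i in range(n_sub):
        samples += [sires[i], dams[i]]
        rows += [(sires[i], "0", "0", 1), (dams[i], "0", "0", 2)]
        for k in kids[i]:
            samples.append(k)
            rows.append((k, sires[i], dams[i], int(rng.integers(1, 3))))
    pedigree = Pedigree(pd.DataFrame(
        rows, columns=["iid", "father", "mother", "sex"]))

    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    L = config.chrom_length_bp
    chrom_lengths = {c: L for c in chroms}
    truth = GroundTruth()
    site_frames = []
    gt_blocks = []

    # parent haplotypes are built per chromosome; focal roles cycle over
    # (sub-pedigree, sire/dam) pairs
    focal_roles = [(i, which) for i in range(n_sub) for which in (0, 1)]
    cm_per_chrom = {1: config.male_map_cM / config.n_chromosomes,
                    2: config.female_map_cM / config.n_chromosomes}

    parent_sex = {s: 1 for s in sires}
    parent_sex.update({d: 2 for d in dams})

    for chrom in chroms:
        n_sites = rng.poisson(L * config.marker_density * len(focal_roles))
        pos = np.unique(rng.integers(1, L + 1, size=n_sites))
        n = pos.size
        role_idx = rng.integers(0, len(focal_roles), size=n)
        base_idx = rng.integers(0, 4, size=n)
        alt_off = rng.integers(1, 4, size=n)
        ref = _BASES[base_idx]
        alt = _BASES[(base_idx + alt_off) % 4]

        # haplotypes: (n_sites, 2) allele indexes per parent
        haps: dict[str, np.ndarray] = {}
        for i in range(n_sub):
            for which, parent in enumerate((sires[i], dams[i])):
                h = np.empty((n, 2), dtype=np.int8)
                focal_here = role_idx == focal_roles.index((i, which))
                hom = rng.integers(0, 2, size=n).astype(np.int8)
                h[:, 0] = hom
                h[:, 1] = hom
                # focal sites: heterozygous with random phase
                ph = rng.integers(0, 2, size=n).astype(np.int8)
                h[focal_here, 0] = ph[focal_here]
                h[focal_here, 1] = 1 - ph[focal_here]
                # co-parent homozygous at the partner's focal sites
                partner_focal = role_idx == focal_roles.index((i, 1 - which))
                h[partner_focal, 0] = hom[partner_focal]
                h[partner_focal, 1] = hom[partner_focal]
                haps[parent] = h

        strong_is_alt = np.isin(alt, list(STRONG))
        sw_pair = np.isin(ref, list("AT")) == strong_is_alt  # one W, one S

        gametes: dict[str, np.ndarray] = {}
        for i in range(n_sub):
            for parent in (sires[i], dams[i]):
                for child in kids[i]:
                    g, mei = _meiosis(
                        parent, child, chrom, pos, haps[parent],
                        cm_per_chrom[parent_sex[parent]], L, config, rng,
                        strong_is_alt, sw_pair)
                    gametes[(parent, child)] = g
                    truth.meioses.append(mei)

        gt = np.empty((n, len(samples), 2), dtype=np.int8)
        for si, s in enumerate(samples):
            if s in haps:
                gt[:, si, :] = haps[s]
            else:
                f, m = pedigree.parents_of(s)
                gt[:, si, 0] = gametes[(f, s)]
                gt[:, si, 1] = gametes[(m, s)]

        if config.genotype_error_rate > 0:
            err = rng.random((n, len(samples))) < config.genotype_error_rate
            for si_, s in enumerate(samples):
                hit = np.flatnonzero(err[:, si_])
                for row in hit:
                    old = tuple(sorted(gt[row, si_]))
                    choices = [g for g in ((0, 0), (0, 1), (1, 1))
                               if g != old]
                    gt[row, si_] = choices[rng.integers(0, len(choices))]
                    truth.error_sites.append((s, chrom, int(pos[row])))

        site_frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}))
        gt_blocks.append(gt)

    sites = pd.concat(site_frames, ignore_index=True)
    gt_all = np.concatenate(gt_blocks, axis=0)
    gq = np.full((len(sites), len(samples)), 99, dtype=np.int16)
    table = GenotypeTable(samples=samples, sites=sites, gt=gt_all, gq=gq,
                          chrom_lengths=chrom_lengths)
    return table, pedigree, truth


def _meiosis(parent: str, child: str, chrom: str, pos: np.ndarray,
             haps: np.ndarray, cm: float, L: int, config: SimConfig,
             rng: np.random.Generator, strong_is_alt: np.ndarray,
             sw_pair: np.ndarray) -> tuple[np.ndarray, TrueMeiosis]:
    n_co = rng.poisson(cm / 100.0)
    co_pos = np.sort(rng.integers(1, L, size=n_co))
    start_hap = int(rng.integers(0, 2))
    background = (start_hap + np.searchsorted(co_pos, pos, side="left")) % 2
    gamete = haps[np.arange(pos.size), background].copy()

    n_tracts = rng.poisson(L * config.nco_rate_per_bp)
    tracts: list[TrueTract] = []
    if n_tracts:
        starts = np.sort(rng.integers(1, L + 1, size=n_tracts))
        lengths = config.tract_model.sample(rng, n_tracts)
        for ts, tl in zip(starts, lengths):
            te = min(int(ts) + int(tl) - 1, L)
            tract = TrueTract(parent, child, chrom, int(ts), int(tl),
                              te - int(ts) + 1)
            lo, hi = np.searchsorted(pos, [ts, te + 1])
            for si in range(lo, hi):
                if haps[si, 0] == haps[si, 1]:
                    continue  # conversion invisible at a homozygous site
                if sw_pair[si]:
                    to_strong = rng.random() < config.gbgc_bias
                    allele = (int(strong_is_alt[si]) if to_strong
                              else 1 - int(strong_is_alt[si]))
                    tract.gc_resolution[int(pos[si])] = to_strong
                else:
                    allele = int(haps[si, 1 - background[si]])
                if allele != gamete[si]:
                    gamete[si] = allele
                    tract.converted_sites.append(int(pos[si]))
            tracts.append(tract)
    return gamete, TrueMeiosis(parent, child, chrom, start_hap, co_pos,
                               tracts)


def inject_assembly_error(table: GenotypeTable, truth: GroundTruth,
                          spec: AnomalySpec
                          ) -> tuple[GenotypeTable, GroundTruth]:
    """Rewrite marker coordinates to present an assembly error.

    Ground truth keeps its true coordinates; the anomaly description and its
    coordinate map are appended to ``truth.anomalies`` so corrections can
    invert them.
    Overlapping injections on the same chromosome are rejected.
    """
    for prev, _ in truth.anomalies:
        if prev.chrom == spec.chrom and not (
                spec.end < prev.start or spec.start > prev.end):
            raise ValueError("overlapping anomaly segments")
    lengths = dict(table.chrom_lengths)
    if spec.kind == "inversion":
        smap = SegmentMap.inversion(lengths, spec.chrom, spec.start, spec.end)
    elif spec.kind == "misplaced_contig":
        smap = SegmentMap.misplaced_contig(lengths, spec.chrom, spec.start,
                                           spec.end, spec.dest)
    elif spec.kind == "single_break":
        smap = SegmentMap.tail_swap(lengths, spec.chrom, spec.start,
                                    spec.chrom2, spec.break2)
    else:
        raise ValueError(f"unknown anomaly kind {spec.kind!r}")
    new_table = remap_table(table, smap)
    truth.anomalies.append((spec, smap))
    return new_table, truth
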