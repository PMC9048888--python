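"""Informative-site selection and genotype-level filters.

A site is informative for a focal parent when that parent is heterozygous
and the co-parent homozygous: the co-parent's transmitted allele is then
forced, so the focal parent's transmitted allele can be read off each
offspring genotype directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .core import GenotypeTable, MISSING, Pedigree, PedigreeError

log = logging.getLogger(__name__)

DEFAULT_GQ_MIN = 30
DEFAULT_EXCESS_HET_SD = 3.5
DEFAULT_END_TRIM = 5


@dataclass(frozen=True)
class InformativeSites:
    """Informative sites for one (focal parent, chromosome), sorted by pos.

    ``transmitted[i, j]`` is the allele index (0/1) the focal parent passed
    to offspring ``offspring[j]`` at ``positions[i]``.  ``phase_alleles``
    records the focal parent's het pair as (ref, alt) bases via ref/alt.
    """

    chrom: str
    focal_parent: str
    co_parent: str
    offspring: tuple[str, ...]
    positions: np.ndarray      # (n,) int64, strictly increasing
    ref: np.ndarray            # (n,) <U1
    alt: np.ndarray            # (n,) <U1
    co_allele: np.ndarray      # (n,) allele index the co-parent is hom for
    transmitted: np.ndarray    # (n, n_off) int8

    def __post_init__(self) -> None:
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def take(self, idx: np.ndarray) -> "InformativeSites":
        return replace(self, positions=self.positions[idx],
                       ref=self.ref[idx], alt=self.alt[idx],
                       co_allele=self.co_allele[idx],
                       transmitted=self.transmitted[idx])


def excess_het_filter(gt_at_site: np.ndarray, n_samples: int | None = None,
                      threshold_sd: float = DEFAULT_EXCESS_HET_SD) -> bool:
    """Keep a site unless heterozygotes exceed random-mating expectation.

    Under random mating the het count is ~Binomial(n, 2p(1-p)); the site is
    rejected when the observed count is more than ``threshold_sd`` binomial
    standard deviations above the mean.  Monomorphic sites are kept.
    """
    gt = np.asarray(gt_at_site)
    called = (gt[:, 0] != MISSING) & (gt[:, 1] != MISSING)
    gt = gt[called]
    n = n_samples if n_samples is not None else gt.shape[0]
    if n == 0:
        return True
    p = float(gt.mean()) if gt.size else 0.0  # alt-allele frequency
    if p <= 0.0 or p >= 1.0:
        return True
    h = 2.0 * p * (1.0 - p)
    mean = n * h
    sd = math.sqrt(n * h * (1.0 - h))
    n_het = int((gt[:, 0] != gt[:, 1]).sum())
    return n_het <= mean + threshold_sd * sd


def select_informative(genotypes: GenotypeTable, pedigree: Pedigree,
                       focal_parent: str, chrom: str, *,
                       offspring: list[str] | None = None,
                       gq_min: int = DEFAULT_GQ_MIN,
                       excess_het_sd: float | None = DEFAULT_EXCESS_HET_SD,
                       mask: list[tuple[int, int]] | None = None
                       ) -> InformativeSites:
    """Informative sites for one focal parent on one chromosome.

    Requires the focal parent heterozygous, the co-parent homozygous, and a
    quality genotype call in every offspring of the sub-pedigree.  Sites
    where any offspring genotype is Mendelian-inconsistent with the parents
    are dropped and logged.  ``mask`` intervals (1-based, inclusive; e.g.
    repeat-masked regions) are excluded.  ``excess_het_sd=None`` disables
    the excess-heterozygosity filter.
    """
    if offspring is None:
        offspring = pedigree.offspring_of(focal_parent)
    if not offspring:
        raise PedigreeError(f"{focal_parent!r} has no offspring")
    co_parents = {pedigree.co_parent(focal_parent, c) for c in offspring}
    if len(co_parents) != 1:
        raise PedigreeError(
            f"offspring of {focal_parent!r} have multiple co-parents "
            f"{sorted(co_parents)}; pass an explicit offspring list")
    co_parent = co_parents.pop()

    cmask = genotypes.chrom_mask(chrom)
    idx = np.flatnonzero(cmask)
    pos = genotypes.sites["pos"].to_numpy()[idx]
    ref = genotypes.sites["ref"].to_numpy()[idx]
    alt = genotypes.sites["alt"].to_numpy()[idx]

    fi = genotypes.sample_index(focal_parent)
    ci = genotypes.sample_index(co_parent)
    oi = np.array([genotypes.sample_index(o) for o in offspring])
    gt = genotypes.gt[idx]
    gq = genotypes.gq[idx]

    focal = gt[:, fi]
    co = gt[:, ci]
    keep = ((focal[:, 0] != MISSING) & (focal[:, 1] != MISSING)
            & (focal[:, 0] != focal[:, 1])
            & (co[:, 0] != MISSING) & (co[:, 0] == co[:, 1])
            & (gq[:, fi] >= gq_min) & (gq[:, ci] >= gq_min))
    off_gt = gt[:, oi]                     # (n, n_off, 2)
    off_called = np.all(off_gt != MISSING, axis=2) \
        & (gq[:, oi] >= gq_min)
    keep &= np.all(off_called, axis=1)

    if mask:
        in_mask = np.zeros(pos.shape, dtype=bool)
        for s, e in mask:
            in_mask |= (pos >= s) & (pos <= e)
        keep &= ~in_mask

    if excess_het_sd is not None:
        eh = np.fromiter(
            (excess_het_filter(gt[i], threshold_sd=excess_het_sd)
             for i in range(gt.shape[0])), dtype=bool, count=gt.shape[0])
        keep &= eh

    # transmitted allele: remove one co-parent allele from each offspring
    co_allele = co[:, 0]
    b = co_allele[:, None]
    has_b = (off_gt[:, :, 0] == b) | (off_gt[:, :, 1] == b)
    transmitted = np.where(off_gt[:, :, 0] == b,
                           off_gt[:, :, 1], off_gt[:, :, 0])
    consistent = np.all(has_b, axis=1)
    n_bad = int((keep & ~consistent).sum())
    if n_bad:
        log.info("dropped %d sites with offspring genotypes inconsistent "
                 "with parents (%s, %s)", n_bad, focal_parent, chrom)
    keep &= consistent

    sel = np.flatnonzero(keep)
    return InformativeSites(
        chrom=chrom, focal_parent=focal_parent, co_parent=co_parent,
        offspring=tuple(offspring),
        positions=pos[sel].astype(np.int64),
        ref=ref[sel].astype(str), alt=alt[sel].astype(str),
        co_allele=co_allele[sel].astype(np.int8),
        transmitted=transmitted[sel].astype(np.int8),
    )


def trim_chromosome_ends(sites: InformativeSites,
                         n_trim: int = DEFAULT_END_TRIM) -> InformativeSites:
    """Drop the n_trim informative sites nearest each chromosome end."""
    n = sites.n_sites
    if n < 2 * n_trim:
        log.warning("chromosome %s has only %d informative sites; all "
                    "removed by end trimming", sites.chrom, n)
        return sites.take(np.array([], dtype=np.int64))
    return sites.take(np.arange(n_trim, n - n_trim))
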