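"""Transmission phasing of the focal parent from sib-ship patterns.

With several offspring per parent, the two parental haplotypes partition
the offspring at every informative site; phase is inferred by chaining
these partitions left to right so that the total number of haplotype
switches across offspring is minimal (minimum-recombinant criterion).
Recombination is rare at the marker scale, so a per-site majority vote
against the running partition attains the minimum-recombinant solution
whenever the sib-ship has enough offspring; exact ties cannot be oriented
and are flagged ambiguous and excluded from event calling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .markers import InformativeSites

log = logging.getLogger(__name__)

MIN_OFFSPRING = 5


@dataclass(frozen=True)
class InheritanceVector:
    """Per-offspring haplotype states (0 = hap1, 1 = hap2) along a chrom."""

    parent: str
    offspring: str
    chrom: str
    positions: np.ndarray  # (n,) int64, ambiguous sites removed
    states: np.ndarray     # (n,) int8

    def __post_init__(self) -> None:
        if self.positions.shape != self.states.shape:
            raise ValueError("positions and states must align")


@dataclass(frozen=True)
class PhaseResult:
    phase: np.ndarray       # (n_sites,) 0/1: 1 means hap1 carries allele 1
    ambiguous: np.ndarray   # (n_sites,) bool
    vectors: tuple[InheritanceVector, ...]

    @property
    def n_switches(self) -> int:
        total = 0
        for v in self.vectors:
            total += int(np.sum(np.diff(v.states) != 0))
        return total


def infer_phase(sites: InformativeSites) -> PhaseResult:
    """Phase the focal parent and emit per-offspring inheritance vectors.

    ``phase[i] = 0`` assigns allele 0 to haplotype 1 at site i, so the
    state of offspring j is ``transmitted[i, j] XOR phase[i]``.
    """
    n, n_off = sites.transmitted.shape
    if n < 2:
        raise ValueError("phasing needs at least two informative sites")
    if n_off < MIN_OFFSPRING:
        warnings.warn(
            f"only {n_off} offspring; phasing is designed for sib-ships of "
            f">= {MIN_OFFSPRING}", RuntimeWarning)
    t = sites.transmitted.astype(np.int8)
    phase = np.zeros(n, dtype=np.int8)
    ambiguous = np.zeros(n, dtype=bool)
    prev = t[0]  # states at the last unambiguous site (phase 0 at site 0)
    for i in range(1, n):
        mism0 = int(np.sum(t[i] != prev))
        mism1 = n_off - mism0
        if mism0 < mism1:
            phase[i] = 0
        elif mism1 < mism0:
            phase[i] = 1
        else:
            ambiguous[i] = True
            continue
        prev = t[i] ^ phase[i]
    keep = ~ambiguous
    vectors = tuple(
        InheritanceVector(
            parent=sites.focal_parent, offspring=o, chrom=sites.chrom,
            positions=sites.positions[keep].copy(),
            states=(t[keep, j] ^ phase[keep]).astype(np.int8))
        for j, o in enumerate(sites.offspring))
    if ambiguous.any():
        log.info("%d ambiguous phase sites excluded on %s (%s)",
                 int(ambiguous.sum()), sites.chrom, sites.focal_parent)
    return PhaseResult(phase=phase, ambiguous=ambiguous, vectors=vectors)
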