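"""Crossover calling from inheritance vectors and genetic-map summaries.

A crossover (CO) is a persistent switch in which parental haplotype an
offspring inherits.  Short haplotype switch-backs are gene-conversion
candidates and are routed to the noncrossover caller instead: interior
discordant runs spanning at most ``long_max`` (100 kb) never produce CO
calls here; runs up to 10 kb are ordinary NCO candidates and runs of
10-100 kb are "long" apparent NCO tracts handled separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .phasing import InheritanceVector

NCO_MAX_SPAN = 10_000
LONG_NCO_MAX_SPAN = 100_000


@dataclass(frozen=True)
class COEvent:
    """A called crossover with its marker-resolution interval (left, right]."""

    parent: str
    offspring: str
    chrom: str
    left: int   # last informative site of the prior state
    right: int  # first informative site of the new state
    status: str = "standard"  # standard | confirmed | provisional

    def __post_init__(self) -> None:
        if self.right <= self.left:
            raise ValueError("CO interval must have positive width")

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def midpoint(self) -> int:
        return (self.left + self.right) // 2


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as (start_idx, end_idx) inclusive."""
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [states.size]))
    return [(int(bounds[i]), int(bounds[i + 1] - 1))
            for i in range(len(bounds) - 1)]


def call_crossovers(vector: InheritanceVector,
                    max_nco_span: int = NCO_MAX_SPAN,
                    long_max: int = LONG_NCO_MAX_SPAN) -> list[COEvent]:
    """Call COs from one offspring's inheritance vector.

    Interior runs spanning <= long_max bp are removed (they are NCO or
    long-NCO candidates) and their flanks merged; the boundaries that
    remain are parsimoniously single COs.  Removal proceeds smallest run
    first so chained short runs collapse deterministically.
    """
    pos = vector.positions
    states = list(vector.states)
    runs = _runs(np.asarray(states))
    # iteratively drop the smallest interior run within the span threshold
    while True:
        interior = [(pos[e] - pos[s] + 1, i)
                    for i, (s, e) in enumerate(runs) if 0 < i < len(runs) - 1]
        removable = [(span, i) for span, i in interior if span <= long_max]
        if not removable:
            break
        _, idx = min(removable)
        del runs[idx]
        # merge neighbours, which now share a state
        merged = [runs[0]]
        for s, e in runs[1:]:
            if states[s] == states[merged[-1][0]]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    out = []
    for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
        out.append(COEvent(vector.parent, vector.offspring, vector.chrom,
                           int(pos[e1]), int(pos[s2])))
    return out


def review_double_co_intervals(cos: Sequence[COEvent],
                               chrom_lengths: dict[str, int],
                               subped_size: dict[str, int],
                               min_interval_bp: int = 60_000,
                               end_distance_bp: int = 2_000_000,
                               min_offspring: int = 7) -> list[COEvent]:
    """Confirm or demote CO pairs sharing one inter-marker interval.

    Two COs from two meioses in the same interval are confirmed only when
    the interval is long, far from the chromosome ends, and both meioses
    come from sub-pedigrees with enough offspring; otherwise both become
    provisional.  ``subped_size`` maps parent id -> number of offspring.
    """
    groups: dict[tuple[str, int, int], list[int]] = {}
    for i, co in enumerate(cos):
        groups.setdefault((co.chrom, co.left, co.right), []).append(i)
    out = list(cos)
    for (chrom, left, right), idxs in groups.items():
        meioses = {(cos[i].parent, cos[i].offspring) for i in idxs}
        if len(meioses) < 2:
            continue
        L = chrom_lengths[chrom]
        ok = (right - left > min_interval_bp
              and left >= end_distance_bp
              and right <= L - end_distance_bp
              and all(subped_size[cos[i].parent] >= min_offspring
                      for i in idxs))
        status = "confirmed" if ok else "provisional"
        for i in idxs:
            out[i] = replace(out[i], status=status)
    return out


def map_length(co_count: int, n_meioses: int) -> float:
    """Genetic map length in cM from a CO count over n_meioses meioses."""
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    return 100.0 * co_count / n_meioses


def sex_averaged_map_length(male_cM: float, female_cM: float) -> float:
    """Sex-averaged map length: arithmetic mean of the sex-specific maps."""
    return 0.5 * (male_cM + female_cM)


def map_length_by_chrom(cos: Iterable[COEvent],
                        n_meioses: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    for co in cos:
        counts[co.chrom] = counts.get(co.chrom, 0) + 1
    return {c: map_length(n, n_meioses) for c, n in sorted(counts.items())}
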