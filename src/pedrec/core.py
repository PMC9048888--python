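"""Shared containers: genotype table and pedigree."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
STRONG = frozenset("GC")
WEAK = frozenset("AT")


class PedigreeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Biallelic SNP genotypes for all pedigree samples.

    ``sites`` has columns chrom, pos (1-based), ref, alt, sorted by
    (chrom, pos).  ``gt`` is (n_sites, n_samples, 2) with allele indexes
    0/1 (unphased; -1 = missing call) and ``gq`` the per-genotype quality.
    """

    samples: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    gq: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_idx[sample]
        except KeyError:
            raise PedigreeError(f"unknown sample id {sample!r}") from None

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def sort(self) -> "GenotypeTable":
        """Return a copy sorted by (chrom, pos); needed after remapping."""
        order = self.sites.sort_values(["chrom", "pos"],
                                       kind="stable").index.to_numpy()
        return GenotypeTable(
            samples=list(self.samples),
            sites=self.sites.loc[order].reset_index(drop=True),
            gt=self.gt[order].copy(),
            gq=self.gq[order].copy(),
            chrom_lengths=dict(self.chrom_lengths),
        )


@dataclass
class Pedigree:
    """PED-style pedigree: individual, father, mother, sex (1=male 2=female).

    Missing parents are encoded as "0".
    """

    table: pd.DataFrame  # columns: iid, father, mother, sex

    def __post_init__(self) -> None:
        need = {"iid", "father", "mother", "sex"}
        if not need.issubset(self.table.columns):
            raise PedigreeError(f"pedigree table needs columns {sorted(need)}")
        self._by_iid = self.table.set_index("iid")

    @property
    def individuals(self) -> list[str]:
        return list(self.table["iid"])

    def sex_of(self, iid: str) -> int:
        if iid not in self._by_iid.index:
            raise PedigreeError(f"unknown individual {iid!r}")
        return int(self._by_iid.loc[iid, "sex"])

    def parents_of(self, iid: str) -> tuple[str, str]:
        if iid not in self._by_iid.index:
            raise PedigreeError(f"unknown individual {iid!r}")
        row = self._by_iid.loc[iid]
        return str(row["father"]), str(row["mother"])

    def offspring_of(self, parent: str) -> list[str]:
        if parent not in self._by_iid.index:
            raise PedigreeError(f"unknown parent id {parent!r}")
        t = self.table
        hit = (t["father"] == parent) | (t["mother"] == parent)
        return list(t.loc[hit, "iid"])

    def co_parent(self, focal: str, child: str) -> str:
        f, m = self.parents_of(child)
        if focal == f:
            return m
        if focal == m:
            return f
        raise PedigreeError(f"{focal!r} is not a parent of {child!r}")

    def sub_pedigrees(self) -> list[tuple[str, str, list[str]]]:
        """(father, mother, offspring) triples for every mated pair."""
        out: dict[tuple[str, str], list[str]] = {}
        for _, row in self.table.iterrows():
            f, m = str(row["father"]), str(row["mother"])
            if f != "0" and m != "0":
                out.setdefault((f, m), []).append(str(row["iid"]))
        return [(f, m, kids) for (f, m), kids in out.items()]


def is_strong_weak_pair(ref: str, alt: str) -> bool:
    """True when one allele is A/T and the other G/C (informative on gBGC)."""
    return (ref in STRONG) != (alt in STRONG)
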