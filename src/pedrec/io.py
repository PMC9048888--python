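"""Readers and writers for VCF, PED, BED, rate-map TSV and run manifests.

Internal coordinates are 1-based inclusive everywhere; BED output converts
to 0-based half-open at the boundary only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeTable, MISSING, Pedigree


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write biallelic SNP genotypes with GT and GQ fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in table.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        sites = table.sites
        for i in range(table.n_sites):
            cols = [str(sites.iloc[i]["chrom"]), str(int(sites.iloc[i]["pos"])),
                    ".", str(sites.iloc[i]["ref"]), str(sites.iloc[i]["alt"]),
                    ".", "PASS", ".", "GT:GQ"]
            for j in range(len(table.samples)):
                a, b = table.gt[i, j]
                gt = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                cols.append(f"{gt}:{table.gq[i, j]}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read biallelic SNPs with GT/GQ into a genotype table (via cyvcf2)."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    try:
        chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header has no contig length lines
        chrom_lengths = {}
    rows, gts, gqs = [], [], []
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        g = np.asarray(var.genotypes)[:, :2]
        g = np.where(g < 0, MISSING, g).astype(np.int8)
        gts.append(g)
        gq = var.format("GQ")
        if gq is None:
            gq = np.full(len(samples), 99)
        gqs.append(np.asarray(gq).reshape(-1).astype(np.int16))
    if not rows:
        raise FormatError(f"no biallelic SNPs in {path}")
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    table = GenotypeTable(samples=samples, sites=sites,
                          gt=np.stack(gts), gq=np.stack(gqs),
                          chrom_lengths=chrom_lengths)
    return table.sort()


# ---------------------------------------------------------------------------
# PED / BED / TSV
# ---------------------------------------------------------------------------

def write_ped(pedigree: Pedigree, path: str | Path,
              family_id: str = "FAM1") -> None:
    with Path(path).open("w") as fh:
        for _, row in pedigree.table.iterrows():
            fh.write(f"{family_id}\t{row['iid']}\t{row['father']}\t"
                     f"{row['mother']}\t{row['sex']}\t0\n")


def read_ped(path: str | Path) -> Pedigree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PED not found: {path}")
    rows = []
    ids = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns")
            rows.append((parts[1], parts[2], parts[3], int(parts[4])))
            ids.add(parts[1])
    for iid, father, mother, _ in rows:
        for p in (father, mother):
            if p != "0" and p not in ids:
                raise FormatError(f"unknown parent id {p!r} in {path}")
    return Pedigree(pd.DataFrame(
        rows, columns=["iid", "father", "mother", "sex"]))


def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start-1, end)."""
    return start_1based - 1, end_1based


def write_bed(intervals: Iterable[tuple], path: str | Path,
              extra_cols: bool = True) -> None:
    """Write (chrom, start_1based, end_1based, *rest) rows as BED."""
    with Path(path).open("w") as fh:
        for row in intervals:
            chrom, s, e, *rest = row
            b0, b1 = to_bed_interval(int(s), int(e))
            cols = [str(chrom), str(b0), str(b1)]
            if extra_cols:
                cols += [str(x) for x in rest]
            fh.write("\t".join(cols) + "\n")


def read_rate_map(path: str | Path) -> pd.DataFrame:
    """Read a TSV rate map (chrom, start, end, rate in cM/Mb)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rate map not found: {path}")
    df = pd.read_csv(path, sep="\t")
    from .stats import validate_rate_map
    return validate_rate_map(df)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mask_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED mask into per-chromosome 1-based inclusive intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            out.setdefault(parts[0], []).append(
                (int(parts[1]) + 1, int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, seed: int, config: dict,
                   outputs: Sequence[str | Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    with path.open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
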