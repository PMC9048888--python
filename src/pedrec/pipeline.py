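"""End-to-end orchestration: markers -> phasing -> COs -> anomalies -> NCOs
-> tract-length fit -> summary statistics.

Every stage writes its outputs under the configured directory and the run
finishes with a manifest (seed, config hash, output checksums) so that the
same configuration and seed reproduce byte-identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import anomalies as anom
from . import crossovers as xo
from . import io as pio
from . import markers, nco, phasing, stats, tractmodel
from .core import GenotypeTable, Pedigree

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    ped: str = ""
    mask_bed: str = ""
    rate_map: str = ""
    outdir: str = "pedrec_out"
    gq_min: int = markers.DEFAULT_GQ_MIN
    excess_het_sd: float = markers.DEFAULT_EXCESS_HET_SD
    end_trim: int = markers.DEFAULT_END_TRIM
    max_nco_span: int = xo.NCO_MAX_SPAN
    long_nco_max: int = xo.LONG_NCO_MAX_SPAN
    complex_window: int = nco.DEFAULT_COMPLEX_WINDOW
    co_window: int = nco.DEFAULT_CO_WINDOW
    nco_rate_per_bp: float = tractmodel.DEFAULT_NCO_RATE
    fit_tract_model: bool = False
    grid_stride: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    cos: list = field(default_factory=list)
    tracts: list = field(default_factory=list)
    anomaly_calls: list = field(default_factory=list)
    map_lengths: dict = field(default_factory=dict)
    informative_counts: dict = field(default_factory=dict)
    converted_counts: dict = field(default_factory=dict)
    mixture_fit: tractmodel.MixtureFit | None = None
    outputs: list = field(default_factory=list)


def detect_events(table: GenotypeTable, pedigree: Pedigree,
                  config: PipelineConfig,
                  mask: dict | None = None) -> RunReport:
    """Run marker selection, phasing and CO/NCO calling for every meiosis."""
    report = RunReport()
    subpeds = pedigree.sub_pedigrees()
    subped_size = {}
    for f, m, kids in subpeds:
        subped_size[f] = len(kids)
        subped_size[m] = len(kids)
    info_store = {}
    for father, mother, kids in subpeds:
        for focal in (father, mother):
            n_info_total = 0
            for chrom in table.chroms:
                sites = markers.select_informative(
                    table, pedigree, focal, chrom, offspring=kids,
                    gq_min=config.gq_min, excess_het_sd=config.excess_het_sd,
                    mask=(mask or {}).get(chrom))
                sites = markers.trim_chromosome_ends(sites, config.end_trim)
                if sites.n_sites < 2:
                    continue
                info_store[(focal, chrom)] = sites
                n_info_total += sites.n_sites
                result = phasing.infer_phase(sites)
                for vec in result.vectors:
                    report.cos.extend(xo.call_crossovers(
                        vec, config.max_nco_span, config.long_nco_max))
                    report.tracts.extend(nco.call_nco_tracts(
                        vec, sites, config.max_nco_span,
                        config.long_nco_max))
            report.informative_counts[focal] = n_info_total * len(kids)
    report.cos = xo.review_double_co_intervals(
        report.cos, table.chrom_lengths, subped_size)
    report.anomaly_calls = (
        anom.detect_inversions(report.cos)
        + anom.detect_misplaced_contigs(report.cos)
        + anom.detect_single_breaks(report.cos))
    report.tracts = nco.filter_nco(report.tracts, pedigree, table)
    report.tracts, _ = nco.classify_events(
        report.tracts, report.cos, config.complex_window, config.co_window)
    # map lengths by parent sex
    n_mei = {1: 0, 2: 0}
    n_co = {1: 0, 2: 0}
    for f, m, kids in subpeds:
        n_mei[1] += len(kids)
        n_mei[2] += len(kids)
    for co in report.cos:
        n_co[pedigree.sex_of(co.parent)] += 1
    if n_mei[1] and n_mei[2]:
        male = xo.map_length(n_co[1], n_mei[1])
        female = xo.map_length(n_co[2], n_mei[2])
        report.map_lengths = {
            "male_cM": male, "female_cM": female,
            "sex_averaged_cM": xo.sex_averaged_map_length(male, female)}
    for t in report.tracts:
        report.converted_counts[t.parent] = (
            report.converted_counts.get(t.parent, 0) + t.n_sites)
    report.info_store = info_store  # type: ignore[attr-defined]
    return report


def build_kmer_data(report: RunReport, table: GenotypeTable,
                    config: PipelineConfig) -> tractmodel.KmerData:
    """Assemble likelihood inputs from calls and informative-site lists."""
    info_store = getattr(report, "info_store")
    obs = []
    converted: dict[tuple[str, str, str], set[int]] = {}
    for t in report.tracts:
        if t.cls == "long" or t.min_length > config.max_nco_span:
            continue
        obs.append(tractmodel.TractObservation(
            t.left_flank, t.first, t.last, t.right_flank,
            meiosis=f"{t.parent}:{t.offspring}", chrom=t.chrom))
        converted.setdefault((t.parent, t.offspring, t.chrom),
                             set()).update(t.converted)
    # one exclusion summary per (meiosis, chromosome)
    nonconv = []
    for (focal, chrom), sites in info_store.items():
        for off in sites.offspring:
            conv = converted.get((focal, off, chrom), set())
            keep = [int(p) for p in sites.positions if int(p) not in conv]
            nonconv.append((keep, table.chrom_lengths[chrom]))
    return tractmodel.KmerData.build(
        obs, nonconv, t_max=config.max_nco_span,
        rate_per_bp=config.nco_rate_per_bp)


def run_pipeline(config: PipelineConfig,
                 table: GenotypeTable | None = None,
                 pedigree: Pedigree | None = None) -> RunReport:
    """Execute the full pipeline and write all outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None or pedigree is None:
        if not Path(config.vcf).exists():
            raise FileNotFoundError(f"input VCF not found: {config.vcf}")
        table = pio.read_vcf(config.vcf)
        pedigree = pio.read_ped(config.ped)
    mask = pio.read_mask_bed(config.mask_bed) if config.mask_bed else None

    report = detect_events(table, pedigree, config, mask)

    co_rows = [(c.chrom, c.left, c.right, f"{c.parent}:{c.offspring}",
                c.status) for c in report.cos]
    co_path = outdir / "crossovers.bed"
    pio.write_bed(co_rows, co_path)
    tract_rows = [{
        "chrom": t.chrom, "parent": t.parent, "offspring": t.offspring,
        "first": t.first, "last": t.last, "min_length": t.min_length,
        "n_sites": t.n_sites, "left_flank": t.left_flank,
        "right_flank": t.right_flank, "class": t.cls,
        "co_associated": t.co_associated,
        "gc_to_strong": t.gc_to_strong, "gc_to_weak": t.gc_to_weak,
    } for t in report.tracts]
    nco_path = outdir / "nco_tracts.tsv"
    pio.write_tsv(pd.DataFrame(tract_rows), nco_path)
    anom_rows = [{
        "kind": a.kind, "chrom": a.chrom, "start": a.start, "end": a.end,
        "n_meioses": a.n_meioses} for a in report.anomaly_calls]
    anom_path = outdir / "anomalies.tsv"
    pio.write_tsv(pd.DataFrame(anom_rows), anom_path)
    map_path = outdir / "map_lengths.tsv"
    pio.write_tsv(pd.DataFrame([report.map_lengths]), map_path)
    outputs = [co_path, nco_path, anom_path, map_path]

    if config.fit_tract_model and report.tracts:
        data = build_kmer_data(report, table, config)
        if len(data.tracts) >= 2:
            fit = tractmodel.fit_mixture(data, grid_stride=config.grid_stride)
            report.mixture_fit = fit
            fit_path = outdir / "tract_model_fit.json"
            with fit_path.open("w") as fh:
                json.dump({"alpha": fit.alpha, "m1": fit.m1, "m2": fit.m2,
                           "loglik": fit.loglik, "ci_m1": fit.ci_m1,
                           "ci_m2": fit.ci_m2}, fh, indent=2)
            outputs.append(fit_path)

    pio.write_manifest(outdir, config.seed, config.to_dict(), outputs)
    report.outputs = [str(p) for p in outputs]
    return report
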