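"""Orchestration of the full selection scan, with individually runnable stages.

Stages: ``pi_fst`` (windowed theta-pi / FST scan and joint top-5% outliers),
``xpclr`` (composite-likelihood scan and top-1% outliers), ``daf`` (per-SNP
delta-AF screen), ``regions`` (merge outliers, attach genes, combine gene
lists, summarize).  ``regions`` consumes the scan results of the same run
when present, and otherwise re-reads the selected-window BED files a previous
run left in the output directory, so the pipeline is a thin composition of
stages rather than a monolith.

All tabular outputs are TSV with a header line and ``#``-prefixed provenance
comments; floats are printed at six significant digits so identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .core import (
    GeneAnnotation,
    GenotypeMatrix,
    InputError,
    PopulationMap,
    Window,
    make_windows,
    read_bed_genes,
    read_contig_lengths,
    read_gff3_genes,
    read_popmap,
    read_vcf,
)
from .daf import DeltaAfRecord, delta_af, filter_high_daf
from .diversity import (
    WindowStatRecord,
    joint_outliers,
    pi_fst_scan,
    single_stat_outliers,
)
from .regions import (
    RegionSummary,
    SweepRegion,
    assign_genes,
    combine_gene_lists,
    genes_of,
    intersect_regions,
    merge_windows,
    summarize_regions,
)
from .xpclr import XpclrParams, XpclrWindowResult, estimate_omega, xpclr_scan

logger = logging.getLogger("sweepscan")

ALL_STAGES = ("pi_fst", "xpclr", "daf", "regions")


@dataclass(frozen=True)
class PipelineConfig:
    vcf: str
    popmap: str
    genes: str | None = None            # GFF3 (.gff/.gff3) or BED
    out_dir: str = "sweepscan_out"
    focal: str = "NY"
    reference: str = "Others"
    window_size: int = 40_000
    step: int = 20_000
    joint_tail: float = 0.05            # "top 5%" joint pi-ratio/FST rule
    xpclr_window: int = 10_000
    xpclr_tail: float = 0.01            # "top 1%" XP-CLR rule
    daf_cutoff: float = 0.7
    exclude_chroms: tuple[str, ...] = ("Z", "W")
    min_snps: int = 10
    max_missing: float = 1.0
    venn_mode: str = "two-set"          # or "three-set"
    omega: float | None = None          # None -> estimate from the data
    rho: float = 3e-8
    q0: float = 0.005
    ld_r2_cutoff: float = 0.95
    max_snps_per_window: int = 200
    integration_points: int = 1000
    flank: int = 50_000

    def __post_init__(self) -> None:
        for tail in (self.joint_tail, self.xpclr_tail):
            if not (0.0 < tail < 1.0):
                raise InputError(f"quantile tail must be in (0, 1), got {tail}")
        if self.venn_mode not in ("two-set", "three-set"):
            raise InputError(
                f"venn_mode must be 'two-set' or 'three-set', got {self.venn_mode!r}"
            )


@dataclass
class PipelineResult:
    config: PipelineConfig
    paths: dict[str, str] = field(default_factory=dict)
    window_records: list[WindowStatRecord] | None = None
    joint_selected: list[WindowStatRecord] | None = None
    fst_threshold: float | None = None
    ratio_threshold: float | None = None
    xpclr_results: list[XpclrWindowResult] | None = None
    xpclr_selected: list[XpclrWindowResult] | None = None
    xpclr_threshold: float | None = None
    omega_hat: float | None = None
    regions_pifst: list[SweepRegion] | None = None
    regions_xpclr: list[SweepRegion] | None = None
    regions_intersection: list[SweepRegion] | None = None
    genes_union: list[str] | None = None
    genes_intersection: list[str] | None = None
    daf_records: list[DeltaAfRecord] | None = None
    daf_high: list[DeltaAfRecord] | None = None
    summaries: dict[str, RegionSummary] | None = None


def _fmt(x: float) -> str:
    if x != x:  # NaN
        return "NA"
    return f"{x:.6g}"


_PATH_FIELDS = ("vcf", "popmap", "genes", "out_dir")


def _provenance(config: PipelineConfig) -> str:
    # paths are reduced to basenames so identical analyses produce
    # byte-identical outputs regardless of where they run
    fields = asdict(config)
    fields.pop("out_dir", None)
    for key in _PATH_FIELDS:
        if fields.get(key):
            fields[key] = os.path.basename(str(fields[key]))
    items = " ".join(f"{k}={v}" for k, v in sorted(fields.items()))
    return f"# sweepscan {__version__}\n# config: {items}\n"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(
    config: PipelineConfig,
) -> tuple[GenotypeMatrix, dict[str, int], PopulationMap, list[GeneAnnotation]]:
    matrix = read_vcf(config.vcf)
    chrom_lengths = read_contig_lengths(config.vcf)
    popmap = read_popmap(config.popmap, config.focal, config.reference)
    known = set(matrix.sample_ids)
    dropped = [s for s in popmap.assignments if s not in known]
    if dropped:
        logger.warning("popmap samples absent from VCF are ignored: %s", ", ".join(dropped))
        popmap = PopulationMap(
            {s: p for s, p in popmap.assignments.items() if s in known},
            config.focal, config.reference,
        )
    matrix = matrix.drop_chroms(config.exclude_chroms)
    chrom_lengths = {
        c: length
        for c, length in chrom_lengths.items()
        if c not in set(config.exclude_chroms)
    }
    genes: list[GeneAnnotation] = []
    if config.genes:
        if config.genes.endswith((".bed", ".bed.gz")):
            genes = read_bed_genes(config.genes)
        else:
            genes = read_gff3_genes(config.genes)
    return matrix, chrom_lengths, popmap, genes


def _read_selected_bed(path: str) -> list[Window]:
    if not os.path.exists(path):
        raise InputError(
            f"{path} not found: run the corresponding scan stage first"
        )
    windows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            windows.append(Window(chrom, int(start), int(end)))
    return windows


def _attach_peaks(
    regions: list[SweepRegion],
    records: list[WindowStatRecord] | None = None,
    xpclr: list[XpclrWindowResult] | None = None,
) -> None:
    for reg in regions:
        if records is not None:
            inside = [
                rec for rec in records
                if rec.valid and rec.window.chrom == reg.chrom
                and rec.window.start < reg.end and reg.start < rec.window.end
            ]
            if inside:
                reg.peak_stats["max_fst"] = max(rec.fst for rec in inside)
                reg.peak_stats["max_log2_ratio"] = max(rec.log2_pi_ratio for rec in inside)
        if xpclr is not None:
            inside_x = [
                res for res in xpclr
                if res.valid and res.window.chrom == reg.chrom
                and res.window.start < reg.end and reg.start < res.window.end
            ]
            if inside_x:
                reg.peak_stats["max_xpclr"] = max(res.score for res in inside_x)


def _write_daf_table(path: str, prov: str, records: list[DeltaAfRecord],
                     extra_comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(prov)
        if extra_comment:
            fh.write(extra_comment)
        fh.write("chrom\tpos\tref\talt\ttracked_allele\taf_focal\taf_ref\tdelta_af\n")
        for rec in records:
            v = rec.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{rec.tracked_allele}\t{_fmt(rec.af_focal)}\t"
                f"{_fmt(rec.af_reference)}\t{_fmt(rec.delta_af)}\n"
            )


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> PipelineResult:
    """Execute the requested stages, writing the result bundle to ``out_dir``."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}")
    os.makedirs(config.out_dir, exist_ok=True)
    result = PipelineResult(config=config)
    prov = _provenance(config)

    def out(name: str) -> str:
        result.paths[name] = os.path.join(config.out_dir, name)
        return result.paths[name]

    logger.info("stage: input")
    matrix, chrom_lengths, popmap, genes = _load_inputs(config)
    scanned_bp = sum(chrom_lengths.values())

    if "pi_fst" in stages:
        logger.info("stage: pi/fst scan")
        windows = make_windows(chrom_lengths, config.window_size, config.step)
        records = pi_fst_scan(
            matrix, popmap, windows,
            min_snps=config.min_snps, max_missing=config.max_missing,
        )
        joint_sel, fst_thr, ratio_thr = joint_outliers(records, config.joint_tail)
        result.window_records = records
        result.joint_selected = joint_sel
        result.fst_threshold = fst_thr
        result.ratio_threshold = ratio_thr

        with open(out("pi_fst_windows.tsv"), "w") as fh:
            fh.write(prov)
            fh.write(f"# thresholds: fst>={_fmt(fst_thr)} log2_ratio>={_fmt(ratio_thr)}\n")
            fh.write("chrom\tstart\tend\tn_snps\tpi_focal\tpi_ref\tlog2_ratio\tfst\tvalid\n")
            for rec in records:
                w = rec.window
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{rec.n_snps_used}\t"
                    f"{_fmt(rec.theta_pi_focal)}\t{_fmt(rec.theta_pi_reference)}\t"
                    f"{_fmt(rec.log2_pi_ratio)}\t{_fmt(rec.fst)}\t{int(rec.valid)}\n"
                )
        with open(out("pi_fst_selected.bed"), "w") as fh:
            for rec in joint_sel:
                w = rec.window
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\tjoint\t{_fmt(rec.fst)}\t.\n")

    if "xpclr" in stages:
        logger.info("stage: xp-clr scan")
        omega_hat = config.omega if config.omega is not None else estimate_omega(matrix, popmap)
        params = XpclrParams(
            omega=omega_hat, rho=config.rho, q0=config.q0,
            ld_r2_cutoff=config.ld_r2_cutoff,
            max_snps_per_window=config.max_snps_per_window,
            integration_points=config.integration_points, flank=config.flank,
        )
        xpclr_results, xpclr_thr, xpclr_sel = xpclr_scan(
            matrix, popmap, params, window_size=config.xpclr_window,
            chrom_lengths=chrom_lengths, upper_tail=config.xpclr_tail,
        )
        result.xpclr_results = xpclr_results
        result.xpclr_selected = xpclr_sel
        result.xpclr_threshold = xpclr_thr
        result.omega_hat = omega_hat

        with open(out("xpclr_windows.tsv"), "w") as fh:
            fh.write(prov)
            fh.write(f"# omega={_fmt(omega_hat)} threshold>={_fmt(xpclr_thr)}\n")
            fh.write("chrom\tstart\tend\tn_snps\tscore\ts_hat\tvalid\n")
            for res in xpclr_results:
                w = res.window
                fh.write(
                    f"{w.chrom}\t{w.start}\t{w.end}\t{res.n_snps_used}\t"
                    f"{_fmt(res.score)}\t{_fmt(res.s_hat)}\t{int(res.valid)}\n"
                )
        with open(out("xpclr_selected.bed"), "w") as fh:
            for res in xpclr_sel:
                w = res.window
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\txpclr\t{_fmt(res.score)}\t.\n")

    if "daf" in stages:
        logger.info("stage: delta-AF")
        daf_records = delta_af(matrix, popmap)
        daf_high = filter_high_daf(daf_records, config.daf_cutoff)
        result.daf_records = daf_records
        result.daf_high = daf_high
        _write_daf_table(out("daf.tsv"), prov, daf_records)
        _write_daf_table(out("daf_high.tsv"), prov, daf_high,
                         f"# cutoff: delta_af > {_fmt(config.daf_cutoff)}\n")

    if "regions" in stages:
        logger.info("stage: regions and genes")
        if result.joint_selected is not None:
            joint_windows = [rec.window for rec in result.joint_selected]
        else:
            joint_windows = _read_selected_bed(
                os.path.join(config.out_dir, "pi_fst_selected.bed")
            )
        if result.xpclr_selected is not None:
            xpclr_windows = [res.window for res in result.xpclr_selected]
        else:
            xpclr_windows = _read_selected_bed(
                os.path.join(config.out_dir, "xpclr_selected.bed")
            )

        regions_pifst = merge_windows(joint_windows, source="pi_fst")
        regions_xpclr = merge_windows(xpclr_windows, source="xpclr")
        regions_both = intersect_regions(regions_pifst, regions_xpclr, source="intersection")
        for regs in (regions_pifst, regions_xpclr, regions_both):
            assign_genes(regs, genes)
        _attach_peaks(regions_pifst, records=result.window_records)
        _attach_peaks(regions_xpclr, xpclr=result.xpclr_results)
        _attach_peaks(regions_both, records=result.window_records,
                      xpclr=result.xpclr_results)

        if config.venn_mode == "two-set" or result.window_records is None:
            gene_sets = [genes_of(regions_pifst), genes_of(regions_xpclr)]
        else:
            fst_sel, _ = single_stat_outliers(result.window_records, "fst", config.joint_tail)
            ratio_sel, _ = single_stat_outliers(
                result.window_records, "log2_pi_ratio", config.joint_tail
            )
            fst_regions = assign_genes(merge_windows([r.window for r in fst_sel]), genes)
            ratio_regions = assign_genes(merge_windows([r.window for r in ratio_sel]), genes)
            gene_sets = [
                genes_of(fst_regions), genes_of(ratio_regions), genes_of(regions_xpclr)
            ]
        genes_union = combine_gene_lists(*gene_sets, mode="union")
        genes_inter = combine_gene_lists(*gene_sets, mode="intersection")

        summaries = {
            "pi_fst": summarize_regions(regions_pifst, scanned_bp),
            "xpclr": summarize_regions(regions_xpclr, scanned_bp),
            "intersection": summarize_regions(regions_both, scanned_bp),
        }
        result.regions_pifst = regions_pifst
        result.regions_xpclr = regions_xpclr
        result.regions_intersection = regions_both
        result.genes_union = genes_union
        result.genes_intersection = genes_inter
        result.summaries = summaries

        def write_regions(name: str, regs: list[SweepRegion]) -> None:
            with open(out(name), "w") as fh:
                for reg in regs:
                    if "max_xpclr" in reg.peak_stats:
                        score = reg.peak_stats["max_xpclr"]
                    else:
                        score = 1000.0 * reg.peak_stats.get("max_fst", 0.0)
                    gene_str = ",".join(reg.genes) if reg.genes else "."
                    fh.write(
                        f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.source}\t"
                        f"{_fmt(score)}\t.\t{gene_str}\n"
                    )

        write_regions("regions_pifst.bed", regions_pifst)
        write_regions("regions_xpclr.bed", regions_xpclr)
        write_regions("regions_intersection.bed", regions_both)

        for name, gene_list in (
            ("genes_pifst.tsv", sorted(genes_of(regions_pifst))),
            ("genes_xpclr.tsv", sorted(genes_of(regions_xpclr))),
            ("genes_union.tsv", genes_union),
            ("genes_intersection.tsv", genes_inter),
        ):
            with open(out(name), "w") as fh:
                fh.write("".join(f"{g}\n" for g in gene_list))

        with open(out("summary.tsv"), "w") as fh:
            fh.write(prov)
            fh.write("source\tkey\tvalue\n")
            for source, summ in summaries.items():
                fh.write(f"{source}\tn_regions\t{summ.n_regions}\n")
                fh.write(f"{source}\ttotal_bp\t{summ.total_bp}\n")
                fh.write(
                    f"{source}\tfraction_of_scanned_genome\t"
                    f"{_fmt(summ.fraction_of_scanned_genome)}\n"
                )
                fh.write(f"{source}\tmean_length_bp\t{_fmt(summ.mean_length_bp)}\n")
                fh.write(f"{source}\tn_chromosomes\t{summ.n_chromosomes}\n")
                fh.write(f"{source}\tn_genes\t{summ.n_genes}\n")

    manifest = {
        "version": __version__,
        "stages": list(stages),
        "config": asdict(config),
        "inputs": {
            name: _sha256(path)
            for name, path in (("vcf", config.vcf), ("popmap", config.popmap),
                               ("genes", config.genes))
            if path
        },
        "scanned_bp": scanned_bp,
        "omega_hat": result.omega_hat,
        "thresholds": {
            "fst": result.fst_threshold,
            "log2_ratio": result.ratio_threshold,
            "xpclr": result.xpclr_threshold,
        },
        "n_joint_selected": None if result.joint_selected is None else len(result.joint_selected),
        "n_xpclr_selected": None if result.xpclr_selected is None else len(result.xpclr_selected),
        "n_daf_high": None if result.daf_high is None else len(result.daf_high),
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return result
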