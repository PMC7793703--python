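"""Merge outlier windows into sweep regions, attach genes, and summarize.

Overlapping or book-ended (end == start) outlier windows on one chromosome
merge into maximal intervals — with a step of half the window size,
consecutive outlier windows share signal and belong to one region.  A gene is
attached to a region iff their half-open intervals overlap by at least 1 bp.
Candidate gene lists from different statistics combine by plain set union or
intersection at the gene-ID level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import ComputationError, GeneAnnotation, Window

logger = logging.getLogger("sweepscan")


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    source: str = ""
    peak_stats: dict[str, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSummary:
    n_regions: int
    total_bp: int
    fraction_of_scanned_genome: float
    mean_length_bp: float
    n_chromosomes: int
    n_genes: int


def merge_windows(windows: list[Window], source: str = "") -> list[SweepRegion]:
    """Union of overlapping/book-ended windows into maximal regions."""
    regions: list[SweepRegion] = []
    for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.end)):
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, w.end)
        else:
            regions.append(SweepRegion(w.chrom, w.start, w.end, source=source))
    return regions


def intersect_regions(a: list[SweepRegion], b: list[SweepRegion], source: str = "") -> list[SweepRegion]:
    """Interval intersection of two merged region sets (>= 1 bp overlaps)."""
    out: list[SweepRegion] = []
    by_chrom: dict[str, list[SweepRegion]] = {}
    for reg in b:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    for reg in a:
        for other in by_chrom.get(reg.chrom, []):
            lo = max(reg.start, other.start)
            hi = min(reg.end, other.end)
            if lo < hi:
                out.append(SweepRegion(reg.chrom, lo, hi, source=source))
    return sorted(out, key=lambda r: (r.chrom, r.start))


def assign_genes(regions: list[SweepRegion], genes: list[GeneAnnotation]) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp (in place; returns regions)."""
    genes_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    missing_chroms: set[str] = set()
    for reg in regions:
        pool = genes_by_chrom.get(reg.chrom)
        if pool is None:
            missing_chroms.add(reg.chrom)
            reg.genes = []
            continue
        reg.genes = sorted(
            {g.gene_id for g in pool if g.start < reg.end and reg.start < g.end}
        )
    if missing_chroms:
        logger.warning("assign_genes: no annotation for chromosome(s) %s",
                       ", ".join(sorted(missing_chroms)))
    return regions


def genes_of(regions: list[SweepRegion]) -> set[str]:
    out: set[str] = set()
    for reg in regions:
        out.update(reg.genes)
    return out


def combine_gene_lists(*gene_sets: set[str], mode: str = "union") -> list[str]:
    """Union or intersection of candidate gene sets, deterministically sorted."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    if not gene_sets:
        return []
    if mode == "union":
        out = set().union(*gene_sets)
    else:
        out = set(gene_sets[0]).intersection(*gene_sets[1:])
    return sorted(out)


def summarize_regions(regions: list[SweepRegion], scanned_genome_bp: int) -> RegionSummary:
    """Counts, total span, genome fraction, mean length, chromosomes, genes."""
    if scanned_genome_bp <= 0:
        raise ComputationError("summarize_regions: scanned_genome_bp must be > 0")
    total = sum(reg.length for reg in regions)
    return RegionSummary(
        n_regions=len(regions),
        total_bp=total,
        fraction_of_scanned_genome=total / scanned_genome_bp,
        mean_length_bp=total / len(regions) if regions else 0.0,
        n_chromosomes=len({reg.chrom for reg in regions}),
        n_genes=len(genes_of(regions)),
    )
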