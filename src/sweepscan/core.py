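"""Domain types, genotype storage, window machinery, and on-disk format I/O.

Internal coordinate convention: 0-based half-open ``[start, end)`` everywhere.
VCF (1-based) and GFF3 (1-based inclusive) are converted at the boundary.
Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with
``MISSING = -1``; missing data are handled per site through reduced allele
counts and are never imputed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("sweepscan")

#: Sentinel dosage for a missing (or half-called) genotype.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


class InputError(ValueError):
    """Unreadable, malformed, or inconsistent user input (CLI exit code 2)."""


class ComputationError(RuntimeError):
    """A statistical stage cannot produce a result (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic SNP locus. ``pos`` is 1-based, as printed in VCF."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP x sample table of alternate-allele dosages.

    Rows are sorted by ``(chrom, pos)`` with no duplicate positions.
    ``dosages`` is an int8 array of shape ``(n_variants, n_samples)`` holding
    values in ``{0, 1, 2, MISSING}``.
    """

    chroms: np.ndarray          # shape (n_variants,), dtype object/str
    pos: np.ndarray             # shape (n_variants,), 1-based, int64
    ref: np.ndarray             # shape (n_variants,)
    alt: np.ndarray             # shape (n_variants,)
    dosages: np.ndarray         # shape (n_variants, n_samples), int8
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chroms) == len(self.ref) == len(self.alt) == n):
            raise ValueError("variant field arrays have inconsistent lengths")
        if self.dosages.shape != (n, len(self.sample_ids)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{n} variants x {len(self.sample_ids)} samples"
            )
        order = np.lexsort((self.pos, self.chroms))
        if not np.array_equal(order, np.arange(n)):
            self.chroms = self.chroms[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.dosages = self.dosages[order]
        key = list(zip(self.chroms.tolist(), self.pos.tolist()))
        if len(set(key)) != n:
            raise ValueError("duplicate (chrom, pos) records in matrix")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def variants(self) -> list[Variant]:
        return [
            Variant(c, int(p), r, a)
            for c, p, r, a in zip(self.chroms, self.pos, self.ref, self.alt)
        ]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise InputError(f"sample {exc.args[0]!r} not present in matrix") from None

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant ``(alt_count, non_missing_allele_count)`` for a sample subset."""
        d = self.dosages if sample_idx is None else self.dosages[:, sample_idx]
        miss = d == MISSING
        alt = np.where(miss, 0, d).sum(axis=1)
        n = 2 * (~miss).sum(axis=1)
        return alt.astype(np.int64), n.astype(np.int64)

    def drop_chroms(self, names: Iterable[str]) -> "GenotypeMatrix":
        """Matrix without the named chromosomes (e.g. sex chromosomes)."""
        names = set(names)
        keep = np.array([c not in names for c in self.chroms], dtype=bool)
        if keep.all():
            return self
        if not keep.any():
            raise InputError("chromosome exclusion removed every SNP")
        return GenotypeMatrix(
            self.chroms[keep], self.pos[keep], self.ref[keep],
            self.alt[keep], self.dosages[keep], list(self.sample_ids),
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (rows are chrom-sorted)."""
        out: dict[str, slice] = {}
        if self.n_variants == 0:
            return out
        chroms = self.chroms
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out


@dataclass
class PopulationMap:
    """Sample-to-population assignment defining focal and reference panels."""

    assignments: dict[str, str]
    focal_label: str
    reference_label: str

    def __post_init__(self) -> None:
        if self.focal_label == self.reference_label:
            raise InputError("focal and reference labels must differ")
        if not self.focal_samples:
            raise InputError(f"no samples assigned to focal label {self.focal_label!r}")
        if not self.reference_samples:
            raise InputError(f"no samples assigned to reference label {self.reference_label!r}")

    @property
    def focal_samples(self) -> list[str]:
        return [s for s, p in self.assignments.items() if p == self.focal_label]

    @property
    def reference_samples(self) -> list[str]:
        return [s for s, p in self.assignments.items() if p == self.reference_label]


@dataclass(frozen=True, order=True)
class Window:
    """Half-open genomic interval ``[start, end)`` in 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, stored 0-based half-open after format conversion."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str, keep_samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (plain or gzipped) into a GenotypeMatrix.

    Multi-allelic records, indels, and non-ACGT alleles are dropped.
    ``./.`` and half-calls become :data:`MISSING`.  Records are sorted by
    ``(chrom, pos)``; duplicate positions keep the first record seen.
    """
    import os

    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise InputError(f"VCF file not found: {path}")
    vcf = VCF(path)
    if keep_samples is not None:
        missing = [s for s in keep_samples if s not in vcf.samples]
        if missing:
            raise InputError(f"samples not in VCF header: {', '.join(missing)}")
        vcf.set_samples(list(keep_samples))
    samples = list(vcf.samples)

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF not in _NUCLEOTIDES
            or rec.ALT[0] not in _NUCLEOTIDES
        ):
            n_dropped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col = phasing
        alleles = gts[:, :-1]
        row = alleles.sum(axis=1, dtype=np.int64)
        row[(alleles < 0).any(axis=1)] = MISSING
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        rows.append(row.astype(np.int8))
    vcf.close()

    if not rows:
        raise InputError(f"no biallelic SNPs retained from {path}")
    logger.info("read_vcf: kept %d biallelic SNPs, dropped %d records", len(rows), n_dropped)

    chroms_a = np.array(chroms, dtype=object)
    pos_a = np.array(pos, dtype=np.int64)
    ref_a = np.array(ref, dtype=object)
    alt_a = np.array(alt, dtype=object)
    dos = np.vstack(rows)

    # drop duplicate (chrom, pos), keeping first occurrence
    seen: set[tuple[str, int]] = set()
    keep = np.ones(len(pos_a), dtype=bool)
    for i, k in enumerate(zip(chroms_a, pos_a)):
        k = (str(k[0]), int(k[1]))
        if k in seen:
            keep[i] = False
        seen.add(k)
    if not keep.all():
        logger.warning("read_vcf: dropped %d duplicate (chrom,pos) records", (~keep).sum())
        chroms_a, pos_a, ref_a, alt_a, dos = (
            chroms_a[keep], pos_a[keep], ref_a[keep], alt_a[keep], dos[keep]
        )

    return GenotypeMatrix(chroms_a, pos_a, ref_a, alt_a, dos, samples)


def read_contig_lengths(path: str) -> dict[str, int]:
    """Chromosome lengths from a VCF's contig header lines.

    Contigs without a declared length fall back to the maximum record
    position on that chromosome.
    """
    import os

    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise InputError(f"VCF file not found: {path}")
    vcf = VCF(path)
    try:
        lengths = {
            name: int(length)
            for name, length in zip(vcf.seqnames, vcf.seqlens)
            if length > 0
        }
    except Exception:
        lengths = {}
    missing = [n for n in vcf.seqnames if n not in lengths]
    if missing or not lengths:
        maxpos: dict[str, int] = {}
        for rec in vcf:
            if rec.CHROM not in lengths:
                maxpos[rec.CHROM] = max(maxpos.get(rec.CHROM, 0), rec.POS)
        lengths.update(maxpos)
        logger.warning(
            "read_contig_lengths: undeclared contig lengths; using max record positions"
        )
    vcf.close()
    return lengths


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a GenotypeMatrix as plain-text VCF v4.2 with GT-only records."""
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(matrix.pos[matrix.chroms == c].max())
            for c in dict.fromkeys(matrix.chroms.tolist())
        }
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for name, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for i in range(matrix.n_variants):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosages[i])
            fh.write(
                f"{matrix.chroms[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Popmap
# ---------------------------------------------------------------------------

def read_popmap(path: str, focal: str, reference: str) -> PopulationMap:
    """Read a two-column ``sample<TAB>population`` TSV (no header).

    Samples with labels other than ``focal``/``reference`` are dropped with a
    warning; labels are case-sensitive.
    """
    import os

    if not os.path.exists(path):
        raise InputError(f"popmap file not found: {path}")
    assignments: dict[str, str] = {}
    n_other = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            sample, pop = parts[0], parts[1]
            if pop in (focal, reference):
                assignments[sample] = pop
            else:
                n_other += 1
    if n_other:
        logger.warning("read_popmap: excluded %d samples with other labels", n_other)
    return PopulationMap(assignments, focal_label=focal, reference_label=reference)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(
    chrom_lengths: Mapping[str, int], size: int, step: int | None = None
) -> list[Window]:
    """Sliding windows of ``size`` bp every ``step`` bp, full windows only.

    Windows start at 0 on each chromosome; a window is emitted only when it
    fits entirely (``start + size <= length``), keeping per-bp statistics
    comparable across windows.  ``step`` defaults to ``size`` (non-overlapping).
    """
    if step is None:
        step = size
    if size <= 0:
        raise ValueError(f"window size must be > 0, got {size}")
    if not (0 < step <= size):
        raise ValueError(
            f"step must be in (0, size]; step={step} size={size} would leave gaps"
        )
    windows: list[Window] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 0:
            raise ValueError(f"negative length for chromosome {chrom}")
        start = 0
        while start + size <= length:
            windows.append(Window(chrom, start, start + size))
            start += step
    return windows


def assign_snps_to_windows(
    matrix: GenotypeMatrix, windows: Sequence[Window]
) -> dict[Window, np.ndarray]:
    """Map each window to the (global) row indices of SNPs it contains.

    A SNP at 1-based position p lies in ``[start, end)`` iff
    ``start <= p - 1 < end``; with 40 kb / 20 kb sliding windows an interior
    SNP therefore belongs to exactly two windows.
    """
    slices = matrix.chrom_slices()
    out: dict[Window, np.ndarray] = {}
    for w in windows:
        sl = slices.get(w.chrom)
        if sl is None:
            out[w] = np.array([], dtype=np.intp)
            continue
        pos0 = matrix.pos[sl] - 1  # 0-based
        lo = np.searchsorted(pos0, w.start, side="left")
        hi = np.searchsorted(pos0, w.end, side="left")
        out[w] = np.arange(sl.start + lo, sl.start + hi, dtype=np.intp)
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def _collapse_duplicates(records: list[GeneAnnotation]) -> list[GeneAnnotation]:
    by_id: dict[str, GeneAnnotation] = {}
    n_dup = 0
    for g in records:
        prev = by_id.get(g.gene_id)
        if prev is None:
            by_id[g.gene_id] = g
        else:
            n_dup += 1
            if prev.chrom != g.chrom:
                logger.warning(
                    "gene %s appears on %s and %s; keeping first record",
                    g.gene_id, prev.chrom, g.chrom,
                )
                continue
            by_id[g.gene_id] = GeneAnnotation(
                g.gene_id, g.chrom, min(prev.start, g.start),
                max(prev.end, g.end), prev.strand,
            )
    if n_dup:
        logger.warning("collapsed %d duplicate gene records to spanning intervals", n_dup)
    return sorted(by_id.values(), key=lambda g: (g.chrom, g.start, g.end))


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path: str, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read gene records from GFF3; 1-based inclusive [s, e] -> [s-1, e)."""
    records: list[GeneAnnotation] = []
    n_bad = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature_type:
                continue
            chrom, _, _, s, e, _, strand = fields[0], fields[1], fields[2], fields[3], fields[4], fields[5], fields[6]
            start1, end1 = int(s), int(e)
            if end1 < start1:
                n_bad += 1
                continue
            attrs = _parse_gff3_attributes(fields[8])
            gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            if gene_id is None:
                n_bad += 1
                continue
            records.append(GeneAnnotation(gene_id, chrom, start1 - 1, end1, strand))
    if n_bad:
        logger.warning("read_gff3_genes: skipped %d malformed records", n_bad)
    return _collapse_duplicates(records)


def read_bed_genes(path: str) -> list[GeneAnnotation]:
    """Read gene intervals from BED4+ (already 0-based half-open)."""
    records: list[GeneAnnotation] = []
    n_bad = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                n_bad += 1
                continue
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                n_bad += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "."
            records.append(GeneAnnotation(fields[3], fields[0], start, end, strand))
    if n_bad:
        logger.warning("read_bed_genes: skipped %d malformed records", n_bad)
    return _collapse_duplicates(records)
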