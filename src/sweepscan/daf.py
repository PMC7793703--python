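"""Per-SNP absolute allele-frequency difference (delta-AF).

Each SNP is polarized on the focal population's major allele: the tracked
allele is whichever allele reaches at least half of the focal panel's
non-missing alleles (exact 50/50 ties break to the alternate allele, a fixed
deterministic choice).  delta-AF is then the absolute difference between the
tracked allele's frequencies in the focal and reference panels; by
construction the focal frequency is >= 0.5 and delta-AF lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, PopulationMap, Variant

logger = logging.getLogger("sweepscan")


@dataclass(frozen=True)
class DeltaAfRecord:
    variant: Variant
    tracked_allele: str     # "ref" or "alt"
    af_focal: float         # frequency of the focal-major allele, >= 0.5
    af_reference: float     # frequency of the same allele in the reference panel
    delta_af: float


def polarize_by_focal_major(dosages_focal) -> str | None:
    """Return "alt" or "ref" for the focal-major allele; None if all missing."""
    d = np.asarray(dosages_focal)
    ok = d != -1
    n = 2 * int(ok.sum())
    if n == 0:
        return None
    alt = int(d[ok].sum())
    return "alt" if alt * 2 >= n else "ref"


def delta_af(matrix: GenotypeMatrix, popmap: PopulationMap) -> list[DeltaAfRecord]:
    """delta-AF for every biallelic SNP; SNPs all-missing in a panel are skipped."""
    fi = matrix.sample_indices(popmap.focal_samples)
    ri = matrix.sample_indices(popmap.reference_samples)
    alt_f, n_f = matrix.allele_counts(fi)
    alt_r, n_r = matrix.allele_counts(ri)
    ok = (n_f > 0) & (n_r > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("delta_af: skipped %d SNPs with an all-missing panel", n_skipped)

    p_alt_f = alt_f / np.maximum(n_f, 1)
    p_alt_r = alt_r / np.maximum(n_r, 1)
    track_alt = 2 * alt_f >= n_f  # ties to alt

    records: list[DeltaAfRecord] = []
    for i in np.flatnonzero(ok):
        if track_alt[i]:
            af_f, af_r = p_alt_f[i], p_alt_r[i]
            allele = "alt"
        else:
            af_f, af_r = 1.0 - p_alt_f[i], 1.0 - p_alt_r[i]
            allele = "ref"
        records.append(
            DeltaAfRecord(
                Variant(str(matrix.chroms[i]), int(matrix.pos[i]),
                        str(matrix.ref[i]), str(matrix.alt[i])),
                allele, float(af_f), float(af_r), float(abs(af_f - af_r)),
            )
        )
    return records


def filter_high_daf(records: list[DeltaAfRecord], cutoff: float = 0.7) -> list[DeltaAfRecord]:
    """SNPs with delta-AF strictly above the cutoff, sorted by (chrom, pos)."""
    out = [rec for rec in records if rec.delta_af > cutoff]
    return sorted(out, key=lambda rec: (rec.variant.chrom, rec.variant.pos))
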