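"""Windowed nucleotide diversity, log2 theta-pi ratio, Weir-Cockerham FST,
and the joint empirical-outlier rule.

Per-site diversity uses the unbiased mean pairwise difference
``2 * c0 * c1 / (n * (n - 1))`` over the ``n`` non-missing alleles; window
diversity is the per-site sum divided by the fixed window length in bp, so
monomorphic and unsequenced bases contribute zero to the numerator only.
FST uses the Weir & Cockerham (1984) variance components ``a`` (among
populations), ``b`` (among individuals within populations) and ``c`` (within
individuals) with ``r = 2`` populations, combined over a window as the
ratio of sums ``sum(a) / sum(a + b + c)``.  Negative windowed values are
retained for ranking.  "Top x%" selections use the nearest-rank rule:
threshold = k-th largest value with ``k = ceil(x * W)``, and the selected set
is every window >= the threshold (ties can make it larger than k).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    ComputationError,
    GenotypeMatrix,
    PopulationMap,
    Window,
    assign_snps_to_windows,
)

logger = logging.getLogger("sweepscan")


@dataclass
class WindowStatRecord:
    window: Window
    n_snps_used: int
    theta_pi_focal: float
    theta_pi_reference: float
    log2_pi_ratio: float        # NaN when invalid
    fst: float                  # NaN when invalid
    valid: bool


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham variance components and their intermediates."""

    a: float
    b: float
    c: float
    n_bar: float = 0.0
    n_c: float = 0.0
    p_bar: float = 0.0
    s2: float = 0.0
    h_bar: float = 0.0


# ---------------------------------------------------------------------------
# Per-site estimators
# ---------------------------------------------------------------------------

def site_pi(dosages_one_pop) -> float:
    """Unbiased per-site pi from one population's dosages; NaN if < 2 alleles."""
    d = np.asarray(dosages_one_pop)
    ok = d != MISSING
    n = 2 * int(ok.sum())
    if n < 2:
        return float("nan")
    c1 = int(d[ok].sum())
    c0 = n - c1
    return 2.0 * c0 * c1 / (n * (n - 1))


def _pop_site_arrays(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant (alt_count, allele_n, het_count) for one population."""
    miss = dosages == MISSING
    alt = np.where(miss, 0, dosages).sum(axis=1).astype(np.float64)
    n = 2.0 * (~miss).sum(axis=1)
    het = (dosages == 1).sum(axis=1).astype(np.float64)
    return alt, n, het


def _site_pi_vector(dosages: np.ndarray) -> np.ndarray:
    alt, n, _ = _pop_site_arrays(dosages)
    out = np.full(len(n), np.nan)
    ok = n >= 2
    c1 = alt[ok]
    c0 = n[ok] - c1
    out[ok] = 2.0 * c0 * c1 / (n[ok] * (n[ok] - 1.0))
    return out


def site_fst_components(dosages_focal, dosages_reference) -> FstComponents | None:
    """Weir-Cockerham (1984) two-population components at one site.

    Returns None when either population has no non-missing diploid or when
    the mean sample size does not support the finite-sample corrections
    (n_bar <= 1).  Observed heterozygosity comes from dosage == 1 counts.
    """
    a, b, c, extras = _fst_component_vectors(
        np.asarray(dosages_focal)[None, :], np.asarray(dosages_reference)[None, :]
    )
    if math.isnan(a[0]):
        return None
    return FstComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]),
        n_bar=float(extras["n_bar"][0]), n_c=float(extras["n_c"][0]),
        p_bar=float(extras["p_bar"][0]), s2=float(extras["s2"][0]),
        h_bar=float(extras["h_bar"][0]),
    )


def _fst_component_vectors(
    dos_focal: np.ndarray, dos_reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Vectorized W&C components over all variants; NaN rows are unusable sites."""
    alt1, m1, het1 = _pop_site_arrays(dos_focal)
    alt2, m2, het2 = _pop_site_arrays(dos_reference)
    n1, n2 = m1 / 2.0, m2 / 2.0          # diploid counts
    usable = (n1 >= 1) & (n2 >= 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(m1 > 0, alt1 / np.where(m1 > 0, m1, 1), np.nan)
        p2 = np.where(m2 > 0, alt2 / np.where(m2 > 0, m2, 1), np.nan)
        h1 = np.where(n1 > 0, het1 / np.where(n1 > 0, n1, 1), np.nan)
        h2 = np.where(n2 > 0, het2 / np.where(n2 > 0, n2, 1), np.nan)

        r = 2.0
        n_bar = (n1 + n2) / r
        usable &= n_bar > 1
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        usable &= n_c > 0
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    mono = (p_bar == 0.0) | (p_bar == 1.0)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    bad = ~usable
    a[bad] = np.nan
    b[bad] = np.nan
    c[bad] = np.nan
    return a, b, c, {"n_bar": n_bar, "n_c": n_c, "p_bar": p_bar, "s2": s2, "h_bar": h_bar}


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def window_pi(
    matrix: GenotypeMatrix, popmap: PopulationMap, window: Window, population: str
) -> float:
    """Per-bp theta-pi for one window and one population label."""
    if population == popmap.focal_label:
        idx = matrix.sample_indices(popmap.focal_samples)
    elif population == popmap.reference_label:
        idx = matrix.sample_indices(popmap.reference_samples)
    else:
        raise ValueError(f"unknown population label {population!r}")
    snps = assign_snps_to_windows(matrix, [window])[window]
    if len(snps) == 0:
        return 0.0
    pis = _site_pi_vector(matrix.dosages[np.ix_(snps, idx)])
    return float(np.nansum(pis)) / window.length


def log2_pi_ratio(theta_ref: float, theta_focal: float) -> float:
    """log2(theta_ref / theta_focal); NaN (invalid) when either is zero."""
    if theta_ref <= 0.0 or theta_focal <= 0.0:
        return float("nan")
    return math.log2(theta_ref / theta_focal)


def window_fst(components: list[FstComponents]) -> float:
    """Ratio-of-sums windowed FST; NaN when the denominator is zero."""
    num = sum(comp.a for comp in components)
    den = sum(comp.a + comp.b + comp.c for comp in components)
    if den == 0.0:
        return float("nan")
    return num / den


def pi_fst_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    min_snps: int = 10,
    max_missing: float = 1.0,
) -> list[WindowStatRecord]:
    """Windowed theta-pi (both populations), log2 ratio, and W&C FST.

    SNPs with a missing-genotype fraction above ``max_missing`` are excluded
    from all window statistics.  A window is valid when it holds at least
    ``min_snps`` usable SNPs, both diversities are positive (so the log2 ratio
    is finite), and the FST denominator is nonzero.
    """
    fi = matrix.sample_indices(popmap.focal_samples)
    ri = matrix.sample_indices(popmap.reference_samples)
    dos_f = matrix.dosages[:, fi]
    dos_r = matrix.dosages[:, ri]

    miss_frac = (matrix.dosages[:, np.concatenate([fi, ri])] == MISSING).mean(axis=1)
    keep = miss_frac <= max_missing
    if not keep.all():
        logger.info("pi_fst_scan: excluded %d SNPs above max-missing %.3g",
                    int((~keep).sum()), max_missing)

    pi_f = _site_pi_vector(dos_f)
    pi_r = _site_pi_vector(dos_r)
    a, b, c, _ = _fst_component_vectors(dos_f, dos_r)
    usable = keep & ~np.isnan(a)
    pi_f = np.where(keep, pi_f, np.nan)
    pi_r = np.where(keep, pi_r, np.nan)

    assignment = assign_snps_to_windows(matrix, windows)
    records: list[WindowStatRecord] = []
    for w in windows:
        idx = assignment[w]
        use = idx[usable[idx]]
        n_used = int(len(use))
        tp_f = float(np.nansum(pi_f[idx])) / w.length
        tp_r = float(np.nansum(pi_r[idx])) / w.length
        num = float(a[use].sum()) if n_used else 0.0
        den = float((a[use] + b[use] + c[use]).sum()) if n_used else 0.0
        fst = num / den if den != 0.0 else float("nan")
        ratio = log2_pi_ratio(tp_r, tp_f)
        valid = n_used >= min_snps and math.isfinite(ratio) and math.isfinite(fst)
        records.append(
            WindowStatRecord(w, n_used, tp_f, tp_r, ratio, fst, valid)
        )
    return records


# ---------------------------------------------------------------------------
# Empirical outlier calling
# ---------------------------------------------------------------------------

def empirical_threshold(values, upper_tail: float) -> float:
    """Nearest-rank upper-tail threshold: the k-th largest with k = ceil(tail * W)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ComputationError("empirical_threshold: no values supplied")
    if not np.isfinite(vals).all():
        raise ComputationError("empirical_threshold: values must be finite")
    if not (0.0 < upper_tail < 1.0):
        raise ValueError(f"upper_tail must be in (0, 1), got {upper_tail}")
    k = math.ceil(upper_tail * vals.size)
    return float(np.sort(vals)[::-1][k - 1])


def joint_outliers(
    records: list[WindowStatRecord], upper_tail: float = 0.05
) -> tuple[list[WindowStatRecord], float, float]:
    """Windows simultaneously in the upper tail of both FST and the log2 ratio.

    Returns ``(selected_records, fst_threshold, ratio_threshold)``.  Only
    valid windows enter the ranking; selection uses >= on both thresholds.
    """
    valid = [rec for rec in records if rec.valid]
    if not valid:
        raise ComputationError("joint_outliers: no valid windows")
    fst_thr = empirical_threshold([rec.fst for rec in valid], upper_tail)
    ratio_thr = empirical_threshold([rec.log2_pi_ratio for rec in valid], upper_tail)
    selected = [
        rec for rec in valid if rec.fst >= fst_thr and rec.log2_pi_ratio >= ratio_thr
    ]
    logger.info(
        "joint_outliers: thresholds fst >= %.4g, log2-ratio >= %.4g; %d of %d windows",
        fst_thr, ratio_thr, len(selected), len(valid),
    )
    return selected, fst_thr, ratio_thr


def single_stat_outliers(
    records: list[WindowStatRecord], stat: str, upper_tail: float = 0.05
) -> tuple[list[WindowStatRecord], float]:
    """Upper-tail outliers on a single statistic ("fst" or "log2_pi_ratio")."""
    valid = [rec for rec in records if rec.valid]
    if not valid:
        raise ComputationError("single_stat_outliers: no valid windows")
    values = [getattr(rec, stat) for rec in valid]
    thr = empirical_threshold(values, upper_tail)
    return [rec for rec in valid if getattr(rec, stat) >= thr], thr
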