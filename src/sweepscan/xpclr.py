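"""Cross-population composite-likelihood-ratio (XP-CLR) sweep scan.

Model.  For a SNP with reference-population frequency ``p1`` of a tracked
allele, the test-population frequency ``y`` after drift is Gaussian with mean
``p1`` and variance ``omega * p1 * (1 - p1)``; density mass falling below 0 or
above 1 collapses onto the boundaries (loss / fixation).  The observed count
``k2`` of the tracked allele among ``m2`` sampled alleles is binomial given
``y``.  Under a hard sweep with selection coefficient ``s`` at recombination
distance ``r`` (Morgans), a neutral lineage escapes the sweeping haplotype
with probability ``c = 1 - q0 ** (r / s)``; conditioning on whether the
tracked allele rode the sweep mixes the binomial success probability between
``1 - c + c*y`` (rode, probability ``y``) and ``c*y`` (escaped).

The per-window score is ``2 * max_s sum_j w_j * (logL_sweep - logL_neutral)``
with LD weights ``w_j`` down-weighting locally duplicated SNPs, maximized
over a grid of ``s`` that includes the neutral point ``s = 0`` (where the
sweep kernel reduces to the neutral kernel exactly), so scores are
non-negative.  Likelihood integrals use a fixed grid of equal cells with
exact Gaussian cell masses and a two-point in-cell rule for the binomial
factor, so the outcome distribution stays normalized by construction.

The scan is deterministic: no randomness anywhere, and the per-window SNP cap
subsamples every k-th SNP by position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr

from .core import (
    MISSING,
    ComputationError,
    GenotypeMatrix,
    PopulationMap,
    Window,
    make_windows,
)
from .diversity import empirical_threshold

logger = logging.getLogger("sweepscan")

_LOG_FLOOR = math.log(1e-300)
# SNPs whose escape probability is this close to 1 are fully unlinked from the
# sweep: their sweep and neutral likelihoods agree to < ~1e-6, so they are
# skipped when accumulating the composite log-likelihood difference.
_C_NEUTRAL_CUTOFF = 1.0 - 1e-6


def _default_s_grid() -> tuple[float, ...]:
    return tuple([0.0] + list(np.logspace(-5, math.log10(0.5), 20)))


@dataclass(frozen=True)
class XpclrParams:
    """Tunable parameters of the XP-CLR scan.

    omega : drift variance coefficient (estimate with :func:`estimate_omega`)
    rho   : recombination rate, Morgans/bp (3e-8 ~ 3 cM/Mb, typical of
            chicken macrochromosomes)
    q0    : initial beneficial-allele frequency of the hitchhiking model
    s_grid: selection coefficients searched; must include the neutral point 0
    """

    omega: float = 0.05
    rho: float = 3e-8
    q0: float = 0.005
    s_grid: tuple[float, ...] = field(default_factory=_default_s_grid)
    ld_r2_cutoff: float = 0.95
    max_snps_per_window: int = 200
    integration_points: int = 1000
    flank: int = 50_000
    min_snps: int = 2

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if not (0 < self.q0 < 1):
            raise ValueError("q0 must be in (0, 1)")
        if any(s < 0 for s in self.s_grid) or list(self.s_grid) != sorted(self.s_grid):
            raise ValueError("s_grid must be sorted and non-negative")
        if not (0 < self.ld_r2_cutoff <= 1):
            raise ValueError("ld_r2_cutoff must be in (0, 1]")
        if self.integration_points < 10:
            raise ValueError("integration_points must be >= 10")


@dataclass(frozen=True)
class XpclrSnpInput:
    """One SNP as seen by the likelihood kernels.

    p1 is the reference-population sample frequency of the tracked allele;
    k2 of m2 sampled alleles in the test population carry it; r_j is the
    genetic distance (Morgans) to the putative sweep site; w_j the LD weight.
    """

    position: int
    p1: float
    k2: int
    m2: int
    r_j: float = 0.0
    w_j: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0):
            raise ValueError("p1 must be in [0, 1]")
        if not (0 <= self.k2 <= self.m2):
            raise ValueError("need 0 <= k2 <= m2")
        if self.r_j < 0 or not (0.0 < self.w_j <= 1.0):
            raise ValueError("invalid r_j or w_j")


@dataclass
class XpclrWindowResult:
    window: Window
    score: float        # 2 * max_s composite log-likelihood difference; NaN if invalid
    s_hat: float        # maximizing s (smallest on ties); NaN if invalid
    n_snps_used: int
    valid: bool


# ---------------------------------------------------------------------------
# Drift-coefficient estimation
# ---------------------------------------------------------------------------

def estimate_omega(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    maf_bounds: tuple[float, float] = (0.1, 0.9),
) -> float:
    """Method-of-moments drift coefficient from genome-wide frequencies.

    Over SNPs whose reference-population frequency lies inside ``maf_bounds``,
    averages ``[(p1 - p2)^2 - p1(1-p1)/m1 - p2(1-p2)/m2] / [p1(1-p1)]`` — the
    squared frequency difference with the binomial sampling noise of both
    panels removed, scaled by the drift variance unit.  Floored at 1e-6.
    """
    ri = matrix.sample_indices(popmap.reference_samples)
    fi = matrix.sample_indices(popmap.focal_samples)
    alt1, m1 = matrix.allele_counts(ri)
    alt2, m2 = matrix.allele_counts(fi)
    ok = (m1 > 0) & (m2 > 0)
    p1 = np.where(ok, alt1 / np.maximum(m1, 1), np.nan)
    p2 = np.where(ok, alt2 / np.maximum(m2, 1), np.nan)
    inside = ok & (p1 > maf_bounds[0]) & (p1 < maf_bounds[1])
    if inside.sum() == 0:
        raise ComputationError(
            "estimate_omega: no SNPs inside the MAF bounds; supply omega manually"
        )
    if inside.sum() < 1000:
        logger.warning("estimate_omega: only %d qualifying SNPs (< 1000); "
                       "estimate may be noisy", int(inside.sum()))
    p1, p2 = p1[inside], p2[inside]
    m1, m2 = m1[inside], m2[inside]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / m1 - p2 * (1 - p2) / m2
    omega = float(np.mean(num / (p1 * (1 - p1))))
    return max(omega, 1e-6)


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------

def escape_probability(r_j: float, s: float, q0: float) -> float:
    """c = 1 - q0 ** (r/s), clipped to [0, 1]; c = 1 at s = 0, c = 0 at r = 0."""
    if s == 0.0:
        return 1.0
    if r_j == 0.0:
        return 0.0
    return float(np.clip(1.0 - q0 ** (r_j / s), 0.0, 1.0))


def _gaussian_parts(p1: np.ndarray, omega: float, n_points: int):
    """Fixed-grid quadrature rule for the drift Gaussian, per SNP.

    The unit interval is split into ``n_points`` equal cells.  Each cell
    contributes its exact Gaussian mass (CDF difference) — so the cell
    weights plus the below-0 / above-1 boundary masses sum to one at machine
    precision and the likelihood kernels stay normalized by construction —
    and the smooth factor is evaluated at the two points ``mu_c +/- sd_c``
    given by the cell's truncated-normal mean and standard deviation, which
    reproduces the in-cell expectation exactly through second order.

    Returns ``(weights, y_lo, y_hi, mass0, mass1)`` with the first three of
    shape ``(n_snps, n_points)``.  Zero-variance rows (p1 in {0, 1}) get zero
    cell weights and all mass on the corresponding boundary.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    n = len(p1)
    sd = np.sqrt(omega * p1 * (1.0 - p1))
    edges = np.arange(n_points + 1) / n_points
    mids = 0.5 * (edges[:-1] + edges[1:])
    weights = np.zeros((n, n_points))
    y_lo = np.tile(mids, (n, 1))
    y_hi = y_lo.copy()
    mass0 = np.zeros(n)
    mass1 = np.zeros(n)
    pos = sd > 0
    if pos.any():
        s = sd[pos, None]
        z = (edges[None, :] - p1[pos, None]) / s
        cdf = ndtr(z)
        sf = ndtr(-z)  # survival keeps relative precision in the upper tail
        pdf = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        d = np.where(
            z[:, :-1] + z[:, 1:] > 0,
            sf[:, :-1] - sf[:, 1:],
            np.diff(cdf, axis=1),
        )
        ok = d > 1e-300
        dd = np.where(ok, d, 1.0)
        ratio = (pdf[:, :-1] - pdf[:, 1:]) / dd
        mu = p1[pos, None] + s * ratio
        var = (s * s) * np.maximum(
            1.0 + (z[:, :-1] * pdf[:, :-1] - z[:, 1:] * pdf[:, 1:]) / dd - ratio * ratio,
            0.0,
        )
        half = np.sqrt(var)
        lo = np.clip(np.where(ok, mu - half, y_lo[pos]), 0.0, 1.0)
        hi = np.clip(np.where(ok, mu + half, y_hi[pos]), 0.0, 1.0)
        weights[pos] = np.where(ok, d, 0.0)
        y_lo[pos] = lo
        y_hi[pos] = hi
        mass0[pos] = cdf[:, 0]
        mass1[pos] = sf[:, -1]
    # degenerate rows: all mass at p1 itself (0 or 1)
    mass0[~pos & (p1 <= 0.5)] = 1.0
    mass1[~pos & (p1 > 0.5)] = 1.0
    return weights, y_lo, y_hi, mass0, mass1


def _binom_log_pmf(k: np.ndarray, m: np.ndarray, p: np.ndarray) -> np.ndarray:
    """log Binom(k; m, p) broadcast over a (n_snps, n_nodes) success grid.

    Probabilities are clipped into [1e-300, 1 - 1e-16]; with non-negative
    exponents this reproduces the exact limits (0 or 1) after exponentiation
    without the 0 * log(0) indeterminacy.
    """
    lc = (gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1))[:, None]
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return lc + k[:, None] * np.log(p) + (m - k)[:, None] * np.log1p(-p)


def _sweep_from_parts(parts, k2: np.ndarray, m2: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Sweep likelihoods from precomputed Gaussian quadrature parts."""
    w, y_lo, y_hi, mass0, mass1 = parts
    c = np.atleast_1d(np.asarray(c, dtype=float))[:, None]

    def mixture(y: np.ndarray) -> np.ndarray:
        rode = np.exp(_binom_log_pmf(k2, m2, 1.0 - c + c * y))
        escaped = np.exp(_binom_log_pmf(k2, m2, c * y))
        return y * rode + (1.0 - y) * escaped

    L = (w * 0.5 * (mixture(y_lo) + mixture(y_hi))).sum(axis=1)
    L += mass0 * (k2 == 0) + mass1 * (k2 == m2)
    return L


def _neutral_likelihoods(
    p1: np.ndarray, k2: np.ndarray, m2: np.ndarray, omega: float, n_points: int
) -> np.ndarray:
    """Vector of neutral likelihoods L (not logged), one per SNP."""
    w, y_lo, y_hi, mass0, mass1 = _gaussian_parts(p1, omega, n_points)
    pmf = 0.5 * (
        np.exp(_binom_log_pmf(k2, m2, y_lo)) + np.exp(_binom_log_pmf(k2, m2, y_hi))
    )
    L = (w * pmf).sum(axis=1)
    L += mass0 * (k2 == 0) + mass1 * (k2 == m2)
    # zero-variance rows: binomial at p1 exactly
    p1 = np.atleast_1d(p1)
    deg = (p1 <= 0.0) | (p1 >= 1.0)
    if deg.any():
        L[deg] = np.exp(
            _binom_log_pmf(k2[deg], m2[deg], p1[deg][:, None])[:, 0]
        )
    return L


def _sweep_likelihoods(
    p1: np.ndarray, k2: np.ndarray, m2: np.ndarray, c: np.ndarray,
    omega: float, n_points: int,
) -> np.ndarray:
    """Vector of sweep likelihoods for per-SNP escape probabilities ``c``."""
    parts = _gaussian_parts(p1, omega, n_points)
    L = _sweep_from_parts(parts, k2, m2, c)
    p1 = np.atleast_1d(p1)
    deg = (p1 <= 0.0) | (p1 >= 1.0)
    if deg.any():
        # delta at y = p1: same rode/escape mixture evaluated at the point
        yd = p1[deg][:, None]
        cd = np.atleast_1d(np.asarray(c, dtype=float))[deg][:, None]
        ld = yd * np.exp(_binom_log_pmf(k2[deg], m2[deg], 1.0 - cd + cd * yd)) \
            + (1.0 - yd) * np.exp(_binom_log_pmf(k2[deg], m2[deg], cd * yd))
        L[deg] = ld[:, 0]
    return L


def neutral_loglik(snp: XpclrSnpInput, params: XpclrParams) -> float:
    """log L under pure drift, floored at log(1e-300)."""
    L = _neutral_likelihoods(
        np.array([snp.p1]), np.array([snp.k2]), np.array([snp.m2]),
        params.omega, params.integration_points,
    )[0]
    return max(math.log(L) if L > 0 else -math.inf, _LOG_FLOOR)


def sweep_loglik(snp: XpclrSnpInput, s: float, params: XpclrParams) -> float:
    """log L under a sweep with coefficient ``s``; equals neutral at c = 1."""
    c = escape_probability(snp.r_j, s, params.q0)
    if c == 1.0:
        return neutral_loglik(snp, params)
    L = _sweep_likelihoods(
        np.array([snp.p1]), np.array([snp.k2]), np.array([snp.m2]),
        np.array([c]), params.omega, params.integration_points,
    )[0]
    return max(math.log(L) if L > 0 else -math.inf, _LOG_FLOOR)


# ---------------------------------------------------------------------------
# LD weights
# ---------------------------------------------------------------------------

def ld_weights(ref_dosages: np.ndarray, r2_cutoff: float) -> np.ndarray:
    """w_j = 1 / (1 + #partners with genotypic r^2 >= cutoff) within the SNP set.

    Correlations use reference-population dosages with pairwise-complete
    samples; zero-variance SNPs correlate with nothing.
    """
    n_snps = ref_dosages.shape[0]
    if n_snps == 0:
        return np.array([])
    d = np.ma.masked_equal(ref_dosages.astype(float), MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(d)
    r2 = np.asarray(np.ma.filled(corr, 0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    n_linked = (r2 >= r2_cutoff).sum(axis=1)
    return 1.0 / (1.0 + n_linked)


# ---------------------------------------------------------------------------
# Windowed scan
# ---------------------------------------------------------------------------

def _tracked_allele_data(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (p1, k2, m2, usable) with the reference minor allele tracked."""
    ri = matrix.sample_indices(popmap.reference_samples)
    fi = matrix.sample_indices(popmap.focal_samples)
    alt_r, m_r = matrix.allele_counts(ri)
    alt_f, m_f = matrix.allele_counts(fi)
    ok = (m_r > 0) & (m_f > 0)
    p_alt_r = np.where(ok, alt_r / np.maximum(m_r, 1), np.nan)
    track_alt = p_alt_r <= 0.5  # ties go to alt
    p1 = np.where(track_alt, p_alt_r, 1.0 - p_alt_r)
    k2 = np.where(track_alt, alt_f, m_f - alt_f)
    usable = ok & (p1 > 0.0) & (p1 < 1.0)  # monomorphic-in-reference carries no CLR signal
    return p1, k2.astype(np.int64), m_f.astype(np.int64), usable


def xpclr_window(
    window: Window, snps: list[XpclrSnpInput], params: XpclrParams
) -> XpclrWindowResult:
    """Score one window from prepared SNP inputs (sweep site at the midpoint)."""
    if len(snps) < params.min_snps:
        return XpclrWindowResult(window, float("nan"), float("nan"), len(snps), False)
    p1 = np.array([s.p1 for s in snps])
    k2 = np.array([s.k2 for s in snps])
    m2 = np.array([s.m2 for s in snps])
    r = np.array([s.r_j for s in snps])
    w = np.array([s.w_j for s in snps])
    score, s_hat = _score_window(p1, k2, m2, r, w, params)
    return XpclrWindowResult(window, score, s_hat, len(snps), True)


def _score_window(
    p1: np.ndarray, k2: np.ndarray, m2: np.ndarray, r: np.ndarray,
    w: np.ndarray, params: XpclrParams, neut_ll: np.ndarray | None = None,
) -> tuple[float, float]:
    if neut_ll is None:
        L = _neutral_likelihoods(p1, k2, m2, params.omega, params.integration_points)
        neut_ll = np.maximum(np.log(np.maximum(L, 1e-300)), _LOG_FLOOR)
    # the Gaussian quadrature rule depends only on p1, not on s: build it once
    parts = _gaussian_parts(p1, params.omega, params.integration_points)
    best = 0.0
    best_s = 0.0
    found = False
    for s in params.s_grid:
        if s == 0.0:
            diff_sum = 0.0
        else:
            with np.errstate(over="ignore"):
                c = np.clip(1.0 - params.q0 ** (r / s), 0.0, 1.0)
            c[r == 0.0] = 0.0
            active = c < _C_NEUTRAL_CUTOFF
            if not active.any():
                diff_sum = 0.0
            else:
                sub = (parts[0][active], parts[1][active], parts[2][active],
                       parts[3][active], parts[4][active])
                Ls = _sweep_from_parts(sub, k2[active], m2[active], c[active])
                sw_ll = np.maximum(np.log(np.maximum(Ls, 1e-300)), _LOG_FLOOR)
                diff_sum = float((w[active] * (sw_ll - neut_ll[active])).sum())
        if not found or diff_sum > best:
            best = diff_sum
            best_s = s
            found = True
    return 2.0 * best, best_s


def xpclr_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    params: XpclrParams,
    window_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    upper_tail: float = 0.01,
) -> tuple[list[XpclrWindowResult], float, list[XpclrWindowResult]]:
    """Genome scan over non-overlapping windows.

    Each window is scored with the putative sweep site at its midpoint, using
    all usable SNPs within ``params.flank`` bp of that midpoint (hitchhiking
    information extends well beyond a 10 kb window), down-weighted for local
    LD and capped at ``max_snps_per_window`` by deterministic every-k-th
    subsampling.  Returns ``(all_results, top-1% threshold, selected)``.
    """
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(matrix.pos[matrix.chroms == c].max())
            for c in dict.fromkeys(matrix.chroms.tolist())
        }
    windows = make_windows(chrom_lengths, window_size, window_size)
    p1, k2, m2, usable = _tracked_allele_data(matrix, popmap)
    ri = matrix.sample_indices(popmap.reference_samples)
    slices = matrix.chrom_slices()

    # neutral log-likelihood is window-independent: compute once per SNP
    neut_ll_all = np.full(matrix.n_variants, np.nan)
    idx_all = np.flatnonzero(usable)
    for chunk in np.array_split(idx_all, max(1, len(idx_all) // 4096)):
        if len(chunk) == 0:
            continue
        L = _neutral_likelihoods(p1[chunk], k2[chunk], m2[chunk],
                                 params.omega, params.integration_points)
        neut_ll_all[chunk] = np.maximum(np.log(np.maximum(L, 1e-300)), _LOG_FLOOR)

    results: list[XpclrWindowResult] = []
    for win in windows:
        sl = slices.get(win.chrom)
        if sl is None:
            results.append(XpclrWindowResult(win, float("nan"), float("nan"), 0, False))
            continue
        pos0 = matrix.pos[sl] - 1
        mid = win.midpoint
        lo = np.searchsorted(pos0, mid - params.flank, side="left")
        hi = np.searchsorted(pos0, mid + params.flank, side="right")
        idx = np.arange(sl.start + lo, sl.start + hi, dtype=np.intp)
        idx = idx[usable[idx]]
        if len(idx) > params.max_snps_per_window:
            stride = math.ceil(len(idx) / params.max_snps_per_window)
            idx = idx[::stride]
        if len(idx) < params.min_snps:
            results.append(XpclrWindowResult(win, float("nan"), float("nan"), len(idx), False))
            continue
        r = np.abs((matrix.pos[idx] - 1) - mid) * params.rho
        w = ld_weights(matrix.dosages[np.ix_(idx, ri)], params.ld_r2_cutoff)
        score, s_hat = _score_window(
            p1[idx], k2[idx], m2[idx], r, w, params, neut_ll=neut_ll_all[idx]
        )
        results.append(XpclrWindowResult(win, score, s_hat, len(idx), True))

    scores = [res.score for res in results if res.valid]
    if not scores:
        raise ComputationError("xpclr_scan: no valid windows")
    threshold = empirical_threshold(scores, upper_tail)
    selected = [res for res in results if res.valid and res.score >= threshold]
    logger.info("xpclr_scan: %d/%d valid windows, top-1%% threshold %.4g, %d selected",
                len(scores), len(results), threshold, len(selected))
    return results, threshold, selected
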