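import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom, norm

import sweepscan as ss
from sweepscan.xpclr import (
    XpclrParams,
    XpclrSnpInput,
    _neutral_likelihoods,
    _sweep_likelihoods,
)

from conftest import build_matrix, split_popmap


def adaptive_neutral_oracle(p1, k2, m2, omega):
    """Neutral drift likelihood by adaptive quadrature (scipy.integrate.quad)."""
    sd = math.sqrt(omega * p1 * (1 - p1))
    f = lambda y: binom.pmf(k2, m2, y) * norm.pdf(y, p1, sd)
    I, _ = quad(f, 0, 1, limit=400, points=[max(0.0, p1 - 5 * sd), p1, min(1.0, p1 + 5 * sd)])
    return I + norm.cdf(0, p1, sd) * (k2 == 0) + norm.sf(1, p1, sd) * (k2 == m2)


def adaptive_sweep_oracle(p1, k2, m2, c, omega):
    """Hitchhiking-mixture likelihood by adaptive quadrature."""
    sd = math.sqrt(omega * p1 * (1 - p1))
    f = lambda y: (
        y * binom.pmf(k2, m2, 1 - c + c * y) + (1 - y) * binom.pmf(k2, m2, c * y)
    ) * norm.pdf(y, p1, sd)
    I, _ = quad(f, 0, 1, limit=400, points=[max(0.0, p1 - 5 * sd), p1, min(1.0, p1 + 5 * sd)])
    return I + norm.cdf(0, p1, sd) * (k2 == 0) + norm.sf(1, p1, sd) * (k2 == m2)


class TestEscapeProbability:
    def test_closed_form_value(self):
        # 1 - exp((r/s) * ln q0) at r=0.003 M, s=0.1, q0=0.005
        expected = 1.0 - math.exp((0.003 / 0.1) * math.log(0.005))
        assert ss.escape_probability(0.003, 0.1, 0.005) == pytest.approx(expected)
        assert expected == pytest.approx(0.147, abs=5e-4)

    def test_neutral_limit(self):
        for r in (0.0, 1e-5, 0.3):
            assert ss.escape_probability(r, 0.0, 0.005) == 1.0

    def test_zero_distance(self):
        for s in (1e-5, 0.1, 0.5):
            assert ss.escape_probability(0.0, s, 0.005) == 0.0


class TestLikelihoodKernels:
    def test_delta_limit_small_omega(self):
        params = XpclrParams(omega=1e-8)
        snp = XpclrSnpInput(position=1, p1=0.5, k2=12, m2=30)
        assert ss.neutral_loglik(snp, params) == pytest.approx(
            math.log(binom.pmf(12, 30, 0.5)), abs=1e-4
        )

    def test_neutral_matches_adaptive_oracle(self):
        params = XpclrParams(omega=0.05)
        snp = XpclrSnpInput(position=1, p1=0.5, k2=15, m2=30)
        mine = math.exp(ss.neutral_loglik(snp, params))
        assert mine == pytest.approx(adaptive_neutral_oracle(0.5, 15, 30, 0.05), rel=1e-4)

    @pytest.mark.parametrize("p1", [0.05, 0.5])
    @pytest.mark.parametrize("omega", [0.01, 0.3])
    def test_outcome_distribution_normalized(self, p1, omega):
        m2 = 30
        k = np.arange(m2 + 1)
        for c in (0.0, 0.5, 1.0):
            L = _sweep_likelihoods(
                np.full(m2 + 1, p1), k, np.full(m2 + 1, m2), np.full(m2 + 1, c),
                omega, 1000,
            )
            assert L.sum() == pytest.approx(1.0, abs=1e-6)

    def test_sweep_equals_neutral_at_c_one(self):
        params = XpclrParams(omega=0.05)
        snp = XpclrSnpInput(position=1, p1=0.3, k2=5, m2=30, r_j=0.01)
        # s = 0 -> c = 1 -> exact neutral reduction
        assert ss.sweep_loglik(snp, 0.0, params) == ss.neutral_loglik(snp, params)

    def test_full_hitchhike_fixes_or_loses_allele(self):
        # c = 0: the allele is fixed iff it rode the sweep, P(k2 = m2) ~ E[y]
        params = XpclrParams(omega=1e-4)
        snp = XpclrSnpInput(position=1, p1=0.5, k2=30, m2=30, r_j=0.0)
        L = math.exp(ss.sweep_loglik(snp, 0.5, params))
        assert L == pytest.approx(0.5, abs=0.01)

    def test_degenerate_reference_frequency(self):
        params = XpclrParams(omega=0.05)
        snp = XpclrSnpInput(position=1, p1=0.0, k2=0, m2=30)
        assert ss.neutral_loglik(snp, params) == pytest.approx(0.0)
        snp2 = XpclrSnpInput(position=1, p1=0.0, k2=3, m2=30)
        assert ss.neutral_loglik(snp2, params) == math.log(1e-300)


class TestOmegaEstimation:
    def test_identical_panels_floor(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 5000)
        dos = rng.binomial(2, p[:, None], size=(5000, 30)).astype(np.int8)
        m = build_matrix(dos.tolist(),
                         positions=np.sort(rng.choice(10**6, 5000, replace=False) + 1))
        pm = split_popmap(m, 15)
        assert ss.estimate_omega(m, pm) <= 0.01

    def test_recovers_generative_coefficient(self):
        cfg = ss.SimulationConfig(seed=12, n_snps=20_000,
                                  omega_focal=0.05, omega_reference=0.0)
        m, _ = ss.simulate(cfg)
        pm = split_popmap(m, 15)
        assert ss.estimate_omega(m, pm) == pytest.approx(0.05, rel=0.15)

    def test_no_qualifying_snps_errors(self):
        m = build_matrix([[0, 0, 2, 2]] * 3, positions=[100, 200, 300])
        pm = split_popmap(m, 2)
        with pytest.raises(ss.ComputationError):
            ss.estimate_omega(m, pm)


class TestLdWeights:
    def test_independent_snps_full_weight(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        w = ss.ld_weights(d, 0.95)
        assert np.all(w == 1.0)

    def test_duplicated_columns_share_weight(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, size=30).astype(np.int8)
        other = rng.integers(0, 3, size=30).astype(np.int8)
        d = np.vstack([row, row, other])
        w = ss.ld_weights(d, 0.95)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == pytest.approx(0.5)
        assert w[2] == pytest.approx(1.0)
        d3 = np.vstack([row, row, row])
        assert np.allclose(ss.ld_weights(d3, 0.95), 1 / 3)

    def test_zero_variance_snp_neutral(self):
        d = np.vstack([np.zeros(10, dtype=np.int8),
                       np.arange(10, dtype=np.int8) % 3])
        w = ss.ld_weights(d, 0.95)
        assert np.all(w == 1.0)


class TestWindowScore:
    def test_score_nonnegative_with_neutral_gridpoint(self):
        rng = np.random.default_rng(4)
        snps = [
            XpclrSnpInput(position=int(p), p1=float(rng.uniform(0.05, 0.5)),
                          k2=int(rng.integers(0, 31)), m2=30,
                          r_j=float(abs(p - 5000) * 3e-8))
            for p in rng.choice(10_000, 30, replace=False)
        ]
        params = XpclrParams(omega=0.05, integration_points=200)
        res = ss.xpclr_window(ss.Window("chr1", 0, 10_000), snps, params)
        assert res.valid
        assert res.score >= 0.0

    def test_sparse_window_invalid(self):
        params = XpclrParams(omega=0.05)
        res = ss.xpclr_window(ss.Window("chr1", 0, 10_000), [], params)
        assert not res.valid

    def test_identical_panels_give_near_zero_scores(self):
        # the same 15 diploids serve as both focal and reference panel
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, 2000)
        half = rng.binomial(2, p[:, None], size=(2000, 15)).astype(np.int8)
        dos = np.hstack([half, half])
        m = build_matrix(dos.tolist(),
                         positions=np.sort(rng.choice(500_000, 2000, replace=False) + 1))
        pm = split_popmap(m, 15)
        om = ss.estimate_omega(m, pm)
        params = XpclrParams(omega=om, integration_points=200)
        results, _, _ = ss.xpclr_scan(m, pm, params, chrom_lengths={"chr1": 500_000})
        scores = [r.score for r in results if r.valid]
        assert max(scores) <= 0.5

    def test_window_count_and_top_selection(self):
        cfg = ss.SimulationConfig(seed=5, n_snps=4000, chrom_length=1_000_000)
        m, _ = ss.simulate(cfg)
        pm = split_popmap(m, 15)
        params = XpclrParams(omega=0.1, integration_points=100)
        results, thr, selected = ss.xpclr_scan(
            m, pm, params, chrom_lengths={"chr1": 1_000_000}
        )
        assert len(results) == 100
        valid_scores = sorted((r.score for r in results if r.valid), reverse=True)
        # top-1% of 100 windows: nearest rank k = 1 -> the maximum
        assert thr == valid_scores[0]
        assert len(selected) >= 1
        assert all(r.score >= thr for r in selected)

    def test_scan_deterministic(self):
        cfg = ss.SimulationConfig(seed=6, n_snps=2000, chrom_length=500_000)
        m, _ = ss.simulate(cfg)
        pm = split_popmap(m, 15)
        params = XpclrParams(omega=0.1, integration_points=100)
        r1, thr1, _ = ss.xpclr_scan(m, pm, params, chrom_lengths={"chr1": 500_000})
        r2, thr2, _ = ss.xpclr_scan(m, pm, params, chrom_lengths={"chr1": 500_000})
        assert thr1 == thr2
        for a, b in zip(r1, r2):
            assert (a.score == b.score) or (math.isnan(a.score) and math.isnan(b.score))
            assert (a.s_hat == b.s_hat) or (math.isnan(a.s_hat) and math.isnan(b.s_hat))
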