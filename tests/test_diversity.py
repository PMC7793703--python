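import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweepscan as ss
from sweepscan.diversity import single_stat_outliers

from conftest import build_matrix, split_popmap


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_pairwise_oracle(dosages):
    """Fraction of differing haplotype pairs, by explicit enumeration."""
    alleles = []
    for d in dosages:
        if d == ss.MISSING:
            continue
        alleles.extend([1] * d + [0] * (2 - d))
    n = len(alleles)
    if n < 2:
        return float("nan")
    diff = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if alleles[i] != alleles[j]
    )
    return diff / (n * (n - 1) / 2)


def wc_oracle(d1, d2):
    """Weir & Cockerham (1984) two-population variance components, written
    directly from the published formulas with scalar arithmetic."""
    d1 = [x for x in d1 if x != ss.MISSING]
    d2 = [x for x in d2 if x != ss.MISSING]
    n1, n2 = len(d1), len(d2)
    if n1 < 1 or n2 < 1 or (n1 + n2) / 2 <= 1:
        return None
    r = 2
    p1, p2 = sum(d1) / (2 * n1), sum(d2) / (2 * n2)
    h1 = sum(1 for x in d1 if x == 1) / n1
    h2 = sum(1 for x in d2 if x == 1) / n2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# site pi
# ---------------------------------------------------------------------------

class TestSitePi:
    def test_two_hets(self):
        # 4 alleles, 2 alt: 4 differing pairs of 6
        assert ss.site_pi([1, 1]) == pytest.approx(2 * 2 * 2 / (4 * 3))

    @pytest.mark.parametrize("dosages", [[0, 0, 0], [2, 2], [2, 2, 2, 2]])
    def test_monomorphic_is_zero(self, dosages):
        assert ss.site_pi(dosages) == 0.0

    def test_insufficient_alleles(self):
        assert math.isnan(ss.site_pi([ss.MISSING, ss.MISSING]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-1, max_value=2), min_size=1, max_size=12))
    def test_matches_pairwise_enumeration(self, dosages):
        expected = pi_pairwise_oracle(dosages)
        got = ss.site_pi(dosages)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)


class TestWindowPi:
    def test_single_snp_per_bp(self):
        m = build_matrix([[1, 1, 0, 0, 0, 0]], positions=[10])
        pm = split_popmap(m, 2)
        w = ss.Window("chr1", 0, 40_000)
        assert ss.window_pi(m, pm, w, "NY") == pytest.approx((2 * 2 * 2 / 12) / 40_000)

    def test_empty_window_is_zero(self):
        m = build_matrix([[1, 1, 0, 0]], positions=[50_001])
        pm = split_popmap(m, 2)
        assert ss.window_pi(m, pm, ss.Window("chr1", 0, 40_000), "NY") == 0.0

    def test_additive_over_snps(self):
        # dosages [1,1] give site pi = 2/3; two such SNPs in a 10 kb window
        m = build_matrix([[1, 1, 0, 0], [1, 1, 2, 2]], positions=[100, 200])
        pm = split_popmap(m, 2)
        w = ss.Window("chr1", 0, 10_000)
        assert ss.window_pi(m, pm, w, "NY") == pytest.approx(2 * (2 / 3) / 10_000)


def test_log2_pi_ratio_values():
    assert ss.log2_pi_ratio(1e-4, 1e-4) == 0.0
    assert ss.log2_pi_ratio(2e-4, 1e-4) == 1.0
    assert math.isnan(ss.log2_pi_ratio(1e-4, 0.0))
    assert math.isnan(ss.log2_pi_ratio(0.0, 1e-4))


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

class TestSiteFst:
    def test_fixed_difference(self):
        comp = ss.site_fst_components([0, 0, 0], [2, 2, 2])
        assert comp.a == pytest.approx(0.5)
        assert comp.b == pytest.approx(0.0)
        assert comp.c == pytest.approx(0.0)
        assert comp.a / (comp.a + comp.b + comp.c) == pytest.approx(1.0)

    def test_no_differentiation_small_a(self):
        comp = ss.site_fst_components([0, 1, 2, 1], [1, 0, 1, 2])
        assert comp.a <= 0.05

    def test_monomorphic_all_zero(self):
        comp = ss.site_fst_components([0, 0], [0, 0])
        assert (comp.a, comp.b, comp.c) == (0.0, 0.0, 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-1, max_value=2), min_size=2, max_size=10),
        st.lists(st.integers(min_value=-1, max_value=2), min_size=2, max_size=10),
    )
    def test_matches_published_formulas(self, d1, d2):
        expected = wc_oracle(d1, d2)
        got = ss.site_fst_components(d1, d2)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got.a == pytest.approx(expected[0], abs=1e-12)
            assert got.b == pytest.approx(expected[1], abs=1e-12)
            assert got.c == pytest.approx(expected[2], abs=1e-12)


def test_window_fst_ratio_of_sums():
    comps = [
        ss.site_fst_components([0, 0, 0], [2, 2, 2]),
        ss.site_fst_components([0, 0, 0], [2, 2, 2]),
    ]
    assert ss.window_fst(comps) == pytest.approx(1.0)
    single = [ss.site_fst_components([0, 0, 0], [2, 2, 2])]
    assert ss.window_fst(single) == pytest.approx(1.0)
    assert math.isnan(ss.window_fst([ss.site_fst_components([0, 0], [0, 0])]))


def test_log2_ratio_antisymmetric_under_panel_swap():
    rng = np.random.default_rng(21)
    m = build_matrix(rng.integers(0, 3, size=(400, 12)).tolist(),
                     positions=np.sort(rng.choice(80_000, 400, replace=False) + 1))
    pm = split_popmap(m, 6)
    pm_swapped = ss.PopulationMap(pm.assignments, "Others", "NY")
    wins = ss.make_windows({"chr1": 80_000}, 20_000, 10_000)
    rec = ss.pi_fst_scan(m, pm, wins, min_snps=1)
    rec_sw = ss.pi_fst_scan(m, pm_swapped, wins, min_snps=1)
    for r1, r2 in zip(rec, rec_sw):
        if r1.valid and r2.valid:
            assert r1.log2_pi_ratio == pytest.approx(-r2.log2_pi_ratio)
            assert r1.fst == pytest.approx(r2.fst)


# ---------------------------------------------------------------------------
# outlier calling
# ---------------------------------------------------------------------------

class TestEmpiricalThreshold:
    def test_nearest_rank_on_distinct_values(self):
        values = list(range(1, 101))
        thr = ss.empirical_threshold(values, 0.05)
        assert thr == 96
        assert sum(v >= thr for v in values) == 5

    def test_all_ties_select_everything(self):
        values = [7.0] * 40
        thr = ss.empirical_threshold(values, 0.05)
        assert all(v >= thr for v in values)

    def test_ceiling_selects_maximum(self):
        values = list(range(10))
        thr = ss.empirical_threshold(values, 0.01)
        assert thr == 9

    def test_empty_rejected(self):
        with pytest.raises(ss.ComputationError):
            ss.empirical_threshold([], 0.05)

    @pytest.mark.parametrize("tail", [0.0, 1.0, 1.5])
    def test_invalid_tail_rejected(self, tail):
        with pytest.raises(ValueError):
            ss.empirical_threshold([1.0, 2.0], tail)


def _records_from_values(fst_vals, ratio_vals):
    recs = []
    for i, (f, r) in enumerate(zip(fst_vals, ratio_vals)):
        w = ss.Window("chr1", i * 20_000, i * 20_000 + 40_000)
        recs.append(ss.WindowStatRecord(w, 20, 1e-4, 1e-4, r, f, True))
    return recs


class TestJointOutliers:
    def test_conjunction_required(self):
        fst = list(np.linspace(0, 1, 100))
        ratio = list(np.linspace(0, 1, 100))
        ratio[-1] = 0.5  # top-FST window mid-pack on the ratio
        recs = _records_from_values(fst, ratio)
        selected, fst_thr, ratio_thr = ss.joint_outliers(recs, 0.05)
        chosen = {rec.window.start for rec in selected}
        assert recs[-1].window.start not in chosen
        for rec in selected:
            assert rec.fst >= fst_thr and rec.log2_pi_ratio >= ratio_thr

    def test_correlated_leaders_selected_exactly(self):
        # both statistics rank identically: joint = top 5 of 100
        vals = list(np.linspace(0, 1, 100))
        recs = _records_from_values(vals, vals)
        selected, _, _ = ss.joint_outliers(recs, 0.05)
        assert {rec.window.start for rec in selected} == {
            rec.window.start for rec in recs[-5:]
        }

    def test_invalid_windows_ignored(self):
        recs = _records_from_values(list(np.linspace(0, 1, 50)), list(np.linspace(0, 1, 50)))
        recs[0].valid = False
        recs[0].fst = float("nan")
        selected, _, _ = ss.joint_outliers(recs, 0.1)
        assert all(rec.valid for rec in selected)

    def test_single_stat_count_matches_nearest_rank(self):
        rng = np.random.default_rng(3)
        recs = _records_from_values(rng.normal(size=200).tolist(),
                                    rng.normal(size=200).tolist())
        sel, thr = single_stat_outliers(recs, "fst", 0.05)
        assert len(sel) == math.ceil(0.05 * 200)


def test_min_snps_marks_sparse_windows_invalid():
    rng = np.random.default_rng(8)
    m = build_matrix(rng.integers(0, 3, size=(30, 8)).tolist(),
                     positions=np.sort(rng.choice(40_000, 30, replace=False) + 1))
    pm = split_popmap(m, 4)
    wins = ss.make_windows({"chr1": 40_000}, 40_000, 40_000)
    recs_strict = ss.pi_fst_scan(m, pm, wins, min_snps=50)
    assert not recs_strict[0].valid
    recs_loose = ss.pi_fst_scan(m, pm, wins, min_snps=1)
    assert recs_loose[0].n_snps_used == recs_strict[0].n_snps_used
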