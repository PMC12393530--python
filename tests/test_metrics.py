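"""Metric unit tests, each checked against an independent oracle:

* Spearman — brute-force average-rank formula;
* Wasserstein — exhaustive transport LP (scipy.linprog) on small instances;
* area FPR/FNR — fine-grid Riemann sums over the piecewise-linear curves.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from chrompen import (
    MetricError,
    ScoreTable,
    area_error_rates,
    compare,
    f1_from_areas,
    spearman_concordance,
    standardize_profile,
    wasserstein_profile_distance,
)
from chrompen.types import NormalizedProfile


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def rank_average(v):
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    ra, rb = rank_average(a), rank_average(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def wasserstein_lp_oracle(x, wa, wb):
    """Minimum-cost transport between two discrete distributions on x."""
    wa = np.asarray(wa, float) / np.sum(wa)
    wb = np.asarray(wb, float) / np.sum(wb)
    n = len(x)
    cost = np.abs(np.subtract.outer(x, x)).ravel()
    a_eq = []
    for i in range(n):  # row sums = wa
        row = np.zeros((n, n)); row[i, :] = 1; a_eq.append(row.ravel())
    for j in range(n):  # col sums = wb
        col = np.zeros((n, n)); col[:, j] = 1; a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.r_[wa, wb],
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def riemann_area_rates(x, proxy, ref, n_grid=1_000_000):
    grid = np.linspace(x[0], x[-1], n_grid)
    p = np.interp(grid, x, proxy)
    r = np.interp(grid, x, ref)
    pos = np.trapezoid(np.maximum(p - r, 0.0), grid)
    neg = np.trapezoid(np.maximum(r - p, 0.0), grid)
    return pos / np.trapezoid(p, grid), neg / np.trapezoid(r, grid)


def norm_profiles(mids, pa, pb):
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    return (NormalizedProfile(mids, pa / pa.max()),
            NormalizedProfile(mids, pb / pb.max()))


# ---------------------------------------------------------------------------
# standardize_profile
# ---------------------------------------------------------------------------

class TestStandardizeProfile:
    def score_table(self, distances, scores):
        return ScoreTable(pd.DataFrame({"distance_bp": distances, "raw_score": scores}))

    def test_constant_scores_give_flat_unit_profile(self):
        d = np.linspace(40_000, 490_000, 500)
        prof = standardize_profile(self.score_table(d, np.full(500, 0.7)), n_bins=10)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_single_occupied_bin(self, contacts_factory):
        cs = contacts_factory([100_000] * 7)
        prof = standardize_profile(cs, n_bins=10)
        assert prof.values.max() == 1.0
        assert np.count_nonzero(prof.values) == 1

    def test_inverse_distance_scores_normalize_to_smin_over_s(self):
        # place one row exactly at each bin midpoint with score s^-1
        from chrompen.binning import bin_grid
        _, mids = bin_grid((35_000, 500_000), 12, "log")
        prof = standardize_profile(self.score_table(mids, 1.0 / mids), n_bins=12)
        np.testing.assert_allclose(prof.values, mids.min() / mids, rtol=1e-12)

    def test_contacts_aggregate_by_sum_scores_by_mean(self, contacts_factory):
        cs = contacts_factory([100_000] * 4 + [300_000])
        cprof = standardize_profile(cs, n_bins=5)
        assert cprof.values.max() == 1.0
        assert sorted(cprof.values[cprof.values > 0]) == pytest.approx([0.25, 1.0])
        st = self.score_table([100_000.0] * 4 + [300_000.0], [0.5] * 4 + [0.5])
        sprof = standardize_profile(st, n_bins=5)
        assert sorted(sprof.values[sprof.values > 0]) == pytest.approx([1.0, 1.0])

    def test_all_zero_aggregate_rejected(self):
        with pytest.raises(MetricError, match="all-zero"):
            standardize_profile(self.score_table([50e3, 60e3], [0.0, 0.0]), n_bins=5)

    def test_no_rows_in_range_rejected(self):
        with pytest.raises(MetricError, match="range"):
            standardize_profile(self.score_table([1e3, 2e3], [1.0, 1.0]), n_bins=5)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_identical_profiles(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 8)
        a = profile_factory(mids, np.linspace(1, 0.1, 8))
        assert spearman_concordance(a, a) == pytest.approx(1.0)

    def test_reversed_profiles(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 8)
        v = np.linspace(1, 0.1, 8)
        assert spearman_concordance(profile_factory(mids, v),
                                    profile_factory(mids, v[::-1])) == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 5)
        a = np.array([1.0, 0.8, 0.8, 0.4, 0.2])
        b = np.array([0.9, 1.0, 0.5, 0.5, 0.1])
        got = spearman_concordance(profile_factory(mids, a), profile_factory(mids, b))
        assert got == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    def test_zero_variance_is_undefined(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 5)
        flat = profile_factory(mids, np.ones(5))
        other = profile_factory(mids, np.linspace(1, 0.2, 5))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert spearman_concordance(flat, other) is None

    def test_mismatched_grids_rejected(self, profile_factory):
        a = profile_factory(np.geomspace(4e4, 4e5, 5), np.linspace(1, 0.2, 5))
        b = profile_factory(np.geomspace(5e4, 4e5, 5), np.linspace(1, 0.2, 5))
        with pytest.raises(MetricError, match="grid"):
            spearman_concordance(a, b)


# ---------------------------------------------------------------------------
# Wasserstein
# ---------------------------------------------------------------------------

class TestWasserstein:
    def test_identical_profiles_zero(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 6)
        a = profile_factory(mids, np.linspace(1, 0.1, 6))
        assert wasserstein_profile_distance(a, a) == pytest.approx(0.0)

    def test_point_mass_transport(self):
        mids = np.array([100_000.0, 200_000.0, 300_000.0])
        a = NormalizedProfile(mids, np.array([1.0, 0.0, 0.0]))
        b = NormalizedProfile(mids, np.array([0.0, 1.0, 0.0]))
        assert wasserstein_profile_distance(a, b) == pytest.approx(100_000.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_three_bin_instances_match_transport_lp(self, seed):
        rng = np.random.default_rng(seed)
        mids = np.sort(rng.uniform(35e3, 5e5, 3))
        wa = rng.uniform(0.05, 1.0, 3)
        wb = rng.uniform(0.05, 1.0, 3)
        a = NormalizedProfile(mids, wa / wa.max())
        b = NormalizedProfile(mids, wb / wb.max())
        got = wasserstein_profile_distance(a, b)
        want = wasserstein_lp_oracle(mids, wa, wb)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-6)


# ---------------------------------------------------------------------------
# area error rates and F1
# ---------------------------------------------------------------------------

class TestAreaRates:
    def test_identical_curves_no_error(self, profile_factory):
        mids = np.geomspace(4e4, 4e5, 10)
        a = profile_factory(mids, np.linspace(1, 0.1, 10))
        fpr, fnr = area_error_rates(a, a)
        assert fpr == 0.0 and fnr == 0.0
        assert f1_from_areas(a, a) == pytest.approx(1.0)

    def test_flat_proxy_over_vanishing_reference(self, profile_factory):
        mids = np.linspace(4e4, 4e5, 10)
        proxy = profile_factory(mids, np.ones(10))
        tiny = np.full(10, 1e-9); tiny[0] = 1.0
        ref = NormalizedProfile(mids, tiny)
        fpr, _ = area_error_rates(proxy, ref)
        # in the limit of a vanishing reference all proxy area is excess;
        # here the reference retains one spike so a sliver is covered
        assert fpr > 0.9

    def test_piecewise_linear_toy_matches_riemann_oracle(self):
        mids = np.array([1.0, 2.0, 3.0, 4.0]) * 1e5
        p = np.array([1.0, 0.2, 0.8, 0.1])
        r = np.array([0.5, 0.6, 0.3, 0.4])
        proxy, ref = norm_profiles(mids, p, r)
        fpr, fnr = area_error_rates(proxy, ref)
        ofpr, ofnr = riemann_area_rates(mids, proxy.values, ref.values)
        assert fpr == pytest.approx(ofpr, rel=1e-6)
        assert fnr == pytest.approx(ofnr, rel=1e-6)

    def test_disjoint_supports_give_zero_f1(self):
        mids = np.linspace(1e5, 4e5, 6)
        a = NormalizedProfile(mids, np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0]))
        b = NormalizedProfile(mids, np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0]))
        assert f1_from_areas(a, b) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_f1_identity_with_error_rates(self, seed):
        rng = np.random.default_rng(seed)
        mids = np.sort(rng.uniform(35e3, 5e5, 12))
        proxy, ref = norm_profiles(mids, rng.uniform(0.01, 1, 12), rng.uniform(0.01, 1, 12))
        fpr, fnr = area_error_rates(proxy, ref)
        p, r = 1.0 - fpr, 1.0 - fnr
        expected = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
        assert f1_from_areas(proxy, ref) == pytest.approx(expected, abs=1e-12)


class TestCompare:
    def make_table(self, distances, scores):
        return ScoreTable(pd.DataFrame({"distance_bp": distances, "raw_score": scores}))

    def test_self_comparison_is_perfect(self, contacts_factory):
        rng = np.random.default_rng(0)
        cs = contacts_factory(rng.uniform(40e3, 480e3, 2000))
        rep = compare(cs, cs, n_bins=20)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.wasserstein_bp == pytest.approx(0.0)
        assert rep.fpr == 0.0 and rep.fnr == 0.0 and rep.f1 == 1.0

    def test_flat_proxy_versus_steep_reference(self, profile_factory):
        # reference ~ s^-2.34 decays to ~2e-3 of its peak; a flat proxy's
        # area is almost entirely excess
        from chrompen.binning import bin_grid
        _, mids = bin_grid((35_000, 500_000), 30, "log")
        ref = profile_factory(mids, (mids / mids.min()) ** -2.34)
        d = np.repeat(mids, 5)
        rep = compare(self.make_table(d, np.ones_like(d)), ref, n_bins=30)
        assert rep.fpr > 0.8
        assert rep.f1 < 0.3

    def test_scale_invariance_of_all_metrics(self, contacts_factory):
        rng = np.random.default_rng(1)
        d = rng.uniform(40e3, 480e3, 3000)
        t1 = self.make_table(d, np.exp(rng.normal(0, 0.3, len(d))))
        t9 = ScoreTable(t1.df.assign(raw_score=t1.df.raw_score * 9.0))
        cs = contacts_factory(rng.uniform(40e3, 480e3, 3000))
        r1, r9 = compare(t1, cs), compare(t9, cs)
        assert r1.to_dict() == pytest.approx(r9.to_dict())


def test_swapping_proxy_and_reference_swaps_error_areas(profile_factory):
    mids = np.linspace(1e5, 4e5, 8)
    rng = np.random.default_rng(3)
    a, b = norm_profiles(mids, rng.uniform(0.1, 1, 8), rng.uniform(0.1, 1, 8))
    fpr_ab, fnr_ab = area_error_rates(a, b)
    fpr_ba, fnr_ba = area_error_rates(b, a)
    area_a = np.trapezoid(a.values, mids)
    area_b = np.trapezoid(b.values, mids)
    # same excess areas, different denominators
    assert fpr_ab * area_a == pytest.approx(fnr_ba * area_a)
    assert fnr_ab * area_b == pytest.approx(fpr_ba * area_b)
    # symmetric metrics
    assert wasserstein_profile_distance(a, b) == pytest.approx(
        wasserstein_profile_distance(b, a))
    assert spearman_concordance(a, b) == pytest.approx(spearman_concordance(b, a))
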