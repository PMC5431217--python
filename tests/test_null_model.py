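import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from temporal_beta import (
    CommunityMatrix,
    NullConfig,
    Stability,
    TemporalBetaNull,
    ValidationError,
    allocate_abundances,
    beta_departure,
    binary_randomize,
    classify_stability,
    null_distribution,
)
from temporal_beta.null_model import default_burn_in, site_rng
from temporal_beta.pipeline import beta_table


def enumerate_fixed_marginals(row_sums, col_sums):
    """Brute-force oracle: all binary matrices with the given margins."""
    n_cols = len(col_sums)
    out = []

    def rec(i, remaining, rows):
        if i == len(row_sums):
            if all(c == 0 for c in remaining):
                out.append(tuple(rows))
            return
        for cols in itertools.combinations(range(n_cols), row_sums[i]):
            if all(remaining[c] > 0 for c in cols):
                rem = list(remaining)
                for c in cols:
                    rem[c] -= 1
                rec(i + 1, rem, rows + [tuple(int(c in cols) for c in range(n_cols))])

    rec(0, list(col_sums), [])
    return out


class TestBinaryRandomize:
    def test_margins_conserved(self, rng):
        P = rng.random((8, 20)) < 0.4
        P[P.sum(axis=1) == 0, 0] = True
        Q = binary_randomize(P, trades=500, rng=rng)
        assert np.array_equal(P.sum(axis=0), Q.sum(axis=0))
        assert np.array_equal(P.sum(axis=1), Q.sum(axis=1))
        assert P.sum() == Q.sum()

    def test_all_ones_unchanged(self, rng):
        P = np.ones((3, 4), dtype=bool)
        Q = binary_randomize(P, trades=100, rng=rng)
        assert np.array_equal(P, Q)

    def test_two_member_ensemble_is_balanced(self, rng):
        # [[1,0],[0,1]] has exactly two fixed-marginals members
        P = np.eye(2, dtype=bool)
        hits = 0
        for _ in range(1000):
            Q = binary_randomize(P, trades=30, rng=rng)
            hits += int(Q[0, 0])
        p = chisquare([hits, 1000 - hits]).pvalue
        assert p > 0.01

    def test_negative_trades_rejected(self, rng):
        with pytest.raises(ValidationError):
            binary_randomize(np.eye(2, dtype=bool), trades=-1, rng=rng)

    def test_all_zero_row_rejected(self, rng):
        P = np.array([[1, 0], [0, 0]], dtype=bool)
        with pytest.raises(ValidationError, match="all-zero row"):
            binary_randomize(P, trades=1, rng=rng)

    def test_input_not_mutated(self, rng):
        P = np.eye(3, dtype=bool) | np.eye(3, k=1, dtype=bool)
        P0 = P.copy()
        binary_randomize(P, trades=200, rng=rng)
        assert np.array_equal(P, P0)


class TestAllocateAbundances:
    def test_single_cell_gets_total(self, rng):
        out = allocate_abundances(np.array([5]), np.array([[1, 0, 0]], dtype=bool), rng=rng)
        assert out.tolist() == [[5, 0, 0]]

    def test_total_equals_presences_forces_ones(self, rng):
        out = allocate_abundances(np.array([3]), np.array([[1, 1, 1]], dtype=bool), rng=rng)
        assert out.tolist() == [[1, 1, 1]]

    def test_surplus_two_over_two_cells_is_binomial_half(self, rng):
        # total 4 over 2 cells: outcomes (1,3),(2,2),(3,1) with probs 1/4,1/2,1/4
        P = np.array([[1, 1]], dtype=bool)
        freq = {(1, 3): 0, (2, 2): 0, (3, 1): 0}
        n = 4000
        for _ in range(n):
            out = allocate_abundances(np.array([4]), P, rng=rng)
            freq[tuple(out[0])] += 1
        p = chisquare(
            [freq[(1, 3)], freq[(2, 2)], freq[(3, 1)]], [n / 4, n / 2, n / 4]
        ).pvalue
        assert p > 0.01

    def test_row_total_below_presences_rejected(self, rng):
        with pytest.raises(ValidationError, match="every present taxon"):
            allocate_abundances(np.array([2]), np.array([[1, 1, 1]], dtype=bool), rng=rng)

    def test_shuffle_nonzero_permutes_observed_values(self, rng):
        P = np.array([[1, 1, 0], [0, 1, 1]], dtype=bool)
        values = np.array([5, 9, 2, 7])
        with pytest.warns(UserWarning, match="totals"):
            out = allocate_abundances(
                np.array([14, 9]), P, scheme="shuffle_nonzero", rng=rng,
                observed_values=values,
            )
        assert sorted(out[P].tolist()) == sorted(values.tolist())
        assert np.all(out[~P] == 0)


class TestDeparture:
    @pytest.mark.parametrize(
        "obs,mean,sd,expected",
        [(0.30, 0.30, 0.05, 0.0), (0.25, 0.30, 0.025, -2.0), (0.35, 0.30, 0.025, 2.0)],
    )
    def test_effect_size_arithmetic(self, obs, mean, sd, expected):
        assert beta_departure(obs, mean, sd) == pytest.approx(expected)

    def test_zero_sd_convention(self):
        assert beta_departure(0.4, 0.3, 0.0) == 0.0

    @pytest.mark.parametrize(
        "value,expected",
        [
            (-2.5, Stability.MORE_STABLE_THAN_CHANCE),
            (-1.0, Stability.INDISTINGUISHABLE),
            (-2.0, Stability.INDISTINGUISHABLE),  # strict inequality
        ],
    )
    def test_classification_threshold_is_strict(self, value, expected):
        assert classify_stability(value) is expected


class TestTemporalBetaNull:
    def test_conservation_every_iteration(self, one_site):
        est = TemporalBetaNull(
            n_iter=50, random_state=0, check_conservation=True
        ).fit(one_site)
        assert np.all((est.per_iteration_means_ >= 0) & (est.per_iteration_means_ <= 1))

    def test_bit_identical_under_fixed_seed(self, one_site):
        a = TemporalBetaNull(n_iter=40, random_state=7).fit(one_site)
        b = TemporalBetaNull(n_iter=40, random_state=7).fit(one_site)
        assert a.beta_dep_ == b.beta_dep_
        assert np.array_equal(a.per_iteration_means_, b.per_iteration_means_)

    def test_persistent_community_is_more_stable_than_null(self, rng):
        # strong year-to-year persistence in identity and abundance
        g = 40
        base = np.maximum(1, rng.poisson(8, size=g))
        counts = np.array(
            [np.maximum(0, base + rng.integers(-1, 2, size=g)) for _ in range(10)]
        )
        counts[:, : g // 2] += 1  # keep half the taxa always present
        m = CommunityMatrix("p", np.arange(2000, 2010), [f"t{j}" for j in range(g)], counts)
        est = TemporalBetaNull(n_iter=200, random_state=1).fit(m)
        assert est.beta_obs_ < est.beta_exp_mean_
        assert est.beta_dep_ < -2

    def test_degenerate_ensemble_flagged(self):
        # full matrix of ones: binary ensemble and allocation are both forced
        counts = np.ones((4, 3), dtype=int)
        m = CommunityMatrix("d", np.arange(2000, 2004), list("abc"), counts)
        est = TemporalBetaNull(n_iter=20, random_state=0).fit(m)
        assert est.degenerate_
        assert est.beta_dep_ == 0.0

    def test_wrapper_matches_estimator(self, one_site):
        cfg = NullConfig(n_iter=30, seed=3)
        nd = null_distribution(one_site, cfg)
        est = TemporalBetaNull(n_iter=30, random_state=3).fit(one_site)
        assert nd.beta_dep == est.beta_dep_
        assert nd.site_id == one_site.site_id

    def test_empty_year_rejected(self):
        counts = np.array([[1, 1], [0, 0], [2, 1]])
        with pytest.raises(ValidationError, match="zero total"):
            TemporalBetaNull(n_iter=5).fit(counts)


class TestSiteStreams:
    def test_streams_differ_between_sites(self):
        a = site_rng(1, "S01").integers(0, 1 << 30, 4)
        b = site_rng(1, "S02").integers(0, 1 << 30, 4)
        assert not np.array_equal(a, b)

    def test_results_independent_of_site_order(self, default_dataset):
        mats = default_dataset.matrices[:4]
        bt1 = beta_table(mats, n_iter=30, seed=5)
        bt2 = beta_table(mats[::-1], n_iter=30, seed=5)
        merged = bt1.merge(bt2, on="site", suffixes=("_a", "_b"))
        assert np.allclose(merged["beta_dep_a"], merged["beta_dep_b"])

    def test_default_burn_in_grows_with_rows(self):
        assert default_burn_in(14) > default_burn_in(4) > 0
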