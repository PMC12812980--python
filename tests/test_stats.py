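import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import oracles
from trophonet.stats import (
    bh_fdr,
    correlation_matrix,
    env_community_correlation,
    mantel_test,
    partial_mantel,
    spearman_pvalue,
    spearman_rho,
)


def euclid(points):
    return squareform(pdist(np.asarray(points, float)))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(1.0, 11.0)
        assert spearman_rho(x, x**2) == pytest.approx(1.0, abs=1e-12)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0, abs=1e-12)

    def test_tied_example_matches_average_rank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        expected = oracles.spearman(x, y)  # 0.948683... with average ranks
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)
        from scipy.stats import spearmanr

        assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    @given(
        x=st.lists(st.integers(0, 20), min_size=5, max_size=12),
        y=st.lists(st.integers(0, 20), min_size=5, max_size=12),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_oracle_and_monotone_invariance(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n], float), np.array(y[:n], float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert math.isnan(spearman_rho(x, y))
            return
        rho = spearman_rho(x, y)
        assert rho == pytest.approx(oracles.spearman(x, y), abs=1e-12)
        # strictly monotone transforms leave rho unchanged
        assert spearman_rho(np.exp(x / 5), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y + 1) == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_flagged(self):
        assert math.isnan(spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])

    def test_exact_permutation_p_small_n(self):
        # at n=5 without ties the exact two-sided p for rho=1 is 2/5! = 1/60
        rho, p = spearman_pvalue([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_sort_oracle(self, p):
        q = bh_fdr(p)
        assert np.allclose(q, oracles.bh_qvalues(p), atol=1e-12)
        assert (q >= 0).all() and (q <= 1).all()
        # step-up monotone: sorted by p, q is non-decreasing
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCorrelationMatrix:
    def test_perfectly_correlated_triple(self):
        base = np.arange(12.0)
        mat = np.vstack([base, base * 2, np.exp(base / 10)])
        res = correlation_matrix(mat)
        assert len(res) == 3
        assert np.allclose(res["rho"], 1.0)

    def test_pair_count_and_constant_flagging(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(6, 15))
        mat[2] = 5.0  # constant taxon
        res = correlation_matrix(mat)
        assert len(res) == 15
        bad = res[(res["taxon_i"] == "v2") | (res["taxon_j"] == "v2")]
        assert bad["rho"].isna().all() and bad["q"].isna().all()
        good = res.dropna()
        assert np.allclose(bh_fdr(good["p_raw"].to_numpy()), good["q"], atol=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.zeros((3, 3)))

    def test_type_one_error_calibration(self):
        # independent noise: fraction of raw p below 0.05 should sit near
        # 0.05; averaged over 200 seeded replicates of 990 pairs
        fracs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            res = correlation_matrix(rng.normal(size=(45, 20)))
            fracs.append(float((res["p_raw"] < 0.05).mean()))
        mean = float(np.mean(fracs))
        se = float(np.std(fracs) / math.sqrt(len(fracs)))
        assert abs(mean - 0.05) < max(0.01, 4 * se)


class TestMantel:
    def test_identity_matrices(self):
        d = euclid(np.random.default_rng(1).normal(size=(8, 2)))
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        d = euclid(rng.normal(size=(7, 2)))
        perm = rng.permutation(7)
        res = mantel_test(d[np.ix_(perm, perm)], d[np.ix_(perm, perm)], n_perm=49, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(3)
        d1 = euclid(rng.normal(size=(4, 2)))
        d2 = euclid(rng.normal(size=(4, 2)))
        res = mantel_test(d1, d2, exact=True)
        r_oracle, p_oracle = oracles.mantel_exact(d1, d2)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 24

    def test_p_resolution_and_reproducibility(self):
        rng = np.random.default_rng(4)
        d1 = euclid(rng.normal(size=(10, 3)))
        d2 = euclid(rng.normal(size=(10, 3)))
        a = mantel_test(d1, d2, n_perm=99, seed=11)
        b = mantel_test(d1, d2, n_perm=99, seed=11)
        assert a.r == b.r and a.p == b.p
        assert (a.p * 100) == pytest.approx(round(a.p * 100))
        assert 0 < a.p <= 1

    def test_asymmetric_input_rejected(self):
        bad = np.arange(16.0).reshape(4, 4)
        good = euclid(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            mantel_test(bad, good)

    def test_null_pvalues_super_uniform(self):
        # under independence P(p <= x) must not exceed x (plus noise)
        rng = np.random.default_rng(100)
        ps = []
        for _ in range(300):
            d1 = euclid(rng.normal(size=(10, 2)))
            d2 = euclid(rng.normal(size=(10, 2)))
            ps.append(mantel_test(d1, d2, n_perm=99, seed=int(rng.integers(2**31))).p)
        ps = np.array(ps)
        for x in (0.05, 0.10, 0.25):
            se = math.sqrt(x * (1 - x) / len(ps))
            assert (ps <= x).mean() <= x + 4 * se

    def test_pearson_flag(self):
        rng = np.random.default_rng(6)
        d1 = euclid(rng.normal(size=(8, 2)))
        res = mantel_test(d1, d1**2, n_perm=49, seed=0, method="pearson")
        assert res.method == "pearson"
        assert -1 <= res.r <= 1


class TestPartialMantel:
    def test_constant_control_equals_plain_mantel(self):
        rng = np.random.default_rng(7)
        d1 = euclid(rng.normal(size=(9, 2)))
        d2 = euclid(rng.normal(size=(9, 2)))
        dc = np.ones((9, 9)) - np.eye(9)
        plain = mantel_test(d1, d2, n_perm=99, seed=5)
        part = partial_mantel(d1, d2, dc, n_perm=99, seed=5)
        assert part.r == pytest.approx(plain.r, abs=1e-9)

    def test_self_control_near_zero(self):
        rng = np.random.default_rng(8)
        d1 = euclid(rng.normal(size=(12, 2)))
        d2 = euclid(rng.normal(size=(12, 2)))
        res = partial_mantel(d1, d2, d2, n_perm=99, seed=0)
        assert abs(res.r) < 0.35  # association with the control is removed

    def test_planted_structure_recovered(self):
        rng = np.random.default_rng(9)
        n = 20
        d2 = euclid(rng.normal(size=(n, 3)))
        dc = euclid(rng.normal(size=(n, 3)))
        noise = rng.normal(scale=0.05, size=(n, n))
        noise = np.abs(noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        d1 = 1.0 * d2 + 0.8 * dc + noise
        res = partial_mantel(d1, d2, dc, n_perm=999, seed=1)
        assert res.r > 0
        assert res.p < 0.05


class TestEnvCommunityCorrelation:
    def test_constant_env_flagged(self):
        d = euclid(np.random.default_rng(1).normal(size=(6, 2)))
        res = env_community_correlation(np.ones(6), d, n_perm=49, seed=0)
        assert not res.defined
        assert math.isnan(res.r)

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(10)
        env = rng.normal(size=20)
        d = np.abs(env[:, None] - env[None, :]) ** 1.3  # monotone in |env_i - env_j|
        res = env_community_correlation(env, d, n_perm=999, seed=2)
        assert res.r > 0
        assert res.p <= 0.05

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            env = rng.normal(size=12)
            d = euclid(rng.normal(size=(12, 2)))
            ps.append(
                env_community_correlation(
                    env, d, n_perm=49, seed=int(rng.integers(2**31))
                ).p
            )
        ps = np.array(ps)
        assert abs(ps.mean() - 0.5) < 0.1
        assert (ps <= 0.05).mean() <= 0.12
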