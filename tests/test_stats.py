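"""Moderated statistics, permutation FDR vs brute force, Storey q-values."""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from atroprot.stats import (moderated_statistic, permutation_fdr, storey_qvalues)


# ---------------------------------------------------------------------------
# Independent brute-force oracle (plain loops, statistics module)
# ---------------------------------------------------------------------------

def _oracle_d_two(a, b, s0):
    a = [x for x in a if not math.isnan(x)]
    b = [x for x in b if not math.isnan(x)]
    if len(a) < 2 or len(b) < 2:
        return math.nan
    ma, mb = statistics.fmean(a), statistics.fmean(b)
    sp2 = (sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)) \
        / (len(a) + len(b) - 2)
    se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return (ma - mb) / (se + s0)


def _oracle_d_one(vals, s0):
    vals = [x for x in vals if not math.isnan(x)]
    if len(vals) < 2:
        return math.nan
    m = statistics.fmean(vals)
    sd = statistics.stdev(vals)
    return m / (sd / math.sqrt(len(vals)) + s0)


def _oracle_two_sample(X, na, s0, target):
    """Exhaustive enumeration of all C(n, na) label splits."""
    n_ids, n = X.shape
    d_obs = [_oracle_d_two(X[i][:na], X[i][na:], s0) for i in range(n_ids)]
    perm_abs = []
    for combo in itertools.combinations(range(n), na):
        rest = [j for j in range(n) if j not in combo]
        perm_abs.append([abs(_oracle_d_two([X[i][j] for j in combo],
                                           [X[i][j] for j in rest], s0))
                         for i in range(n_ids)])
    return _oracle_threshold(d_obs, perm_abs, target)


def _oracle_one_sample(X, s0, target):
    n_ids, n = X.shape
    d_obs = [_oracle_d_one(list(X[i]), s0) for i in range(n_ids)]
    perm_abs = []
    for signs in itertools.product((1, -1), repeat=n):
        perm_abs.append([abs(_oracle_d_one([s * x for s, x in zip(signs, X[i])], s0))
                         for i in range(n_ids)])
    return _oracle_threshold(d_obs, perm_abs, target)


def _oracle_threshold(d_obs, perm_abs, target):
    abs_obs = sorted({abs(d) for d in d_obs if not math.isnan(d)}, reverse=True)
    best_theta = math.inf
    for theta in abs_obs:
        r = sum(1 for d in d_obs if not math.isnan(d) and abs(d) >= theta)
        falses = sorted(sum(1 for v in row if v >= theta) for row in perm_abs)
        mid = len(falses) // 2
        med = (falses[mid] if len(falses) % 2 else
               (falses[mid - 1] + falses[mid]) / 2)
        if med / max(r, 1) <= target:
            best_theta = theta
    sig = {i for i, d in enumerate(d_obs)
           if not math.isnan(d) and abs(d) >= best_theta}
    return sig, best_theta


# ---------------------------------------------------------------------------
# Moderated statistic
# ---------------------------------------------------------------------------

class TestModeratedStatistic:
    def test_zero_variance_made_finite_by_s0(self):
        d, eff = moderated_statistic([1.0, 1.0, 1.0], None, s0=0.1)
        assert d == pytest.approx(10.0)
        assert eff == pytest.approx(1.0)

    def test_s0_zero_reduces_to_classical_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=4), rng.normal(1, 1, size=5)
        d, _ = moderated_statistic(a, b, s0=0.0)
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert d == pytest.approx(t)

    def test_moderation_always_shrinks(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            a, b = rng.normal(size=3), rng.normal(size=3)
            d, _ = moderated_statistic(a, b, s0=0.1)
            t, _ = moderated_statistic(a, b, s0=0.0)
            assert abs(d) <= abs(t) + 1e-12

    def test_s0_monotone(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=3), rng.normal(size=3)
        ds = [abs(moderated_statistic(a, b, s0=s)[0]) for s in (0.0, 0.05, 0.1, 0.5)]
        assert all(x >= y - 1e-12 for x, y in zip(ds, ds[1:]))

    def test_insufficient_n_not_testable(self):
        d, eff = moderated_statistic([1.0], None)
        assert math.isnan(d) and math.isnan(eff)
        d, eff = moderated_statistic([1.0, 2.0], [3.0])
        assert math.isnan(d)


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

class TestPermutationFdr:
    def test_3v3_is_exhaustive_with_20_splits(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        labels = ["a"] * 3 + ["b"] * 3
        res = permutation_fdr(X, labels, n_perm=250, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 20
        res2 = permutation_fdr(X, labels, n_perm="exhaustive", seed=5)
        pd.testing.assert_frame_equal(res.table, res2.table)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_sample_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 6))
        X[:3] += 1.5
        res = permutation_fdr(pd.DataFrame(X), ["a"] * 3 + ["b"] * 3,
                              s0=0.1, target_fdr=0.05, n_perm="exhaustive")
        sig_oracle, theta_oracle = _oracle_two_sample(X, 3, 0.1, 0.05)
        sig_impl = set(np.where(res.table["significant"])[0])
        assert sig_impl == sig_oracle
        if math.isfinite(theta_oracle):
            assert res.fdr_threshold_stat == pytest.approx(theta_oracle)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_sample_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 10)
        X = rng.normal(size=(8, 4))
        X[:2] += 2.0
        res = permutation_fdr(pd.DataFrame(X), None, s0=0.1,
                              target_fdr=0.05, n_perm="exhaustive")
        sig_oracle, theta_oracle = _oracle_one_sample(X, 0.1, 0.05)
        assert set(np.where(res.table["significant"])[0]) == sig_oracle

    def test_null_data_yields_no_discoveries(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(0, 0.3, size=(300, 6)))
            res = permutation_fdr(X, ["a"] * 3 + ["b"] * 3, seed=seed)
            counts.append(int(res.table["significant"].sum()))
        assert np.mean(counts) < 1.0

    def test_seed_reproducible_when_sampled(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(50, 12)))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permutation_fdr(X, labels, n_perm=50, seed=11)
        r2 = permutation_fdr(X, labels, n_perm=50, seed=11)
        assert not r1.exhaustive
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_effect_orientation_via_groups(self):
        X = pd.DataFrame(np.array([[1.0, 1.1, 0.9, 0.0, 0.1, -0.1]]))
        labels = ["den"] * 3 + ["ctrl"] * 3
        res = permutation_fdr(X, labels, groups=("den", "ctrl"))
        assert res.table["effect"].iloc[0] == pytest.approx(1.0)
        res_r = permutation_fdr(X, labels, groups=("ctrl", "den"))
        assert res_r.table["effect"].iloc[0] == pytest.approx(-1.0)

    def test_rows_with_missing_replicates_not_testable(self):
        X = pd.DataFrame([[1.0, np.nan, np.nan, 0.0, 0.1, 0.2],
                          [1.0, 1.1, 0.9, 0.0, 0.1, 0.2]])
        res = permutation_fdr(X, ["a"] * 3 + ["b"] * 3)
        assert np.isnan(res.table["d_stat"].iloc[0])
        assert not res.table["significant"].iloc[0]
        assert np.isfinite(res.table["d_stat"].iloc[1])


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

class TestStoreyQValues:
    def test_hand_computed_step_up(self):
        res = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(res.table["q_value"], [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        res = storey_qvalues([0.2], pi0=0.5)
        assert res.table["q_value"].iloc[0] == pytest.approx(0.1)

    def test_small_m_defaults_pi0_to_one(self):
        res = storey_qvalues([0.5, 0.1, 0.9])
        assert res.pi0 == 1.0

    def test_uniform_p_pi0_near_one(self):
        rng = np.random.default_rng(8)
        res = storey_qvalues(rng.uniform(size=10_000))
        assert 0.9 <= res.pi0 <= 1.0

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        res = storey_qvalues(p)
        order = np.argsort(p)
        q_sorted = res.table["q_value"].to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-15).all()
        assert (res.table["q_value"] <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            storey_qvalues([-0.1])
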