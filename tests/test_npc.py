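"""Second-level NPC inference: estimators, corrections, synchrony, calibration."""

import numpy as np
import pytest
from scipy import stats

from npcombine import (
    fdr_bh,
    first_level_pvalues,
    fwe_correct,
    make_permutation_scheme,
    npc_test,
    second_level_pvalue,
)


def _fwe_oracle(obs, null):
    """Brute-force min-p FWE: enumerate permutations one by one."""
    k, p = null.shape
    out = np.empty(p)
    for j in range(p):
        count = sum(1 for row in null if row.min() <= obs[j])
        out[j] = (count + 1) / (k + 1)
    return out


def _bh_oracle(p):
    """Independent step-up BH: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestSecondLevel:
    def test_hand_enumeration(self):
        # surrogates (0.2, 0.5, 0.01, 0.8) vs observed 0.1: one is <=, so (1+1)/5
        null = np.array([0.2, 0.5, 0.01, 0.8])
        assert second_level_pvalue(np.array([0.1]), null)[0] == pytest.approx(0.4)

    def test_boundaries(self):
        null = np.linspace(0.1, 0.9, 10_000)
        assert second_level_pvalue(np.array([0.05]), null)[0] == pytest.approx(
            1 / 10_001
        )
        assert second_level_pvalue(np.array([0.95]), null)[0] == 1.0

    def test_ties_count_as_extreme(self):
        null = np.array([0.3, 0.3, 0.7])
        assert second_level_pvalue(np.array([0.3]), null)[0] == pytest.approx(3 / 4)


class TestFWE:
    def test_hand_enumeration_two_variables(self):
        obs = np.array([0.05, 0.5])
        null = np.array([[0.1, 0.2], [0.02, 0.6], [0.3, 0.4]])
        got = fwe_correct(obs, null)
        assert got == pytest.approx(_fwe_oracle(obs, null))
        assert got == pytest.approx([0.5, 1.0])

    def test_single_variable_reduces_to_uncorrected(self, rng):
        obs = rng.uniform(size=1)
        null = rng.uniform(size=(50, 1))
        assert fwe_correct(obs, null) == pytest.approx(
            second_level_pvalue(obs, null)
        )

    def test_dominates_uncorrected(self, rng):
        obs = rng.uniform(size=6)
        null = rng.uniform(size=(200, 6))
        assert np.all(fwe_correct(obs, null) >= second_level_pvalue(obs, null))


class TestFDR:
    def test_example(self):
        assert fdr_bh(np.array([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        assert fdr_bh(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_matches_independent_step_up(self, rng):
        p = rng.uniform(size=20)
        assert fdr_bh(p) == pytest.approx(_bh_oracle(p), rel=1e-12)


class TestNPCTest:
    def test_result_contract(self, small_dataset):
        y, x = small_dataset
        scheme = make_permutation_scheme(30, 99, seed=5)
        res = npc_test(y, x, scheme)
        grid = np.round(res.p_npc * 100) / 100
        assert np.all(np.abs(res.p_npc - grid) < 1e-12)  # multiples of 1/(K+1)
        assert np.all(res.p_npc >= 1 / 100) and np.all(res.p_npc <= 1.0)
        assert np.all(res.p_fwe >= res.p_npc)
        assert np.all(res.p_fdr >= res.p_npc)
        assert np.all(res.p_gmean <= res.p_mean)

    def test_bitwise_determinism(self, small_dataset):
        y, x = small_dataset
        scheme = make_permutation_scheme(30, 50, seed=5)
        r1 = npc_test(y, x, scheme)
        r2 = npc_test(y, x, scheme)
        assert np.array_equal(r1.p_npc, r2.p_npc)
        assert np.array_equal(r1.null_summaries, r2.null_summaries)

    def test_batching_does_not_change_result(self, small_dataset):
        y, x = small_dataset
        scheme = make_permutation_scheme(30, 101, seed=9)
        r1 = npc_test(y, x, scheme, batch_size=7)
        r2 = npc_test(y, x, scheme, batch_size=10_000)
        assert np.array_equal(r1.null_summaries, r2.null_summaries)

    def test_single_replication_equals_direct_permutation_test(self, rng):
        """With R = 1 the NPC reduces exactly to permuting the first-level p."""
        n, k = 24, 200
        y = rng.standard_normal((n, 1))
        x = rng.standard_normal(n)
        scheme = make_permutation_scheme(n, k, seed=11)
        res = npc_test(y, x, scheme)
        p_obs = stats.pearsonr(y[:, 0], x).pvalue
        count = sum(
            1
            for perm in scheme.perms
            if stats.pearsonr(y[:, 0], x[perm]).pvalue <= p_obs + 1e-12
        )
        assert res.p_npc[0] == pytest.approx((count + 1) / (k + 1))

    def test_synchrony_no_cross_variable_leakage(self, small_dataset):
        """Reordering trait columns reorders every output vector identically."""
        y, x = small_dataset
        scheme = make_permutation_scheme(30, 80, seed=2)
        res = npc_test(y, x, scheme)
        shuffle = np.array([2, 0, 1])
        res_shuf = npc_test(y, x[:, shuffle], scheme)
        # p_npc is a tie-robust count, so it commutes exactly; the continuous
        # summaries agree to BLAS reordering noise
        assert np.array_equal(res.p_npc[shuffle], res_shuf.p_npc)
        for attr in ("p_mean", "p_gmean", "p_fwe", "p_fdr"):
            assert getattr(res, attr)[shuffle] == pytest.approx(
                getattr(res_shuf, attr), rel=1e-12
            )

    def test_mean_combiner_second_level_uses_mean(self, small_dataset):
        y, x = small_dataset
        scheme = make_permutation_scheme(30, 60, seed=3)
        res = npc_test(y, x, scheme, combiner="mean")
        assert res.combiner == "mean"
        assert res.p_npc == pytest.approx(
            second_level_pvalue(res.p_mean, res.null_summaries)
        )


def test_null_calibration_uniform():
    """Under the global null, p_npc is uniform on its attainable grid.

    200 independent datasets (N = 50, R = 20, K = 500): chi-square
    goodness of fit on deciles must not reject at alpha = 0.01, and the
    rejection rate at alpha = 0.05 must sit within its binomial 99% range.
    """
    n_data, n, r, k = 200, 50, 20, 500
    root = np.random.SeedSequence(1234)
    pvals = np.empty(n_data)
    for i, child in enumerate(root.spawn(n_data)):
        rng_i = np.random.default_rng(child)
        y = rng_i.standard_normal((n, r))
        x = rng_i.standard_normal(n)
        scheme = make_permutation_scheme(
            n, k, seed=int(child.generate_state(1)[0] % 2**31)
        )
        pvals[i] = npc_test(y, x, scheme).p_npc[0]
    counts, _ = np.histogram(pvals, bins=10, range=(0.0, 1.0))
    gof = stats.chisquare(counts)
    assert gof.pvalue > 0.01
    n_reject = int((pvals < 0.05).sum())
    lo = stats.binom.ppf(0.005, n_data, 0.05)
    hi = stats.binom.ppf(0.995, n_data, 0.05)
    assert lo <= n_reject <= hi


def test_first_level_p_reused_by_npc(small_dataset):
    """npc_test's observed summaries come from the same first level as
    first_level_pvalues run standalone."""
    y, x = small_dataset
    scheme = make_permutation_scheme(30, 20, seed=1)
    res = npc_test(y, x, scheme)
    fl = first_level_pvalues(y, x)
    assert res.first_level.p0 == pytest.approx(fl.p0, rel=1e-14)
    assert res.p_gmean == pytest.approx(np.exp(np.log(fl.p0).mean(axis=0)))
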