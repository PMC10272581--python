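import itertools

import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.nullmodels import (
    bnti,
    nti,
    pairwise_turnover,
    rc_bray,
    shuffle_tip_labels,
)


class TestShuffleTipLabels:
    def test_offdiagonal_multiset_preserved(self, toy_dist):
        shuffled = shuffle_tip_labels(toy_dist, seed=3)
        a = np.sort(toy_dist.to_numpy()[np.triu_indices(3, 1)])
        b = np.sort(shuffled.to_numpy()[np.triu_indices(3, 1)])
        np.testing.assert_array_equal(a, b)
        assert list(shuffled.index) == list(toy_dist.index)

    def test_all_permutations_reachable(self):
        """Across seeds, a 4-label matrix visits all 24 label arrangements."""
        d = pd.DataFrame(
            np.arange(16).reshape(4, 4) + np.arange(16).reshape(4, 4).T,
            index=list("abcd"),
            columns=list("abcd"),
            dtype=float,
        )
        np.fill_diagonal(d.values, 0)
        seen = set()
        for seed in range(600):
            s = shuffle_tip_labels(d, seed=seed)
            seen.add(tuple(s.to_numpy()[np.triu_indices(4, 1)]))
        assert len(seen) == 24

    def test_identity_preserved_under_seeded_identity_perm(self, toy_dist):
        for seed in range(200):
            s = shuffle_tip_labels(toy_dist, seed=seed)
            if s.equals(toy_dist):
                return
        pytest.fail("identity permutation never sampled in 200 seeds")


class TestNTI:
    def test_exhaustive_null_matches_sampled(self, random_tree):
        """Sampled NTI (999 reps) agrees with the exhaustive tip-relabeling
        null on a 5-tip tree within Monte-Carlo error."""
        tree = random_tree(5, seed=2)
        d = ea.patristic_distances(tree)
        comm = pd.Series({d.index[0]: 3.0, d.index[2]: 1.0, d.index[4]: 2.0})
        exact = nti(comm, d, method="exhaustive").standardized
        samples = [
            nti(comm, d, reps=999, seed=s).standardized for s in range(20)
        ]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - exact) < 3 * se

    def test_sign_convention_clustered_pair_positive(self, random_tree):
        """A community of two sister tips has minimal MNTD, hence NTI > 0."""
        tree = random_tree(12, seed=8)
        d = ea.patristic_distances(tree)
        pair = d.replace(0, np.inf).stack().idxmin()
        comm = pd.Series(1.0, index=list(pair))
        assert nti(comm, d, reps=199, seed=0).standardized > 0

    def test_observed_not_mutated(self, random_tree):
        tree = random_tree(8, seed=1)
        d = ea.patristic_distances(tree)
        before = d.copy()
        comm = pd.Series(1.0, index=d.index[:4])
        res = nti(comm, d, reps=99, seed=5)
        pd.testing.assert_frame_equal(d, before)
        assert res.observed == pytest.approx(ea.mntd(comm, d))


class TestBetaNTI:
    def test_exhaustive_null_matches_sampled(self, random_tree):
        tree = random_tree(6, seed=4)
        d = ea.patristic_distances(tree)
        k = pd.Series(1.0, index=d.index[:3])
        m = pd.Series([2.0, 1.0, 1.0], index=d.index[2:5])
        exact = bnti(k, m, d, method="exhaustive").standardized
        samples = [bnti(k, m, d, reps=999, seed=s).standardized for s in range(20)]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - exact) < 3 * se

    def test_identical_communities_give_zero(self, random_tree):
        """betaMNTD of a pair with itself is 0 in observation and every
        null replicate; the standardized score is 0, not NaN."""
        tree = random_tree(8, seed=3)
        d = ea.patristic_distances(tree)
        comm = pd.Series([3.0, 1.0, 2.0], index=d.index[:3])
        res = bnti(comm, comm, d, reps=99, seed=1)
        assert res.observed == 0
        assert res.standardized == 0

    def test_deterministic_for_seed(self, random_tree):
        tree = random_tree(10, seed=6)
        d = ea.patristic_distances(tree)
        k = pd.Series(1.0, index=d.index[:4])
        m = pd.Series(1.0, index=d.index[4:8])
        a = bnti(k, m, d, reps=199, seed=42).standardized
        b = bnti(k, m, d, reps=199, seed=42).standardized
        assert a == b


class TestRCBray:
    def _pool(self, seed=0, n=8, s=30):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame(
            rng.multinomial(300, np.ones(s) / s, size=n),
            index=[f"c{i}" for i in range(n)],
            columns=[f"o{i}" for i in range(s)],
        )
        return t

    def test_bounds(self):
        pool = self._pool()
        res = rc_bray(pool.iloc[0], pool.iloc[1], pool, reps=99, seed=0)
        assert -1 <= res.standardized <= 1

    def test_identical_communities_go_to_minus_one(self):
        pool = self._pool(seed=1)
        res = rc_bray(pool.iloc[0], pool.iloc[0], pool, reps=199, seed=2)
        assert res.observed == 0
        assert res.standardized == pytest.approx(-1.0, abs=0.02)

    def test_monotone_in_observed_bc(self):
        """For a fixed null sample, a more dissimilar observed pair cannot
        get a smaller RC."""
        pool = self._pool(seed=3)
        rng = np.random.default_rng(7)
        rows = [rc_bray(pool.iloc[i], pool.iloc[j], pool, reps=199, seed=11)
                for i, j in [(0, 1), (2, 3)]]
        for res in rows:
            null = np.sort(res.null_values)
            rcs = []
            for obs in [null[10], null[100], null[190]]:
                less = (null < obs - 1e-12).sum()
                eq = (np.abs(null - obs) <= 1e-12).sum()
                rcs.append(2 * ((less + 0.5 * eq) / len(null) - 0.5))
            assert rcs == sorted(rcs)

    def test_single_community_pool_rejected(self):
        pool = self._pool().iloc[:1]
        with pytest.raises(ValueError):
            rc_bray(pool.iloc[0], pool.iloc[0], pool, reps=9, seed=0)


class TestPairwiseTurnover:
    def test_pair_count_and_schema(self, random_tree):
        tree = random_tree(30, seed=9)
        d = ea.patristic_distances(tree)
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            rng.multinomial(200, np.ones(30) / 30, size=10),
            index=[f"s{i}" for i in range(10)],
            columns=d.index,
        )
        t = pairwise_turnover(table, d, reps=49, seed=1)
        assert len(t) == 45  # C(10, 2)
        assert set(t.columns) >= {
            "sample_a", "sample_b", "bmntd_obs", "bnti", "bc_obs", "rc_bray",
            "process_class",
        }
        assert t["rc_bray"].between(-1, 1).all()

    def test_reproducible_and_order_independent_seeding(self, random_tree):
        tree = random_tree(15, seed=10)
        d = ea.patristic_distances(tree)
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.multinomial(100, np.ones(15) / 15, size=4) + 1,
            index=list("wxyz"),
            columns=d.index,
        )
        t1 = pairwise_turnover(table, d, reps=99, seed=5)
        t2 = pairwise_turnover(table, d, reps=99, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        # a pair's result does not depend on which other samples are present
        sub = pairwise_turnover(table.iloc[:2], d, reps=99, seed=5)
        assert sub.loc[0, "bnti"] == t1.loc[0, "bnti"]
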