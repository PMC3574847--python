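"""AMOVA components against hand computation and an independent formula oracle."""

import numpy as np
import pytest
from scipy.stats import kstest

from clonediv.amova import (
    amova,
    amova_one_level,
    amova_permutation_p,
    expand_by_group,
    pairwise_distance_matrix,
)
from clonediv.errors import AnalysisError
from clonediv.seq_io import collapse_haplotypes

from conftest import make_clones, mutate_at, random_dna


def oracle_components(dist, groups):
    """Explicit double-loop implementation of the variance decomposition."""
    groups = list(groups)
    n = len(groups)
    labels = sorted(set(groups))
    g = len(labels)
    d2 = np.asarray(dist, float) ** 2
    ssd_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssd_within = 0.0
    for lab in labels:
        idx = [i for i, x in enumerate(groups) if x == lab]
        ssd_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    sigma_w = ssd_within / (n - g)
    n_prime = (n - sum(groups.count(lab) ** 2 for lab in labels) / n) / (g - 1)
    sigma_a = ((ssd_total - ssd_within) / (g - 1) - sigma_w) / n_prime
    return sigma_a, sigma_w


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        d = pairwise_distance_matrix(["ACGT", "ACGT"])
        assert d[0, 1] == 0

    def test_hand_counted_distance(self):
        rng = np.random.default_rng(0)
        a = random_dna(rng, 50)
        b = mutate_at(a, [1, 10, 20, 30], rng)
        assert pairwise_distance_matrix([a, b])[0, 1] == 4

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        anc = random_dna(rng, 80)
        seqs = [mutate_at(anc, rng.choice(80, k, replace=False), rng) for k in (0, 3, 5, 9)]
        d = pairwise_distance_matrix(seqs)
        assert (d == d.T).all() and (np.diag(d) == 0).all()
        n = len(seqs)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestOneLevel:
    def test_degenerate_identical_sequences(self):
        d = np.zeros((6, 6))
        with pytest.warns(UserWarning):
            res = amova_one_level(d, ["a"] * 3 + ["b"] * 3)
        assert (res.pct_among, res.pct_within) == (0.0, 100.0)

    def test_hand_computed_two_by_two(self):
        """Within distance 0, between distance 4: all variation among groups."""
        d = np.array(
            [
                [0, 0, 4, 4],
                [0, 0, 4, 4],
                [4, 4, 0, 0],
                [4, 4, 0, 0],
            ]
        )
        res = amova_one_level(d, ["a", "a", "b", "b"])
        # by hand: SSD_total = 64/4 = 16, SSD_within = 0, n' = 2, sigma_a = 8
        assert res.sigma2_within == pytest.approx(0.0)
        assert res.sigma2_among == pytest.approx(8.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(6, 15))
            x = rng.integers(0, 10, size=(n, 20))
            d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
            groups = rng.choice(["a", "b", "c"], size=n)
            if min((groups == lab).sum() for lab in "abc") < 2:
                continue
            res = amova_one_level(d, groups)
            sa, sw = oracle_components(d, groups)
            assert res.sigma2_among == pytest.approx(sa)
            assert res.sigma2_within == pytest.approx(sw)

    def test_percentages_always_sum_to_100(self):
        rng = np.random.default_rng(3)
        saw_negative = False
        for seed in range(40):
            r = np.random.default_rng(seed)
            seqs = [random_dna(r, 40) for _ in range(10)]
            d = pairwise_distance_matrix(seqs)
            groups = ["a"] * 5 + ["b"] * 5
            res = amova_one_level(d, groups)
            assert res.pct_among + res.pct_within == pytest.approx(100.0)
            saw_negative |= res.sigma2_among < 0
        # random grouping of structureless data produces negative components
        assert saw_negative

    def test_scale_invariance_of_ratios(self):
        rng = np.random.default_rng(4)
        anc = random_dna(rng, 60)
        seqs = [mutate_at(anc, rng.choice(60, k, replace=False), rng) for k in (1, 2, 3, 6, 8, 9)]
        d = pairwise_distance_matrix(seqs).astype(float)
        groups = ["a", "a", "a", "b", "b", "b"]
        r1 = amova_one_level(d, groups)
        r2 = amova_one_level(2 * d, groups)
        assert r1.pct_among == pytest.approx(r2.pct_among)
        assert r1.phi_st == pytest.approx(r2.phi_st)

    def test_small_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(AnalysisError, match="b"):
            amova_one_level(d, ["a", "a", "b"])

    def test_invariant_to_within_group_order(self):
        rng = np.random.default_rng(5)
        seqs = [random_dna(rng, 40) for _ in range(8)]
        d = pairwise_distance_matrix(seqs)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        perm = np.array([2, 0, 3, 1, 6, 7, 4, 5])  # permutes within groups only
        r1 = amova_one_level(d, groups)
        r2 = amova_one_level(d[np.ix_(perm, perm)], groups[perm])
        assert r1.phi_st == pytest.approx(r2.phi_st)


class TestPermutationP:
    def test_perfect_separation_minimal_p(self):
        rng = np.random.default_rng(6)
        a = random_dna(rng, 200)
        b = mutate_at(a, range(50, 90), rng)
        seqs = [a] * 5 + [b] * 5
        d = pairwise_distance_matrix(seqs)
        groups = ["a"] * 5 + ["b"] * 5
        p, _ = amova_permutation_p(d, groups, n_perm=999, seed=0)
        # only label permutations recreating the split reach Phi_obs
        assert p <= 1 / (1 + 999) + 0.02

    def test_null_p_uniform(self):
        """Structureless data: permutation p approximately U(0,1) across datasets."""
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(100 + seed)
            seqs = [random_dna(rng, 60) for _ in range(12)]
            d = pairwise_distance_matrix(seqs)
            groups = ["a"] * 6 + ["b"] * 6
            p, _ = amova_permutation_p(d, groups, n_perm=499, seed=seed)
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_p_stable_across_seeds(self):
        rng = np.random.default_rng(7)
        anc = random_dna(rng, 100)
        seqs = [mutate_at(anc, rng.choice(100, rng.integers(0, 6), replace=False), rng) for _ in range(12)]
        d = pairwise_distance_matrix(seqs)
        groups = ["a"] * 6 + ["b"] * 6
        p1, _ = amova_permutation_p(d, groups, n_perm=10_000, seed=1)
        p2, _ = amova_permutation_p(d, groups, n_perm=10_000, seed=2)
        assert abs(p1 - p2) < 0.02


class TestExpandByGroup:
    def test_multiplicities_expand_with_carrier_groups(self):
        rng = np.random.default_rng(8)
        a = random_dna(rng, 50)
        b = mutate_at(a, [0, 1, 2], rng)
        clones = make_clones([(a, 2)], individual="N1") + make_clones(
            [(a, 1), (b, 3)], individual="S1"
        )
        table = collapse_haplotypes(clones)
        dist, labels = expand_by_group(table, {"N1": "North", "S1": "South"})
        assert len(labels) == 6
        assert sorted(labels) == ["North", "North", "South", "South", "South", "South"]
        res = amova(dist, labels, n_perm=99, seed=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)
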