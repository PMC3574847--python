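"""Connection limit, network construction and group/subgroup assignment."""

import math

import numpy as np

from clonediv.network import (
    assign_groups,
    build_networks,
    connection_limit,
    probability_of_parsimony,
)
from clonediv.simulate import simulate_strains

from conftest import make_table, mutate_at, random_dna


def oracle_limit(length: int, confidence: float) -> int:
    """Independent evaluation of the distinct-sites parsimony series in log space."""
    j, log_p = 1, 0.0
    while True:
        log_next = log_p + math.log1p(-(j) / length)  # P_{j+1} adds factor (1 - j/L)
        if math.exp(log_next) < confidence or j + 1 > length:
            return j
        j += 1
        log_p = log_next


class DisjointSet:
    """Tiny union-find used as the brute-force component oracle."""

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


class TestConnectionLimit:
    def test_matches_independent_series_evaluation(self):
        for length in (100, 300, 600, 1200):
            assert connection_limit(length, 0.95) == oracle_limit(length, 0.95)

    def test_monotone_in_length(self):
        assert connection_limit(1200, 0.95) >= connection_limit(600, 0.95)

    def test_near_certain_confidence_allows_single_steps_only(self):
        assert connection_limit(600, 1 - 1e-12) in (0, 1)

    def test_probability_series_decreasing(self):
        probs = [probability_of_parsimony(j, 600) for j in range(1, 30)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert probs[0] == 1.0


class TestBuildNetworks:
    def test_two_haplotypes_one_step(self):
        rng = np.random.default_rng(0)
        a = random_dna(rng, 60)
        b = mutate_at(a, [7], rng)
        net = build_networks(make_table([(a, 3), (b, 1)]), limit=5)
        assert net.n_components == 1
        (edge,) = net.graph.edges(data=True)
        assert edge[2]["steps"] == 1

    def test_distant_clusters_stay_separate(self):
        rng = np.random.default_rng(1)
        a = random_dna(rng, 200)
        a2 = mutate_at(a, [3], rng)
        b = mutate_at(a, range(50, 90), rng)  # 40 steps away
        b2 = mutate_at(b, [120], rng)
        net = build_networks(make_table([(a, 3), (a2, 2), (b, 3), (b2, 1)]), limit=8)
        assert net.n_components == 2

    def test_components_match_threshold_graph_oracle(self):
        from clonediv.amova import pairwise_distance_matrix

        rng = np.random.default_rng(2)
        for trial in range(10):
            anc = random_dna(rng, 120)
            seqs = [
                (mutate_at(anc, rng.choice(120, rng.integers(0, 12), replace=False), rng), 1)
                for _ in range(15)
            ]
            seqs = [(s, c) for s, c in dict(seqs).items()]  # dedupe
            table = make_table(seqs)
            limit = 4
            net = build_networks(table, limit)
            dist = pairwise_distance_matrix(table.sequences)
            dsu = DisjointSet(len(table))
            for i in range(len(table)):
                for j in range(i + 1, len(table)):
                    if dist[i, j] <= limit:
                        dsu.union(i, j)
            oracle = {}
            for i, hid in enumerate(table.ids):
                oracle.setdefault(dsu.find(i), set()).add(hid)
            assert {frozenset(c) for c in net.components} == {
                frozenset(v) for v in oracle.values()
            }

    def test_components_nonincreasing_in_limit(self):
        rng = np.random.default_rng(3)
        anc = random_dna(rng, 150)
        table = make_table(
            [(mutate_at(anc, rng.choice(150, rng.integers(1, 10), replace=False), rng), 1) for _ in range(10)]
        )
        counts = [build_networks(table, limit).n_components for limit in (1, 2, 4, 8, 16)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_path_steps_bounded_below_by_hamming(self):
        import networkx as nx

        from clonediv.amova import pairwise_distance_matrix

        rng = np.random.default_rng(4)
        anc = random_dna(rng, 150)
        table = make_table(
            [(mutate_at(anc, rng.choice(150, rng.integers(1, 6), replace=False), rng), 1) for _ in range(8)]
        )
        net = build_networks(table, limit=6)
        dist = pairwise_distance_matrix(table.sequences)
        idx = {hid: i for i, hid in enumerate(table.ids)}
        for comp in net.components:
            sub = net.graph.subgraph(comp)
            lengths = dict(nx.all_pairs_dijkstra_path_length(sub, weight="steps"))
            for a in comp:
                for b in comp:
                    if a != b:
                        assert lengths[a][b] >= dist[idx[a], idx[b]]


class TestAssignGroups:
    def test_single_component_no_subgroups(self):
        rng = np.random.default_rng(5)
        a = random_dna(rng, 100)
        table = make_table([(a, 2), (mutate_at(a, [1], rng), 1), (mutate_at(a, [2, 3], rng), 1)])
        net = build_networks(table, limit=8)
        groups = assign_groups(net, subgroup_threshold=5)
        assert set(groups.values()) == {"Group1"}
        assert all(v is None for v in net.subgroup_labels.values())

    def test_three_clusters_get_three_subgroups(self, default_params):
        strains = simulate_strains(default_params, seed=2)
        table = make_table([(seq, 1) for seq in strains.sequences.values()])
        net = build_networks(table, limit=8)
        assign_groups(net, subgroup_threshold=5)
        g1_subs = {
            net.subgroup_labels[h]
            for h, g in net.group_labels.items()
            if g == "Group1"
        }
        assert g1_subs == {"1a", "1b", "1c"}

    def test_subgroups_track_true_lineages(self, default_params):
        """Haplotypes simulated from one subgroup land in one label."""
        strains = simulate_strains(default_params, seed=6)
        table = make_table([(seq, 1) for seq in strains.sequences.values()])
        net = build_networks(table, limit=8)
        assign_groups(net, subgroup_threshold=5)
        seq_to_id = {h.sequence: h.haplotype_id for h in table}
        by_true = {}
        for sid, seq in strains.sequences.items():
            by_true.setdefault(strains.subgroup[sid], set()).add(
                net.subgroup_labels[seq_to_id[seq]] or net.group_labels[seq_to_id[seq]]
            )
        for true_sub, labels in by_true.items():
            assert len(labels) == 1, f"true subgroup {true_sub} split across {labels}"

    def test_labels_invariant_under_input_order(self):
        rng = np.random.default_rng(7)
        anc = random_dna(rng, 200)
        far = mutate_at(anc, range(100, 140), rng)
        seqs = [(anc, 4), (mutate_at(anc, [1], rng), 2), (far, 3), (mutate_at(far, [0], rng), 1)]
        t1 = make_table(seqs)
        t2 = make_table(list(reversed(seqs)))
        n1 = build_networks(t1, 8)
        n2 = build_networks(t2, 8)
        assign_groups(n1)
        assign_groups(n2)
        lab1 = {t1.by_id(h).sequence: g for h, g in n1.group_labels.items()}
        lab2 = {t2.by_id(h).sequence: g for h, g in n2.group_labels.items()}
        assert lab1 == lab2
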