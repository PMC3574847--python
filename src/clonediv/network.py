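"""Statistical-parsimony haplotype networks with a probability-based step limit.

Haplotypes are connected only while the probability that the implied chain of
single-step mutations is free of superimposed changes stays above a confidence
level (conventionally 95%).  The limit calculation here follows a distinct-
sites argument: if j mutational events fall independently and uniformly on the
L sites of the amplicon, the connection is parsimonious when no site is hit
twice,

    P_j = prod_{i=1}^{j-1} (1 - i / L),

and the connection limit is the largest j with P_j >= confidence.  P_j is
monotone decreasing in j and increasing in L, so longer fragments justify
longer connections.  A fixed limit can be supplied to override the series.

Networks are built by agglomeration over ascending distance classes: every
pair within the limit receives an edge annotated with its mutational steps and
the d-1 inferred intermediate haplotypes; ambiguity loops are retained rather
than broken, so the component structure equals that of the distance-threshold
graph.  Connected components, ordered by total haplotype frequency, define the
groups (Group 1 = largest); cutting edges longer than a subgroup threshold
inside a group defines its subgroups (1a, 1b, ... by descending frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import pandas as pd

from ._distance import encode, pairwise_matrix
from .errors import InputError, ParameterError
from .seq_io import HaplotypeTable

__all__ = [
    "probability_of_parsimony",
    "connection_limit",
    "HaploNetwork",
    "build_networks",
    "assign_groups",
]


def probability_of_parsimony(steps: int, length: int) -> float:
    """Probability that `steps` mutational events hit distinct sites of an
    amplicon of `length` sites (no superimposed changes)."""
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    if length < 1:
        raise ParameterError("length must be >= 1")
    p = Fraction(1)
    for i in range(1, min(steps, length + 1)):
        p *= Fraction(length - i, length)
    return float(p) if steps <= length else 0.0


def connection_limit(length: int, confidence: float = 0.95, max_steps: int | None = None) -> int:
    """Largest number of steps whose probability of parsimony reaches `confidence`."""
    if not (0.0 < confidence < 1.0):
        raise ParameterError("confidence must be in (0, 1)")
    cap = max_steps if max_steps is not None else length
    limit = 0
    for j in range(1, cap + 1):
        if probability_of_parsimony(j, length) >= confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class HaploNetwork:
    """A parsimony network: graph over haplotype ids plus derived labels."""

    graph: nx.Graph
    connection_limit: int
    components: list[list[str]]  # sorted by total frequency, descending
    group_labels: dict[str, str] = field(default_factory=dict)
    subgroup_labels: dict[str, str | None] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id_a": a,
                "id_b": b,
                "steps": d["steps"],
                "inferred_intermediates": d["steps"] - 1,
            }
            for a, b, d in sorted(self.graph.edges(data=True), key=lambda e: (e[2]["steps"], e[0], e[1]))
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "steps", "inferred_intermediates"])

    def labels_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype_id": hid,
                "frequency": self.graph.nodes[hid]["frequency"],
                "group": self.group_labels.get(hid, ""),
                "subgroup": self.subgroup_labels.get(hid) or "",
            }
            for hid in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows)


def build_networks(haplotypes: HaplotypeTable, limit: int) -> HaploNetwork:
    """Connect haplotypes whose substitution distance is within the limit.

    Edges are inserted in ascending distance order; within a distance class the
    higher-frequency pair comes first, then lexicographic ids (the insertion
    order is deterministic but, with loops retained, does not change the
    resulting graph).  Components are returned sorted by total frequency
    descending, ties by smallest member id.
    """
    if len(haplotypes) == 0:
        raise InputError("cannot build a network from an empty haplotype table")
    if limit < 0:
        raise ParameterError("limit must be >= 0")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.haplotype_id, frequency=h.count)
    dist = pairwise_matrix(encode(haplotypes.sequences))
    pairs = []
    for i in range(len(haplotypes)):
        for j in range(i + 1, len(haplotypes)):
            d = int(dist[i, j])
            if 1 <= d <= limit:
                hi, hj = haplotypes.haplotypes[i], haplotypes.haplotypes[j]
                pairs.append((d, -(hi.count + hj.count), hi.haplotype_id, hj.haplotype_id))
    for d, _, a, b in sorted(pairs):
        g.add_edge(a, b, steps=d)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-sum(g.nodes[h]["frequency"] for h in c), c[0]))
    return HaploNetwork(graph=g, connection_limit=limit, components=comps)


_SUBGROUP_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def assign_groups(network: HaploNetwork, subgroup_threshold: int = 5) -> dict[str, str]:
    """Label components Group1, Group2, ... (by descending total frequency) and
    split each group into subgroups by cutting edges longer than the threshold.

    Subgroup labels ("1a", "1b", ...) are assigned by descending subgroup
    frequency and only when a group splits into more than one subgroup.
    Results are stored on the network and the group map is returned.
    """
    groups: dict[str, str] = {}
    subgroups: dict[str, str | None] = {}
    for rank, comp in enumerate(network.components, start=1):
        gname = f"Group{rank}"
        for hid in comp:
            groups[hid] = gname
        sub = network.graph.subgraph(comp).copy()
        long_edges = [(a, b) for a, b, d in sub.edges(data=True) if d["steps"] > subgroup_threshold]
        sub.remove_edges_from(long_edges)
        parts = [sorted(p) for p in nx.connected_components(sub)]
        if len(parts) <= 1:
            for hid in comp:
                subgroups[hid] = None
            continue
        parts.sort(key=lambda p: (-sum(network.graph.nodes[h]["frequency"] for h in p), p[0]))
        for s_idx, part in enumerate(parts):
            label = f"{rank}{_SUBGROUP_LETTERS[s_idx]}"
            for hid in part:
                subgroups[hid] = label
    network.group_labels = groups
    network.subgroup_labels = subgroups
    return groups
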