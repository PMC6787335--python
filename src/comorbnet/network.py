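"""Comorbidity network construction and fast-greedy community detection.

The network has one node per condition appearing in at least one retained
rule (node attribute: weighted prevalence, which drives node size in plots)
and one undirected edge per unordered pair with a retained rule direction
(edge weight: the unweighted number of stratum participants with both
conditions, which drives edge width).

Communities are found by agglomerative greedy modularity maximisation
(Clauset–Newman–Moore): start from singleton communities and repeatedly merge
the pair of communities giving the largest modularity increase, returning the
partition at peak modularity. Ties in ΔQ are broken lexicographically on the
smallest member label so results are deterministic across platforms.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cohort import CohortTable
from .prevalence import weighted_prevalence
from .rules import RuleSet


@dataclass
class CommunityPartition:
    """Node → community assignment with its modularity and merge history."""

    membership: dict
    modularity: float
    merge_history: list  # [(label_a, label_b, Q_after_merge), ...]

    def communities(self) -> list[set]:
        out: dict = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def build_network(ruleset: RuleSet, cohort: CohortTable) -> nx.Graph:
    """Undirected comorbidity network from a pruned rule set.

    Both rule directions of a pair collapse onto a single edge. Isolated
    conditions (no retained rule) are excluded.
    """
    stratum = ruleset.stratum
    if stratum not in cohort.strata:
        raise ValueError(
            f"ruleset stratum {stratum!r} not present in cohort strata "
            f"{cohort.strata}")
    x = cohort.indicators(stratum)
    names = cohort.condition_names
    idx = {name: j for j, name in enumerate(names)}
    g = nx.Graph(stratum=stratum)
    for pair in sorted(ruleset.pairs(), key=sorted):
        a, b = sorted(pair)
        count = int((x[:, idx[a]] * x[:, idx[b]]).sum())
        for node in (a, b):
            if node not in g:
                g.add_node(node,
                           prevalence=weighted_prevalence(cohort, node, stratum))
        g.add_edge(a, b, cooccurrence_count=count, weight=count)
    return g


def modularity(network: nx.Graph, partition: dict,
               use_edge_weights: bool = True) -> float:
    """Newman modularity Q = Σ_c [ W_c/W − (S_c/2W)² ].

    W is the total edge weight, W_c the intra-community weight and S_c the
    summed (weighted) degree of community c. Every node must be assigned.
    """
    missing = [v for v in network.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition is missing nodes: {sorted(missing)}")
    weight_key = "weight" if use_edge_weights else None
    total = network.size(weight=weight_key)
    if total == 0:
        return 0.0
    intra: dict = {}
    degree: dict = {}
    for u, v, data in network.edges(data=True):
        w = data.get("weight", 1.0) if use_edge_weights else 1.0
        degree[partition[u]] = degree.get(partition[u], 0.0) + w
        degree[partition[v]] = degree.get(partition[v], 0.0) + w
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    q = 0.0
    for c in set(partition[v] for v in network.nodes):
        q += intra.get(c, 0.0) / total - (degree.get(c, 0.0) / (2 * total)) ** 2
    return q


def detect_communities(network: nx.Graph,
                       use_edge_weights: bool = True) -> CommunityPartition:
    """Fast-greedy (Clauset–Newman–Moore) modularity maximisation.

    Merges proceed all the way to a single community while tracking Q; the
    returned partition is the one at peak modularity (the initial singleton
    partition is a candidate, so a single-node network yields one community
    with Q = 0).
    """
    nodes = sorted(network.nodes)
    if not nodes:
        raise ValueError("cannot detect communities in an empty network")
    total = network.size(weight="weight" if use_edge_weights else None)
    # community state: label = smallest member; members, weighted degree a_c,
    # and pairwise inter-community weights e
    members = {v: {v} for v in nodes}
    if total == 0:
        membership = {v: i for i, v in enumerate(nodes)}
        return CommunityPartition(membership, 0.0, [])
    deg = {v: 0.0 for v in nodes}
    e: dict = {}
    for u, v, data in network.edges(data=True):
        w = data.get("weight", 1.0) if use_edge_weights else 1.0
        deg[u] += w
        deg[v] += w
        if u != v:
            key = (min(u, v), max(u, v))
            e[key] = e.get(key, 0.0) + w

    def current_q():
        intra = {}
        label_of = {v: lab for lab, mem in members.items() for v in mem}
        for (u, v), w in e.items():
            if label_of[u] == label_of[v]:
                intra[label_of[u]] = intra.get(label_of[u], 0.0) + w
        q = 0.0
        for lab, mem in members.items():
            s = sum(deg[v] for v in mem)
            q += intra.get(lab, 0.0) / total - (s / (2 * total)) ** 2
        return q

    history = []
    q = current_q()
    best_q = q
    best_partition = {v: lab for lab, mem in members.items() for v in mem}

    while len(members) > 1:
        best = None  # (dq, label_i, label_j)
        labels = sorted(members)
        comm_deg = {lab: sum(deg[v] for v in mem) for lab, mem in members.items()}
        # inter-community weight
        label_of = {v: lab for lab, mem in members.items() for v in mem}
        inter: dict = {}
        for (u, v), w in e.items():
            lu, lv = label_of[u], label_of[v]
            if lu != lv:
                key = (min(lu, lv), max(lu, lv))
                inter[key] = inter.get(key, 0.0) + w
        for li, lj in itertools.combinations(labels, 2):
            eij = inter.get((li, lj), 0.0)
            dq = eij / total - 2 * (comm_deg[li] / (2 * total)) * (comm_deg[lj] / (2 * total))
            if best is None or dq > best[0] + 1e-12:
                best = (dq, li, lj)
            # ties: keep the lexicographically earliest (li, lj); the sorted
            # iteration order guarantees that without extra bookkeeping
        dq, li, lj = best
        members[li] = members[li] | members[lj]
        del members[lj]
        q += dq
        history.append((li, lj, q))
        if q > best_q + 1e-12:
            best_q = q
            best_partition = {v: lab for lab, mem in members.items() for v in mem}

    # canonical community ids: 0..C-1 in label order
    labs = sorted(set(best_partition.values()))
    relabel = {lab: i for i, lab in enumerate(labs)}
    membership = {v: relabel[best_partition[v]] for v in nodes}
    q_check = modularity(network, membership, use_edge_weights)
    if abs(q_check - best_q) > 1e-9:  # pragma: no cover - internal consistency
        raise AssertionError("merge-tracked Q disagrees with recomputed Q")
    return CommunityPartition(membership, q_check, history)
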