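"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined by a minimum-spanning forest over Hamming distances
on retained sites, using only connections at or below the parsimony
connection limit: the largest number of mutational steps that can be
accepted with >= 95% probability of involving no superimposed (homoplasious)
change.  Multi-step edges pass through inferred, unsampled intermediate
haplotypes; equally parsimonious alternative connections are retained as
ambiguity loops rather than resolved automatically (resolution classically
uses frequency and geographic criteria that need human judgement).

The published TCS software constants are not fully documented, so the
connection limit here uses an explicit Jukes-Cantor multiple-hits
estimator: with j observed differences over L sites the JC-corrected
expected number of substitutions is L*d_JC(j/L); the probability that no
extra (hidden) change occurred is approximated as

    P(j) = exp(-(L * d_JC(j/L) - j)),

and the limit is the largest j with P(j) >= confidence.  The limit can be
overridden wherever it is consumed, so a published figure's structure can
be reproduced by forcing its limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeDataset


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j observed differences over L sites reflect exactly
    j mutations (no multiple hits), under the JC excess-substitution model."""
    if j == 0:
        return 1.0
    p = j / L
    if p >= 0.75:
        return 0.0
    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return float(np.exp(-(L * d - j)))


def connection_limit(L: int, confidence: float = 0.95) -> int:
    """Largest step count connectable at the given confidence (>= 1)."""
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while j < L and parsimony_probability(j + 1, L) >= confidence:
        j += 1
    return j


@dataclass
class ParsimonyNetwork:
    graph: nx.Graph                      # nodes: haplotype ids; edges: steps
    subnetworks: list[set[str]]
    connection_limit_steps: int
    confidence: float
    inferred_intermediates: int
    ambiguities: list[tuple[str, str, int]]  # alternative equal-cost edges
    root_scores: dict[str, float] = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"haplotype_1": u, "haplotype_2": v, "steps": d["steps"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["haplotype_1", "haplotype_2", "steps"])

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for i, sub in enumerate(self.subnetworks, start=1):
            for h in sorted(sub):
                rows.append({"haplotype": h, "subnetwork": i})
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        serial = 0
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, frequency=int(data.get("frequency", 0)),
                       populations=";".join(data.get("populations", [])),
                       inferred=False)
        for u, v, d in self.graph.edges(data=True):
            steps = d["steps"]
            if steps == 1:
                g.add_edge(u, v, steps=1)
            else:
                prev = u
                for s in range(steps - 1):
                    serial += 1
                    mid = f"mv{serial}"
                    g.add_node(mid, frequency=0, populations="", inferred=True)
                    g.add_edge(prev, mid, steps=1)
                    prev = mid
                g.add_edge(prev, v, steps=1)
        nx.write_graphml(g, path)


def build_network(
    hd: HaplotypeDataset, limit: int | None = None, confidence: float = 0.95
) -> ParsimonyNetwork:
    """Minimum-spanning forest over haplotypes using edges <= the limit.

    Kruskal with deterministic tie order (steps, then lexical node order);
    non-tree edges that could replace a tree edge of the same weight are
    reported as ambiguity loops.  Components of the forest are the
    subnetworks; singletons are valid subnetworks.
    """
    L = len(hd.retained_sites)
    if limit is None:
        limit = connection_limit(L, confidence)
    ids = [h for h, _ in hd.haplotypes]
    m = hd.retained_matrix()
    diff = (m[:, None, :] != m[None, :, :]).sum(axis=2)
    counts = hd.subset_counts(None)

    g = nx.Graph()
    for idx, hid in enumerate(ids):
        pops = [p for p in hd.populations if hd.counts.loc[hid, p] > 0]
        g.add_node(hid, frequency=int(counts[idx]), populations=pops)
    candidates = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if 0 < diff[i, j] <= limit:
                candidates.append((int(diff[i, j]), ids[i], ids[j]))
    candidates.sort()

    forest = nx.Graph()
    forest.add_nodes_from(ids)
    for steps, u, v in candidates:
        if not nx.has_path(forest, u, v):
            forest.add_edge(u, v, steps=steps)
            g.add_edge(u, v, steps=steps)

    ambiguities = []
    for steps, u, v in candidates:
        if g.has_edge(u, v):
            continue
        path = nx.shortest_path(forest, u, v)
        max_w = max(
            forest.edges[a, b]["steps"] for a, b in zip(path[:-1], path[1:])
        )
        if steps == max_w:
            ambiguities.append((u, v, steps))

    subnetworks = [set(c) for c in nx.connected_components(g)]
    subnetworks.sort(key=lambda s: (-len(s), min(s)))
    intermediates = sum(d["steps"] - 1 for _, _, d in g.edges(data=True))
    net = ParsimonyNetwork(
        graph=g,
        subnetworks=subnetworks,
        connection_limit_steps=limit,
        confidence=confidence,
        inferred_intermediates=intermediates,
        ambiguities=ambiguities,
    )
    net.root_scores = root_scores(net)
    return net


def root_scores(net: ParsimonyNetwork) -> dict[str, float]:
    """Heuristic rooting weights: frequency x (1 + degree), normalised per
    subnetwork.  A simple surrogate for outgroup-free root probability -
    frequent, central haplotypes score highest (coalescent expectation that
    the ancestral haplotype is common and interior)."""
    scores: dict[str, float] = {}
    for sub in net.subnetworks:
        raw = {
            h: net.graph.nodes[h]["frequency"] * (1 + net.graph.degree[h])
            for h in sub
        }
        total = sum(raw.values())
        for h, val in raw.items():
            scores[h] = val / total if total > 0 else 1.0 / len(sub)
    return scores
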