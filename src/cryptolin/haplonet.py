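"""Haplotype collapsing and fixed-limit statistical parsimony networks.

Aligned organellar sequences are collapsed to unique haplotypes, pairwise
mutational step counts are computed under a configurable gap treatment,
and haplotypes are connected into a network by adding single-step edges in
order of increasing distance up to a fixed connection limit (the TCS-style
manual limit; the probability-of-parsimony calculation is not attempted).
Multi-step connections are expanded through inferred intermediate nodes;
exact ties for a component-merging connection are retained as marked
alternative ("loop") edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import HaplotypeSet

__all__ = [
    "collapse_haplotypes",
    "pairwise_steps",
    "build_parsimony_network",
    "ParsimonyNetwork",
]

GAP = "-"
GAP_MODES = ("ignore", "fifth_state", "indel_block_as_one")


def collapse_haplotypes(alignment: dict[str, str]) -> HaplotypeSet:
    """Collapse aligned sequences to unique haplotypes.

    Haplotypes are numbered h1, h2, ... by decreasing frequency, ties
    broken by first occurrence in the input.
    """
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    seq_first: dict[str, int] = {}
    seq_count: dict[str, int] = {}
    for pos, (ind, seq) in enumerate(alignment.items()):
        seq = seq.upper()
        seq_count[seq] = seq_count.get(seq, 0) + 1
        seq_first.setdefault(seq, pos)
    ordered = sorted(seq_count, key=lambda s: (-seq_count[s], seq_first[s]))
    hap_of_seq = {seq: f"h{i + 1}" for i, seq in enumerate(ordered)}
    sequences = {hap_of_seq[seq]: seq for seq in ordered}
    assignment = {ind: hap_of_seq[seq.upper()] for ind, seq in alignment.items()}
    return HaplotypeSet(sequences, assignment)


def _steps(a: str, b: str, gap_mode: str) -> int:
    if gap_mode == "ignore":
        return sum(1 for x, y in zip(a, b) if x != y and x != GAP and y != GAP)
    if gap_mode == "fifth_state":
        return sum(1 for x, y in zip(a, b) if x != y)
    if gap_mode == "indel_block_as_one":
        subs = sum(
            1 for x, y in zip(a, b) if x != y and x != GAP and y != GAP
        )
        indels = 0
        in_block = False
        for x, y in zip(a, b):
            one_gapped = (x == GAP) != (y == GAP)
            if one_gapped and not in_block:
                indels += 1
            in_block = one_gapped
        return subs + indels
    raise ValueError(f"unknown gap_mode {gap_mode!r}; choose from {GAP_MODES}")


def pairwise_steps(h: HaplotypeSet, gap_mode: str = "indel_block_as_one") -> pd.DataFrame:
    """Integer mutational-step distance matrix between haplotypes."""
    if gap_mode not in GAP_MODES:
        raise ValueError(f"unknown gap_mode {gap_mode!r}; choose from {GAP_MODES}")
    ids = h.haplotype_ids
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, j in combinations(ids, 2):
        d = _steps(h.sequences[i], h.sequences[j], gap_mode)
        mat.loc[i, j] = mat.loc[j, i] = d
    return mat


@dataclass
class ParsimonyNetwork:
    """Haplotype network: observed nodes, inferred intermediates, step edges."""

    graph: nx.Graph  # nodes carry frequency (0 for inferred), edges kind
    components: list[set[str]]  # observed-haplotype membership per component
    limit: int

    def observed_edges(self) -> list[tuple[str, str, int]]:
        """Haplotype-to-haplotype connections with their step counts
        (collapsing inferred intermediates back into single entries)."""
        return [
            (u, v, d["steps"])
            for u, v, d in self._hap_graph().edges(data=True)
        ]

    def _hap_graph(self) -> nx.Graph:
        G = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            if data.get("observed", False):
                G.add_node(node, **data)
        for u, v, data in self.graph.edges(data=True):
            su, sv = data.get("span", (u, v))
            if su != sv and not G.has_edge(su, sv):
                G.add_edge(su, sv, steps=data["total_steps"], kind=data["kind"])
        return G

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "steps": d["steps"], "kind": d["kind"]}
            for u, v, d in self._hap_graph().edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "steps", "kind"])

    def write_graphml(self, path) -> None:
        G = self.graph.copy()
        for u, v, d in G.edges(data=True):
            d.pop("span", None)  # tuples are not GraphML-serializable
        nx.write_graphml(G, str(path))


def build_parsimony_network(
    h: HaplotypeSet,
    limit: int = 7,
    gap_mode: str = "indel_block_as_one",
) -> ParsimonyNetwork:
    """Fixed-limit statistical parsimony network.

    Candidate connections are sorted by increasing step count (ties:
    higher summed haplotype frequency first, then lexicographic ids) and
    added while they join distinct components; pairs farther apart than
    ``limit`` are never connected, so the result may be a forest.  A
    connection whose step count exactly ties the one that merged the same
    two components is kept as an alternative edge of kind ``"loop"``.
    Connections of more than one step are expanded through inferred
    intermediate nodes of frequency zero.
    """
    if limit < 1:
        raise ValueError("connection limit must be at least 1")
    if not h.sequences:
        raise ValueError("empty haplotype set")
    freq = h.frequencies
    dist = pairwise_steps(h, gap_mode)
    ids = h.haplotype_ids
    pairs = sorted(
        ((dist.loc[u, v], u, v) for u, v in combinations(ids, 2)),
        key=lambda t: (t[0], -(freq[t[1]] + freq[t[2]]), t[1], t[2]),
    )
    parent = {u: u for u in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    G = nx.Graph()
    for u in ids:
        G.add_node(u, frequency=freq[u], observed=True)
    n_intermediate = 0
    accepted: list[tuple[str, str, int, str]] = []
    i = 0
    while i < len(pairs):
        d = pairs[i][0]
        # process one distance class at a time so exact ties can be detected
        block = [p for p in pairs if p[0] == d]
        i += len(block)
        if d == 0 or d > limit:
            continue
        roots_at_start = {u: find(u) for u in ids}
        for _, u, v in block:
            if find(u) != find(v):
                accepted.append((u, v, d, "parsimony"))
                parent[find(u)] = find(v)
            elif roots_at_start[u] != roots_at_start[v]:
                accepted.append((u, v, d, "loop"))
    for u, v, d, kind in accepted:
        prev = u
        for step in range(1, d):
            n_intermediate += 1
            mid = f"i{n_intermediate}"
            G.add_node(mid, frequency=0, observed=False)
            G.add_edge(prev, mid, steps=1, kind=kind, span=(u, v), total_steps=d)
            prev = mid
        G.add_edge(prev, v, steps=1, kind=kind, span=(u, v), total_steps=d)
    comps = []
    seen = set()
    for u in ids:
        r = find(u)
        if r not in seen:
            seen.add(r)
            comps.append({v for v in ids if find(v) == r})
    return ParsimonyNetwork(G, comps, limit)
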