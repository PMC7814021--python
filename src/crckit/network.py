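"""TF-SE regulatory network, degrees, auto-regulatory cliques, CES.

A TF node enters the network iff it is expressed (TPM above threshold) and
has at least one proximal SE.  A directed edge s -> t exists iff a motif
hit of s falls inside an ATAC-within-SE search region of an SE proximal to
t.  Core regulatory circuitries (CRCs) are the maximal cliques (size >= 2)
of the bidirectional support graph restricted to auto-regulated TFs: each
member binds its own SE and the SEs of every other member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .motifs import MotifHit

__all__ = [
    "TFNode",
    "CRCNetwork",
    "CRCResult",
    "build_network",
    "degrees",
    "enumerate_cliques",
    "clique_enrichment",
    "DEFAULT_TPM_THRESHOLD",
]

DEFAULT_TPM_THRESHOLD = 10.0


@dataclass(frozen=True)
class TFNode:
    symbol: str
    tpm: float
    proximal_ses: frozenset[str] = frozenset()

    def expressed(self, tpm_threshold: float = DEFAULT_TPM_THRESHOLD) -> bool:
        return self.tpm >= tpm_threshold

    def admitted(self, tpm_threshold: float = DEFAULT_TPM_THRESHOLD) -> bool:
        return self.expressed(tpm_threshold) and bool(self.proximal_ses)


@dataclass
class CRCNetwork:
    """Directed TF graph plus per-edge SE support."""

    graph: nx.DiGraph
    # (source, target) -> set of SE ids whose search regions carry a hit
    se_support: dict[tuple[str, str], frozenset[str]]
    nodes: dict[str, TFNode]

    def edge_hits(self, s: str, t: str) -> int:
        return self.graph.edges[s, t]["n_hits"] if self.graph.has_edge(s, t) else 0


@dataclass
class CRCResult:
    cliques: list[tuple[str, ...]]
    degrees: pd.DataFrame
    ces: dict[str, float]


def build_network(
    tf_nodes: Sequence[TFNode],
    se_gene_map: Mapping[str, Sequence[str]],
    hits: Sequence[MotifHit],
    region_se_ids: Optional[Mapping] = None,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> CRCNetwork:
    """Assemble the directed TF-SE network from motif hits.

    ``se_gene_map`` maps SE id -> gene symbols assigned to that SE;
    each hit's search region must be traceable to one SE, either via
    ``region_se_ids`` (region name -> SE id) or the region name itself
    being an SE id.
    """
    known_ses = set(se_gene_map)
    admitted = {
        n.symbol: n for n in tf_nodes if n.admitted(tpm_threshold)
    }
    # SE -> admitted TFs for which this SE is proximal
    se_targets: dict[str, set[str]] = {}
    for sym, node in admitted.items():
        for se in node.proximal_ses:
            se_targets.setdefault(se, set()).add(sym)

    g = nx.DiGraph()
    g.add_nodes_from(sorted(admitted))
    for sym, node in admitted.items():
        g.nodes[sym]["tpm"] = node.tpm
    support: dict[tuple[str, str], set[str]] = {}
    hit_counts: dict[tuple[str, str], int] = {}
    out_ses: dict[str, set[str]] = {s: set() for s in admitted}
    for h in hits:
        se_id = None
        if region_se_ids is not None:
            se_id = region_se_ids.get(h.region.name)
        if se_id is None:
            se_id = h.region.name
        if se_id not in known_ses:
            raise KeyError(
                f"motif hit region {h.region.name!r} references unknown SE "
                f"{se_id!r}"
            )
        source = h.pwm_name
        if source not in admitted:
            continue
        targets = se_targets.get(se_id, ())
        if targets:
            out_ses[source].add(se_id)
        for t in sorted(targets):
            support.setdefault((source, t), set()).add(se_id)
            hit_counts[(source, t)] = hit_counts.get((source, t), 0) + 1
    for (s, t), ses in support.items():
        g.add_edge(s, t, n_hits=hit_counts[(s, t)])
    for s, ses in out_ses.items():
        g.nodes[s]["bound_ses"] = frozenset(ses)
    return CRCNetwork(
        graph=g,
        se_support={k: frozenset(v) for k, v in support.items()},
        nodes=admitted,
    )


def degrees(net: CRCNetwork) -> pd.DataFrame:
    """Per-TF in/out/total degree.

    in(t) = number of distinct TFs with an edge into t (self counted);
    out(s) = number of distinct SEs, among admitted targets' proximal SEs,
    that contain at least one hit of s (self counted); total = in + out.
    """
    rows = []
    for sym in sorted(net.graph.nodes):
        indeg = net.graph.in_degree(sym)
        outdeg = len(net.graph.nodes[sym].get("bound_ses", ()))
        rows.append((sym, net.nodes[sym].tpm, indeg, outdeg, indeg + outdeg))
    return pd.DataFrame(
        rows, columns=["symbol", "tpm", "in_degree", "out_degree", "total_degree"]
    ).set_index("symbol")


def enumerate_cliques(net: CRCNetwork) -> list[tuple[str, ...]]:
    """Maximal interconnected auto-regulatory cliques (CRCs).

    Restrict to auto-regulated TFs (self-edge), build the undirected
    support graph with an edge where both directions exist, and enumerate
    maximal cliques of size >= 2 (Bron-Kerbosch with pivoting via
    networkx).  Each clique is alphabetically sorted; the list is sorted by
    (size desc, lexicographic).
    """
    auto = [n for n in net.graph.nodes if net.graph.has_edge(n, n)]
    support = nx.Graph()
    support.add_nodes_from(auto)
    for i, a in enumerate(auto):
        for b in auto[i + 1 :]:
            if net.graph.has_edge(a, b) and net.graph.has_edge(b, a):
                support.add_edge(a, b)
    cliques = [
        tuple(sorted(c)) for c in nx.find_cliques(support) if len(c) >= 2
    ]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def clique_enrichment(cliques: Sequence[Sequence[str]]) -> dict[str, float]:
    """CES: fraction of all cliques containing each member TF.

    Zero cliques -> empty mapping (scores undefined, reported missing).
    """
    if not cliques:
        return {}
    counts: dict[str, int] = {}
    for c in cliques:
        for tf in set(c):
            counts[tf] = counts.get(tf, 0) + 1
    return {tf: counts[tf] / len(cliques) for tf in sorted(counts)}
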