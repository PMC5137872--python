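"""Shared fixtures: hand-built micro-graphs and graph transforms."""

import pytest

from graphpep.graph import ContractedDBG, Edge, revcomp


def make_graph(k: int, seqs: dict[str, str], links: list[tuple[str, str]]) -> ContractedDBG:
    """Build a bidirected graph from forward edges; twins and mirrored links
    are added explicitly so tests control exactly what the graph contains."""
    edges = {}
    for eid, seq in seqs.items():
        tid = eid + "'"
        if revcomp(seq) == seq:
            edges[eid] = Edge(eid, seq, eid, [])
            continue
        edges[eid] = Edge(eid, seq, tid, [])
        edges[tid] = Edge(tid, revcomp(seq), eid, [])
    for a, b in links:
        edges[a].successors.append(b)
        ta, tb = edges[a].twin_id, edges[b].twin_id
        if (tb, ta) != (a, b):  # avoid doubling self-symmetric links
            edges[tb].successors.append(ta)
    return ContractedDBG(k, edges)


def twin_relabel(g: ContractedDBG) -> ContractedDBG:
    """Swap every edge with its twin (ids preserved, contents exchanged)."""
    tw = {eid: g.edges[eid].twin_id for eid in g.edges}
    edges = {}
    for x in g.edges:
        old = g.edges[tw[x]]
        edges[x] = Edge(x, old.seq, tw[old.twin_id], sorted(tw[s] for s in old.successors))
    return ContractedDBG(g.k, edges)


@pytest.fixture
def two_edge_graph():
    """k=4 micro-fixture: ATGAAA -> AAACGTAAATGA, spelling ATGAAACGTAAATGA
    (codons M K R K stop)."""
    return make_graph(4, {"e1": "ATGAAA", "e2": "AAACGTAAATGA"}, [("e1", "e2")])


@pytest.fixture
def single_edge_graph():
    return make_graph(4, {"e": "ATGAAACGTAAATAA"}, [])
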