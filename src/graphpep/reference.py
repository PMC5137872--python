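"""Slow reference implementations used to validate the optimized algorithms.

These are deliberately naive: the peptide oracle spells every path of the
graph up to the edge bound and applies the fully-tryptic-segment definition
verbatim on the spelled strings; the set-cover oracle enumerates all subsets.
They exist so that tests can compare the production code against an
independent computation, and are unsuitable for anything but tiny inputs.
"""

from __future__ import annotations

from itertools import combinations

from .graph import ContractedDBG, spell_path
from .peptides import GeneticCode, PepParams, STANDARD_CODE

__all__ = ["brute_force_peptides", "exact_min_cover", "greedy_bound"]


def _all_paths(g: ContractedDBG, max_edges: int, max_paths: int = 2_000_000):
    """Every edge path of length <= max_edges (revisits allowed)."""
    count = 0
    for start in sorted(g.edges):
        stack = [[start]]
        while stack:
            path = stack.pop()
            count += 1
            if count > max_paths:
                raise RuntimeError("path enumeration budget exceeded")
            yield path
            if len(path) < max_edges:
                for s in g.edges[path[-1]].successors:
                    stack.append(path + [s])


def brute_force_peptides(
    g: ContractedDBG,
    params: PepParams = PepParams(),
    code: GeneticCode = STANDARD_CODE,
) -> set[str]:
    """All fully tryptic peptide sequences by exhaustive path spelling.

    Only defined for graphs whose edges are all short (no long-edge gene
    pass); raises otherwise.
    """
    if any(len(e.seq) > params.long_edge_threshold for e in g.edges.values()):
        raise ValueError("oracle only supports graphs with short edges")
    kr = params.cleavage
    out: set[str] = set()
    for path in _all_paths(g, params.max_edges_per_path):
        s = spell_path(g, path)
        for q in range(len(s)):
            is_start = q + 3 <= len(s) and s[q : q + 3] in code.starts
            after_kr = q >= 3 and code.table.get(s[q - 3 : q]) in kr
            if not (is_start or after_kr):
                continue
            pep = []
            ncleav = 0
            pos = q
            while pos + 3 <= len(s):
                aa = code.table[s[pos : pos + 3]]
                if aa == "*":
                    if pep and params.min_pep_len <= len(pep) <= params.max_pep_len:
                        out.add("".join(pep))
                    break
                pep.append(aa)
                pos += 3
                if len(pep) > params.max_pep_len:
                    break
                if aa in kr:
                    if params.min_pep_len <= len(pep):
                        out.add("".join(pep))
                    ncleav += 1
                    if ncleav > params.max_miscleavage:
                        break
    return out


def exact_min_cover(sets: dict[str, frozenset], universe: frozenset) -> int:
    """Size of a minimum family of ``sets`` whose union covers ``universe``.

    Exhaustive search over subsets, smallest first; assumes a cover exists.
    """
    ids = sorted(sets)
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            u = frozenset().union(*(sets[c] for c in combo))
            if universe <= u:
                return r
    raise ValueError("no cover exists")


def greedy_bound(universe_size: int) -> float:
    """ln(n) + 1 approximation guarantee of greedy set cover."""
    import math

    return math.log(max(universe_size, 1)) + 1.0
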