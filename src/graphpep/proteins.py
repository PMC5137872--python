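"""Protein inference by a second, peptide-constrained graph traversal.

Identified peptides are mapped back onto the assembly graph; the traversal
is then restricted to the *covered* edges (those spanned by at least one
identified peptide's DNA segment) and enumerates candidate open reading
frames.  A greedy minimum set cover selects a smallest family of candidate
proteins containing every identified peptide.  Where no in-frame start or
stop is reachable inside the covered subgraph, maximal fragments are emitted
with their completeness flags cleared rather than dropped, so the coverage
contract (every mappable peptide is contained in some output protein) holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import ContractedDBG, PathSegment, spell_path
from .peptides import (
    GeneticCode,
    PepParams,
    STANDARD_CODE,
    TrypticPeptide,
    find_long_edge_orfs,
    translate,
)

__all__ = [
    "ProteinCandidate",
    "map_peptides_to_graph",
    "covered_subgraph",
    "enumerate_candidate_orfs",
    "select_min_protein_set",
    "run_protein_inference",
]


@dataclass
class ProteinCandidate:
    aa_seq: str
    path: PathSegment
    covers: frozenset[str] = frozenset()
    complete_start: bool = False
    complete_stop: bool = False

    @property
    def is_complete(self) -> bool:
        return self.complete_start and self.complete_stop


def map_peptides_to_graph(
    peptides: list[TrypticPeptide],
    g: ContractedDBG,
    params: PepParams = PepParams(),
    code: GeneticCode = STANDARD_CODE,
) -> tuple[dict[str, list[PathSegment]], list[str]]:
    """Locate each peptide's DNA segment(s) on the graph.

    Provenance recorded at enumeration time is reused verbatim; peptides
    without provenance (supplied externally) are located by scanning the
    three-frame translations of every edge (twins cover the reverse strand)
    and of short-edge paths up to the edge bound.  Returns the mapping by
    amino-acid sequence plus the list of unmappable sequences.
    """
    mapped: dict[str, list[PathSegment]] = {}
    todo = []
    for p in peptides:
        if p.provenance:
            mapped.setdefault(p.aa_seq, []).extend(p.provenance)
        else:
            todo.append(p.aa_seq)
    unmapped = []
    if todo:
        located = _scan_for_peptides(g, set(todo), params, code)
        for aa in todo:
            if located.get(aa):
                mapped.setdefault(aa, []).extend(located[aa])
            else:
                unmapped.append(aa)
    for aa in mapped:
        mapped[aa] = sorted(set(mapped[aa]), key=lambda s: (s.edge_ids, s.start))
    return mapped, sorted(set(unmapped))


def _scan_for_peptides(g, targets: set[str], params: PepParams, code: GeneticCode):
    """Substring scan over spelled paths; canonical first-edge coordinates.

    Paths are rooted at every edge; multi-edge extension mirrors the
    enumeration semantics (short edges only, though a path may end in one
    long edge) and is bounded by the longest target.
    """
    found: dict[str, list[PathSegment]] = {aa: [] for aa in targets}
    long_edges = {eid for eid in g.edges if len(g.edges[eid].seq) > params.long_edge_threshold}
    max_nt = 3 * max(len(a) for a in targets) + 3

    def scan_path(path, s):
        first_len = len(g.edges[path[0]].seq)
        prev_end = len(s) - (len(g.edges[path[-1]].seq) - (g.k - 1)) if len(path) > 1 else 0
        for frame in range(3):
            prot = translate(s[frame : frame + 3 * ((len(s) - frame) // 3)], code)
            for aa in targets:
                start = prot.find(aa)
                while start != -1:
                    nt0 = frame + 3 * start
                    nt1 = nt0 + 3 * len(aa)
                    # the first edge must introduce the start base and the
                    # match must reach the last edge (shorter paths already
                    # reported interior matches)
                    if nt0 < first_len and (len(path) == 1 or nt1 > prev_end):
                        found[aa].append(_trim_to_interval(g, path, nt0, nt1))
                    start = prot.find(aa, start + 1)

    stack = []
    for eid in sorted(g.edges):
        s = g.edges[eid].seq
        scan_path([eid], s)
        if eid not in long_edges:
            stack.append(([eid], s))
    while stack:
        path, s = stack.pop()
        if len(path) > 1:
            scan_path(path, s)
        if (
            len(path) < params.max_edges_per_path
            and path[-1] not in long_edges
            and len(s) - len(g.edges[path[0]].seq) < max_nt
        ):
            for nxt in g.edges[path[-1]].successors:
                stack.append((path + [nxt], s + g.edges[nxt].seq[g.k - 1 :]))
    return found


def _trim_to_interval(g: ContractedDBG, path: list[str], start: int, end: int) -> PathSegment:
    """Restrict a path to the edges spelling [start, end), rebasing coordinates.

    Each edge canonically introduces its bases beyond the (k-1) overlap; the
    kept sub-path starts at the edge introducing ``start`` and the returned
    offsets are relative to the spelling of that sub-path.
    """
    k1 = g.k - 1
    bounds = []  # introduced interval of each edge in path coordinates
    b = 0
    for i, eid in enumerate(path):
        ln = len(g.edges[eid].seq)
        e = b + (ln if i == 0 else ln - k1)
        bounds.append((b, e))
        b = e
    first = next(i for i, (_, e) in enumerate(bounds) if e > start)
    last = next(i for i, (_, e) in enumerate(bounds) if e >= end)
    shift = 0 if first == 0 else bounds[first][0] - k1
    return PathSegment(tuple(path[first : last + 1]), start - shift, end - shift)


def covered_subgraph(g: ContractedDBG, segments: list[PathSegment]) -> set[str]:
    """Union of edge ids touched by any mapped segment (twins not added)."""
    out: set[str] = set()
    for seg in segments:
        out.update(seg.edge_ids)
    return out


def enumerate_candidate_orfs(
    g: ContractedDBG,
    covered: set[str],
    peptide_seqs: dict[str, str],
    params: PepParams = PepParams(),
    code: GeneticCode = STANDARD_CODE,
    max_protein_len: int = 2000,
    max_protein_edges: int = 50,
    fallback_roots: list[tuple[str, int]] = (),
) -> list[ProteinCandidate]:
    """Candidate proteins from a DFS over the covered subgraph.

    Roots: every start codon on a covered edge, plus (for coverage of genes
    whose start lies outside the subgraph) the three frames of covered edges
    with no covered predecessor.  Walks restart after in-frame stops; runs
    that leave the subgraph or hit the bounds emit maximal fragments with
    ``complete_stop=False``.  ``peptide_seqs`` maps peptide id -> sequence
    and determines each candidate's ``covers`` set by substring containment.
    """
    unknown = covered - set(g.edges)
    if unknown:
        raise ValueError(f"covered edges not in graph: {sorted(unknown)[:3]}")
    candidates: dict[tuple[str, bool, bool], ProteinCandidate] = {}

    def emit(aa: str, seg_path: list[str], nt0: int, nt1: int, cstart: bool, cstop: bool):
        if not aa:
            return
        seg = _trim_to_interval(g, seg_path, nt0, nt1)
        covers = frozenset(pid for pid, pep in peptide_seqs.items() if pep in aa)
        key = (aa, cstart, cstop)
        if key not in candidates:
            candidates[key] = ProteinCandidate(aa, seg, covers, cstart, cstop)

    def walk(root_edge: str, root_pos: int, complete_start: bool):
        e0 = g.edges[root_edge]
        stack = [([root_edge], e0.seq, root_pos, root_pos, "", complete_start)]
        while stack:
            path, spelled, orf_start, pos, prot, cstart = stack.pop()
            halted = False
            while pos + 3 <= len(spelled):
                codon = spelled[pos : pos + 3]
                aa = code.table[codon]
                if aa == "*":
                    emit(prot, path, orf_start, pos, cstart, True)
                    # restart after the stop in the same frame, start unknown
                    prot, orf_start, cstart = "", pos + 3, False
                    pos += 3
                    continue
                prot += aa
                pos += 3
                if len(prot) >= max_protein_len:
                    halted = True
                    emit(prot, path, orf_start, pos, cstart, False)
                    break
            if halted:
                continue
            succ = [s for s in g.edges[path[-1]].successors if s in covered]
            if not succ or len(path) >= max_protein_edges:
                emit(prot, path, orf_start, pos, cstart, False)
                continue
            for s in succ:
                stack.append(
                    (path + [s], spelled + g.edges[s].seq[g.k - 1 :], orf_start, pos, prot, cstart)
                )

    no_cov_pred = {
        eid
        for eid in covered
        if not any(eid in g.edges[p].successors for p in covered)
    }
    startless = {(eid, f) for eid in no_cov_pred for f in range(3)}
    startless.update((eid, f % 3) for eid, f in fallback_roots if eid in covered)
    for eid in sorted(covered):
        seq = g.edges[eid].seq
        for p in range(len(seq) - 2):
            if seq[p : p + 3] in code.starts:
                walk(eid, p, complete_start=True)
    for eid, f in sorted(startless):
        walk(eid, f, complete_start=False)
    return sorted(
        candidates.values(),
        key=lambda c: (-len(c.covers), -(c.complete_start + c.complete_stop), -len(c.aa_seq), c.aa_seq),
    )


def select_min_protein_set(
    candidates: list[ProteinCandidate], peptide_ids: set[str]
) -> list[ProteinCandidate]:
    """Greedy minimum set cover over peptide ids.

    Repeatedly pick the candidate covering the most still-uncovered
    peptides; ties prefer complete ORFs, then longer sequences, then
    lexicographic sequence.  Peptides covered by no candidate are ignored
    (reported upstream as unmappable).
    """
    coverable = peptide_ids & frozenset().union(*(c.covers for c in candidates)) if candidates else set()
    uncovered = set(coverable)
    chosen: list[ProteinCandidate] = []
    pool = list(candidates)
    while uncovered:
        best = max(
            pool,
            key=lambda c: (
                len(c.covers & uncovered),
                c.complete_start + c.complete_stop,
                len(c.aa_seq),
                tuple(-ord(x) for x in c.aa_seq),
            ),
        )
        gain = best.covers & uncovered
        if not gain:
            break
        chosen.append(best)
        uncovered -= gain
        pool.remove(best)
    return chosen


@dataclass
class InferenceResult:
    proteins: list[tuple[str, ProteinCandidate]]  # (assigned id, candidate)
    unmapped_peptides: list[str] = field(default_factory=list)
    covered_edges: set[str] = field(default_factory=set)

    def fasta_records(self) -> list[tuple[str, str]]:
        out = []
        for pid, cand in self.proteins:
            flags = ("complete" if cand.is_complete else
                     ("no_stop" if cand.complete_start else
                      ("no_start" if cand.complete_stop else "fragment")))
            prov = f"{'|'.join(cand.path.edge_ids)}:{cand.path.start}-{cand.path.end}"
            out.append((f"{pid} {flags} peptides={len(cand.covers)} {prov}", cand.aa_seq))
        return out


def run_protein_inference(
    g: ContractedDBG,
    identified: list[TrypticPeptide],
    params: PepParams = PepParams(),
    code: GeneticCode = STANDARD_CODE,
    complete_only: bool = False,
) -> InferenceResult:
    """Full second-pass composition: map -> restrict -> enumerate -> cover.

    The output database additionally includes every long-edge predicted
    protein that contains at least one identified peptide, so that genes on
    intact contigs stay searchable in the second round.
    """
    mapped, unmapped = map_peptides_to_graph(identified, g, params, code)
    segments = [s for segs in mapped.values() for s in segs]
    covered = covered_subgraph(g, segments)
    pep_ids = {f"p{i}": aa for i, aa in enumerate(sorted(mapped))}
    # root a start-less walk in each mapped segment's own frame so that every
    # mappable peptide is guaranteed to land inside some candidate
    roots = [(s.edge_ids[0], s.start % 3) for s in segments]
    candidates = enumerate_candidate_orfs(g, covered, pep_ids, params, code, fallback_roots=roots)
    if complete_only:
        candidates = [c for c in candidates if c.is_complete]
    chosen = select_min_protein_set(candidates, set(pep_ids))

    # long-edge genes hosting at least one identified peptide
    seen_seqs = {c.aa_seq for c in chosen}
    extras = []
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if len(e.seq) <= params.long_edge_threshold:
            continue
        for prot, seg in find_long_edge_orfs(e, params, code):
            if prot in seen_seqs:
                continue
            covers = frozenset(pid for pid, pep in pep_ids.items() if pep in prot)
            if covers:
                seen_seqs.add(prot)
                extras.append(ProteinCandidate(prot, seg, covers, True, True))

    proteins = [(f"Protein{i + 1}", c) for i, c in enumerate(chosen + extras)]
    return InferenceResult(proteins=proteins, unmapped_peptides=unmapped, covered_edges=covered)
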