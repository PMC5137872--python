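"""Fully tryptic peptide enumeration from a contracted de Bruijn graph.

Two passes produce the peptide database:

* a gene pass on *long* edges (longer than ``long_edge_threshold``) that
  extracts complete open reading frames in the three forward frames of each
  edge (reverse-strand genes fall out of the twin edge) and digests them
  in silico, and
* a codon-frame-aware depth-first search rooted on *short* edges that walks
  every outgoing path, so that peptides whose coding sequence spans several
  short edges (broken contigs) are still enumerated.

A fully tryptic peptide starts at a start codon or right after a K/R codon
and ends at a K/R codon or immediately before a stop codon.  The DFS admits
"after-cleavage" roots without verifying an upstream reading frame: the
database is deliberately permissive, and downstream target-decoy FDR control
absorbs sequences that are not real.  Traversal never extends beyond a long
edge, although the peptide under construction may be finished inside one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable

from .graph import ContractedDBG, Edge, GraphValidationError, PathSegment, validate_graph

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "PepParams",
    "TrypticPeptide",
    "translate",
    "digest",
    "find_long_edge_orfs",
    "candidate_starts",
    "enumerate_graph_peptides",
    "peptide_fasta_records",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _standard_table() -> dict[str, str]:
    t = CodonTable.unambiguous_dna_by_id[1]
    table = dict(t.forward_table)
    for c in t.stop_codons:
        table[c] = "*"
    return table


@dataclass(frozen=True)
class GeneticCode:
    """Codon translation table plus start/stop codon sets."""

    table: dict[str, str] = field(default_factory=_standard_table)
    starts: frozenset[str] = frozenset({"ATG"})
    stops: frozenset[str] = STOP_CODONS

    def with_alt_starts(self) -> "GeneticCode":
        """Also accept the common bacterial alternative starts GTG/TTG."""
        return replace(self, starts=frozenset({"ATG", "GTG", "TTG"}))


STANDARD_CODE = GeneticCode()


@dataclass(frozen=True)
class PepParams:
    """Tunables of the peptide enumeration.

    ``long_edge_threshold`` separates the gene pass from the DFS (500 nt);
    ``min_pep_len``/``max_pep_len`` bound reported peptides in residues;
    ``max_miscleavage`` internal K/R sites may be left uncut;
    ``max_edges_per_path`` and ``max_pep_len`` bound the DFS (cycles in the
    graph make a bound necessary); ``min_orf_len`` (nt, including the stop)
    filters the gene pass.
    """

    long_edge_threshold: int = 500
    min_pep_len: int = 6
    max_miscleavage: int = 0
    max_pep_len: int = 50
    max_edges_per_path: int = 20
    min_orf_len: int = 60
    cleavage: frozenset[str] = frozenset({"K", "R"})
    emit_dead_end: bool = False
    include_partial_orfs: bool = False

    def __post_init__(self):
        if min(
            self.long_edge_threshold,
            self.min_pep_len,
            self.max_miscleavage + 1,
            self.max_pep_len,
            self.max_edges_per_path,
            self.min_orf_len,
        ) <= 0:
            raise ValueError("all PepParams bounds must be positive")
        if self.min_pep_len > self.max_pep_len:
            raise ValueError("min_pep_len > max_pep_len")


@dataclass(frozen=True)
class TrypticPeptide:
    """A peptide with its graph provenance.

    ``source`` is ``long_edge_gene`` for gene-pass peptides and ``graph_dfs``
    for DFS peptides (gene-pass wins when both find the same sequence).
    """

    aa_seq: str
    provenance: tuple[PathSegment, ...]
    source: str

    @property
    def pep_id(self) -> str:
        return "pep_" + hashlib.sha1(self.aa_seq.encode()).hexdigest()[:12]


def translate(dna: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a DNA string (length divisible by 3); stops become '*'."""
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} not divisible by 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        try:
            out.append(code.table[codon])
        except KeyError:
            raise ValueError(f"non-ACGT codon {codon!r} at offset {i}") from None
    return "".join(out)


def digest(protein: str, params: PepParams) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest: ``(peptide, start, end)`` fragments.

    Cleaves after every K/R; fragments joining up to ``max_miscleavage + 1``
    consecutive pieces are reported if their length is within bounds.
    """
    if "*" in protein:
        raise ValueError("protein contains a stop symbol")
    cuts = [0] + [i + 1 for i, aa in enumerate(protein) if aa in params.cleavage] + [len(protein)]
    cuts = sorted(set(cuts))
    out = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + params.max_miscleavage, len(cuts))):
            a, b = cuts[i], cuts[j]
            if params.min_pep_len <= b - a <= params.max_pep_len:
                out.append((protein[a:b], a, b))
    return out


def find_long_edge_orfs(
    edge: Edge, params: PepParams, code: GeneticCode = STANDARD_CODE
) -> list[tuple[str, PathSegment]]:
    """Complete ORFs (start codon .. in-frame stop) in the three forward
    frames of one edge.  The returned segment spans start codon through stop
    codon inclusive; the protein excludes the stop.  With
    ``include_partial_orfs`` ORFs broken by the edge boundary (missing stop,
    or missing start at the edge head) are also reported.
    """
    seq = edge.seq
    out: list[tuple[str, PathSegment]] = []
    for frame in range(3):
        stops = [p for p in range(frame, len(seq) - 2, 3) if seq[p : p + 3] in code.stops]
        starts = [p for p in range(frame, len(seq) - 2, 3) if seq[p : p + 3] in code.starts]
        si = 0
        for s in starts:
            while si < len(stops) and stops[si] < s:
                si += 1
            if si < len(stops):
                t = stops[si]
                if t + 3 - s >= params.min_orf_len:
                    prot = translate(seq[s:t], code)
                    out.append((prot, PathSegment((edge.id,), s, t + 3)))
            elif params.include_partial_orfs:
                end = s + 3 * ((len(seq) - s) // 3)
                if end - s >= params.min_orf_len:
                    out.append((translate(seq[s:end], code), PathSegment((edge.id,), s, end)))
        if params.include_partial_orfs and stops:
            # head fragment running into the first stop without a start codon
            t = stops[0]
            if t + 3 - frame >= params.min_orf_len and t > frame:
                prot = translate(seq[frame:t], code)
                if prot and not any(s < t for s in starts):
                    out.append((prot, PathSegment((edge.id,), frame, t + 3)))
    return out


def candidate_starts(
    edge: Edge, code: GeneticCode = STANDARD_CODE, cleavage: frozenset[str] = frozenset({"K", "R"})
) -> list[tuple[int, str]]:
    """DFS roots determinable within one edge, sorted by offset.

    A root is a position holding a start codon, or a position immediately
    preceded by an in-edge K/R codon.  Start codons straddling the edge end
    are resolved during traversal, not here.
    """
    seq = edge.seq
    out = []
    for p in range(len(seq)):
        if p + 3 <= len(seq) and seq[p : p + 3] in code.starts:
            out.append((p, "start_codon"))
        if p >= 3 and code.table.get(seq[p - 3 : p]) in cleavage:
            out.append((p, "after_cleavage"))
    return out


def enumerate_graph_peptides(
    g: ContractedDBG,
    params: PepParams = PepParams(),
    code: GeneticCode = STANDARD_CODE,
) -> list[TrypticPeptide]:
    """All fully tryptic peptides encoded in the graph.

    Returns peptides sorted by amino-acid sequence; duplicates arising from
    the (k-1) overlap or from multiple encoding paths are merged with their
    provenance unioned.  The graph must validate; k must be at least 4 so
    that a codon always fits inside the (k-1)-overlap (the rooting argument
    of the DFS relies on it).
    """
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(violations)
    if g.k < 4:
        raise ValueError("peptide enumeration requires k >= 4")

    found: dict[str, dict] = {}

    def record(aa: str, seg: PathSegment, source: str) -> None:
        if not (params.min_pep_len <= len(aa) <= params.max_pep_len):
            return
        slot = found.setdefault(aa, {"provenance": set(), "source": source})
        slot["provenance"].add(seg)
        if source == "long_edge_gene":
            slot["source"] = "long_edge_gene"

    long_edges = {eid for eid, e in g.edges.items() if len(e.seq) > params.long_edge_threshold}

    # ---- gene pass on long edges -----------------------------------------
    for eid in sorted(long_edges):
        for prot, seg in find_long_edge_orfs(g.edges[eid], params, code):
            for pep, a, b in digest(prot, params):
                record(pep, PathSegment(seg.edge_ids, seg.start + 3 * a, seg.start + 3 * b), "long_edge_gene")

    # ---- DFS on short edges ----------------------------------------------
    kr = params.cleavage
    k1 = g.k - 1

    def walk(root_edge: str, root_pos: int, need_start_codon: bool) -> None:
        """Consume codons from (root_edge, root_pos) along every outgoing
        path, emitting tryptic peptides.  ``need_start_codon`` marks roots
        whose validity hinges on the (possibly edge-spanning) first codon
        being a start codon."""
        e0 = g.edges[root_edge]
        stack = [([root_edge], e0.seq, root_pos, "", 0, len(e0.seq) > params.long_edge_threshold)]
        while stack:
            path, spelled, pos, pep, ncleav, in_long = stack.pop()
            halted = False
            while pos + 3 <= len(spelled):
                if need_start_codon and pos == root_pos and spelled[pos : pos + 3] not in code.starts:
                    halted = True
                    break
                codon = spelled[pos : pos + 3]
                aa = code.table[codon]
                if aa == "*":
                    if pep:
                        record(pep, _trim(g, path, root_pos, pos), "graph_dfs")
                    halted = True
                    break
                pep += aa
                pos += 3
                if len(pep) > params.max_pep_len:
                    halted = True
                    break
                if aa in kr:
                    record(pep, _trim(g, path, root_pos, pos), "graph_dfs")
                    ncleav += 1
                    if ncleav > params.max_miscleavage or in_long:
                        halted = True
                        break
            if halted:
                continue
            # need more sequence: extend into successors
            last = g.edges[path[-1]]
            succ = [] if (in_long or len(path) >= params.max_edges_per_path) else last.successors
            if not succ:
                if params.emit_dead_end and pep:
                    record(pep, _trim(g, path, root_pos, pos), "graph_dfs")
                continue
            for s in succ:
                nxt = g.edges[s]
                stack.append(
                    (
                        path + [s],
                        spelled + nxt.seq[k1:],
                        pos,
                        pep,
                        ncleav,
                        len(nxt.seq) > params.long_edge_threshold,
                    )
                )

    for eid in sorted(g.edges):
        e = g.edges[eid]
        if eid in long_edges:
            continue
        seen_roots = set()
        for p, kind in candidate_starts(e, code, kr):
            if p not in seen_roots:
                seen_roots.add(p)
                walk(eid, p, need_start_codon=False)
        # start codons straddling the edge end (resolved along each branch)
        for p in range(max(0, len(e.seq) - 2), len(e.seq)):
            if p not in seen_roots:
                seen_roots.add(p)
                walk(eid, p, need_start_codon=True)

    return [
        TrypticPeptide(aa, tuple(sorted(v["provenance"], key=lambda s: (s.edge_ids, s.start))), v["source"])
        for aa, v in sorted(found.items())
    ]


def _trim(g: ContractedDBG, path: list[str], start: int, end: int) -> PathSegment:
    """Restrict a walk's edge path to the edges actually spelling [start, end)."""
    k1 = g.k - 1
    kept = []
    intro_start = 0
    for i, eid in enumerate(path):
        length = len(g.edges[eid].seq)
        intro_end = intro_start + (length if i == 0 else length - k1)
        if i == 0 or intro_start < end:
            kept.append(eid)
        if intro_end >= end:
            break
        intro_start = intro_end
    return PathSegment(tuple(kept), start, end)


def peptide_fasta_records(peptides: list[TrypticPeptide]) -> list[tuple[str, str]]:
    """(header, sequence) pairs for the peptide FASTA, lexicographic order."""
    out = []
    for p in sorted(peptides, key=lambda x: x.aa_seq):
        prov = ",".join(f"{'|'.join(s.edge_ids)}:{s.start}-{s.end}" for s in p.provenance)
        out.append((f"{p.pep_id} {p.source} {prov}", p.aa_seq))
    return out
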