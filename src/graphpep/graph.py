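"""Contracted de Bruijn graph model and I/O.

The assembly graph produced by a de Bruijn graph assembler is modelled as a
bidirected graph: every edge carries a DNA sequence of length >= k, every
edge has a *twin* spelling the reverse complement (a palindromic edge is its
own twin), and an edge ``a`` is followed by ``b`` when the last ``k-1`` bases
of ``a`` equal the first ``k-1`` bases of ``b``.  Paths are spelled with
(k-1)-overlap collapse, and every coordinate in the package is 0-based,
half-open.  A spelled-path position belongs canonically to the FIRST edge
that introduces it: positions < len(e1) belong to e1, each later edge
contributes its bases from offset k-1 on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "Edge",
    "ContractedDBG",
    "PathSegment",
    "GraphValidationError",
    "FastgParseError",
    "revcomp",
    "spell_path",
    "path_length",
    "segment_seq",
    "validate_graph",
    "load_fastg",
    "load_native",
    "write_native",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
_DNA_RE = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GraphValidationError(ValueError):
    """Raised when a graph violates the contracted-dBG invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(v.message for v in self.violations[:5])
        if len(self.violations) > 5:
            msg += f" (+{len(self.violations) - 5} more)"
        super().__init__(f"invalid graph: {msg}")


class FastgParseError(ValueError):
    pass


@dataclass
class Edge:
    """One oriented edge (contig) of the graph."""

    id: str
    seq: str
    twin_id: str
    successors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ContractedDBG:
    """A contracted de Bruijn graph: k plus a map of oriented edges."""

    k: int
    edges: dict[str, Edge]

    def twin(self, edge_id: str) -> Edge:
        return self.edges[self.edges[edge_id].twin_id]

    def predecessors(self, edge_id: str) -> list[str]:
        """Edge ids having ``edge_id`` among their successors (computed)."""
        return [e.id for e in self.edges.values() if edge_id in e.successors]

    def __contains__(self, edge_id: str) -> bool:
        return edge_id in self.edges


@dataclass(frozen=True)
class PathSegment:
    """A located DNA interval on a path of adjacent edges.

    ``start``/``end`` are offsets into the spelled path (0-based, half-open);
    the first edge of ``edge_ids`` canonically contains position ``start``.
    """

    edge_ids: tuple[str, ...]
    start: int
    end: int

    def __post_init__(self):
        if not self.edge_ids:
            raise ValueError("PathSegment needs at least one edge")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment interval [{self.start},{self.end})")


def path_length(g: ContractedDBG, edge_ids) -> int:
    """Spelled length of a path: sum(len) - (n-1)*(k-1)."""
    ids = list(edge_ids)
    return sum(len(g.edges[e].seq) for e in ids) - (len(ids) - 1) * (g.k - 1)


def spell_path(g: ContractedDBG, edge_ids) -> str:
    """Spell a path by (k-1)-overlap collapse; consecutive edges must link."""
    ids = list(edge_ids)
    if not ids:
        raise ValueError("empty path")
    out = [g.edges[ids[0]].seq]
    for a, b in zip(ids, ids[1:]):
        if b not in g.edges[a].successors:
            raise ValueError(f"edges not adjacent in graph: {a} -> {b}")
        out.append(g.edges[b].seq[g.k - 1 :])
    return "".join(out)


def segment_seq(g: ContractedDBG, seg: PathSegment) -> str:
    """DNA spelled by a PathSegment."""
    spelled = spell_path(g, seg.edge_ids)
    if seg.end > len(spelled):
        raise ValueError(f"segment end {seg.end} beyond spelled length {len(spelled)}")
    return spelled[seg.start : seg.end]


@dataclass(frozen=True)
class Violation:
    rule: str
    edge_ids: tuple[str, ...]
    message: str


def validate_graph(g: ContractedDBG) -> list[Violation]:
    """Check every invariant; violations are returned as data, not raised."""
    out: list[Violation] = []
    for eid, e in g.edges.items():
        if not _DNA_RE.match(e.seq):
            out.append(Violation("alphabet", (eid,), f"edge {eid} has non-ACGT symbols"))
            continue
        if len(e.seq) < g.k:
            out.append(Violation("length", (eid,), f"edge {eid} shorter than k={g.k}"))
        if e.twin_id not in g.edges:
            out.append(Violation("unresolved", (eid,), f"twin {e.twin_id} of {eid} missing"))
        else:
            t = g.edges[e.twin_id]
            if t.twin_id != eid:
                out.append(
                    Violation("twin_involution", (eid, e.twin_id), f"twin of twin of {eid} is {t.twin_id}")
                )
            if t.seq != revcomp(e.seq):
                out.append(
                    Violation(
                        "twin_revcomp", (eid, e.twin_id), f"twin {e.twin_id} is not reverse complement of {eid}"
                    )
                )
        for s in e.successors:
            if s not in g.edges:
                out.append(Violation("unresolved", (eid, s), f"successor {s} of {eid} missing"))
                continue
            if e.seq[-(g.k - 1) :] != g.edges[s].seq[: g.k - 1]:
                out.append(Violation("overlap", (eid, s), f"overlap mismatch between {eid} and {s}"))
            # adjacency symmetry: b in succ(a) <=> twin(a) in succ(twin(b))
            if e.twin_id in g.edges and g.edges[s].twin_id in g.edges:
                if e.twin_id not in g.edges[g.edges[s].twin_id].successors:
                    out.append(
                        Violation(
                            "symmetry",
                            (eid, s),
                            f"link {eid}->{s} lacks mirrored link {g.edges[s].twin_id}->{e.twin_id}",
                        )
                    )
    return out


def _check(g: ContractedDBG) -> ContractedDBG:
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(violations)
    return g


# ---------------------------------------------------------------------------
# FASTG (SPAdes dialect)
# ---------------------------------------------------------------------------

def _fastg_name(token: str, lineno: int) -> tuple[str, bool]:
    token = token.strip().rstrip(";")
    if not token:
        raise FastgParseError(f"line {lineno}: empty edge name")
    rc = token.endswith("'")
    return (token[:-1] if rc else token), rc


def _oriented(name: str, rc: bool) -> str:
    return name + "'" if rc else name


def load_fastg(path, k: int = 31) -> ContractedDBG:
    """Load a SPAdes-dialect FASTG file.

    Record headers name an oriented node, optionally followed by
    ``:succ1,succ2,...`` and a terminal ``;``.  A trailing apostrophe marks
    the reverse-complement orientation.  FASTG carries no k, so it must be
    supplied (default 31).  Missing orientations and mirrored links are
    synthesized; all invariants are then verified.
    """
    seqs: dict[str, str] = {}
    links: dict[str, list[str]] = {}
    order: list[str] = []
    cur: str | None = None
    buf: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur is not None:
                    seqs[cur] = "".join(buf)
                buf = []
                header = line[1:].strip()
                if not header.endswith(";"):
                    raise FastgParseError(f"line {lineno}: FASTG header must end with ';': {line!r}")
                header = header[:-1]
                if ":" in header:
                    name_tok, succ_part = header.split(":", 1)
                    succ_toks = [t for t in succ_part.split(",") if t.strip()]
                    if not succ_toks:
                        raise FastgParseError(f"line {lineno}: empty successor list")
                else:
                    name_tok, succ_toks = header, []
                name, rc = _fastg_name(name_tok, lineno)
                cur = _oriented(name, rc)
                if cur in seqs:
                    raise FastgParseError(f"line {lineno}: duplicate record {cur}")
                order.append(cur)
                links[cur] = [_oriented(*_fastg_name(t, lineno)) for t in succ_toks]
            else:
                if cur is None:
                    raise FastgParseError(f"line {lineno}: sequence before first header")
                buf.append(line.upper())
        if cur is not None:
            seqs[cur] = "".join(buf)
    if not seqs:
        raise FastgParseError("no records in FASTG file")
    return _assemble(seqs, links, k, order)


# ---------------------------------------------------------------------------
# Native format: edges FASTA + links TSV (+ optional twin-pair TSV)
# ---------------------------------------------------------------------------

def load_native(edges_fasta, links_tsv, k: int, twins_tsv=None) -> ContractedDBG:
    """Load the native pair {edge FASTA, directed-link TSV} with k given.

    Twins may be declared explicitly in ``twins_tsv`` (two ids per row);
    otherwise the loader pairs edges whose sequences are mutual reverse
    complements and materializes a ``<id>_rc`` twin for the rest, mirroring
    every link onto the twins.
    """
    seqs: dict[str, str] = {}
    order: list[str] = []
    with open(edges_fasta) as fh:
        for header, seq in SimpleFastaParser(fh):
            eid = header.split()[0]
            if eid in seqs:
                raise ValueError(f"duplicate edge id {eid!r} in {edges_fasta}")
            seq = seq.upper()
            if len(seq) < k:
                raise ValueError(f"edge {eid!r} shorter than k={k}")
            seqs[eid] = seq
            order.append(eid)

    links: dict[str, list[str]] = {eid: [] for eid in seqs}
    with open(links_tsv) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{links_tsv}:{lineno}: expected from<TAB>to")
            a, b = parts[0], parts[1]
            for x in (a, b):
                if x not in seqs:
                    raise ValueError(f"{links_tsv}:{lineno}: link references unknown edge {x!r}")
            links.setdefault(a, []).append(b)

    twin_of: dict[str, str] = {}
    if twins_tsv is not None:
        with open(twins_tsv) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                for x in (a, b):
                    if x not in seqs:
                        raise ValueError(f"{twins_tsv}:{lineno}: unknown edge {x!r}")
                twin_of[a] = b
                twin_of[b] = a
    else:
        # deterministic reverse-complement pairing among listed edges
        by_seq: dict[str, list[str]] = {}
        for eid in order:
            by_seq.setdefault(seqs[eid], []).append(eid)
        for eid in order:
            if eid in twin_of:
                continue
            rc = revcomp(seqs[eid])
            if rc == seqs[eid]:
                twin_of[eid] = eid
                continue
            for cand in by_seq.get(rc, []):
                if cand != eid and cand not in twin_of:
                    twin_of[eid] = cand
                    twin_of[cand] = eid
                    break
    return _assemble(seqs, links, k, order, twin_of)


def _assemble(
    seqs: dict[str, str],
    links: dict[str, list[str]],
    k: int,
    order: list[str],
    twin_of: dict[str, str] | None = None,
) -> ContractedDBG:
    """Common tail of the loaders: synthesize twins, mirror links, validate."""
    twin_of = dict(twin_of or {})
    seqs = dict(seqs)
    order = list(order)

    def synth_twin(eid: str) -> str:
        rc = revcomp(seqs[eid])
        if rc == seqs[eid]:
            twin_of[eid] = eid
            return eid
        tid = eid[:-1] if eid.endswith("'") else eid + "'"
        if tid in seqs and tid not in twin_of:
            # oriented counterpart already present (both-orientation file)
            twin_of[eid] = tid
            twin_of[tid] = eid
            return tid
        if tid in seqs:  # primed name taken by an already-paired edge
            tid = eid + "_rc"
        seqs[tid] = rc
        order.append(tid)
        twin_of[eid] = tid
        twin_of[tid] = eid
        links.setdefault(tid, [])
        return tid

    # resolve successor names that refer to orientations not yet materialized
    for eid in list(order):
        if eid not in twin_of:
            synth_twin(eid)
    for eid, succ in list(links.items()):
        for s in succ:
            if s not in seqs:
                base = s[:-1] if s.endswith("'") else s + "'"
                if base in seqs:
                    synth_twin(base)
                else:
                    raise ValueError(f"unresolved successor name {s!r} (from {eid})")
    # palindromic records may be referenced by their primed name
    rename = {eid + "'": eid for eid in order if twin_of.get(eid) == eid}
    adj: dict[str, list[str]] = {eid: [] for eid in order}
    for eid, succ in links.items():
        eid = rename.get(eid, eid)
        for s in succ:
            s = rename.get(s, s)
            if s not in seqs:
                raise ValueError(f"unresolved successor name {s!r}")
            if s not in adj[eid]:
                adj[eid].append(s)
    # mirror links: b in succ(a) => twin(a) in succ(twin(b))
    changed = True
    while changed:
        changed = False
        for a in order:
            for b in list(adj[a]):
                ta, tb = twin_of[a], twin_of[b]
                if ta not in adj[tb]:
                    adj[tb].append(ta)
                    changed = True
    edges = {
        eid: Edge(id=eid, seq=seqs[eid], twin_id=twin_of[eid], successors=sorted(adj[eid]))
        for eid in order
    }
    return _check(ContractedDBG(k=k, edges=edges))


def write_native(g: ContractedDBG, edges_fasta, links_tsv, twins_tsv) -> None:
    """Write the native format deterministically (sorted ids, 80-col FASTA)."""
    ids = sorted(g.edges)
    with open(edges_fasta, "w") as fh:
        for eid in ids:
            fh.write(f">{eid}\n")
            seq = g.edges[eid].seq
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(links_tsv, "w") as fh:
        for eid in ids:
            for s in g.edges[eid].successors:
                fh.write(f"{eid}\t{s}\n")
    with open(twins_tsv, "w") as fh:
        seen = set()
        for eid in ids:
            pair = tuple(sorted((eid, g.edges[eid].twin_id)))
            if pair not in seen:
                seen.add(pair)
                fh.write(f"{pair[0]}\t{pair[1]}\n")
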