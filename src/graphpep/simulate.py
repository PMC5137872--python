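"""Ground-truthed synthetic inputs for the whole pipeline.

Three generators:

* :func:`simulate_community` — small microbial genomes with planted
  protein-coding genes (ATG .. stop, no internal in-frame stops, both
  strands) and sequence blocks copied verbatim between genomes.  The copied
  blocks are sampled so that they usually cut through genes of the donor
  genome, which is what makes the assembly graph branch inside coding
  regions — the situation the graph traversal is designed to exploit.
* :func:`build_dbg` — a contracted de Bruijn graph built directly from the
  genome sequences (no read simulation or assembler): k-mers of both strands
  are collected, a seeded fraction is dropped (a k-mer and its reverse
  complement are always dropped together, keeping the graph symmetric), and
  maximal non-branching chains are collapsed into edges with twins and
  mirrored links.
* :func:`simulate_identifications` — a PSM table: each in-bounds tryptic
  peptide of the proteome is detected with a fixed probability and scored
  from the "correct" distribution, noise target rows and an equal number of
  decoy rows are scored from the "incorrect" distribution.  Scores are
  E-value-like (lower is better): correct matches draw
  ``10**(-Normal(10, 1.2))``, incorrect ones ``10**(-Normal(4, 0.8))``; the
  two families are well separated so FDR calibration has a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import DECOY_PREFIX
from .graph import ContractedDBG, Edge, revcomp, validate_graph
from .peptides import PepParams, STANDARD_CODE, digest

__all__ = [
    "SimParams",
    "IdentSimParams",
    "PlantedGene",
    "Community",
    "simulate_community",
    "build_dbg",
    "kmer_index",
    "trace_interval",
    "simulate_identifications",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimParams:
    """Community generator settings.

    Defaults describe a small, dense community: three 5 kb genomes carrying
    17 genes each (~50 genes total) of 90-240 nt, with ~10% of each genome
    copied between genomes in ~300 nt blocks.  ``kmer_dropout`` removes a
    fraction of k-mers before graph construction, emulating assembly
    fragmentation.
    """

    n_genomes: int = 3
    genome_len: int = 5000
    n_genes: int = 17            # per genome
    gene_len: tuple[int, int] = (90, 240)  # nt, multiple of 3, incl. start+stop
    gc_content: float = 0.5
    repeat_rate: float = 0.1
    repeat_block: int = 200
    k: int = 21
    kmer_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for f in (self.gc_content, self.repeat_rate, self.kmer_dropout):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.gene_len[0] % 3 or self.gene_len[1] % 3 or self.gene_len[0] < 18:
            raise ValueError("gene_len bounds must be multiples of 3, >= 18")


@dataclass(frozen=True)
class IdentSimParams:
    detection_prob: float = 0.8
    n_noise: int = 300
    correct_logmean: float = 10.0
    correct_logsd: float = 1.2
    incorrect_logmean: float = 4.0
    incorrect_logsd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    genome: int
    start: int       # genome coordinates of the full gene incl. stop codon
    end: int
    strand: str      # '+' or '-'
    protein: str     # aa sequence, leading M, no stop symbol


@dataclass
class Community:
    genomes: list[str]
    genes: list[PlantedGene]
    params: SimParams


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def _random_gene(rng: np.random.Generator, length: int) -> str:
    """ATG + (length/3 - 2) non-stop codons + stop codon."""
    codons = [c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)) if c not in _STOPS and c != "ATG"]
    n_mid = length // 3 - 2
    mid = "".join(rng.choice(codons) for _ in range(n_mid))
    return "ATG" + mid + str(rng.choice(_STOPS))


def simulate_community(params: SimParams) -> Community:
    """Deterministic community with planted genes and inter-genome repeats."""
    rng = np.random.default_rng(params.seed)
    genomes: list[str] = []
    genes: list[PlantedGene] = []

    for gi in range(params.n_genomes):
        lens = [int(rng.integers(params.gene_len[0] // 3, params.gene_len[1] // 3 + 1)) * 3 for _ in range(params.n_genes)]
        need = sum(lens)
        n_blocks = 0
        if gi and params.repeat_rate > 0:
            n_blocks = max(1, round(params.repeat_rate * params.genome_len / params.repeat_block))
        n_items = params.n_genes + n_blocks
        # planted items keep >= 6 nt of background between them so each gene
        # can carry an in-frame stop codon directly upstream of its start
        # (stop-insulated loci: the true start is identifiable from sequence)
        slack = params.genome_len - need - n_blocks * params.repeat_block - 6 * (n_items + 1)
        if slack < 0:
            raise ValueError("genes (plus repeat blocks) exceed genome length")
        gap_w = rng.dirichlet(np.ones(n_items + 1))
        gaps = np.floor(gap_w * slack).astype(int) + 6
        genome = list(_random_dna(rng, params.genome_len, params.gc_content))
        pos = 0
        items = [("gene", L) for L in lens] + [("block", params.repeat_block)] * n_blocks
        order = rng.permutation(len(items))
        block_slots = []
        for idx, oi in enumerate(order):
            kind, L = items[oi]
            pos += int(gaps[idx])
            if kind == "gene":
                gene_seq = _random_gene(rng, L)
                strand = "+" if rng.random() < 0.5 else "-"
                placed = gene_seq if strand == "+" else revcomp(gene_seq)
                genome[pos : pos + L] = list(placed)
                ins = str(rng.choice(_STOPS))
                if strand == "+":
                    genome[pos - 3 : pos] = list(ins)
                else:
                    genome[pos + L : pos + L + 3] = list(revcomp(ins))
                prot = _translate_fast(gene_seq[3 : L - 3])
                genes.append(
                    PlantedGene(f"g{gi}_{len([g for g in genes if g.genome == gi])}", gi, pos, pos + L, strand, "M" + prot)
                )
            else:
                block_slots.append((pos, pos + L))
            pos += L
        # copy repeat blocks verbatim from the previous genome, sampled so
        # they tend to cut through that genome's genes
        src_genes = [g for g in genes if g.genome == gi - 1]
        if block_slots:
            picks = rng.choice(len(src_genes), size=min(len(block_slots), len(src_genes)), replace=False)
        for bi, (bs, be) in enumerate(block_slots):
            src = genomes[gi - 1]
            anchor = src_genes[int(picks[bi % len(picks)])]
            lo = max(0, min(anchor.start + (anchor.end - anchor.start) // 2, len(src) - params.repeat_block))
            genome[bs:be] = list(src[lo : lo + params.repeat_block])
        genomes.append("".join(genome))
    return Community(genomes=genomes, genes=genes, params=params)


def _translate_fast(dna: str) -> str:
    return "".join(STANDARD_CODE.table[dna[i : i + 3]] for i in range(0, len(dna), 3))


# ---------------------------------------------------------------------------
# de Bruijn graph construction
# ---------------------------------------------------------------------------

def build_dbg(seqs: list[str], k: int, kmer_dropout: float = 0.0, seed: int = 0) -> ContractedDBG:
    """Contracted de Bruijn graph of ``seqs`` (both strands) with dropout."""
    if any(len(s) < k for s in seqs):
        raise ValueError(f"all sequences must be at least k={k} long")
    canon: set[str] = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            canon.add(min(km, revcomp(km)))
    if kmer_dropout > 0:
        rng = np.random.default_rng(seed)
        ordered = sorted(canon)
        keep = rng.random(len(ordered)) >= kmer_dropout
        canon = {km for km, kp in zip(ordered, keep) if kp}
    if not canon:
        raise ValueError("all k-mers dropped")
    kmers: set[str] = set()
    for km in canon:
        kmers.add(km)
        kmers.add(revcomp(km))

    by_prefix: dict[str, list[str]] = {}
    for km in kmers:
        by_prefix.setdefault(km[: k - 1], []).append(km)
    for v in by_prefix.values():
        v.sort()

    def succ(km):
        return by_prefix.get(km[1:], [])

    n_pred: dict[str, int] = {km: 0 for km in kmers}
    pred_of: dict[str, str] = {}
    for km in kmers:
        for s in succ(km):
            n_pred[s] += 1
            pred_of[s] = km  # only meaningful when n_pred == 1

    def is_unitig_start(km: str) -> bool:
        if n_pred[km] != 1:
            return True
        return len(succ(pred_of[km])) != 1

    visited: set[str] = set()
    spelled: list[str] = []

    def extend(start: str) -> str:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = succ(cur)
            if len(nxt) != 1 or n_pred[nxt[0]] != 1 or nxt[0] in visited or is_unitig_start(nxt[0]):
                break
            cur = nxt[0]
            chain.append(cur)
            visited.add(cur)
        return chain[0] + "".join(c[-1] for c in chain[1:])

    for km in sorted(kmers):
        if km not in visited and is_unitig_start(km):
            spelled.append(extend(km))
    # leftover perfect cycles (every node in/out degree 1).  A plain cycle is
    # broken at its smallest k-mer and its twin cycle spelled as the exact
    # reverse complement; a self-reverse-complement cycle is broken at a
    # rotation whose linear spelling is palindromic, giving a self-twin edge.
    for km in sorted(kmers):
        if km in visited:
            continue
        cyc = [km]
        visited.add(km)
        cur = km
        while True:
            nxt = succ(cur)[0]
            if nxt == km:
                break
            cyc.append(nxt)
            visited.add(nxt)
            cur = nxt
        if revcomp(km) in set(cyc):  # self-rc cycle
            for i in range(len(cyc)):
                rot = cyc[i:] + cyc[:i]
                s = rot[0] + "".join(c[-1] for c in rot[1:])
                if revcomp(s) == s:
                    spelled.append(s)
                    break
            else:
                raise AssertionError("self-rc cycle admits no palindromic break")
        else:
            j = cyc.index(min(cyc))
            rot = cyc[j:] + cyc[:j]
            s = rot[0] + "".join(c[-1] for c in rot[1:])
            spelled.append(s)
            spelled.append(revcomp(s))
            visited.update(revcomp(c) for c in cyc)

    spelled.sort()
    ids = {s: f"E{i}" for i, s in enumerate(spelled)}
    edges: dict[str, Edge] = {}
    firsts = {s[: k - 1]: [] for s in spelled}
    for s in spelled:
        firsts.setdefault(s[: k - 1], []).append(s)
    for s in spelled:
        rc = revcomp(s)
        twin = ids.get(rc)
        if twin is None:
            raise AssertionError("twin unitig missing; rc-symmetric contraction failed")
        successors = []
        for t in succ(s[-k:]):
            for cand in firsts.get(t[: k - 1], []):
                if cand.startswith(t):
                    successors.append(ids[cand])
        edges[ids[s]] = Edge(id=ids[s], seq=s, twin_id=twin, successors=sorted(set(successors)))
    g = ContractedDBG(k=k, edges=edges)
    violations = validate_graph(g)
    if violations:
        raise AssertionError(f"constructed graph invalid: {violations[:3]}")
    return g


def kmer_index(g: ContractedDBG) -> dict[str, tuple[str, int]]:
    """k-mer -> (edge id, offset); each k-mer occurs once per orientation."""
    idx: dict[str, tuple[str, int]] = {}
    for eid in sorted(g.edges):
        seq = g.edges[eid].seq
        for i in range(len(seq) - g.k + 1):
            idx.setdefault(seq[i : i + g.k], (eid, i))
    return idx


def trace_interval(g: ContractedDBG, idx: dict, seq: str, a: int, b: int):
    """Map positions [a, b) of ``seq`` to a graph path, or None on any gap.

    Returns ``(edge_ids, start_offset)`` where ``start_offset`` is the offset
    of position ``a`` in the spelled path of ``edge_ids``; the result is
    verified by respelling.
    """
    from .graph import PathSegment, segment_seq

    k = g.k
    if not (0 <= a < b <= len(seq)) or len(seq) < k:
        raise ValueError("bad interval")
    ps = min(a, len(seq) - k)
    pe = min(max(a, b - k), len(seq) - k)
    path: list[str] = []
    start_off = None
    prev = None
    for p in range(ps, pe + 1):
        hit = idx.get(seq[p : p + k])
        if hit is None:
            return None
        eid, off = hit
        if prev is None:
            path.append(eid)
            start_off = off + (a - ps)
        else:
            peid, poff = prev
            if (eid, off) == (peid, poff + 1):
                pass
            elif off == 0 and eid in g.edges[peid].successors:
                path.append(eid)
            else:
                return None
        prev = (eid, off)
    try:
        seg = PathSegment(tuple(path), start_off, start_off + (b - a))
        ok = segment_seq(g, seg) == seq[a:b]
    except ValueError:
        return None
    return (tuple(path), start_off) if ok else None


# ---------------------------------------------------------------------------
# identification simulation
# ---------------------------------------------------------------------------

def tryptic_peptides_of(proteins: list[str], pep_params: PepParams) -> set[str]:
    """Unique in-bounds fully tryptic peptides of a proteome."""
    out: set[str] = set()
    for prot in proteins:
        out.update(p for p, _, _ in digest(prot, pep_params))
    return out


def simulate_identifications(
    proteins: list[str],
    params: IdentSimParams = IdentSimParams(),
    pep_params: PepParams = PepParams(),
    protein_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulated PSM table (generic_tsv dialect) with ground-truth labels.

    Columns: spectrum_id, peptide, protein, score, label (true/false/decoy).
    The ``label`` column is the simulation truth used for calibration tests;
    the FDR machinery never reads it.
    """
    rng = np.random.default_rng(params.seed)
    if protein_ids is None:
        protein_ids = [f"prot{i}" for i in range(len(proteins))]
    pep_src: dict[str, str] = {}
    for pid, prot in zip(protein_ids, proteins):
        for p, _, _ in digest(prot, pep_params):
            pep_src.setdefault(p, pid)
    rows = []
    n = 0
    for pep in sorted(pep_src):
        if rng.random() < params.detection_prob:
            score = 10.0 ** -(rng.normal(params.correct_logmean, params.correct_logsd))
            rows.append((f"spec{n:06d}", pep, pep_src[pep], score, "true"))
            n += 1
    for _ in range(params.n_noise):
        length = int(rng.integers(max(pep_params.min_pep_len, 7), 21))
        pep = "".join(rng.choice(list(_AA)) for _ in range(length - 1)) + str(rng.choice(["K", "R"]))
        score = 10.0 ** -(rng.normal(params.incorrect_logmean, params.incorrect_logsd))
        rows.append((f"spec{n:06d}", pep, "noise_target", score, "false"))
        n += 1
    for _ in range(params.n_noise):
        length = int(rng.integers(max(pep_params.min_pep_len, 7), 21))
        pep = "".join(rng.choice(list(_AA)) for _ in range(length - 1)) + str(rng.choice(["K", "R"]))
        score = 10.0 ** -(rng.normal(params.incorrect_logmean, params.incorrect_logsd))
        rows.append((f"spec{n:06d}", pep, DECOY_PREFIX + "sim", score, "decoy"))
        n += 1
    return pd.DataFrame(rows, columns=["spectrum_id", "peptide", "protein", "score", "label"])
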