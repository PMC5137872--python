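"""End-to-end validation studies.

These procedures generate ground-truthed synthetic inputs, run the package's
algorithms on them, and measure agreement with independent references (the
brute-force enumerations in :mod:`graphpep.reference`) or with the planted
truth.  They back both the heavier tests and the reproduction script.

Recoverability of a planted peptide.  A fully tryptic peptide of a planted
gene is *recoverable by design* when its length is within bounds, its coding
path (plus the codon providing its N-terminal context) survives k-mer
dropout, and either

* its host gene lies wholly inside a single graph edge (the long-edge gene
  pass digests it), or
* the context codon sits on a short edge, the path stays within the DFS edge
  bound, and any long edge on the path is the final one (the DFS may finish
  a peptide inside a long edge but never traverses beyond it).

Peptides rooted inside a long edge but belonging to a gene broken across the
edge boundary are not recoverable by either pass; they are excluded from the
denominator and quantified separately.
"""

from __future__ import annotations

import math

import numpy as np

from .database import DECOY_PREFIX
from .fdr import PSMRecord, compute_qvalues, filter_at_fdr
from .graph import ContractedDBG, revcomp
from .peptides import PepParams, TrypticPeptide, digest, enumerate_graph_peptides, find_long_edge_orfs
from .proteins import ProteinCandidate, run_protein_inference, select_min_protein_set
from .reference import brute_force_peptides, exact_min_cover
from .simulate import (
    IdentSimParams,
    SimParams,
    build_dbg,
    kmer_index,
    simulate_community,
    simulate_identifications,
    trace_interval,
)

__all__ = [
    "oracle_equivalence_study",
    "planted_recovery_study",
    "protein_recovery_study",
    "set_cover_study",
    "fdr_calibration_study",
]


def oracle_equivalence_study(n_graphs: int = 100, seed: int = 0, max_edges: int = 20) -> dict:
    """DFS enumeration vs. exhaustive path-spelling oracle on random graphs.

    Random fragmented graphs (k=7) are drawn until ``n_graphs`` with at most
    ``max_edges`` edges have been tested; returns the fraction agreeing
    exactly (as a set of peptide sequences).  Both sides use a path bound of
    10 edges: the oracle's cost is the number of distinct paths, which cycles
    make explode at larger bounds, while the equivalence property itself is
    parametric in the bound.
    """
    agree = tested = 0
    attempt = 0
    while tested < n_graphs and attempt < 50 * n_graphs:
        rng = np.random.default_rng((seed * 100_003 + attempt) % 2**31)
        attempt += 1
        nseq = int(rng.integers(1, 3))
        seqs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 110)))) for _ in range(nseq)]
        g = build_dbg(seqs, k=7, kmer_dropout=0.12, seed=int(rng.integers(2**31)))
        if len(g.edges) > max_edges:
            continue
        tested += 1
        params = PepParams(min_pep_len=1, max_edges_per_path=10)
        mine = {p.aa_seq for p in enumerate_graph_peptides(g, params)}
        agree += mine == brute_force_peptides(g, params)
    return {"n": tested, "agreement_pct": 100.0 * agree / tested if tested else float("nan")}


def _classify_planted_peptides(comm, g: ContractedDBG, params: PepParams):
    """Per unique in-bounds peptide: (recoverable_by_design, spans_multiple_edges)."""
    idx = kmer_index(g)
    long_edges = {eid for eid, e in g.edges.items() if len(e.seq) > params.long_edge_threshold}
    out: dict[str, tuple[bool, bool]] = {}
    for gene in comm.genes:
        genome = comm.genomes[gene.genome]
        sl = genome[gene.start : gene.end]
        gene_nt = sl if gene.strand == "+" else revcomp(sl)
        tr_gene = trace_interval(g, idx, gene_nt, 0, len(gene_nt))
        gene_in_one_edge = tr_gene is not None and len(tr_gene[0]) == 1
        for pep, a, b in digest(gene.protein, params):
            ctx0 = 3 * a - 3 if a > 0 else 3 * a
            # a C-terminal peptide is only emitted once the stop codon is
            # seen, so the stop must be reachable too
            ctx1 = 3 * b + 3 if b == len(gene.protein) and pep[-1] not in params.cleavage else 3 * b
            tr = trace_interval(g, idx, gene_nt, ctx0, ctx1)
            dfs_ok = multi = False
            if tr is not None:
                path, _ = tr
                own = trace_interval(g, idx, gene_nt, 3 * a, 3 * b)
                multi = own is not None and len(own[0]) > 1
                longs = [i for i, e in enumerate(path) if e in long_edges]
                dfs_ok = (
                    len(path) <= params.max_edges_per_path
                    and path[0] not in long_edges
                    and all(i == len(path) - 1 for i in longs)
                )
            rec = gene_in_one_edge or dfs_ok
            prev = out.get(pep, (False, False))
            out[pep] = (prev[0] or rec, prev[1] or multi)
    return out


def planted_recovery_study(seed: int = 0, kmer_dropout: float = 0.0, params: PepParams | None = None) -> dict:
    """Graph enumeration vs. the planted proteome on one community.

    Also computes the contigs-only baseline (digesting complete ORFs of each
    edge in isolation) for the multi-edge-spanning peptide comparison.
    """
    params = params or PepParams()
    sim = SimParams(seed=seed, kmer_dropout=kmer_dropout)
    comm = simulate_community(sim)
    g = build_dbg(comm.genomes, k=sim.k, kmer_dropout=sim.kmer_dropout, seed=sim.seed)
    found = {p.aa_seq for p in enumerate_graph_peptides(g, params)}
    baseline = set()
    for eid in sorted(g.edges):
        for prot, _ in find_long_edge_orfs(g.edges[eid], params):
            baseline.update(p for p, _, _ in digest(prot, params))
    cls = _classify_planted_peptides(comm, g, params)
    recoverable = {p for p, (r, _) in cls.items() if r}
    multi = {p for p, (_, m) in cls.items() if m}
    return {
        "n_inbounds": len(cls),
        "n_recoverable": len(recoverable),
        "n_recovered_of_recoverable": len(recoverable & found),
        "recovery_pct": 100.0 * len(recoverable & found) / len(recoverable) if recoverable else float("nan"),
        "n_multi_edge": len(multi),
        "n_multi_edge_recovered_graph": len(multi & found),
        "n_multi_edge_recovered_contigs": len(multi & baseline),
        "n_edges": len(g.edges),
    }


def protein_recovery_study(seed: int = 0, kmer_dropout: float = 0.01, peptides_per_gene: int = 2) -> dict:
    """Protein reconstruction from sampled identified peptides.

    Samples ``peptides_per_gene`` in-bounds tryptic peptides per planted
    gene, runs the full inference, and measures (a) violations of the
    coverage contract and (b) exact reconstruction of planted proteins whose
    full coding path lies within the covered subgraph.
    """
    params = PepParams()
    sim = SimParams(seed=seed, kmer_dropout=kmer_dropout)
    comm = simulate_community(sim)
    g = build_dbg(comm.genomes, k=sim.k, kmer_dropout=sim.kmer_dropout, seed=sim.seed)
    enum = {p.aa_seq: p for p in enumerate_graph_peptides(g, params)}
    rng = np.random.default_rng((seed * 7919 + 1) % 2**31)
    identified: dict[str, TrypticPeptide] = {}
    sampled_genes: set[str] = set()
    for gene in comm.genes:
        peps = [p for p, _, _ in digest(gene.protein, params)]
        if len(peps) < peptides_per_gene:
            continue
        sampled_genes.add(gene.gene_id)
        for i in rng.choice(len(peps), size=peptides_per_gene, replace=False):
            pep = peps[int(i)]
            identified[pep] = enum.get(pep, TrypticPeptide(pep, (), "graph_dfs"))
    res = run_protein_inference(g, list(identified.values()), params)
    seqs = [c.aa_seq for _, c in res.proteins]
    mappable = set(identified) - set(res.unmapped_peptides)
    violations = sum(not any(p in s for s in seqs) for p in mappable)
    idx = kmer_index(g)
    outset = set(seqs)
    denom = hits = 0
    for gene in comm.genes:
        if gene.gene_id not in sampled_genes:
            continue  # contributed no identified peptide: not expected in a minimum cover
        genome = comm.genomes[gene.genome]
        sl = genome[gene.start : gene.end]
        gene_nt = sl if gene.strand == "+" else revcomp(sl)
        tr = trace_interval(g, idx, gene_nt, 0, len(gene_nt))
        if tr is None or not all(e in res.covered_edges for e in tr[0]):
            continue
        denom += 1
        hits += gene.protein in outset
    return {
        "n_identified": len(identified),
        "n_mappable": len(mappable),
        "coverage_violations": violations,
        "n_reconstructable": denom,
        "n_exact": hits,
        "exact_pct": 100.0 * hits / denom if denom else float("nan"),
        "n_proteins": len(res.proteins),
    }


def set_cover_study(n_instances: int = 100, seed: int = 0) -> dict:
    """Greedy protein selection vs. exhaustive minimum set cover."""
    from .graph import PathSegment

    eq = within = covered = 0
    for i in range(n_instances):
        rng = np.random.default_rng((seed * 65_537 + i) % 2**31)
        npep = int(rng.integers(3, 16))
        ncand = int(rng.integers(2, 13))
        peps = [f"p{j}" for j in range(npep)]
        cands, sets = [], {}
        for j in range(ncand):
            cov = frozenset(rng.choice(peps, size=int(rng.integers(1, npep + 1)), replace=False))
            aa = "".join(rng.choice(list("ACDEFGHIK"), size=int(rng.integers(5, 30))))
            cands.append(ProteinCandidate(aa, PathSegment(("e",), 0, 3), cov, True, True))
            sets[f"c{j}"] = cov
        universe = frozenset().union(*sets.values())
        chosen = select_min_protein_set(cands, set(peps))
        got = frozenset().union(*(c.covers for c in chosen)) if chosen else frozenset()
        covered += got == universe
        opt = exact_min_cover(sets, universe)
        within += len(chosen) <= opt * (math.log(len(universe)) + 1)
        eq += len(chosen) == opt
    return {
        "n": n_instances,
        "all_covered_pct": 100.0 * covered / n_instances,
        "within_bound_pct": 100.0 * within / n_instances,
        "optimal_pct": 100.0 * eq / n_instances,
    }


def fdr_calibration_study(n_replicates: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Realized false-discovery proportion at q <= alpha on synthetic PSMs."""
    fdps = []
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed * 104_729 + rep) % 2**31)
        prots = ["M" + "".join(rng.choice(aas, size=79)) for _ in range(60)]
        df = simulate_identifications(prots, IdentSimParams(seed=int(rng.integers(2**31))))
        psms = [
            PSMRecord(r.spectrum_id, r.peptide, r.peptide, [r.protein], float(r.score), r.protein.startswith(DECOY_PREFIX))
            for r in df.itertuples(index=False)
        ]
        labels = {r.spectrum_id: r.label for r in df.itertuples(index=False)}
        acc = filter_at_fdr(compute_qvalues(psms), alpha)
        if acc:
            fdps.append(sum(labels[r.spectrum_id] == "false" for r in acc) / len(acc))
    arr = np.asarray(fdps)
    return {
        "n": len(arr),
        "alpha": alpha,
        "mean_fdp": float(arr.mean()),
        "sd_fdp": float(arr.std()),
    }
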