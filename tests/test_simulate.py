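"""Synthetic community, graph construction, and identification simulation."""

import numpy as np
import pytest

from graphpep.graph import revcomp, spell_path, validate_graph
from graphpep.peptides import PepParams, enumerate_graph_peptides, translate
from graphpep.simulate import (
    IdentSimParams,
    SimParams,
    build_dbg,
    kmer_index,
    simulate_community,
    simulate_identifications,
    trace_interval,
    tryptic_peptides_of,
)


class TestCommunity:
    def test_gene_structure_and_counts(self):
        comm = simulate_community(SimParams(n_genomes=2, n_genes=3, seed=1))
        assert len(comm.genes) == 6
        for gene in comm.genes:
            assert gene.protein.startswith("M")
            assert "*" not in gene.protein
            genome = comm.genomes[gene.genome]
            sl = genome[gene.start : gene.end]
            nt = sl if gene.strand == "+" else revcomp(sl)
            assert nt[:3] == "ATG"
            assert nt[-3:] in ("TAA", "TAG", "TGA")
            assert translate(nt[:-3]) == gene.protein

    def test_deterministic_under_seed(self):
        a = simulate_community(SimParams(seed=7))
        b = simulate_community(SimParams(seed=7))
        assert a.genomes == b.genomes and a.genes == b.genes

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_community(SimParams(genome_len=500, n_genes=10, gene_len=(90, 240)))

    def test_no_repeats_no_shared_kmers(self):
        comm = simulate_community(SimParams(repeat_rate=0.0, seed=3))
        k = 21
        kms = [
            {g[i : i + k] for i in range(len(g) - k + 1)} for g in comm.genomes
        ]
        assert not (kms[0] & kms[1]) and not (kms[0] & kms[2])


class TestBuildDbg:
    def test_lossless_single_sequence(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        g = build_dbg([seq], k=21, kmer_dropout=0.0)
        # no repeated 20-mer in 400 random bases with overwhelming probability
        assert len(g.edges) == 2
        assert seq in (e.seq for e in g.edges.values())

    def test_graph_always_validates(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(2)]
            g = build_dbg(seqs, k=15, kmer_dropout=0.02, seed=seed)
            assert validate_graph(g) == []

    def test_repeated_interior_kmer_branches(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), size=60))
        core = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=60))
        c = "".join(rng.choice(list("ACGT"), size=60))
        d = "".join(rng.choice(list("ACGT"), size=60))
        g = build_dbg([a + core + b, c + core + d], k=21, kmer_dropout=0.0)
        assert len(g.edges) > 4  # shared core forces branch vertices

    def test_full_dropout_raises(self):
        with pytest.raises(ValueError, match="dropped"):
            build_dbg(["ACGTACGTACGTACGTACGTACGT"], k=7, kmer_dropout=1.0)

    def test_fragmentation_dial(self):
        comm = simulate_community(SimParams(seed=5))
        stats = []
        for dropout in (0.0, 0.001, 0.01):
            g = build_dbg(comm.genomes, k=21, kmer_dropout=dropout, seed=5)
            lens = sorted((len(e.seq) for e in g.edges.values()), reverse=True)
            half = sum(lens) / 2
            acc = 0
            for n50 in lens:
                acc += n50
                if acc >= half:
                    break
            stats.append((len(g.edges), n50))
        counts = [s[0] for s in stats]
        n50s = [s[1] for s in stats]
        assert counts[0] <= counts[1] <= counts[2]
        assert n50s[0] >= n50s[1] >= n50s[2]

    def test_losslessness_peptides_recoverable(self):
        """With no dropout the graph encodes every in-bounds tryptic peptide."""
        comm = simulate_community(SimParams(n_genomes=1, n_genes=6, genome_len=2500, seed=6))
        g = build_dbg(comm.genomes, k=21, kmer_dropout=0.0)
        params = PepParams()
        found = {p.aa_seq for p in enumerate_graph_peptides(g, params)}
        truth = tryptic_peptides_of([gene.protein for gene in comm.genes], params)
        # single unfragmented genome: the gene pass alone recovers the proteome
        assert truth <= found


class TestTrace:
    def test_maps_genome_interval_to_path_lossless(self):
        comm = simulate_community(SimParams(seed=8))
        g = build_dbg(comm.genomes, k=21, kmer_dropout=0.0)
        idx = kmer_index(g)
        genome = comm.genomes[0]
        for a in range(0, len(genome) - 100, 211):
            path, off = trace_interval(g, idx, genome, a, a + 90)
            assert spell_path(g, path)[off : off + 90] == genome[a : a + 90]

    def test_maps_genome_interval_with_dropout_gaps(self):
        comm = simulate_community(SimParams(seed=8))
        g = build_dbg(comm.genomes, k=21, kmer_dropout=0.01, seed=8)
        idx = kmer_index(g)
        genome = comm.genomes[0]
        hits = 0
        for a in range(0, len(genome) - 100, 211):
            tr = trace_interval(g, idx, genome, a, a + 40)
            if tr is None:
                continue  # interval hit a dropped k-mer
            hits += 1
            path, off = tr
            assert spell_path(g, path)[off : off + 40] == genome[a : a + 40]
        assert hits >= 5


class TestIdentifications:
    def test_full_detection_no_noise(self):
        comm = simulate_community(SimParams(n_genomes=1, seed=9))
        prots = [g.protein for g in comm.genes]
        df = simulate_identifications(prots, IdentSimParams(detection_prob=1.0, n_noise=0))
        truth = tryptic_peptides_of(prots, PepParams())
        assert set(df["peptide"]) == truth
        assert (df["label"] == "true").all()

    def test_zero_detection_only_noise(self):
        comm = simulate_community(SimParams(n_genomes=1, seed=9))
        df = simulate_identifications([g.protein for g in comm.genes], IdentSimParams(detection_prob=0.0, n_noise=10))
        assert len(df) == 20  # noise targets + decoys
        assert set(df["label"]) == {"false", "decoy"}

    def test_deterministic(self):
        comm = simulate_community(SimParams(n_genomes=1, seed=9))
        prots = [g.protein for g in comm.genes]
        a = simulate_identifications(prots, IdentSimParams(seed=4))
        b = simulate_identifications(prots, IdentSimParams(seed=4))
        assert a.equals(b)

    def test_scores_separated(self):
        comm = simulate_community(SimParams(n_genomes=1, seed=9))
        df = simulate_identifications([g.protein for g in comm.genes], IdentSimParams(seed=4))
        true_scores = df[df.label == "true"]["score"].astype(float)
        bad_scores = df[df.label != "true"]["score"].astype(float)
        assert true_scores.median() < bad_scores.median() * 1e-3
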