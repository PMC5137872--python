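"""Peptide enumeration: translation, digestion, ORF pass, and graph DFS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphpep.graph import Edge, segment_seq
from graphpep.peptides import (
    PepParams,
    STANDARD_CODE,
    candidate_starts,
    digest,
    enumerate_graph_peptides,
    find_long_edge_orfs,
    translate,
)
from graphpep.reference import brute_force_peptides
from graphpep.simulate import build_dbg

from conftest import make_graph, twin_relabel


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,aa",
        [("ATGAAACGT", "MKR"), ("ATGTAA", "M*"), ("", "")],
    )
    def test_examples(self, dna, aa):
        assert translate(dna) == aa

    def test_bad_length(self):
        with pytest.raises(ValueError, match="divisible"):
            translate("ATGA")

    def test_bad_symbol(self):
        with pytest.raises(ValueError, match="codon"):
            translate("ATN")


class TestDigest:
    @pytest.mark.parametrize(
        "protein,min_len,mc,expected",
        [
            ("MKRPGK", 1, 0, ["MK", "R", "PGK"]),
            ("MKRPGK", 2, 0, ["MK", "PGK"]),
            ("MKRPGK", 1, 1, ["MK", "MKR", "R", "RPGK", "PGK"]),
        ],
    )
    def test_examples(self, protein, min_len, mc, expected):
        params = PepParams(min_pep_len=min_len, max_miscleavage=mc)
        got = [p for p, _, _ in digest(protein, params)]
        assert sorted(got) == sorted(expected)

    def test_positions_recover_fragments(self):
        params = PepParams(min_pep_len=1, max_miscleavage=1)
        prot = "MKRPGKAAAK"
        for pep, a, b in digest(prot, params):
            assert prot[a:b] == pep

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_fragments_are_fully_tryptic(self, prot):
        params = PepParams(min_pep_len=1, max_miscleavage=1)
        for pep, a, b in digest(prot, params):
            assert a == 0 or prot[a - 1] in "KR"
            assert pep[-1] in "KR" or b == len(prot)
            assert sum(c in "KR" for c in pep[:-1]) <= 1


class TestLongEdgeOrfs:
    def test_simple_orf(self):
        e = Edge("z", "CCATGAAATAACC", "z'", [])
        out = find_long_edge_orfs(e, PepParams(min_orf_len=6))
        assert [(p, s.start, s.end) for p, s in out] == [("MK", 2, 11)]

    def test_no_start_codon(self):
        e = Edge("z", "CCCAAACCCTAA", "z'", [])
        assert find_long_edge_orfs(e, PepParams(min_orf_len=3)) == []

    def test_unterminated_orf_excluded_by_default(self):
        e = Edge("z", "ATGAAA", "z'", [])
        assert find_long_edge_orfs(e, PepParams(min_orf_len=3)) == []

    def test_partial_orfs_flag(self):
        e = Edge("z", "ATGAAAAAA", "z'", [])
        params = PepParams(min_orf_len=3, include_partial_orfs=True)
        prots = [p for p, _ in find_long_edge_orfs(e, params)]
        assert "MKK" in prots


class TestCandidateStarts:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAA", [(0, "start_codon")]),
            ("AAACGT", [(3, "after_cleavage")]),
            ("CCCCCC", []),
        ],
    )
    def test_examples(self, seq, expected):
        e = Edge("x", seq, "x'", [])
        assert candidate_starts(e) == expected


class TestEnumerate:
    def test_two_edge_fixture(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        peps = enumerate_graph_peptides(two_edge_graph, params)
        assert {p.aa_seq for p in peps} == {"MK", "R", "K"}
        by_aa = {p.aa_seq: p for p in peps}
        r_segs = [(s.edge_ids, s.start, s.end) for s in by_aa["R"].provenance]
        assert (("e2",), 3, 6) in r_segs

    def test_min_length_filter(self, two_edge_graph):
        assert enumerate_graph_peptides(two_edge_graph, PepParams(min_pep_len=6)) == []

    def test_single_edge_codon_scan(self, single_edge_graph):
        peps = enumerate_graph_peptides(single_edge_graph, PepParams(min_pep_len=1))
        assert {p.aa_seq for p in peps} == {"MK", "R", "K"}

    def test_provenance_translates_to_peptide(self, two_edge_graph):
        for p in enumerate_graph_peptides(two_edge_graph, PepParams(min_pep_len=1)):
            for seg in p.provenance:
                assert translate(segment_seq(two_edge_graph, seg)) == p.aa_seq

    def test_no_stop_and_cleavage_rule(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=300))]
        g = build_dbg(seqs, k=7, kmer_dropout=0.05, seed=5)
        params = PepParams(min_pep_len=1, max_miscleavage=1)
        for p in enumerate_graph_peptides(g, params):
            assert "*" not in p.aa_seq
            # C-terminus K/R unless the peptide ends right before a stop codon
            if p.aa_seq[-1] not in "KR":
                assert any(
                    _followed_by_stop(g, seg) for seg in p.provenance
                )
            assert sum(c in "KR" for c in p.aa_seq[:-1]) <= 1

    def test_duplicates_merged_with_union_of_provenance(self):
        # same peptide encoded on two disconnected edges
        g = make_graph(4, {"a": "AAAATGAAACGTAAA", "b": "CCAATGAAACGTACC"}, [])
        params = PepParams(min_pep_len=1)
        by_aa = {p.aa_seq: p for p in enumerate_graph_peptides(g, params)}
        assert "MK" in by_aa
        edge_sets = {s.edge_ids[0] for s in by_aa["MK"].provenance}
        assert {"a", "b"} <= edge_sets

    def test_long_edge_handled_by_gene_pass(self):
        rng = np.random.default_rng(11)
        filler = "".join(rng.choice(list("ACGT"), size=80))
        seq = filler + "TAAATGAAACGTGAAAAATACCCGGGTAA" + filler
        e = Edge("L", seq, "L'", [])
        g = make_graph(4, {}, [])
        g.edges["L"] = e
        g.edges["L'"] = Edge("L'", __import__("graphpep.graph", fromlist=["revcomp"]).revcomp(seq), "L", [])
        params = PepParams(min_pep_len=1, long_edge_threshold=100, min_orf_len=9)
        peps = enumerate_graph_peptides(g, params)
        gene_peps = {p.aa_seq for p in peps if p.source == "long_edge_gene"}
        assert {"MK", "R"} <= gene_peps

    def test_oracle_equivalence_sample(self):
        """DFS equals brute-force all-paths enumeration on random graphs."""
        checked = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            nseq = int(rng.integers(1, 3))
            seqs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 110)))) for _ in range(nseq)]
            g = build_dbg(seqs, k=7, kmer_dropout=0.12, seed=seed)
            if len(g.edges) > 20:
                continue
            checked += 1
            for mc in (0, 1):
                params = PepParams(min_pep_len=1, max_miscleavage=mc)
                mine = {p.aa_seq for p in enumerate_graph_peptides(g, params)}
                assert mine == brute_force_peptides(g, params)
        assert checked >= 5

    def test_twin_relabel_invariance(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=150))]
        g = build_dbg(seqs, k=7, kmer_dropout=0.1, seed=3)
        params = PepParams(min_pep_len=1)
        a = {p.aa_seq for p in enumerate_graph_peptides(g, params)}
        b = {p.aa_seq for p in enumerate_graph_peptides(twin_relabel(g), params)}
        assert a == b


def _followed_by_stop(g, seg):
    """The codon after the segment (possibly spanning successor edges) is a stop."""
    from graphpep.graph import spell_path

    def probe(last_edge, spelled):
        nxt = spelled[seg.end : seg.end + 3]
        if len(nxt) == 3:
            return nxt in STANDARD_CODE.stops
        return any(
            probe(s, spelled + g.edges[s].seq[g.k - 1 :]) for s in g.edges[last_edge].successors
        )

    return probe(seg.edge_ids[-1], spell_path(g, seg.edge_ids))
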