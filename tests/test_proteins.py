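"""Protein inference: mapping, covered subgraph, ORF enumeration, set cover."""

import math

import numpy as np
import pytest

from graphpep.graph import PathSegment, segment_seq
from graphpep.peptides import PepParams, TrypticPeptide, enumerate_graph_peptides, translate
from graphpep.proteins import (
    ProteinCandidate,
    covered_subgraph,
    enumerate_candidate_orfs,
    map_peptides_to_graph,
    run_protein_inference,
    select_min_protein_set,
)
from graphpep.reference import exact_min_cover


def _pep(aa):
    return TrypticPeptide(aa, (), "graph_dfs")


class TestMapping:
    def test_external_peptides_located(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        mapped, unmapped = map_peptides_to_graph([_pep("MK"), _pep("R"), _pep("WWWW")], two_edge_graph, params)
        assert (("e1",), 0, 6) in {(s.edge_ids, s.start, s.end) for s in mapped["MK"]}
        assert (("e2",), 3, 6) in {(s.edge_ids, s.start, s.end) for s in mapped["R"]}
        assert unmapped == ["WWWW"]

    def test_provenance_reused_verbatim(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        peps = enumerate_graph_peptides(two_edge_graph, params)
        mapped, unmapped = map_peptides_to_graph(peps, two_edge_graph, params)
        assert not unmapped
        for p in peps:
            assert set(p.provenance) <= set(mapped[p.aa_seq])

    def test_mapped_segments_translate_back(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        mapped, _ = map_peptides_to_graph([_pep("MK"), _pep("K")], two_edge_graph, params)
        for aa, segs in mapped.items():
            for seg in segs:
                assert translate(segment_seq(two_edge_graph, seg)) == aa


class TestCoveredSubgraph:
    def test_union_of_touched_edges(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        mapped, _ = map_peptides_to_graph([_pep("MK"), _pep("K")], two_edge_graph, params)
        segs = [s for ss in mapped.values() for s in ss]
        cov = covered_subgraph(two_edge_graph, segs)
        assert {"e1", "e2"} <= cov

    def test_empty(self, two_edge_graph):
        assert covered_subgraph(two_edge_graph, []) == set()


class TestCandidateOrfs:
    def test_complete_orf_on_fixture(self, two_edge_graph):
        cands = enumerate_candidate_orfs(
            two_edge_graph, {"e1", "e2"}, {"p0": "MK", "p1": "K"}, PepParams(min_pep_len=1)
        )
        complete = [c for c in cands if c.is_complete]
        assert any(c.aa_seq == "MKRK" and c.covers == {"p0", "p1"} for c in complete)

    def test_fragment_when_start_missing(self, two_edge_graph):
        cands = enumerate_candidate_orfs(two_edge_graph, {"e2"}, {"p0": "K"}, PepParams(min_pep_len=1))
        assert any(not c.complete_start and "K" in c.aa_seq for c in cands)

    def test_empty_covered_set(self, two_edge_graph):
        assert enumerate_candidate_orfs(two_edge_graph, set(), {}, PepParams(min_pep_len=1)) == []

    def test_unknown_covered_edge_raises(self, two_edge_graph):
        with pytest.raises(ValueError, match="zz"):
            enumerate_candidate_orfs(two_edge_graph, {"zz"}, {}, PepParams(min_pep_len=1))


class TestSetCover:
    def _cand(self, j, covers, length=10):
        aa = chr(ord("A") + j) * length
        return ProteinCandidate(aa, PathSegment(("e",), 0, 3), frozenset(covers), True, True)

    def test_dominant_candidate_wins(self):
        c1, c2, c3 = self._cand(0, {"p1", "p2"}), self._cand(1, {"p2", "p3"}), self._cand(2, {"p1", "p2", "p3"})
        chosen = select_min_protein_set([c1, c2, c3], {"p1", "p2", "p3"})
        assert chosen == [c3]

    def test_disjoint_needs_both(self):
        c1, c2 = self._cand(0, {"p1", "p2"}), self._cand(1, {"p3"})
        assert len(select_min_protein_set([c1, c2], {"p1", "p2", "p3"})) == 2

    def test_tie_broken_by_longer(self):
        c1 = self._cand(0, {"p1"}, length=20)
        c2 = self._cand(1, {"p1"}, length=5)
        assert select_min_protein_set([c2, c1], {"p1"}) == [c1]

    def test_greedy_against_exact_oracle(self):
        eq = 0
        n = 60
        for seed in range(n):
            rng = np.random.default_rng(seed)
            npep = int(rng.integers(3, 16))
            ncand = int(rng.integers(2, 13))
            peps = [f"p{i}" for i in range(npep)]
            cands, sets = [], {}
            for j in range(ncand):
                cov = frozenset(rng.choice(peps, size=int(rng.integers(1, npep + 1)), replace=False))
                cands.append(self._cand(j, cov, length=int(rng.integers(5, 30))))
                sets[f"c{j}"] = cov
            universe = frozenset().union(*sets.values())
            chosen = select_min_protein_set(cands, set(peps))
            got = frozenset().union(*(c.covers for c in chosen))
            assert got == universe  # covers everything coverable
            opt = exact_min_cover(sets, universe)
            assert len(chosen) <= opt * (math.log(len(universe)) + 1)
            assert len(chosen) <= opt + 2
            eq += len(chosen) == opt
        assert eq > n / 2  # equals the optimum on a majority of instances


class TestEndToEnd:
    def test_fixture_yields_single_protein(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        peps = {p.aa_seq: p for p in enumerate_graph_peptides(two_edge_graph, params)}
        res = run_protein_inference(two_edge_graph, [peps["MK"], peps["K"]], params)
        assert [c.aa_seq for _, c in res.proteins] == ["MKRK"]
        assert res.proteins[0][0] == "Protein1"
        assert res.proteins[0][1].is_complete

    def test_empty_identified(self, two_edge_graph):
        res = run_protein_inference(two_edge_graph, [], PepParams(min_pep_len=1))
        assert res.proteins == []

    def test_coverage_contract(self, two_edge_graph):
        params = PepParams(min_pep_len=1)
        peps = {p.aa_seq: p for p in enumerate_graph_peptides(two_edge_graph, params)}
        res = run_protein_inference(two_edge_graph, list(peps.values()), params)
        seqs = [c.aa_seq for _, c in res.proteins]
        for aa in peps:
            assert any(aa in s for s in seqs)

    def test_long_edge_gene_included_when_peptide_identified(self):
        from conftest import make_graph
        import numpy as np

        rng = np.random.default_rng(11)
        filler = "".join(rng.choice(list("ACGT"), size=80))
        seq = filler + "TAAATGAAACGTGAAAAATACCCGGGTAA" + filler
        g = make_graph(4, {"L": seq}, [])
        params = PepParams(min_pep_len=1, long_edge_threshold=100, min_orf_len=9)
        peps = {p.aa_seq: p for p in enumerate_graph_peptides(g, params)}
        gene_pep = next(p for p in peps.values() if p.source == "long_edge_gene")
        res = run_protein_inference(g, [gene_pep], params)
        assert any(gene_pep.aa_seq in c.aa_seq for _, c in res.proteins)
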