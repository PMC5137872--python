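# Methods

## Problem setting

Metagenome-guided metaproteomics searches MS/MS spectra against protein
sequences predicted from an assembly of the community's DNA.  Assemblies of
complex communities are fragmented: many genes are split across contig
boundaries, and the peptides encoded at those boundaries are invisible to a
contig-based database.  The assembly *graph*, however, still connects the
fragments.  `graphpep` works directly on the contracted de Bruijn graph:

1. **Peptide enumeration** — all fully tryptic peptides encoded by paths in
   the graph become the first-round search database;
2. **FDR filtering** — search-engine identifications are filtered by
   target-decoy FDR;
3. **Protein inference** — a second, peptide-constrained traversal
   reconstructs a minimum set of protein sequences containing every
   identified peptide, which becomes the second-round search database.

## Graph model

An assembly graph is a bidirected contracted de Bruijn graph: every edge
carries a DNA sequence of length ≥ k; every edge has a twin spelling the
reverse complement (a palindromic edge is its own twin); edge `a` may be
followed by `b` when the last k−1 bases of `a` equal the first k−1 bases of
`b`; links are mirrored (`b ∈ succ(a)` ⟺ `twin(a) ∈ succ(twin(b))`).  Paths
are spelled with (k−1)-overlap collapse, so a path over edges of lengths
`L1..Ln` spells `ΣLi − (n−1)(k−1)` bases.  All coordinates are 0-based,
half-open, and a spelled position belongs canonically to the first edge that
introduces it.  Input formats: SPAdes-dialect FASTG (apostrophe marks the
reverse orientation; k must be given, default 31, the value at which such
graphs keep usable connectivity) and a native pair {edge FASTA, link TSV,
optional twin TSV}; missing orientations and mirrored links are synthesized
and every invariant is then checked.

## Peptide enumeration

A fully tryptic peptide starts at a start codon (ATG by default; GTG/TTG
behind a flag) or immediately after a K/R codon, and ends at a K/R codon or
immediately before a stop.  Two passes:

* **Gene pass** on edges longer than `long_edge_threshold` (default 500 nt):
  complete ORFs (start codon to in-frame stop, ≥ `min_orf_len` = 60 nt
  including the stop) in the three forward frames are digested in silico;
  reverse-strand genes fall out of the twin edge.  ORFs broken by the edge
  boundary are excluded by default (`include_partial_orfs` admits them).
* **Graph DFS** rooted on short edges: every start-codon position and every
  position directly preceded by an in-edge K/R codon roots a codon walk
  along all outgoing paths.  At a K/R the pending peptide is emitted (and
  extended while the missed-cleavage budget allows, default 0); at a stop it
  is emitted and the walk halts; start codons straddling the edge end are
  resolved per branch during the walk.  Traversal may finish the current
  peptide inside a long edge but never continues beyond it.  Peptides left
  hanging at a graph dead end are dropped (non-tryptic C-terminus) unless
  `emit_dead_end` is set.

After-cleavage roots are admitted without verifying any upstream reading
frame.  The resulting database is deliberately permissive — decoy-based FDR
control downstream absorbs sequences that do not exist in the sample; this
follows the same logic that makes six-frame databases workable.

Bounds: peptides are reported between `min_pep_len` (6) and `max_pep_len`
(50) residues — observable tryptic peptides in MS are almost always shorter
than 50 aa — and a walk visits at most `max_edges_per_path` (20) edges,
which also terminates walks through graph cycles.  Duplicate peptides are
merged by sequence with provenance (path segments) unioned.  The DFS
requires k ≥ 4, so that a codon always fits inside the (k−1) overlap; this
is what lets roots be detected edge-locally without missing any path
context (an equivalence the test suite checks against a brute-force
all-paths enumeration).

## Target-decoy databases and FDR

Peptide databases use reversed decoys that keep a C-terminal K/R in place
(decoys stay fully tryptic); protein databases use plain reversal.  Decoys
colliding with any target sequence are dropped and counted.  The FDR
estimate at rank *i* of the best-to-worst ordering is `D_i / T_i` (zero
before the first target; the conservative `(D+1)/T` variant is a flag), and
q-values are the running minimum from the worst rank up.  Peptide-level
estimation keeps each stripped peptide's best PSM.  A match shared between a
target and a decoy protein counts as target; at equal score targets sort
before decoys.  The pipeline filters round 1 at 5% peptide-level FDR — a
deliberately loose cut, because these peptides only *constrain* protein
reconstruction — and reports both rounds at 1%.

## Protein inference

Identified peptides are mapped to DNA segments (recorded provenance is
reused; external peptides are located by translating edges and short-edge
paths in all frames).  The covered subgraph is the set of edges touched by
at least one segment; twins are not implicitly added.  A DFS restricted to
covered edges walks from every start codon (and, start-less, from the entry
frames of the subgraph plus each mapped segment's own frame — the latter
guarantees structurally that every mappable peptide lands inside some
candidate).  Complete ORFs carry both completeness flags; where no in-frame
start or stop is reachable inside the subgraph, maximal fragments are
emitted flagged rather than dropped, because dropping them would break the
coverage contract (`--complete-only` restores the strict reading).  Bounds:
2000 residues and 50 edges per candidate.

Greedy set cover then selects candidates: most uncovered peptides first;
ties prefer complete ORFs, then longer sequences, then lexicographic order.
The completeness preference is load-bearing: a start-less read-through
fragment covering the same peptides is otherwise longer than the true gene
and would displace it.  Greedy carries the usual ln(n)+1 guarantee; an
exhaustive solver in `graphpep.reference` exists for validation only.  The
final database adds every long-edge predicted protein containing at least
one identified peptide, so genes on intact contigs stay searchable in round
2.

## Synthetic data

The generator produces the conditions the pipeline is designed for, with
known ground truth:

* **Communities** — default 3 genomes × 5 kb, 17 genes per genome (~51
  total), gene lengths 90–240 nt (uniform over codon counts), both strands,
  GC 0.5.  Genes are ATG + non-stop codons + stop, planted at
  non-overlapping loci with ≥ 6 nt background between items, and
  *stop-insulated*: an in-frame stop sits directly upstream of each start.
  Without insulation ~25% of genes have an upstream in-frame ATG with no
  intervening stop, making the true start unrecoverable from sequence alone
  by any method.  `repeat_rate` (0.1) copies ~200 nt blocks from the
  previous genome, anchored at donor gene midpoints, so that assembly-graph
  branching occurs *inside* coding regions — the situation that produces
  peptides spanning multiple edges.
* **Graphs** — k-mers of both strands are collected (k = 21 by default;
  5 kb random sequences essentially never repeat a 20-mer, so the lossless
  graph is one edge pair per genome plus repeat-induced branches), a seeded
  fraction (`kmer_dropout`) is removed — always together with its reverse
  complement, keeping the graph symmetric — and maximal non-branching chains
  are collapsed.  Twin pairing is by exact reverse-complement match of
  unitig spellings; isolated cycles are broken at their minimal k-mer with
  the twin cycle emitted as the exact reverse complement, and
  self-reverse-complement cycles at a rotation whose spelling is palindromic
  (a self-twin edge).  Dropout of 0.01 fragments a 15 kb community into
  ~300 edges of ~100 nt.
* **Identifications** — every in-bounds tryptic peptide of the planted
  proteome is detected with probability 0.8 and scored from the "correct"
  distribution (E-value-like, `10^-N(10, 1.2)`); 300 noise target matches
  and 300 decoy matches draw from the "incorrect" distribution
  (`10^-N(4, 0.8)`).  Equal noise-target and decoy counts from the same
  distribution are what make the decoy count an unbiased estimate of false
  target matches, hence the calibration target of the FDR machinery.

What the simulator does **not** model: read errors, coverage variation,
chimeric assembly, real codon usage and amino-acid composition, homologous
genes within a genome, spectral properties of peptides (detectability is
uniform), and retention/charge effects.  Passing tests therefore demonstrate
algorithmic correctness on graphs with the right topology, not end-to-end
performance on real instrument data.

## Validation studies and problem sizes

`graphpep.validation` holds the study procedures run by both the test suite
and `scripts/acceptance.py`:

* **Oracle equivalence** — 100 random fragmented graphs (k = 7, ≤ 20 edges):
  DFS output equals a brute-force enumeration that spells every path and
  applies the tryptic definition verbatim.  Both sides use a path bound of
  10 edges; the property is parametric in the bound, and the oracle's cost
  (number of distinct paths) explodes on cyclic graphs at larger bounds.
* **Planted recovery** — a peptide is *recoverable by design* when its
  length is in bounds, its coding path plus N-terminal context codon (plus
  the stop codon, for protein-end peptides) survives dropout, and either its
  gene sits wholly in one edge (gene pass) or the context sits on a short
  edge with any long edge last on the path (DFS semantics).  At dropout 0
  recovery of this class is asserted at 100%; peptides rooted inside a long
  edge but belonging to a boundary-broken gene are counted separately — they
  are invisible to both passes by construction.  The multi-edge comparison
  against a contigs-only baseline (per-edge complete ORFs) aggregates three
  replicate communities, because one community yields only 1–3
  junction-crossing peptides.
* **Protein recovery** — two sampled peptides per gene; hard assertion that
  every mappable identified peptide is a substring of an output protein;
  exact-reconstruction is measured over genes that contributed peptides and
  whose full coding path lies in the covered subgraph.
* **Set cover** — 100 instances (≤ 12 candidates, ≤ 15 peptides) against
  the exhaustive optimum.
* **FDR calibration** — 200 replicate synthetic PSM tables; realized false
  discovery proportion at q ≤ 0.05.

## Numerical and degenerate-input choices

* Determinism everywhere: a single integer seed drives every random draw;
  iteration orders are sorted; FASTA/TSV writers are byte-stable.
* Score ties: targets before decoys (flag for the conservative opposite).
* Empty identified-peptide sets yield an empty protein database and a
  warning, not an error.
* Unmappable peptides are data (reported), never exceptions.
* Graph validation returns violations as data; loaders raise only after
  collecting them.

## Known limitations

* The DFS rooting argument requires k ≥ 4 (enforced).
* Candidate ORFs longer than 2000 residues are truncated at the bound; a
  peptide spanning the truncation point of an extremely long gene could be
  missed by the coverage contract.
* Peptide mapping for externally supplied peptides scans paths of short
  edges only (plus a final long edge), mirroring enumeration semantics; a
  peptide genuinely starting inside a long edge and crossing into another
  edge is reported unmappable.
* The minimum set cover is greedy (ln(n)+1-approximate), as the exact
  problem is NP-hard; the exhaustive solver is retained for tests only.
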