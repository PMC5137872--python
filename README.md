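# graphpep

Peptide and protein inference for metaproteomics, computed directly from the
contracted de Bruijn graph of a metagenome (or metagenome+metatranscriptome)
assembly.

## Why

Metaproteomics identifies MS/MS spectra against protein sequences predicted
from the community's metagenome.  Assemblies of complex communities are
fragmented, and genes broken across contig boundaries are invisible to a
contig-derived database.  The assembly *graph* still connects those
fragments: a peptide whose coding sequence spans two or three short contigs
corresponds to a path through the graph.  `graphpep` exploits this in a
two-round scheme:

1. **Peptide enumeration.**  All *fully tryptic* peptides encoded in the
   graph — starting at a start codon or right after a K/R codon, ending at a
   K/R codon or right before a stop — are enumerated: complete ORFs on long
   edges (> 500 nt) are digested in silico, and a codon-frame-aware
   depth-first search over short-edge paths finds the contig-spanning
   peptides.  This permissive set is the round-1 search database.
2. **FDR filtering.**  Search-engine PSMs are filtered by target-decoy FDR.
   With decoy count *D* and target count *T* among the top-scoring matches,
   FDR̂ = *D*/*T*, and the q-value of a match is the minimum FDR̂ at which it
   would be accepted.  Round 1 is cut loosely (5%, peptide level) because
   its peptides only constrain the next step.
3. **Protein inference.**  Identified peptides are mapped back to DNA
   segments on the graph; a second traversal restricted to the *covered*
   edges enumerates candidate ORFs, and a greedy minimum set cover selects
   the smallest protein set containing every identified peptide.  Those
   proteins are the round-2 database, searched and reported at 1% FDR.

Decoys are sequence reversals — preserving the C-terminal K/R for peptide
databases, plain reversal for protein databases.

## Worked example

A two-edge graph (k = 4) in the native format — edge FASTA plus link TSV:

```sh
printf '>e1\nATGAAA\n>e2\nAAACGTAAATGA\n' > edges.fa
printf 'e1\te2\n' > links.tsv
graphpep enumerate-peptides edges.fa --links links.tsv -k 4 --min-pep-len 1 -o peps.fa
cat peps.fa
```

```
>pep_a7ee38bb7be4 graph_dfs e2:6-9
K
>pep_2c859ac5409f graph_dfs e1:0-6
MK
>pep_06576556d1ad graph_dfs e2:3-6
R
```

The spelled path `ATGAAA·CGTAAATGA` reads `ATG AAA CGT AAA TGA` = M K R K
stop, so the tryptic peptides are `MK` (from the start codon to the first
K), `R` and `K` (between cleavage sites); each FASTA header carries the
source pass and the edge coordinates of the encoding.  Suppose the search
engine then identifies `MK` and `K`:

```sh
printf 'peptide\nMK\nK\n' > ident.tsv
graphpep infer-proteins edges.fa ident.tsv --links links.tsv -k 4 -o prot.fa
cat prot.fa
```

```
>Protein1 complete peptides=2 e1|e2:0-12
MKRK
```

One protein — the complete ORF spanning both edges — covers both peptides;
`complete` means it runs from a start codon to just before a stop.

The whole two-round pipeline can be exercised end to end on synthetic data
(three 5 kb genomes with planted genes, graph fragmented by 1% k-mer
dropout, simulated identifications):

```sh
graphpep pipeline --outdir run --seed 1
```

```
"n_edges": 310,
"n_graph_peptides": 1257,
"n_proteins": 69,
"round1": { "n_psms": 122, "n_unique_peptides": 122, "pct_spectra_identified": 16.31 },
"round2": { "n_psms": 122, "n_unique_peptides": 122, "pct_spectra_identified": 16.31 }
```

Round 2 identifies at least as many unique peptides as round 1 at the same
1% FDR: every round-1 peptide is contained in a reconstructed protein, and
peptides whose coding paths were broken in round 1's database can reappear
inside reconstructed proteins.

Other subcommands: `makedb` (target+decoy FASTA), `filter-psms` (q-values,
filtering, a Table-style summary, and the recommended MSGF+ settings via
`--emit-msgf-params`), `simulate` (write a ground-truthed community),
`validate-graph`.  FASTG input is selected with `--format fastg`; k is not
stored in FASTG and must be supplied (default 31).

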