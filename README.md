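# gkmloc

Gapped k-mer encoding of protein sequences over a reduced amino-acid
alphabet, with a one-versus-one SVM pipeline for subcellular-localization
prediction.

## The problem

Predicting where a protein resides in the cell (cytoplasm, membrane,
mitochondrion, ...) from its sequence alone is a standard multiclass
classification task in bioinformatics. The simplest encodings — amino-acid
or dipeptide composition — ignore most of the order information in the
sequence, while raw k-peptide counting explodes combinatorially: there are
20^k possible k-mers, so already at k = 4 the feature space has 160,000
cells, almost all of them empty.

`gkmloc` implements an encoding that tames both problems at once:

1. **Alphabet reduction.** The 20 amino acids are partitioned into t = 6
   physicochemical classes — hydrophilic `L` {R,D,E,N,Q,K,H}, hydrophobic
   `B` {L,I,V,A,M,F}, neutral `W` {S,T,Y,W}, and the singletons proline
   `P`, glycine `G`, cysteine `C` — shrinking the k-mer space from 20^k
   to 6^k.
2. **Gapped k-mers.** A gapped k-mer is a length-k word in which g
   positions are wildcards (`_`) matching any class. Every one of the
   l − k + 1 overlapping windows of a length-l sequence contributes one
   count under each of the C(k, g) gap placements, so the window `BBW`
   is counted as `_BW`, `B_W` and `BB_` when g = 1. The wildcard acts
   like a gap in pairwise alignment: `BBB` and `BBW` both match `BB_`,
   so the encoding tolerates point substitutions. The feature vector

       V_{k,g}(S) = [v_1, v_2, ..., v_m]^T

   collects the counts (or frequencies) of the m distinct gapped
   k-peptides; the full space has dimension C(k, g) · t^(k−g), and an
   *observed* vocabulary keeps only the patterns that occur in the
   training corpus.
3. **Trie counting.** Plain k-mer counts are stored at the leaves of a
   depth-k trie whose arity is the alphabet size. Any gapped table is
   then obtained without rescanning the sequence: delete the gapped
   layers and merge the subtrees beneath them, summing leaf counts. One
   tree yields every gap placement.

Two additional components round out the pipeline: a spaced-dipeptide
("XDY") encoding — an ordered residue pair separated by exactly d
arbitrary residues, a 400-cell vector over the raw alphabet — and a
one-versus-one RBF-SVM evaluator with grid search over
C, γ ∈ {2^−5, ..., 2^5}, jackknife (leave-one-out) testing, and
per-class sensitivity, specificity, Matthews correlation and overall
accuracy computed from the pooled confusion matrix.

A seeded synthetic-data generator produces labeled protein-like datasets
with class-specific motifs planted on the reduced alphabet, so the whole
pipeline is testable without external database downloads.

## Worked example

```python
from gkmloc import (reduce_sequence, count_kmers, count_gapped,
                    gapped_counts_via_trie, full_dimension, ReducedSequence,
                    DEFAULT_SCHEME)

rseq = reduce_sequence("RIAVYYPG")
print("reduced:", rseq.symbols)

demo = ReducedSequence("LBBBWWG", alphabet=DEFAULT_SCHEME.class_alphabet)
print("3-mer types:", sorted(count_kmers(demo, 3).counts))
gapped = count_gapped(demo, 3, 1)
print("gapped 3-mer types:", len(gapped.counts))
print("full dimension (t=6, k=3, g=1):", full_dimension(6, 3, 1))

binary = ReducedSequence("BBBWWBBWB", alphabet=("B", "W"))
print("B_B count via trie:", gapped_counts_via_trie(binary, 3, 1)["B_B"])
```

prints

```
reduced: LBBBWWPG
3-mer types: ['BBB', 'BBW', 'BWW', 'LBB', 'WWG']
gapped 3-mer types: 12
full dimension (t=6, k=3, g=1): 108
B_B count via trie: 2
```

Reading the output: each residue of `RIAVYYPG` is replaced by its class
symbol (R→L, I/A/V→B, Y→W, P→P, G→G). The 7-symbol sequence `LBBBWWG`
has five distinct 3-mers, so its plain 3-mer vector is 5-dimensional;
allowing one gap expands those five windows into twelve distinct gapped
patterns out of a full space of C(3,1) · 6² = 108. In the binary example
`BBBWWBBWB`, the pattern `B_B` (any class in the middle) occurs twice —
the trie-collapse route and direct window enumeration agree exactly.

## Command line

```sh
gkmloc fixtures --spec spec.cfg -o data/          # synthetic labeled FASTA
gkmloc reduce data/cyto.fasta > reduced.fasta     # reduced-alphabet FASTA
gkmloc features --k 5 --g 1 --mode observed data/*.fasta -o feats.tsv
gkmloc dipep --d 3 data/cyto.fasta -o dipep.tsv
gkmloc eval feats.tsv data/labels.tsv --folds 10 --seed 7 -o report.tsv
```

Every subcommand accepts `--config FILE` (plain `key=value` lines) as a
source of defaults, and all randomness flows from the explicit seeds, so
equal inputs give byte-identical outputs.

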