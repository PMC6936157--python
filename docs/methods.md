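# Methods

## Encoding model

A protein sequence is first mapped residue-by-residue onto a reduced
alphabet of t physicochemical classes. The built-in scheme has six
classes — hydrophilic `L` {R,D,E,N,Q,K,H}, hydrophobic `B` {L,I,V,A,M,F},
neutral `W` {S,T,Y,W}, proline `P`, glycine `G`, cysteine `C` — and
alternative schemes can be supplied as plain `<symbol><TAB><residues>`
files. Class symbols intentionally reuse amino-acid letters (the field's
customary notation), so raw and reduced strings are kept as distinct
types (`str` vs `ReducedSequence`) and reduction is only defined on raw
residue strings; double reduction is a type error, never a silent
corruption.

Over the reduced sequence, the gapped k-mer vector counts every
overlapping length-k window once per gap-position set: for g gaps there
are C(k, g) placements, each replacing the chosen positions with the
wildcard `_`. Plain k-mer counting is the g = 0 special case. The full
pattern space has dimension C(k, g) · t^(k−g); an `observed` vocabulary
retains only patterns seen in the training corpus, which is the
dimension-reduction tactic the encoding relies on at larger k.

The spaced-dipeptide ("XDY") vector is computed on the raw 20-letter
alphabet: for spacing d, each ordered pair (seq[i], seq[i+d+1])
increments one of 400 cells (X-major alphabetical indexing; d = 0 is the
classical dipeptide composition).

## Trie counting

Plain k-mer counts are held at the leaves of a depth-k trie whose arity
equals the alphabet size. A gapped table for any gap-position set is
derived by deleting the gapped layers and merging the subtrees beneath
them, summing the counts of corresponding leaves; gapping the head
position merges the root's subtrees. The merge is exactly
marginalization over the gapped coordinate, so for every pattern the
collapsed count equals the sum of the counts of the patterns that refine
it — a property-tested identity. The trie route is required to agree
element-wise with direct sliding-window enumeration; the equivalence is
enforced both by a hypothesis property test and by a 1,000-sequence
randomized sweep (lengths 10–500, t ∈ {2, 6}, k ≤ 6, g ≤ k).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| k | word length (residues) | 5 (CLI) | dimension grows as t^(k−g) |
| g | number of gaps | 1 (CLI) | 0 ≤ g ≤ k; g = k is a degenerate all-gap pattern (dimension C(k,k) = 1), permitted and counted |
| d | dipeptide spacing | 0 | 0 ≤ d; d > l − 2 gives the zero vector |
| t | reduced alphabet size | 6 | fixed by the scheme |
| normalization | counts vs frequency | counts | frequency divides by the window total, giving length invariance |
| unknown_policy | non-standard residue handling | skip | see below |
| C, γ grid | SVM hyperparameters | 2^e, e = −5..5 | integer exponents; 121 pairs |
| cv_folds | grid-search CV folds | 10 | stratified, seeded; reduced with a warning on tiny classes |

## Numerical and design choices

- **Counts by default.** Worked examples in the literature print raw
  occurrence counts, and raw counts round-trip losslessly through the
  TSV/LIBSVM writers; frequency normalization (count / window total) is
  the recommended option when feeding the SVM, since it removes sequence
  length as a confounder. The pipeline never standardizes features
  silently.
- **Non-standard residues** (X, B, Z, U, O, J): the default `skip`
  policy marks the position and excludes every window touching it, so
  the alphabet stays at exactly t symbols and the count-conservation
  identity Σ counts = C(k, g) · (valid windows) holds on dirty input.
  `error` rejects the sequence naming residue and position;
  `extra_class` maps all non-standard residues to one additional symbol,
  growing the alphabet to t + 1 (and hence the full dimension).
- **Gap sets are arbitrary position combinations**, not only contiguous
  runs — the dimension formula C(k, g) counts all subsets, and head,
  middle and tail gaps are all exercised by the worked examples.
- **Vocabulary ordering** is lexicographic in alphabet order with the
  gap symbol sorting last. No ordering is canonical in the field; a
  fixed one makes feature matrices byte-reproducible.
- **Tie-breaking in grid search**: the (C, γ) pair with the best mean
  CV accuracy wins; ties break to the smallest C, then the smallest γ,
  so degenerate inputs resolve deterministically to (2^−5, 2^−5).
- **Two-stage protocol by default**: the grid search runs once on the
  full dataset and the chosen (C, γ) is held fixed across all jackknife
  folds. This mirrors how such pipelines are conventionally reported but
  lets test-sample information influence hyperparameter choice, so the
  resulting accuracy is optimistically biased; `nested=True` (CLI
  `--nested`) re-selects the pair inside every fold at k(k−1)/2 × 121 ×
  folds extra SVM fits per sample.
- **Multiclass metric reduction**: Sn, Sp and MCC are computed
  one-vs-rest per class from the pooled jackknife confusion matrix; OA
  is trace / N. MCC is defined as 0 whenever its denominator vanishes
  (empty class or degenerate predictor).
- **Singleton classes** survive the jackknife but can never be predicted
  correctly (their only member is held out); this is logged, and a fold
  whose training half retains a single class falls back to predicting
  the majority label.

## Synthetic data

The fixture generator emulates the one property of real localization
benchmarks the encoding exploits: class-conditional enrichment of short
reduced-alphabet words. Sequences are i.i.d. draws from a background
residue distribution (uniform over the 20 standard residues by default);
each class plants its motifs by sampling, at each motif position, any
residue of the named physicochemical class, so the signal is invisible
at the raw-residue level in expectation but exact after reduction — it
exercises the reduction → gapped-k-mer path specifically. A sequence of
length l offers l // (2·|motif|) insertion slots and each is filled with
probability `insertion_rate`; at rate 0 the classes are exchangeable.

The bundled 98-sequence benchmark shape (43/30/13/12 across four
classes, lengths 80–160) follows the class proportions of the classic
apoptosis-protein benchmark; its content is entirely synthetic. What
passing tests show is that the pipeline recovers planted compositional
class structure and stays at chance on exchangeable nulls — not that it
reaches any particular accuracy on real Swiss-Prot-derived data, which
exhibits homology, length/composition confounds and annotation noise
the generator deliberately omits.

Problem sizes used by the test suite: signal-recovery and null tests run
the full 98-sequence fixture with the complete 121-pair grid at k = 3,
g = 1 (observed vocabulary, frequency normalization); the
rate-monotonicity sweep uses 20-sequence datasets with a reduced 2×2
grid over three seeds, a size at which the monotone trend is already
stable.

## Known limitations

- The encoding discards positional information entirely beyond the
  k-window; two sequences with permuted k-mer content are
  indistinguishable.
- The observed-vocabulary tactic makes the feature space
  training-corpus-dependent; vectors from different corpora are not
  directly comparable unless built against a shared vocabulary.
- `extra_class` inflates the alphabet with a catch-all symbol whose
  k-mers mix chemically unrelated residues; `skip` (the default)
  discards windows instead, which slightly undercounts near
  non-standard residues.
- The nucleotide alphabet is structurally supported (any scheme file
  works) but untested in this version.
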