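"""Gapped k-mer counting and feature-vector construction.

A gapped k-mer is a length-``k`` word over the reduced class alphabet in
which ``g`` positions are replaced by a gap symbol that matches any
class.  For a sequence of length ``l`` every one of the ``l - k + 1``
overlapping windows contributes one count to each of the ``C(k, g)``
gap-position placements, so a window such as ``BBW`` is counted under
``_BW``, ``B_W`` and ``BB_`` when ``g = 1``.

Two counting routes are provided and must agree exactly:

* direct sliding-window enumeration (:func:`count_gapped`), and
* a depth-``k`` trie whose leaves hold plain k-mer counts, from which
  any gapped table is obtained by deleting the gapped layers and
  merging the subtrees beneath them (:func:`gapped_counts_via_trie`).

The trie route builds the k-mer tree once and derives every gap
placement from it, which is the point of the structure.

The full pattern space has dimension ``C(k, g) * t**(k-g)`` for an
alphabet of ``t`` classes; an *observed* vocabulary instead retains only
the patterns that occur in a training corpus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .alphabet import SKIP_SYMBOL, ReducedSequence

__all__ = [
    "CountTable",
    "Vocabulary",
    "FeatureVector",
    "MultiTreeNode",
    "MultiTree",
    "count_kmers",
    "enumerate_gap_sets",
    "count_gapped",
    "build_multitree",
    "collapse_multitree",
    "gapped_counts_via_trie",
    "full_dimension",
    "build_vocabulary",
    "vectorize",
    "pattern_sort_key",
]

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Pattern -> count map for one (k, g) setting.

    Only observed patterns are stored (all counts are positive).
    ``window_total`` is the number of counted windows times the number
    of gap-position sets, so the counts always sum to it.
    """

    counts: dict[str, int]
    k: int
    g: int
    window_total: int
    gap_symbol: str = "_"

    def __getitem__(self, pattern: str) -> int:
        return self.counts.get(pattern, 0)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Vocabulary:
    """Ordered pattern list a feature vector is aligned to.

    ``full`` mode enumerates all ``C(k,g) * t**(k-g)`` patterns;
    ``observed`` mode keeps only patterns present in some training
    count table.  Ordering is lexicographic in alphabet order with the
    gap symbol sorting last, so matrices are reproducible.
    """

    patterns: tuple[str, ...]
    mode: str
    k: int
    g: int
    alphabet: tuple[str, ...]
    gap_symbol: str = "_"

    def __len__(self) -> int:
        return len(self.patterns)

    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.patterns)}


@dataclass
class FeatureVector:
    """Numeric projection of a :class:`CountTable` onto a vocabulary."""

    values: np.ndarray
    vocabulary: Vocabulary
    normalization: str = "counts"
    source_id: str = ""


def _valid_window_starts(symbols: str, k: int) -> list[int]:
    """Starts of length-k windows free of skip markers."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    starts = []
    for i in range(len(symbols) - k + 1):
        win = symbols[i : i + k]
        if SKIP_SYMBOL not in win:
            starts.append(i)
    return starts


def count_kmers(rseq: ReducedSequence, k: int) -> CountTable:
    """Count every overlapping k-mer window (step 1) of a reduced sequence.

    Windows touching a skipped residue are excluded; for clean input the
    window total is ``l - k + 1``.  A sequence shorter than ``k`` yields
    an empty table.
    """
    counts: dict[str, int] = {}
    starts = _valid_window_starts(rseq.symbols, k)
    for i in starts:
        word = rseq.symbols[i : i + k]
        counts[word] = counts.get(word, 0) + 1
    return CountTable(counts=counts, k=k, g=0, window_total=len(starts),
                      gap_symbol=rseq.gap_symbol)


def enumerate_gap_sets(k: int, g: int) -> list[tuple[int, ...]]:
    """All C(k, g) gap-position subsets of {0..k-1}, lexicographic."""
    if not 0 <= g <= k:
        raise ValueError(f"need 0 <= g <= k, got g={g}, k={k}")
    return list(itertools.combinations(range(k), g))


def _gap_word(window: str, gap_set: tuple[int, ...], gap_symbol: str) -> str:
    chars = list(window)
    for pos in gap_set:
        chars[pos] = gap_symbol
    return "".join(chars)


def count_gapped(rseq: ReducedSequence, k: int, g: int) -> CountTable:
    """Sliding-window gapped k-mer counts over all C(k, g) gap placements.

    ``g = 0`` reduces to :func:`count_kmers`.
    """
    gap_sets = enumerate_gap_sets(k, g)
    gap = rseq.gap_symbol
    counts: dict[str, int] = {}
    starts = _valid_window_starts(rseq.symbols, k)
    for i in starts:
        window = rseq.symbols[i : i + k]
        for gs in gap_sets:
            word = _gap_word(window, gs, gap)
            counts[word] = counts.get(word, 0) + 1
    return CountTable(counts=counts, k=k, g=g,
                      window_total=len(starts) * len(gap_sets), gap_symbol=gap)


# ---------------------------------------------------------------------------
# Multi-tree (trie) counting


@dataclass
class MultiTreeNode:
    children: dict[str, "MultiTreeNode"] = field(default_factory=dict)
    count: int = 0  # window count; positive only at leaves

    def subtree_count(self) -> int:
        if not self.children:
            return self.count
        return sum(c.subtree_count() for c in self.children.values())


@dataclass
class MultiTree:
    """Depth-k trie whose root-to-leaf paths spell observed k-mers.

    The arity follows the alphabet of the sequence it was built from
    (binary for a two-class reduction, six-ary for the default scheme);
    leaf counts are exactly the plain k-mer counts.
    """

    root: MultiTreeNode
    depth: int
    alphabet: tuple[str, ...]
    gap_symbol: str = "_"

    def n_leaves(self) -> int:
        def walk(node: MultiTreeNode) -> int:
            if not node.children:
                return 1 if node.count > 0 or node is not self.root else 0
            return sum(walk(c) for c in node.children.values())

        return walk(self.root)

    def leaf_table(self) -> CountTable:
        """The k-mer count table stored at the leaves."""
        return collapse_multitree(self, ())


def build_multitree(rseq: ReducedSequence, k: int) -> MultiTree:
    """Build the depth-k counting trie by inserting every valid window."""
    root = MultiTreeNode()
    starts = _valid_window_starts(rseq.symbols, k)
    for i in starts:
        node = root
        for sym in rseq.symbols[i : i + k]:
            node = node.children.setdefault(sym, MultiTreeNode())
        node.count += 1
    return MultiTree(root=root, depth=k, alphabet=tuple(rseq.alphabet),
                     gap_symbol=rseq.gap_symbol)


def collapse_multitree(tree: MultiTree, gap_positions) -> CountTable:
    """Gapped counts for one gap-position set, by layer deletion.

    Each layer whose depth is in ``gap_positions`` is removed and the
    subtrees beneath it are merged, summing the counts of corresponding
    leaves — gapping the head position deletes the root's children layer
    and merges its subtrees, a middle position merges mid-level
    subtrees, and the empty set returns the leaf table unchanged.
    """
    gap_set = tuple(sorted(set(gap_positions)))
    for pos in gap_set:
        if not 0 <= pos < tree.depth:
            raise ValueError(f"gap position {pos} outside depth {tree.depth}")
    gap = tree.gap_symbol
    in_gap = set(gap_set)

    def walk(node: MultiTreeNode, depth: int) -> dict[str, int]:
        if depth == tree.depth:
            return {"": node.count} if node.count else {}
        out: dict[str, int] = {}
        if depth in in_gap:
            merged: dict[str, int] = {}
            for child in node.children.values():
                for suffix, c in walk(child, depth + 1).items():
                    merged[suffix] = merged.get(suffix, 0) + c
            for suffix, c in merged.items():
                out[gap + suffix] = c
        else:
            for sym, child in node.children.items():
                for suffix, c in walk(child, depth + 1).items():
                    out[sym + suffix] = c
        return out

    counts = walk(tree.root, 0)
    return CountTable(counts=counts, k=tree.depth, g=len(gap_set),
                      window_total=sum(counts.values()), gap_symbol=gap)


def gapped_counts_via_trie(rseq: ReducedSequence, k: int, g: int) -> CountTable:
    """Gapped counts from one trie collapsed over every gap set.

    Element-wise identical to :func:`count_gapped`; the trie is built
    once and reused for all C(k, g) placements.
    """
    gap_sets = enumerate_gap_sets(k, g)
    tree = build_multitree(rseq, k)
    counts: dict[str, int] = {}
    for gs in gap_sets:
        part = collapse_multitree(tree, gs)
        for pattern, c in part.counts.items():
            counts[pattern] = counts.get(pattern, 0) + c
    return CountTable(counts=counts, k=k, g=g,
                      window_total=sum(counts.values()), gap_symbol=rseq.gap_symbol)


# ---------------------------------------------------------------------------
# Vocabularies and vectors


def full_dimension(t: int, k: int, g: int) -> int:
    """Size of the full gapped pattern space, ``C(k,g) * t**(k-g)``.

    ``g = 0`` gives the plain k-mer dimension ``t**k``.
    """
    if t < 1:
        raise ValueError(f"alphabet size must be >= 1, got {t}")
    if not 0 <= g <= k or k < 1:
        raise ValueError(f"need k >= 1 and 0 <= g <= k, got k={k}, g={g}")
    return comb(k, g) * t ** (k - g)


def pattern_sort_key(pattern: str, alphabet: tuple[str, ...], gap_symbol: str = "_"):
    """Lexicographic key in alphabet order; the gap symbol sorts last."""
    rank = {sym: i for i, sym in enumerate(alphabet)}
    gap_rank = len(alphabet)
    return tuple(gap_rank if ch == gap_symbol else rank[ch] for ch in pattern)


def build_vocabulary(
    tables: list[CountTable],
    mode: str = "observed",
    alphabet: tuple[str, ...] = (),
    k: int | None = None,
    g: int | None = None,
    gap_symbol: str = "_",
) -> Vocabulary:
    """Build the ordered pattern vocabulary for a corpus of count tables.

    ``observed`` keeps the union of patterns present in ``tables``;
    ``full`` enumerates the complete ``C(k,g) * t**(k-g)`` space (and
    requires ``alphabet``; ``k``/``g`` default to the tables' values).
    """
    if mode not in ("observed", "full"):
        raise ValueError(f"mode must be observed|full, got {mode!r}")
    if tables:
        ks = {t.k for t in tables}
        gs = {t.g for t in tables}
        if len(ks) > 1 or len(gs) > 1:
            raise ValueError(f"mixed k/g across tables: k={sorted(ks)}, g={sorted(gs)}")
        k = k if k is not None else ks.pop()
        g = g if g is not None else gs.pop()
        gap_symbol = tables[0].gap_symbol
    if k is None or g is None:
        if mode == "full":
            raise ValueError("full mode needs k and g (no tables given)")
        k, g = 0, 0
    if mode == "observed":
        patterns = set()
        for t in tables:
            patterns.update(t.counts)
    else:
        if not alphabet:
            raise ValueError("full mode needs the class alphabet")
        patterns = set()
        for gap_set in enumerate_gap_sets(k, g):
            fill = [i for i in range(k) if i not in gap_set]
            for combo in itertools.product(alphabet, repeat=len(fill)):
                chars = [gap_symbol] * k
                for i, sym in zip(fill, combo):
                    chars[i] = sym
                patterns.add("".join(chars))
    ordered = tuple(sorted(patterns, key=lambda p: pattern_sort_key(p, tuple(alphabet), gap_symbol))
                    if alphabet else sorted(patterns))
    return Vocabulary(patterns=ordered, mode=mode, k=k, g=g,
                      alphabet=tuple(alphabet), gap_symbol=gap_symbol)


def vectorize(table: CountTable, vocab: Vocabulary, normalization: str = "counts") -> FeatureVector:
    """Project a count table onto a vocabulary.

    Patterns absent from the vocabulary are dropped; vocabulary patterns
    absent from the table read 0.  Under ``frequency`` each count is
    divided by the table's window total, so the values sum to 1 whenever
    the vocabulary covers everything observed.
    """
    if normalization not in ("counts", "frequency"):
        raise ValueError(f"normalization must be counts|frequency, got {normalization!r}")
    if table.k != vocab.k or table.g != vocab.g:
        raise ValueError(
            f"table (k={table.k}, g={table.g}) does not match "
            f"vocabulary (k={vocab.k}, g={vocab.g})"
        )
    values = np.array([float(table.counts.get(p, 0)) for p in vocab.patterns])
    if normalization == "frequency" and table.window_total > 0:
        values /= table.window_total
    return FeatureVector(values=values, vocabulary=vocab, normalization=normalization)


def feature_matrix(
    rseqs: list[ReducedSequence],
    k: int,
    g: int,
    mode: str = "observed",
    normalization: str = "counts",
    alphabet: tuple[str, ...] = (),
    counter=gapped_counts_via_trie,
):
    """Count every sequence, build one vocabulary, and stack the vectors.

    Returns ``(matrix, vocabulary)`` with one row per sequence.  Logs the
    observed-vs-full dimension reduction at INFO.
    """
    tables = [counter(rs, k, g) for rs in rseqs]
    if not alphabet and rseqs:
        alphabet = tuple(rseqs[0].alphabet)
    vocab = build_vocabulary(tables, mode=mode, alphabet=alphabet, k=k, g=g)
    if alphabet:
        full = full_dimension(len(alphabet), k, g)
        pct = 100.0 * (1 - len(vocab) / full) if full else 0.0
        logger.info(
            "vocabulary: %d patterns (%s mode); full space %d; reduced by %.2f%%",
            len(vocab), mode, full, pct,
        )
    X = np.vstack([vectorize(t, vocab, normalization).values for t in tables]) \
        if tables else np.empty((0, len(vocab)))
    return X, vocab
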