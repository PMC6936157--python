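"""Reduced amino-acid alphabets.

Maps raw 20-letter protein sequences onto a small alphabet of
physicochemical classes.  The default scheme partitions the standard
amino acids into six classes:

========  ======  =======================
class     symbol  residues
========  ======  =======================
hydrophilic  L    R, D, E, N, Q, K, H
hydrophobic  B    L, I, V, A, M, F
neutral      W    S, T, Y, W
proline      P    P
glycine      G    G
cysteine     C    C
========  ======  =======================

Class symbols deliberately reuse amino-acid letters, so raw and reduced
sequences are kept as distinct types (:class:`ReducedSequence` wraps the
latter) and reduction is only ever applied to raw residue strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "STANDARD_AA",
    "NONSTANDARD_AA",
    "SKIP_SYMBOL",
    "ReductionScheme",
    "ReducedSequence",
    "DEFAULT_SCHEME",
    "reduce_sequence",
    "validate_scheme",
    "load_scheme",
]

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/non-standard codes that may appear in real FASTA records.
NONSTANDARD_AA = "XBZUOJ"

#: Internal marker substituted for a non-standard residue under the
#: ``skip`` policy; any window containing it is excluded from counting.
SKIP_SYMBOL = "!"


@dataclass(frozen=True)
class ReductionScheme:
    """A total map from the 20 standard amino acids to class symbols.

    Parameters
    ----------
    name
        Identifier for the scheme.
    mapping
        Residue letter -> single class symbol, defined for exactly the
        20 standard amino acids.
    class_alphabet
        Ordered distinct class symbols (size ``t``).
    gap_symbol
        Character used for gap (wildcard) positions in gapped patterns;
        must not collide with any class symbol.
    """

    name: str
    mapping: dict[str, str] = field(hash=False)
    class_alphabet: tuple[str, ...]
    gap_symbol: str = "_"

    @property
    def t(self) -> int:
        """Number of classes (reduced alphabet size)."""
        return len(self.class_alphabet)

    def classes_of(self, symbol: str) -> tuple[str, ...]:
        """Residues mapping to ``symbol``."""
        return tuple(r for r, c in self.mapping.items() if c == symbol)


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence over a reduced class alphabet.

    ``symbols`` may contain :data:`SKIP_SYMBOL` markers (under the
    ``skip`` unknown-residue policy); counting operations exclude any
    window touching a marker.
    """

    symbols: str
    source_id: str = ""
    alphabet: tuple[str, ...] = ()
    gap_symbol: str = "_"

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def length(self) -> int:
        return len(self.symbols)


def _default_mapping() -> dict[str, str]:
    groups = {
        "L": "RDENQKH",
        "B": "LIVAMF",
        "W": "STYW",
        "P": "P",
        "G": "G",
        "C": "C",
    }
    return {res: cls for cls, residues in groups.items() for res in residues}


#: Six-class physicochemical reduction (hydrophilic / hydrophobic /
#: neutral / proline / glycine / cysteine).
DEFAULT_SCHEME = ReductionScheme(
    name="physchem6",
    mapping=_default_mapping(),
    class_alphabet=("L", "B", "W", "P", "G", "C"),
)


def validate_scheme(scheme: ReductionScheme) -> tuple[bool, list[str]]:
    """Check all :class:`ReductionScheme` invariants.

    Returns ``(ok, diagnostics)``; diagnostics name every violation
    (unmapped residues, duplicate class symbols, images outside the
    declared alphabet, gap-symbol collisions).
    """
    diags: list[str] = []
    mapped = set(scheme.mapping)
    standard = set(STANDARD_AA)
    for res in sorted(standard - mapped):
        diags.append(f"{res} unmapped")
    for res in sorted(mapped - standard):
        diags.append(f"{res} is not a standard amino acid")
    if len(set(scheme.class_alphabet)) != len(scheme.class_alphabet):
        diags.append("duplicate symbols in class_alphabet")
    for sym in scheme.class_alphabet:
        if len(sym) != 1:
            diags.append(f"class symbol {sym!r} is not a single character")
    alpha = set(scheme.class_alphabet)
    for res, sym in sorted(scheme.mapping.items()):
        if sym not in alpha:
            diags.append(f"{res} maps to {sym!r}, not in class_alphabet")
    if len(scheme.gap_symbol) != 1 or scheme.gap_symbol in alpha:
        diags.append(f"gap symbol {scheme.gap_symbol!r} collides with class alphabet")
    used = set(scheme.mapping.values())
    for sym in sorted(alpha - used):
        diags.append(f"class {sym} has no residues")
    return (not diags, diags)


def reduce_sequence(
    seq: str,
    scheme: ReductionScheme = DEFAULT_SCHEME,
    unknown_policy: str = "skip",
    source_id: str = "",
    extra_symbol: str = "X",
) -> ReducedSequence:
    """Reduce a raw amino-acid string onto the class alphabet.

    Non-standard residues (X, B, Z, U, O, J, ...) are handled per
    ``unknown_policy``:

    ``error``
        raise :class:`ValueError` naming the residue and its position;
    ``skip``
        mark the position so no k-mer window containing it is counted
        (the alphabet stays at exactly ``t`` symbols);
    ``extra_class``
        map every non-standard residue to one additional symbol
        (``extra_symbol``), growing the alphabet to ``t + 1``.
    """
    if unknown_policy not in ("error", "skip", "extra_class"):
        raise ValueError(f"unknown_policy must be error|skip|extra_class, got {unknown_policy!r}")
    alphabet = tuple(scheme.class_alphabet)
    if unknown_policy == "extra_class":
        if extra_symbol in alphabet or extra_symbol == scheme.gap_symbol:
            raise ValueError(f"extra symbol {extra_symbol!r} collides with the scheme")
        alphabet = alphabet + (extra_symbol,)
    out: list[str] = []
    for pos, res in enumerate(seq):
        sym = scheme.mapping.get(res)
        if sym is None:
            if unknown_policy == "error":
                raise ValueError(f"non-standard residue {res!r} at position {pos}")
            sym = SKIP_SYMBOL if unknown_policy == "skip" else extra_symbol
        out.append(sym)
    return ReducedSequence(
        symbols="".join(out),
        source_id=source_id,
        alphabet=alphabet,
        gap_symbol=scheme.gap_symbol,
    )


def load_scheme(path, name: str | None = None, gap_symbol: str = "_") -> ReductionScheme:
    """Read a scheme file: one line per class, ``<symbol><TAB><res,res,...>``.

    Blank lines and ``#`` comments are ignored.  The class alphabet
    order follows file order.  The result is validated.
    """
    mapping: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                sym, residues = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected '<symbol><TAB><residues>'") from None
            sym = sym.strip()
            if sym in order:
                raise ValueError(f"{path}:{lineno}: duplicate class symbol {sym!r}")
            order.append(sym)
            for res in residues.split(","):
                res = res.strip().upper()
                if res in mapping:
                    raise ValueError(f"{path}:{lineno}: residue {res} assigned twice")
                mapping[res] = sym
    scheme = ReductionScheme(
        name=name or str(path),
        mapping=mapping,
        class_alphabet=tuple(order),
        gap_symbol=gap_symbol,
    )
    ok, diags = validate_scheme(scheme)
    if not ok:
        raise ValueError(f"invalid scheme {path}: " + "; ".join(diags))
    return scheme
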