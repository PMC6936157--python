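"""Spaced dipeptide ("XDY") composition.

An ordered residue pair (X, Y) separated by exactly ``d`` arbitrary
residues, counted over the raw 20-letter alphabet.  ``d = 0`` is the
classical dipeptide composition.  The vector always has 400 cells,
indexed X-major in alphabetical order (AA, AC, AD, ..., YY).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import STANDARD_AA

__all__ = ["SpacedDipeptideVector", "spaced_dipeptide_vector", "PAIR_LABELS"]

_AA_INDEX = {res: i for i, res in enumerate(STANDARD_AA)}

#: The 400 ordered pair labels, X-major alphabetical.
PAIR_LABELS = tuple(x + y for x in STANDARD_AA for y in STANDARD_AA)


@dataclass
class SpacedDipeptideVector:
    """400-cell count (or frequency) vector for one spacing ``d``.

    For clean input of length ``l`` the counts sum to ``max(0, l-d-1)``.
    """

    values: np.ndarray
    d: int
    normalization: str = "counts"
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def cell(self, x: str, y: str) -> float:
        return float(self.values[_AA_INDEX[x] * 20 + _AA_INDEX[y]])


def spaced_dipeptide_vector(
    seq: str,
    d: int,
    normalization: str = "counts",
    source_id: str = "",
) -> SpacedDipeptideVector:
    """Count residue pairs ``(seq[i], seq[i+d+1])`` for every valid ``i``.

    Pairs touching a non-standard residue are skipped.  A spacing too
    large for the sequence yields the all-zero vector; a negative ``d``
    is rejected.
    """
    if d < 0:
        raise ValueError(f"spacing d must be >= 0, got {d}")
    if normalization not in ("counts", "frequency"):
        raise ValueError(f"normalization must be counts|frequency, got {normalization!r}")
    values = np.zeros(400)
    n = 0
    for i in range(len(seq) - d - 1):
        x, y = seq[i], seq[i + d + 1]
        ix, iy = _AA_INDEX.get(x), _AA_INDEX.get(y)
        if ix is None or iy is None:
            continue
        values[ix * 20 + iy] += 1
        n += 1
    if normalization == "frequency" and n > 0:
        values /= n
    return SpacedDipeptideVector(values=values, d=d, normalization=normalization,
                                 source_id=source_id)
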