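"""The 21-symbol encoding alphabet.

Windows are encoded over the 20 standard amino acids (alphabetical
one-letter codes) plus a 21st "null" symbol.  The null symbol covers two
cases that the encoders treat identically: window positions that fall
beyond a protein terminus, and non-standard residue codes (X, U, B, Z,
O, J) that occur in real sequence records.  Non-standard residues are
accepted in sequences but are never Ser/Thr candidate sites.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol used for out-of-terminus window positions and non-standard residues.
NULL = "-"

#: Full 21-symbol ordering used by every encoder and profile: A..Y then null.
ALPHABET: tuple[str, ...] = tuple(AMINO_ACIDS) + (NULL,)

N_SYMBOLS = len(ALPHABET)  # 21

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def symbol_index(symbol: str) -> int:
    """Index of ``symbol`` in the 21-letter alphabet.

    Anything that is not one of the 20 standard amino acids (the null
    marker, X, U, ...) maps to the shared null bin, index 20.
    """
    return _INDEX.get(symbol, N_SYMBOLS - 1)


def is_standard(symbol: str) -> bool:
    return symbol in _INDEX
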