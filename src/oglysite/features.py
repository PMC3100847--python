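"""Window encodings for SVM input.

Three encodings of a length-``Ws`` window:

* **sparse** — each of the ``Ws - 1`` non-center positions is a 21-bit
  one-hot block (20 amino acids + null), ordered left to right; the
  center Ser/Thr is appended as 2 one-hot bits [S, T].  Total length
  ``21*(Ws-1) + 2``; every vector has exactly ``Ws`` set bits.
* **composition** — the 21-dim frequency vector of window symbols
  (center included, null padding counted), which sums to 1 and is
  therefore comparable across window sizes.
* **ica** — the ``Ws = 7`` variant used for component analysis: the six
  non-center positions sparse-coded into a 126-dim binary vector, the
  center omitted entirely so that Ser- and Thr-centered windows with
  identical flanks encode identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabet import ALPHABET, N_SYMBOLS, NULL, symbol_index
from .exceptions import ValidationError
from .io import GlycoProteinRecord
from .sites import SequenceWindow, excise_window

SPARSE = "sparse"
COMPOSITION = "composition"
ENCODINGS = (SPARSE, COMPOSITION)

ICA_WS = 7
ICA_DIM = N_SYMBOLS * (ICA_WS - 1)  # 126


def sparse_dim(ws: int) -> int:
    """Length of the sparse encoding: 21·(Ws−1) + 2."""
    return N_SYMBOLS * (ws - 1) + 2


@dataclass
class WindowFeatures:
    encoding: str
    vector: np.ndarray
    ws: int


def encode_sparse(window: SequenceWindow) -> WindowFeatures:
    """One-hot encode a window; blocks left to right, center as 2 tail bits."""
    if window.center_residue not in "ST":
        raise ValidationError(f"center residue {window.center_residue!r} not Ser/Thr")
    ws = window.ws
    vec = np.zeros(sparse_dim(ws), dtype=np.float64)
    center = (ws - 1) // 2
    block = 0
    for i, sym in enumerate(window.symbols):
        if i == center:
            continue
        vec[block * N_SYMBOLS + symbol_index(sym)] = 1.0
        block += 1
    base = N_SYMBOLS * (ws - 1)
    vec[base + (0 if window.center_residue == "S" else 1)] = 1.0
    return WindowFeatures(SPARSE, vec, ws)


def decode_sparse(vector: np.ndarray, ws: int) -> SequenceWindow:
    """Invert :func:`encode_sparse` (positions/ids are not recoverable;
    the decoded window carries center_position 0)."""
    if vector.shape[0] != sparse_dim(ws):
        raise ValidationError(
            f"vector length {vector.shape[0]} does not match sparse dim {sparse_dim(ws)}"
        )
    symbols: list[str] = []
    for b in range(ws - 1):
        block = vector[b * N_SYMBOLS : (b + 1) * N_SYMBOLS]
        symbols.append(ALPHABET[int(np.argmax(block))])
    center_bits = vector[N_SYMBOLS * (ws - 1) :]
    center = "S" if center_bits[0] >= center_bits[1] else "T"
    mid = (ws - 1) // 2
    symbols.insert(mid, center)
    return SequenceWindow(0, center, ws, symbols)


def encode_composition(window: SequenceWindow) -> WindowFeatures:
    """21-dim symbol frequency over all window symbols, center included."""
    vec = np.zeros(N_SYMBOLS, dtype=np.float64)
    for sym in window.symbols:
        vec[symbol_index(sym)] += 1.0
    vec /= window.ws
    return WindowFeatures(COMPOSITION, vec, window.ws)


def encode_ica_window(window: SequenceWindow) -> np.ndarray:
    """126-dim sparse coding of the six flank positions of a Ws=7 window."""
    if window.ws != ICA_WS:
        raise ValidationError(f"ICA encoding requires Ws={ICA_WS}, got {window.ws}")
    vec = np.zeros(ICA_DIM, dtype=np.float64)
    center = (ICA_WS - 1) // 2
    block = 0
    for i, sym in enumerate(window.symbols):
        if i == center:
            continue
        vec[block * N_SYMBOLS + symbol_index(sym)] = 1.0
        block += 1
    return vec


def encode_window(window: SequenceWindow, encoding: str) -> np.ndarray:
    if encoding == SPARSE:
        return encode_sparse(window).vector
    if encoding == COMPOSITION:
        return encode_composition(window).vector
    raise ValidationError(f"unknown encoding {encoding!r}")


def build_design_matrix(
    labeled_sites: Sequence[tuple[GlycoProteinRecord, int, int]],
    ws: int,
    encoding: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and ±1 label vector for ``(record, position, label)`` triples.

    Rows align with the input order; labels must be +1 (positive site)
    or −1 (negative site).  An empty input yields a 0-row matrix of the
    correct width.
    """
    if encoding not in ENCODINGS:
        raise ValidationError(f"unknown encoding {encoding!r}")
    width = sparse_dim(ws) if encoding == SPARSE else N_SYMBOLS
    X = np.zeros((len(labeled_sites), width), dtype=np.float64)
    y = np.zeros(len(labeled_sites), dtype=np.int64)
    for row, (rec, pos, label) in enumerate(labeled_sites):
        if label not in (1, -1):
            raise ValidationError(f"label must be +1 or -1, got {label}")
        X[row] = encode_window(excise_window(rec, pos, ws), encoding)
        y[row] = label
    return X, y


def ica_design_matrix(
    sites: Sequence[tuple[GlycoProteinRecord, int]]
) -> np.ndarray:
    """n×126 binary matrix of Ws=7 flank encodings for ``(record, position)`` pairs."""
    X = np.zeros((len(sites), ICA_DIM), dtype=np.float64)
    for row, (rec, pos) in enumerate(sites):
        X[row] = encode_ica_window(excise_window(rec, pos, ICA_WS))
    return X


def windows_design_matrix(windows: Iterable[SequenceWindow], encoding: str) -> np.ndarray:
    """Encode pre-excised windows; all must share one window size."""
    windows = list(windows)
    if not windows:
        raise ValidationError("no windows to encode")
    ws = windows[0].ws
    if any(w.ws != ws for w in windows):
        raise ValidationError("mixed window sizes in one design matrix")
    return np.vstack([encode_window(w, encoding) for w in windows])
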