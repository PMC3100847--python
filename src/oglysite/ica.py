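"""PCA→ICA decomposition of sparse-coded 7-mer windows.

The six flank positions of each Ws=7 window are sparse-coded into a
126-dim binary vector, reduced to the top 10 principal components, and
unmixed by fixed-point negentropy-maximizing ICA (FastICA, symmetric
decorrelation).  Each independent component is mapped back through the
PCA loadings into the 126-dim input space and reshaped into a
6-position × 21-symbol map; the sign of each component is fixed so that
its largest-magnitude element is positive, and that arg-max
``(symbol, offset)`` names the component.  A component dominated by one
element reveals a position-specific residue preference — e.g. Pro at
−1 next to isolated glycosylation sites — as statistically independent
of the other flank positions.

Strictly, ICA mixing columns are linear directions, not probabilities;
the decoded maps are therefore presented as signed magnitudes under the
positivity convention rather than as existence ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .alphabet import ALPHABET, N_SYMBOLS
from .exceptions import IcaConvergenceError, ValidationError
from .features import ICA_DIM, ICA_WS, ica_design_matrix
from .io import GlycoProteinRecord

N_COMPONENTS = 10

#: A decoded component whose largest element carries more than this
#: fraction of its L2 norm is called dominated by a single
#: (symbol, position) element.
DOMINANT_ELEMENT_THRESHOLD = 0.9

#: Relative flank positions of a Ws=7 window, center excluded.
FLANK_OFFSETS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)


@dataclass
class IcaDecomposition:
    site_class: str
    components: np.ndarray  # 126 x n_components, input-space directions
    decoded_maps: list[np.ndarray]  # per component: 6 positions x 21 symbols
    top_elements: list[tuple[str, int]]  # per component: (symbol, offset)
    sources: np.ndarray  # n x n_components
    explained_variance: np.ndarray  # PCA eigenvalues, length n_components

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def pca_reduce(
    X: np.ndarray, k: int = N_COMPONENTS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project ``X`` (mean-centered internally) onto its top ``k`` PCs.

    Returns ``(scores n×k, loadings d×k, explained_variance k)`` with
    orthonormal loadings and non-increasing explained variance.
    """
    n = X.shape[0]
    if n <= k:
        raise ValidationError(f"need more than {k} samples for {k} components, got {n}")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValidationError("degenerate input: all rows identical (zero variance)")
    # full (exact) SVD: deterministic, and cheap at these dimensions
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X.astype(np.float64))
    return scores, pca.components_.T, pca.explained_variance_


def run_ica(
    scores: np.ndarray,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 5e-3,
    fun: str = "cube",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix PCA scores into independent sources.

    Returns ``(unmixing k×k, sources n×k, mixing k×k)``; deterministic
    for a fixed seed.  Raises :class:`IcaConvergenceError` when the
    fixed-point iteration does not converge (e.g. on near-Gaussian
    input, where independent components are not identifiable).

    The default contrast is the kurtosis-based negentropy approximation
    (``cube``), which converges reliably on the strongly non-Gaussian
    scores of sparse-coded windows; ``logcosh`` is available but can
    oscillate indefinitely between symmetric solutions on such data.
    """
    k = scores.shape[1]
    ica = FastICA(
        n_components=k, random_state=seed, max_iter=max_iter, tol=tol,
        whiten="unit-variance", fun=fun,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            sources = ica.fit_transform(scores)
        except ConvergenceWarning:
            raise IcaConvergenceError(max_iter) from None
    unmixing = ica.components_ @ ica.whitening_ if ica.whitening_ is not None else ica.components_
    return unmixing, sources, ica.mixing_


def decompose(
    sites: Sequence[tuple[GlycoProteinRecord, int]] | np.ndarray,
    site_class: str,
    seed: int = 0,
    k: int = N_COMPONENTS,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> IcaDecomposition:
    """Full pipeline: encode (if needed), PCA-reduce, ICA, decode.

    ``sites`` is either ``(record, position)`` pairs or a pre-built
    n×126 binary matrix.  Fixed-point ICA convergence depends on the
    random initialization, so up to ``n_restarts`` deterministic
    restarts are attempted before giving up; near-Gaussian input fails
    every restart and raises :class:`IcaConvergenceError`.
    """
    if isinstance(sites, np.ndarray):
        X = sites
        if X.shape[1] != ICA_DIM:
            raise ValidationError(f"expected {ICA_DIM} columns, got {X.shape[1]}")
    else:
        X = ica_design_matrix(list(sites))
    scores, loadings, explained = pca_reduce(X, k=k)
    last_err: IcaConvergenceError | None = None
    for restart in range(n_restarts):
        try:
            _, sources, mixing = run_ica(
                scores, seed=(seed + 1000 * restart) % 2**31, max_iter=max_iter
            )
            break
        except IcaConvergenceError as err:
            last_err = err
    else:
        raise last_err
    components = loadings @ mixing  # 126 x k, back in input space
    decomp = IcaDecomposition(site_class, components, [], [], sources, explained)
    decode_components(decomp)
    return decomp


def decode_components(decomp: IcaDecomposition) -> IcaDecomposition:
    """Reshape each component into a 6×21 map, fix signs, find top elements.

    Sign convention: each component (and its source column) is flipped so
    that its largest-magnitude map element is positive.  Fills
    ``decoded_maps`` and ``top_elements`` in place and returns the
    decomposition.
    """
    decomp.decoded_maps = []
    decomp.top_elements = []
    for j in range(decomp.n_components):
        comp = decomp.components[:, j]
        flat_idx = int(np.argmax(np.abs(comp)))
        if comp[flat_idx] < 0:
            comp = -comp
            decomp.components[:, j] = comp
            decomp.sources[:, j] = -decomp.sources[:, j]
        cmap = comp.reshape(len(FLANK_OFFSETS), N_SYMBOLS)
        decomp.decoded_maps.append(cmap)
        pos_i, sym_i = np.unravel_index(int(np.argmax(cmap)), cmap.shape)
        decomp.top_elements.append((ALPHABET[sym_i], FLANK_OFFSETS[pos_i]))
    return decomp


def dominance_ratios(decomp: IcaDecomposition) -> np.ndarray:
    """Per component: |largest element| / L2 norm of the component.

    High values indicate a single dominant (symbol, position) element;
    decompositions of composition-biased (motif-free) windows stay low.
    """
    out = np.zeros(decomp.n_components)
    for j in range(decomp.n_components):
        comp = decomp.components[:, j]
        norm = np.linalg.norm(comp)
        out[j] = np.max(np.abs(comp)) / norm if norm > 0 else 0.0
    return out


def write_decomposition(decomp: IcaDecomposition, outdir: str | Path,
                        header_comment: str | None = None) -> None:
    """Write one 6×21 map per component plus a top-element summary."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for j, cmap in enumerate(decomp.decoded_maps):
        df = pd.DataFrame(cmap, index=list(FLANK_OFFSETS), columns=list(ALPHABET))
        with open(outdir / f"component_{j:02d}.tsv", "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index_label="offset")
    summary = pd.DataFrame(
        {
            "component": range(decomp.n_components),
            "top_symbol": [s for s, _ in decomp.top_elements],
            "top_offset": [o for _, o in decomp.top_elements],
            "dominance": dominance_ratios(decomp),
        }
    )
    with open(outdir / "components_summary.tsv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        summary.to_csv(fh, sep="\t", index=False)
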