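"""Position-specific amino-acid existence-ratio profiles.

For a class of sites (clustered positives, isolated positives, or
negatives) the *existence ratio* of amino acid ``a`` at relative
position ``p`` is the fraction of sites whose window carries ``a`` at
offset ``p`` from the center.  Because the 21 symbols (20 amino acids +
null for overrun termini) partition every window position, each column
of the 21×Ws ratio matrix sums to 1.  The default window of 31 covers
offsets −15..+15, wide enough to show flank signals such as elevated
Pro at −1/+3 or Val at −3/+8 next to isolated glycosylation sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, N_SYMBOLS, symbol_index
from .exceptions import ValidationError
from .io import GlycoProteinRecord
from .sites import excise_window

DEFAULT_WS = 31


@dataclass
class PositionProfile:
    site_class: str  # "clustered" | "isolated" | "negative" (free-form allowed)
    ws: int
    ratios: np.ndarray  # 21 symbols x Ws positions
    n_sites: int

    @property
    def offsets(self) -> list[int]:
        h = (self.ws - 1) // 2
        return list(range(-h, h + 1))

    def ratio(self, symbol: str, offset: int) -> float:
        h = (self.ws - 1) // 2
        if not -h <= offset <= h:
            raise ValidationError(f"offset {offset} outside ±{h} for Ws={self.ws}")
        return float(self.ratios[symbol_index(symbol), offset + h])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratios, index=list(ALPHABET), columns=self.offsets)

    def write(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="symbol")


def compute_profile(
    sites: Sequence[tuple[GlycoProteinRecord, int]],
    site_class: str,
    ws: int = DEFAULT_WS,
) -> PositionProfile:
    """Existence-ratio matrix over the windows of one site class.

    ``ratios[k, p]`` = (number of sites with symbol ``k`` at relative
    position ``p``) / (number of sites); null is counted where windows
    overrun the protein termini.
    """
    if not sites:
        raise ValidationError("cannot compute a profile from zero sites")
    if ws < 3 or ws % 2 == 0:
        raise ValidationError(f"window size must be odd and >= 3, got {ws}")
    counts = np.zeros((N_SYMBOLS, ws), dtype=np.float64)
    for rec, pos in sites:
        win = excise_window(rec, pos, ws)
        for col, sym in enumerate(win.symbols):
            counts[symbol_index(sym), col] += 1.0
    return PositionProfile(site_class, ws, counts / len(sites), len(sites))


def profile_contrast(a: PositionProfile, b: PositionProfile) -> np.ndarray:
    """Elementwise difference ``a − b``; flags positions where class ``a``
    deviates from class ``b`` (typically the negatives)."""
    if a.ws != b.ws:
        raise ValidationError(f"window size mismatch: {a.ws} vs {b.ws}")
    return a.ratios - b.ratios
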