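"""Shared test utilities: record builders and independent oracles."""

from __future__ import annotations

import numpy as np

from oglysite.alphabet import AMINO_ACIDS
from oglysite.io import GlycoProteinRecord, SiteAnnotation


def mkrec(
    seq: str,
    positives: tuple[int, ...] = (),
    protein_id: str = "P1",
    glycan_type: str = "GalNAc",
) -> GlycoProteinRecord:
    """Build a record with the given 1-based positive positions."""
    sites = [
        SiteAnnotation(p, seq[p - 1], glycan_type, "positive") for p in positives
    ]
    return GlycoProteinRecord(protein_id, seq, sites)


def random_annotated_records(
    seed: int,
    n_proteins: int = 30,
    length: int = 200,
    positives_per_protein: int = 8,
) -> list[GlycoProteinRecord]:
    """Uniform-composition records with uniformly chosen positive Ser/Thr."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        st = [p + 1 for p, c in enumerate(seq) if c in "ST"]
        if not st:
            seq = seq[:-1] + "S"
            st = [length]
        k = min(positives_per_protein, max(1, len(st) // 3))
        pos = sorted(int(p) for p in rng.choice(st, size=k, replace=False))
        recs.append(mkrec(seq, tuple(pos), protein_id=f"R{i:03d}"))
    return recs


def brute_force_site_types(seq: str, positives: set[int]) -> dict[int, str]:
    """O(n^2) nearest-Ser/Thr-neighbor typing oracle.

    Walks outward residue by residue from each positive site instead of
    using a sorted index, so it shares no code path with the package.
    """
    out = {}
    n = len(seq)
    for p in positives:
        left = next((q for q in range(p - 1, 0, -1) if seq[q - 1] in "ST"), None)
        right = next((q for q in range(p + 1, n + 1) if seq[q - 1] in "ST"), None)
        neighbors = [q for q in (left, right) if q is not None]
        clustered = any(q in positives for q in neighbors)
        out[p] = "clustered" if clustered else "isolated"
    return out
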