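"""Clustered/isolated typing of glycosylation sites and window excision.

A glycosylated (positive) Ser/Thr is *clustered* when the nearest Ser or
Thr along the chain on at least one side — at any distance, skipping
every non-Ser/Thr residue — is itself glycosylated; otherwise it is
*isolated*.  The rule is a property of the Ser/Thr lattice of the
protein, not of a fixed-width window: a glycosylated Thr in a
Thr-Gly-Asp-Ser repeat whose Ser neighbors are unmodified is isolated no
matter how dense the repeat is, whereas two adjacent glycosylated
residues in a mucin run are mutually clustered.

``require_both_sides=True`` switches to the stricter AND reading (both
nearest Ser/Thr neighbors glycosylated); the default OR reading is the
one consistent with calling runs of adjacent positives "clustered".
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alphabet import NULL
from .exceptions import ValidationError
from .io import GlycoProteinRecord

CLUSTERED = "clustered"
ISOLATED = "isolated"
SITE_TYPES = (CLUSTERED, ISOLATED)


@dataclass
class SiteTyping:
    protein_id: str
    position: int
    residue: str
    site_type: str  # "clustered" or "isolated"


@dataclass
class SequenceWindow:
    """A fixed odd-length subsequence centered on a Ser/Thr site.

    ``symbols`` has exactly ``ws`` entries; positions beyond the protein
    termini carry the null symbol, so nulls can only form a contiguous
    prefix and/or suffix.
    """

    center_position: int
    center_residue: str
    ws: int
    symbols: list[str]

    @property
    def offsets(self) -> range:
        h = (self.ws - 1) // 2
        return range(-h, h + 1)


def classify_sites(
    record: GlycoProteinRecord, require_both_sides: bool = False
) -> list[SiteTyping]:
    """Type every positive site of ``record`` as clustered or isolated.

    A positive with no Ser/Thr neighbor on one side is judged on the
    existing side alone; a positive that is the only Ser/Thr in the
    protein is isolated.
    """
    st = record.ser_thr_positions()
    positives = set(record.positive_positions())
    out: list[SiteTyping] = []
    for pos in sorted(positives):
        i = bisect_left(st, pos)
        if i >= len(st) or st[i] != pos:
            raise ValidationError(
                f"{record.protein_id}: positive site {pos} is not a Ser/Thr position"
            )
        neighbors = []
        if i > 0:
            neighbors.append(st[i - 1])
        if i + 1 < len(st):
            neighbors.append(st[i + 1])
        if not neighbors:
            clustered = False
        elif require_both_sides:
            clustered = all(n in positives for n in neighbors)
        else:
            clustered = any(n in positives for n in neighbors)
        out.append(
            SiteTyping(
                record.protein_id,
                pos,
                record.residue_at(pos),
                CLUSTERED if clustered else ISOLATED,
            )
        )
    return out


def excise_window(record: GlycoProteinRecord, position: int, ws: int) -> SequenceWindow:
    """Cut the length-``ws`` window centered at ``position`` (1-based).

    ``symbols[i]`` is the residue at ``position + (i - (ws-1)/2)`` or the
    null symbol where that index falls outside the sequence.
    """
    if ws < 3 or ws % 2 == 0:
        raise ValidationError(f"window size must be odd and >= 3, got {ws}")
    center = record.residue_at(position)
    if center not in "ST":
        raise ValidationError(
            f"{record.protein_id}: window center {position} is {center}, not Ser/Thr"
        )
    h = (ws - 1) // 2
    n = len(record.sequence)
    symbols = [
        record.sequence[p - 1] if 1 <= p <= n else NULL
        for p in range(position - h, position + h + 1)
    ]
    return SequenceWindow(position, center, ws, symbols)


def type_counts(
    records: Iterable[GlycoProteinRecord], require_both_sides: bool = False
) -> tuple[int, int, int]:
    """Dataset totals ``(n_clustered, n_isolated, n_negative)``.

    Negatives are all unannotated Ser/Thr; clustered + isolated equals
    the number of positive sites.
    """
    n_clustered = n_isolated = n_negative = 0
    for rec in records:
        typings = classify_sites(rec, require_both_sides=require_both_sides)
        n_clustered += sum(1 for t in typings if t.site_type == CLUSTERED)
        n_isolated += sum(1 for t in typings if t.site_type == ISOLATED)
        n_st = sum(1 for c in rec.sequence if c in "ST")
        n_negative += n_st - len(typings)
    return n_clustered, n_isolated, n_negative


def typed_positive_sites(
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    require_both_sides: bool = False,
) -> list[tuple[GlycoProteinRecord, int]]:
    """All ``(record, position)`` positives of one type, in record order."""
    if site_type not in SITE_TYPES:
        raise ValidationError(f"unknown site type {site_type!r}")
    out = []
    for rec in records:
        for t in classify_sites(rec, require_both_sides=require_both_sides):
            if t.site_type == site_type:
                out.append((rec, t.position))
    return out


def negative_sites(
    records: Sequence[GlycoProteinRecord],
) -> list[tuple[GlycoProteinRecord, int]]:
    """All unannotated Ser/Thr ``(record, position)`` pairs."""
    out = []
    for rec in records:
        from .io import enumerate_ser_thr_sites

        for pos, _res, status in enumerate_ser_thr_sites(rec):
            if status == "negative":
                out.append((rec, pos))
    return out
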