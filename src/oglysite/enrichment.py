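"""Occurrence statistics of glycosylation sites in disordered regions.

Given per-residue DOMAIN/ID segmentations, this module counts how many
glycosylation sites, Ser/Thr residues, and residues overall fall inside
intrinsically disordered (ID) regions, broken down by clustered/isolated
site type or by glycan type, and derives the site-density ratios
(sites per ID residue vs. per residue overall, and per ID-Ser/Thr vs.
per Ser/Thr overall) whose fold changes quantify ID enrichment.

Reporting precision follows the field convention for such tables:
percentages to one decimal, densities on values near 1% to two
decimals, fold changes to one decimal — all rounded half-up.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ValidationError
from .io import GLYCAN_TYPES, GlycoProteinRecord, enumerate_ser_thr_sites
from .sites import classify_sites

# Row order of the site-type breakdown table.
ROW_CLUSTERED = "clustered"
ROW_ISOLATED = "isolated"
ROW_TOTAL = "total"
ROW_SER_THR = "ser_thr"
ROW_RESIDUES = "residues"
TABLE1_ROWS = (ROW_CLUSTERED, ROW_ISOLATED, ROW_TOTAL, ROW_SER_THR, ROW_RESIDUES)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(n_in_id: int, n_total: int, ndigits: int = 1) -> Optional[float]:
    """``100·n_in_id/n_total`` rounded half-up; None for a zero denominator."""
    if n_total == 0:
        return None
    return round_half_up(100.0 * n_in_id / n_total, ndigits)


@dataclass
class EnrichmentTable:
    """Counts of items inside ID regions per category.

    ``counts`` maps a category name to ``(n_in_id, n_total)``.  For the
    site-type breakdown the categories are clustered/isolated/total
    glycosylation sites, all Ser/Thr residues, and all residues.
    """

    counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (n_in, n_tot) in self.counts.items():
            if n_in > n_tot:
                raise ValidationError(
                    f"{name}: {n_in} in ID exceeds total {n_tot}"
                )
        c, i, t = (self.counts.get(r) for r in (ROW_CLUSTERED, ROW_ISOLATED, ROW_TOTAL))
        if c is not None and i is not None and t is not None:
            if c[0] + i[0] != t[0] or c[1] + i[1] != t[1]:
                raise ValidationError(
                    "clustered + isolated counts do not sum to the total row"
                )

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int]]) -> "EnrichmentTable":
        return cls(dict(counts))

    def n_in_id(self, row: str) -> int:
        return self.counts[row][0]

    def n_total(self, row: str) -> int:
        return self.counts[row][1]

    def percent_in_id(self, row: str) -> Optional[float]:
        return percent(*self.counts[row])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, n_in, n_tot, percent(n_in, n_tot))
            for name, (n_in, n_tot) in self.counts.items()
        ]
        return pd.DataFrame(
            rows, columns=["category", "n_in_ID", "n_total", "percent_in_ID"]
        )


def site_region_lookup(record: GlycoProteinRecord, position: int) -> str:
    """Class ("DOMAIN" or "ID") of the segment containing a 1-based position."""
    if not record.regions:
        raise ValidationError(f"{record.protein_id}: no region segmentation attached")
    starts = [seg.start for seg in record.regions]
    i = bisect_right(starts, position) - 1
    if i < 0 or not record.regions[i].start <= position <= record.regions[i].end:
        raise ValidationError(
            f"{record.protein_id}: position {position} not covered by any segment"
        )
    return record.regions[i].klass


def _require_regions(records: Sequence[GlycoProteinRecord]) -> None:
    missing = [r.protein_id for r in records if not r.regions]
    if missing:
        raise ValidationError(
            f"records without region segmentation: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )


def build_enrichment_table(
    records: Sequence[GlycoProteinRecord],
    glycan_filter: Optional[str] = "GalNAc",
    with_typing: bool = True,
    require_both_sides: bool = False,
) -> EnrichmentTable:
    """Site-type breakdown of ID occupancy, computed by exhaustive scan.

    Counts positive sites (optionally restricted to one glycan type),
    split into clustered/isolated when ``with_typing``, alongside the
    Ser/Thr and all-residue denominators of the same protein set.
    """
    _require_regions(records)
    if glycan_filter is not None and glycan_filter not in GLYCAN_TYPES:
        raise ValidationError(f"unknown glycan type {glycan_filter!r}")
    n_res = n_res_id = n_st = n_st_id = 0
    n_pos = {ROW_CLUSTERED: [0, 0], ROW_ISOLATED: [0, 0], ROW_TOTAL: [0, 0]}
    for rec in records:
        id_ranges = [(s.start, s.end) for s in rec.regions if s.klass == "ID"]
        n_res += len(rec.sequence)
        n_res_id += sum(e - s + 1 for s, e in id_ranges)
        for pos, _res, _status in enumerate_ser_thr_sites(rec):
            n_st += 1
            if site_region_lookup(rec, pos) == "ID":
                n_st_id += 1
        typing = {
            t.position: t.site_type
            for t in classify_sites(rec, require_both_sides=require_both_sides)
        }
        for site in rec.sites:
            if site.status != "positive":
                continue
            if glycan_filter is not None and site.glycan_type != glycan_filter:
                continue
            in_id = site_region_lookup(rec, site.position) == "ID"
            n_pos[ROW_TOTAL][1] += 1
            n_pos[ROW_TOTAL][0] += in_id
            if with_typing:
                row = typing[site.position]
                n_pos[row][1] += 1
                n_pos[row][0] += in_id
    counts: dict[str, tuple[int, int]] = {}
    if with_typing:
        counts[ROW_CLUSTERED] = tuple(n_pos[ROW_CLUSTERED])
        counts[ROW_ISOLATED] = tuple(n_pos[ROW_ISOLATED])
    counts[ROW_TOTAL] = tuple(n_pos[ROW_TOTAL])
    counts[ROW_SER_THR] = (n_st_id, n_st)
    counts[ROW_RESIDUES] = (n_res_id, n_res)
    return EnrichmentTable(counts)


def build_glycan_enrichment_table(
    records: Sequence[GlycoProteinRecord]
) -> pd.DataFrame:
    """Per-glycan-type ID occupancy of O-linked sites and of Ser/Thr.

    One row per glycan type present: protein count, O-linked sites in
    ID / total, Ser/Thr in ID / total over the proteins carrying that
    type, and both percentages.
    """
    _require_regions(records)
    rows = []
    for gt in GLYCAN_TYPES:
        carriers = [
            r for r in records
            if any(s.status == "positive" and s.glycan_type == gt for s in r.sites)
        ]
        if not carriers:
            continue
        o_in = o_tot = st_in = st_tot = 0
        for rec in carriers:
            for site in rec.sites:
                if site.status == "positive" and site.glycan_type == gt:
                    o_tot += 1
                    o_in += site_region_lookup(rec, site.position) == "ID"
            for pos, _res, _status in enumerate_ser_thr_sites(rec):
                st_tot += 1
                st_in += site_region_lookup(rec, pos) == "ID"
        rows.append(
            {
                "glycan_type": gt,
                "n_proteins": len(carriers),
                "o_sites_in_ID": o_in,
                "st_in_ID": st_in,
                "o_sites_total": o_tot,
                "st_total": st_tot,
                "o_percent_in_ID": percent(o_in, o_tot),
                "st_percent_in_ID": percent(st_in, st_tot),
            }
        )
    return pd.DataFrame(rows)


def glycan_table_from_counts(
    counts: Mapping[str, tuple[int, int, int, int, int]]
) -> pd.DataFrame:
    """Same layout as :func:`build_glycan_enrichment_table` but from
    pre-tabulated counts ``(n_proteins, o_in_ID, st_in_ID, o_total, st_total)``."""
    rows = []
    for gt, (n_prot, o_in, st_in, o_tot, st_tot) in counts.items():
        rows.append(
            {
                "glycan_type": gt,
                "n_proteins": n_prot,
                "o_sites_in_ID": o_in,
                "st_in_ID": st_in,
                "o_sites_total": o_tot,
                "st_total": st_tot,
                "o_percent_in_ID": percent(o_in, o_tot),
                "st_percent_in_ID": percent(st_in, st_tot),
            }
        )
    return pd.DataFrame(rows)


def derived_density_ratios(table: EnrichmentTable) -> dict[str, Optional[float]]:
    """Site densities inside/outside ID regions and their fold changes.

    Returns unrounded values: sites per ID residue, per residue overall,
    per domain residue; the same over Ser/Thr denominators (all as
    percentages); and the two ID-over-overall fold changes.  Ratios with
    a zero denominator are None (undefined), never an exception.
    """
    s_in, s_tot = table.counts[ROW_TOTAL]
    st_in, st_tot = table.counts[ROW_SER_THR]
    r_in, r_tot = table.counts[ROW_RESIDUES]
    s_dom = s_tot - s_in
    st_dom = st_tot - st_in
    r_dom = r_tot - r_in

    def ratio(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den else None

    d = {
        "sites_per_id_residue": ratio(s_in, r_in),
        "sites_per_residue": ratio(s_tot, r_tot),
        "sites_per_domain_residue": ratio(s_dom, r_dom),
        "sites_per_id_st": ratio(s_in, st_in),
        "sites_per_st": ratio(s_tot, st_tot),
        "sites_per_domain_st": ratio(s_dom, st_dom),
    }
    d["fold_id_over_all_residue"] = (
        d["sites_per_id_residue"] / d["sites_per_residue"]
        if d["sites_per_residue"] else None
    )
    d["fold_id_over_all_st"] = (
        d["sites_per_id_st"] / d["sites_per_st"] if d["sites_per_st"] else None
    )
    return d


def format_density_report(densities: Mapping[str, Optional[float]]) -> dict[str, Optional[float]]:
    """Round a density report at printed precision: densities to 2
    decimals except the ID-Ser/Thr density (order 10%, printed to 1),
    folds to 1 decimal."""
    nd = {
        "sites_per_id_residue": 2,
        "sites_per_residue": 2,
        "sites_per_domain_residue": 2,
        "sites_per_id_st": 1,
        "sites_per_st": 2,
        "sites_per_domain_st": 2,
        "fold_id_over_all_residue": 1,
        "fold_id_over_all_st": 1,
    }
    return {
        k: (None if v is None else round_half_up(v, nd.get(k, 2)))
        for k, v in densities.items()
    }


def per_protein_track(
    record: GlycoProteinRecord,
    require_both_sides: bool = False,
    width: int = 60,
) -> str:
    """Plain-text track of a protein's segmentation with sites overlaid.

    One character per residue: ``D`` domain, ``i`` ID, with positive
    sites marked ``C``/``I`` by their clustered/isolated type, plus a
    legend line listing each site.  Works without a segmentation (the
    background is then ``.``).
    """
    n = len(record.sequence)
    if record.regions:
        track = []
        for seg in record.regions:
            track.extend(("D" if seg.klass == "DOMAIN" else "i") * (seg.end - seg.start + 1))
    else:
        track = ["."] * n
    typing = classify_sites(record, require_both_sides=require_both_sides)
    for t in typing:
        track[t.position - 1] = "C" if t.site_type == "clustered" else "I"
    lines = [f">{record.protein_id} length={n}"]
    for i in range(0, n, width):
        lines.append(f"{i + 1:>6} {''.join(track[i : i + width])}")
    for t in typing:
        region = site_region_lookup(record, t.position) if record.regions else "?"
        lines.append(
            f"site {t.residue}{t.position} {t.site_type} {region}"
        )
    return "\n".join(lines)
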