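"""Readers and writers for the package's external representations.

Three plain-text inputs describe a glycoprotein dataset:

* a FASTA file with the protein sequences;
* a tab-separated *site table* (``protein_id  position  residue
  glycan_type  status``) carrying per-site O-glycosylation annotations,
  in the spirit of UniProt ``CARBOHYD`` feature lines;
* a tab-separated *region table* (``protein_id  start  end  klass``)
  giving a binary per-residue segmentation of each protein into
  structural domains (``DOMAIN``) and intrinsically disordered regions
  (``ID``), the output format of disorder-assignment pipelines.

All file coordinates are 1-based inclusive.  Site tables may list only
positives; negatives are then every unannotated Ser/Thr
(:func:`enumerate_ser_thr_sites`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

PathLike = Union[str, Path]

GLYCAN_TYPES: tuple[str, ...] = (
    "GalNAc", "GlcNAc", "Gal", "Xyl", "Fuc", "Glc", "HexNAc", "Hex",
)
STATUSES = ("positive", "negative")
REGION_CLASSES = ("DOMAIN", "ID")

SITE_COLUMNS = ["protein_id", "position", "residue", "glycan_type", "status"]
REGION_COLUMNS = ["protein_id", "start", "end", "klass"]


@dataclass
class SiteAnnotation:
    """One annotated Ser/Thr site (1-based position)."""

    position: int
    residue: str  # "S" or "T"
    glycan_type: str
    status: str  # "positive" or "negative"


@dataclass
class RegionSegment:
    """One ordered/disordered segment, 1-based inclusive coordinates."""

    start: int
    end: int
    klass: str  # "DOMAIN" or "ID"


@dataclass
class GlycoProteinRecord:
    """A protein sequence with its site annotations and optional segmentation."""

    protein_id: str
    sequence: str
    sites: list[SiteAnnotation] = field(default_factory=list)
    regions: Optional[list[RegionSegment]] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: position {position} outside [1, {len(self.sequence)}]"
            )
        return self.sequence[position - 1]

    def positive_positions(self) -> list[int]:
        return sorted(s.position for s in self.sites if s.status == "positive")

    def ser_thr_positions(self) -> list[int]:
        return [i + 1 for i, c in enumerate(self.sequence) if c in "ST"]


def read_fasta(path: PathLike) -> list[GlycoProteinRecord]:
    """Read a FASTA file into sequence-only records.

    The token before the first whitespace of each header becomes the
    protein id; sequences are uppercased.  Duplicate ids and sequence
    data appearing before any header are rejected.
    """
    path = Path(path)
    # Pre-scan for the one malformation Bio.SeqIO silently ignores:
    # sequence data before the first header.  Report its line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break

    records: list[GlycoProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        records.append(GlycoProteinRecord(pid, str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[GlycoProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _by_id(records: Sequence[GlycoProteinRecord]) -> dict[str, GlycoProteinRecord]:
    return {r.protein_id: r for r in records}


def _read_table(path: PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_site_table(
    path: PathLike, records: Sequence[GlycoProteinRecord]
) -> list[GlycoProteinRecord]:
    """Attach site annotations from a tab-separated table to ``records``.

    Rows are schema-checked (residue in {S,T}, known glycan type and
    status) before the sequence cross-check; the residue stated in each
    row must match the sequence at that position.  Returns the same
    record objects with ``sites`` populated.
    """
    path = Path(path)
    index = _by_id(records)
    df = _read_table(path, SITE_COLUMNS)
    seen: set[tuple[str, int]] = set()
    for rec in records:
        rec.sites = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.protein_id
        residue = row.residue
        if residue not in ("S", "T"):
            raise ValidationError(
                f"{path}: row {rownum}: residue {residue!r} is not S or T"
            )
        if row.glycan_type not in GLYCAN_TYPES:
            raise ValidationError(
                f"{path}: row {rownum}: unknown glycan type {row.glycan_type!r} "
                f"(expected one of {GLYCAN_TYPES})"
            )
        if row.status not in STATUSES:
            raise ValidationError(f"{path}: row {rownum}: bad status {row.status!r}")
        try:
            position = int(row.position)
        except ValueError:
            raise FormatError(f"{path}: row {rownum}: non-integer position {row.position!r}")
        if pid not in index:
            raise ValidationError(f"{path}: row {rownum}: unknown protein id {pid!r}")
        rec = index[pid]
        if not 1 <= position <= len(rec.sequence):
            raise ValidationError(
                f"{path}: {pid} position {position} outside [1, {len(rec.sequence)}]"
            )
        actual = rec.sequence[position - 1]
        if actual != residue:
            raise ValidationError(
                f"{path}: {pid} position {position}: table says {residue}, "
                f"sequence has {actual}"
            )
        key = (pid, position)
        if key in seen:
            raise ValidationError(f"{path}: duplicate site ({pid}, {position})")
        seen.add(key)
        rec.sites.append(SiteAnnotation(position, residue, row.glycan_type, row.status))
    for rec in records:
        rec.sites.sort(key=lambda s: s.position)
    return list(records)


def write_site_table(records: Iterable[GlycoProteinRecord], path: PathLike,
                     header_comment: str | None = None) -> None:
    rows = [
        (r.protein_id, s.position, s.residue, s.glycan_type, s.status)
        for r in records
        for s in r.sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    _write_tsv(df, path, header_comment)


def read_region_table(
    path: PathLike, records: Sequence[GlycoProteinRecord]
) -> list[GlycoProteinRecord]:
    """Attach DOMAIN/ID segmentations; segments must tile each sequence.

    Segments are sorted and checked for full, non-overlapping coverage
    of [1, len(sequence)] per protein; any gap or overlap is reported
    with the offending interval.
    """
    path = Path(path)
    index = _by_id(records)
    df = _read_table(path, REGION_COLUMNS)
    per_protein: dict[str, list[RegionSegment]] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.protein_id
        if pid not in index:
            raise ValidationError(f"{path}: row {rownum}: unknown protein id {pid!r}")
        if row.klass not in REGION_CLASSES:
            raise ValidationError(f"{path}: row {rownum}: bad klass {row.klass!r}")
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise FormatError(f"{path}: row {rownum}: non-integer coordinates")
        if start > end:
            raise ValidationError(f"{path}: {pid}: segment ({start},{end}) has start > end")
        per_protein.setdefault(pid, []).append(RegionSegment(start, end, row.klass))

    for pid, segments in per_protein.items():
        rec = index[pid]
        segments.sort(key=lambda s: s.start)
        expected = 1
        for seg in segments:
            if seg.start < expected:
                raise ValidationError(
                    f"{pid}: segment ({seg.start},{seg.end},{seg.klass}) overlaps "
                    f"previous coverage at position {seg.start}"
                )
            if seg.start > expected:
                raise ValidationError(
                    f"{pid}: coverage gap [{expected},{seg.start - 1}] before "
                    f"segment ({seg.start},{seg.end},{seg.klass})"
                )
            expected = seg.end + 1
        if expected != len(rec.sequence) + 1:
            raise ValidationError(
                f"{pid}: segments cover [1,{expected - 1}] but sequence length is "
                f"{len(rec.sequence)}"
            )
        rec.regions = segments
    return list(records)


def write_region_table(records: Iterable[GlycoProteinRecord], path: PathLike,
                       header_comment: str | None = None) -> None:
    rows = [
        (r.protein_id, seg.start, seg.end, seg.klass)
        for r in records
        if r.regions
        for seg in r.regions
    ]
    df = pd.DataFrame(rows, columns=REGION_COLUMNS)
    _write_tsv(df, path, header_comment)


def _write_tsv(df: pd.DataFrame, path: PathLike, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def enumerate_ser_thr_sites(record: GlycoProteinRecord) -> list[tuple[int, str, str]]:
    """All Ser/Thr positions of a record as ``(position, residue, status)``.

    A position is ``positive`` iff a positive annotation exists there;
    every other Ser/Thr is ``negative`` (the convention that unannotated
    Ser/Thr are treated as non-glycosylated).
    """
    positives = {s.position for s in record.sites if s.status == "positive"}
    return [
        (i + 1, c, "positive" if (i + 1) in positives else "negative")
        for i, c in enumerate(record.sequence)
        if c in "ST"
    ]
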