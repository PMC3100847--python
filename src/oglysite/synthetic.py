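"""Synthetic glycoprotein datasets with planted, parameterized structure.

The generator emits the three standard inputs (FASTA, site table,
region table) plus a ground-truth table, with every statistical feature
of interest planted explicitly so downstream modules can be tested for
exact recovery:

* proteins are tiled with alternating DOMAIN/ID segments whose residue
  composition differs (ID segments are enriched in the
  disorder-promoting residues P/S/T/A/G/E/Q/K and depleted in
  C/W/F/I/Y/V/L/M), so composition-based classifiers have a realistic
  signal;
* *clustered* positives are runs of k ≥ 2 adjacent glycosylated Ser/Thr
  (each member's nearest Ser/Thr neighbor is a glycosylated run mate,
  so nearest-neighbor typing recovers the planted label exactly);
* *isolated* positives are single glycosylated Ser/Thr flanked by
  non-glycosylated Ser sentinels with no other Ser/Thr in between, and
  carry position-specific flank motifs (e.g. Pro at −1) drawn with
  configured probabilities — at a motif offset the background filler
  never uses the motif residue, so the planted probability is exact;
* each clustered run / isolated site is placed inside an ID segment
  with its own configured probability, giving a known ID-enrichment
  level.

Defaults emulate the scale of curated mammalian mucin-type
O-glycoprotein sets: 98 proteins, ~306 clustered and 145 isolated
positive sites, ~30% of residues in ID regions, 91%/75% of
clustered/isolated sites inside ID regions.

The module also carries the packaged reference count tables
(:func:`table_fixtures`) from a published curated survey of 107
mucin-type and 83 non-mucin-type mammalian O-glycoproteins with
DICHOT-style domain/disorder segmentations, for exercising the
enrichment arithmetic on real printed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .exceptions import ConfigError
from .io import (
    GlycoProteinRecord,
    RegionSegment,
    SiteAnnotation,
    write_fasta,
    write_region_table,
    write_site_table,
)
from .sites import SequenceWindow

# ---------------------------------------------------------------------------
# Background compositions

# Average globular-protein frequencies (Robinson–Robinson-like), order A..Y.
_BASE_FREQS = {
    "A": 0.078, "C": 0.024, "D": 0.052, "E": 0.059, "F": 0.044,
    "G": 0.083, "H": 0.025, "I": 0.062, "K": 0.056, "L": 0.092,
    "M": 0.024, "N": 0.041, "P": 0.043, "Q": 0.034, "R": 0.051,
    "S": 0.059, "T": 0.055, "V": 0.066, "W": 0.014, "Y": 0.032,
}

# Disorder-promoting tilt applied to ID segments.
_ID_TILT = {
    "P": 2.2, "S": 1.6, "T": 1.5, "A": 1.3, "G": 1.4, "E": 1.3,
    "Q": 1.3, "K": 1.2, "R": 1.1, "D": 1.0, "H": 0.9, "N": 0.9,
    "M": 0.7, "L": 0.6, "V": 0.6, "I": 0.5, "Y": 0.5, "F": 0.4,
    "W": 0.3, "C": 0.15,
}


def _freq_vector(freqs: dict[str, float]) -> np.ndarray:
    v = np.array([freqs[a] for a in AMINO_ACIDS], dtype=np.float64)
    return v / v.sum()


DOMAIN_FREQS = _freq_vector(_BASE_FREQS)
ID_FREQS = _freq_vector({a: _BASE_FREQS[a] * _ID_TILT[a] for a in AMINO_ACIDS})

_NON_ST = [a for a in AMINO_ACIDS if a not in "ST"]

#: Default planted flank-motif probabilities for isolated sites,
#: ``(offset, residue) -> probability``: elevated Pro at −1/+3, sharp Val
#: peaks at −3/+8, Ala at −6/+5.
DEFAULT_MOTIF_PROBS: dict[tuple[int, str], float] = {
    (-1, "P"): 0.30,
    (3, "P"): 0.25,
    (-3, "V"): 0.16,
    (8, "V"): 0.16,
    (-6, "A"): 0.15,
    (5, "A"): 0.15,
}

_ISOLATED_HALF_SPAN = 10  # sentinels at ±10; motifs must sit strictly inside


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic dataset, with study-scale defaults."""

    n_proteins: int = 98
    mean_length: float = 430.0
    sd_length: float = 120.0
    min_length: int = 150
    # Mean segment lengths; defaults give an expected ID residue
    # fraction of about 70/(70+160) ~= 0.30.
    id_segment_mean: float = 70.0
    domain_segment_mean: float = 160.0
    min_segment: int = 25
    n_clustered_runs: int = 102
    run_length: int = 3
    n_isolated_sites: int = 145
    p_id_clustered: float = 0.91
    p_id_isolated: float = 0.75
    p_center_thr: float = 0.6  # Thr is glycosylated more often than Ser
    motif_probs: dict[tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PROBS)
    )
    glycan_type: str = "GalNAc"
    #: When True, flank-motif patterns are made exclusive to positive
    #: sites: no negative Ser/Thr anywhere in the dataset carries a motif
    #: residue at a motif offset.  Intended for deterministic
    #: single-motif configurations (separability experiments).
    exclusive_motifs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.run_length < 2:
            raise ConfigError("clustered runs need run_length >= 2")
        for p_name in ("p_id_clustered", "p_id_isolated", "p_center_thr"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{p_name}={p} outside [0, 1]")
        for (off, aa), p in self.motif_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"motif probability for ({off},{aa}) outside [0,1]")
            if aa in "ST":
                raise ConfigError("motif residues must not be Ser/Thr")
            if not -(_ISOLATED_HALF_SPAN - 1) <= off <= _ISOLATED_HALF_SPAN - 1 or off == 0:
                raise ConfigError(
                    f"motif offset {off} must be nonzero and within "
                    f"±{_ISOLATED_HALF_SPAN - 1}"
                )
        if self.run_length + 2 > self.min_segment:
            raise ConfigError(
                f"run_length {self.run_length} does not fit in the minimum "
                f"segment length {self.min_segment}"
            )


@dataclass
class _ProteinState:
    protein_id: str
    seq: list[str]
    segments: list[RegionSegment]
    reserved: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    records: list[GlycoProteinRecord]
    ground_truth: pd.DataFrame
    config: GeneratorConfig

    def write(self, outdir: str | Path, header_comment: Optional[str] = None) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "sites": outdir / "sites.tsv",
            "regions": outdir / "regions.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_site_table(self.records, paths["sites"], header_comment)
        write_region_table(self.records, paths["regions"], header_comment)
        with open(paths["ground_truth"], "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.ground_truth.to_csv(fh, sep="\t", index=False)
        return paths


def _draw_segments(rng: np.random.Generator, length: int, cfg: GeneratorConfig) -> list[RegionSegment]:
    segments: list[RegionSegment] = []
    klass = "ID" if rng.random() < 0.5 else "DOMAIN"
    pos = 1
    while pos <= length:
        mean = cfg.id_segment_mean if klass == "ID" else cfg.domain_segment_mean
        seg_len = max(cfg.min_segment, int(round(rng.normal(mean, mean / 3.0))))
        end = min(length, pos + seg_len - 1)
        if length - end < cfg.min_segment:
            end = length
        segments.append(RegionSegment(pos, end, klass))
        pos = end + 1
        klass = "DOMAIN" if klass == "ID" else "ID"
    return segments


def _background_residue(rng: np.random.Generator, klass: str,
                        exclude: Sequence[str] = ()) -> str:
    freqs = ID_FREQS if klass == "ID" else DOMAIN_FREQS
    if exclude:
        keep = [i for i, a in enumerate(AMINO_ACIDS) if a not in exclude]
        p = freqs[keep] / freqs[keep].sum()
        return AMINO_ACIDS[keep[int(rng.choice(len(keep), p=p))]]
    return AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=freqs))]


def _conflicts(reserved: list[tuple[int, int]], start: int, end: int, gap: int = 2) -> bool:
    return any(start <= e + gap and end >= s - gap for s, e in reserved)


def _place(
    rng: np.random.Generator,
    states: list[_ProteinState],
    span: int,
    klass: str,
    what: str,
    max_attempts: int = 500,
) -> tuple[_ProteinState, int]:
    """Reserve a span of ``span`` residues inside a segment of ``klass``."""
    weights = np.array([len(st.seq) for st in states], dtype=np.float64)
    weights /= weights.sum()
    for _ in range(max_attempts):
        st = states[int(rng.choice(len(states), p=weights))]
        candidates = [
            seg for seg in st.segments
            if seg.klass == klass and seg.end - seg.start + 1 >= span
        ]
        if not candidates:
            continue
        seg = candidates[int(rng.integers(len(candidates)))]
        start = int(rng.integers(seg.start, seg.end - span + 2))
        end = start + span - 1
        if _conflicts(st.reserved, start, end):
            continue
        st.reserved.append((start, end))
        return st, start
    raise ConfigError(
        f"could not place {what} (span {span} in a {klass} segment) after "
        f"{max_attempts} attempts; the configuration is too dense for the "
        "generated segment layout"
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full dataset; byte-identical for a fixed config/seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    states: list[_ProteinState] = []
    for i in range(config.n_proteins):
        length = max(config.min_length,
                     int(round(rng.normal(config.mean_length, config.sd_length))))
        segments = _draw_segments(rng, length, config)
        seq = []
        for seg in segments:
            freqs = ID_FREQS if seg.klass == "ID" else DOMAIN_FREQS
            idx = rng.choice(len(AMINO_ACIDS), size=seg.end - seg.start + 1, p=freqs)
            seq.extend(AMINO_ACIDS[j] for j in idx)
        states.append(_ProteinState(f"SYN{i + 1:04d}", seq, segments))

    # Coarse feasibility check before any emission.
    demand = (
        config.n_clustered_runs * (config.run_length + 4)
        + config.n_isolated_sites * (2 * _ISOLATED_HALF_SPAN + 5)
    )
    id_capacity = sum(
        seg.end - seg.start + 1
        for st in states for seg in st.segments if seg.klass == "ID"
    )
    if demand > 0.8 * id_capacity:
        raise ConfigError(
            f"infeasible config: planted elements need ~{demand} ID residues "
            f"but only {id_capacity} were generated"
        )

    positives: dict[str, list[SiteAnnotation]] = {st.protein_id: [] for st in states}
    gt_rows: list[dict] = []
    motif_aas = {aa for _off, aa in config.motif_probs}
    exclude_in_span = tuple(motif_aas) if config.exclusive_motifs else ()

    for _ in range(config.n_clustered_runs):
        in_id = rng.random() < config.p_id_clustered
        klass = "ID" if in_id else "DOMAIN"
        st, start = _place(rng, states, config.run_length, klass, "clustered run")
        for pos in range(start, start + config.run_length):
            residue = "T" if rng.random() < config.p_center_thr else "S"
            st.seq[pos - 1] = residue
            positives[st.protein_id].append(
                SiteAnnotation(pos, residue, config.glycan_type, "positive")
            )
            gt_rows.append(
                dict(protein_id=st.protein_id, position=pos, residue=residue,
                     site_type="clustered", in_id=in_id, motifs="")
            )

    span = 2 * _ISOLATED_HALF_SPAN + 1
    for _ in range(config.n_isolated_sites):
        in_id = rng.random() < config.p_id_isolated
        klass = "ID" if in_id else "DOMAIN"
        st, start = _place(rng, states, span, klass, "isolated site")
        center = start + _ISOLATED_HALF_SPAN
        residue = "T" if rng.random() < config.p_center_thr else "S"
        motif_at = {off: aa for (off, aa) in config.motif_probs}
        hits = []
        for off in range(-_ISOLATED_HALF_SPAN, _ISOLATED_HALF_SPAN + 1):
            pos = center + off
            if off == 0:
                st.seq[pos - 1] = residue
            elif abs(off) == _ISOLATED_HALF_SPAN:
                st.seq[pos - 1] = "S"  # non-glycosylated sentinel
            elif off in motif_at:
                aa = motif_at[off]
                if rng.random() < config.motif_probs[(off, aa)]:
                    st.seq[pos - 1] = aa
                    hits.append(f"{off:+d}:{aa}")
                else:
                    st.seq[pos - 1] = _background_residue(
                        rng, klass, exclude=("S", "T", aa) + exclude_in_span
                    )
            else:
                st.seq[pos - 1] = _background_residue(
                    rng, klass, exclude=("S", "T") + exclude_in_span
                )
        positives[st.protein_id].append(
            SiteAnnotation(center, residue, config.glycan_type, "positive")
        )
        gt_rows.append(
            dict(protein_id=st.protein_id, position=center, residue=residue,
                 site_type="isolated", in_id=in_id, motifs=";".join(hits))
        )

    if config.exclusive_motifs:
        _strip_background_motifs(states, positives, config)

    records = []
    for st in states:
        sites = sorted(positives[st.protein_id], key=lambda s: s.position)
        records.append(
            GlycoProteinRecord(st.protein_id, "".join(st.seq), sites, st.segments)
        )
    gt = pd.DataFrame(
        gt_rows, columns=["protein_id", "position", "residue", "site_type", "in_id", "motifs"]
    ).sort_values(["protein_id", "position"], kind="stable").reset_index(drop=True)
    return SyntheticDataset(records, gt, config)


def _strip_background_motifs(
    states: list[_ProteinState],
    positives: dict[str, list[SiteAnnotation]],
    config: GeneratorConfig,
) -> None:
    """Remove motif residues seen at motif offsets of *negative* Ser/Thr.

    Reserved spans are left untouched (planted motifs of positives live
    there and their fillers already exclude motif residues), so after
    this pass a motif pattern occurs only around positive sites.
    """
    for st in states:
        pos_set = {s.position for s in positives[st.protein_id]}
        length = len(st.seq)
        for q0, ch in enumerate(st.seq):
            q = q0 + 1
            if ch not in "ST" or q in pos_set:
                continue
            for (off, aa) in config.motif_probs:
                t = q + off
                if not 1 <= t <= length:
                    continue
                if _conflicts(st.reserved, t, t, gap=0):
                    continue
                if st.seq[t - 1] == aa:
                    st.seq[t - 1] = "G" if aa != "G" else "L"


def generate_ica_windows(
    n: int,
    signals: Sequence[tuple[int, str, float]],
    seed: int = 0,
) -> tuple[list[SequenceWindow], np.ndarray]:
    """Ws=7 windows with independent planted position-specific signals.

    ``signals`` is a list of ``(offset, residue, probability)``; each
    window draws every signal independently (residue present at that
    offset with the given probability, otherwise a uniform draw over the
    other 19 amino acids).  Returns the windows and the n×len(signals)
    binary draw matrix — the ground-truth independent sources.
    """
    rng = np.random.default_rng(seed)
    sig_at = {off: (aa, p) for off, aa, p in signals}
    if 0 in sig_at or any(abs(off) > 3 for off in sig_at):
        raise ConfigError("signal offsets must be nonzero and within ±3 for Ws=7")
    windows: list[SequenceWindow] = []
    draws = np.zeros((n, len(signals)), dtype=np.float64)
    sig_order = {off: j for j, (off, _aa, _p) in enumerate(signals)}
    for i in range(n):
        center = "T" if rng.random() < 0.5 else "S"
        symbols: list[str] = []
        for off in range(-3, 4):
            if off == 0:
                symbols.append(center)
            elif off in sig_at:
                aa, p = sig_at[off]
                hit = rng.random() < p
                draws[i, sig_order[off]] = float(hit)
                if hit:
                    symbols.append(aa)
                else:
                    others = [a for a in AMINO_ACIDS if a != aa]
                    symbols.append(others[int(rng.integers(len(others)))])
            else:
                symbols.append(AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
        windows.append(SequenceWindow(0, center, 7, symbols))
    return windows, draws


# ---------------------------------------------------------------------------
# Packaged reference count tables
#
# Printed counts from a published curated survey of mammalian
# O-glycoproteins (UniProt annotations, DICHOT domain/disorder
# segmentations): 107 mucin-type (O-GalNAc) proteins broken down by
# clustered/isolated site type, and 83 non-mucin-type proteins broken
# down by glycan type.  ``(n_in_ID, n_total)`` per category, and
# ``(n_proteins, o_sites_in_ID, st_in_ID, o_sites_total, st_total)``
# per glycan type.

SITE_TYPE_REFERENCE_COUNTS: dict[str, tuple[int, int]] = {
    "clustered": (283, 311),
    "isolated": (116, 154),
    "total": (399, 465),
    "ser_thr": (2779, 7228),
    "residues": (14028, 45962),
}

GLYCAN_REFERENCE_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "GalNAc": (107, 399, 2779, 465, 7228),
    "GlcNAc": (28, 45, 4076, 57, 5287),
    "Gal": (14, 23, 376, 43, 1365),
    "Xyl": (20, 34, 649, 40, 1593),
    "Fuc": (8, 1, 62, 14, 572),
    "Glc": (8, 0, 91, 8, 447),
    "HexNAc": (4, 3, 94, 4, 136),
    "Hex": (1, 1, 23, 1, 53),
}


def table_fixtures() -> dict[str, dict]:
    """The packaged reference counts, keyed ``site_type`` and ``glycan``."""
    return {
        "site_type": dict(SITE_TYPE_REFERENCE_COUNTS),
        "glycan": dict(GLYCAN_REFERENCE_COUNTS),
    }
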