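"""Disorder-region lookup, enrichment tables, density ratios, tracks."""

import numpy as np
import pytest

from helpers import mkrec
from oglysite.enrichment import (
    EnrichmentTable,
    build_enrichment_table,
    build_glycan_enrichment_table,
    derived_density_ratios,
    format_density_report,
    per_protein_track,
    round_half_up,
    site_region_lookup,
)
from oglysite.exceptions import ValidationError
from oglysite.io import GlycoProteinRecord, RegionSegment, SiteAnnotation
from oglysite.synthetic import table_fixtures


def segmented(seq, segments, positives=()):
    rec = mkrec(seq, positives)
    rec.regions = [RegionSegment(s, e, k) for s, e, k in segments]
    return rec


class TestSiteRegionLookup:
    def test_boundary_positions(self):
        rec = segmented("A" * 20, [(1, 10, "ID"), (11, 20, "DOMAIN")])
        assert site_region_lookup(rec, 10) == "ID"
        assert site_region_lookup(rec, 11) == "DOMAIN"

    def test_single_all_id_protein(self):
        rec = segmented("A" * 20, [(1, 20, "ID")])
        for pos in (1, 10, 20):
            assert site_region_lookup(rec, pos) == "ID"

    def test_uncovered_position_raises(self):
        rec = segmented("A" * 20, [(1, 10, "ID")])
        with pytest.raises(ValidationError, match="not covered"):
            site_region_lookup(rec, 15)

    def test_brute_force_oracle_on_random_segmentations(self):
        """Interval lookup agrees with per-residue scanning on random
        DOMAIN/ID tilings up to length 10,000."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(50, 10_000))
            cuts = np.unique(rng.integers(1, n + 1, size=rng.integers(1, 12)))
            bounds = [1, *cuts.tolist(), n + 1]
            segs, klasses = [], []
            for i in range(len(bounds) - 1):
                if bounds[i] >= bounds[i + 1]:
                    continue
                k = "ID" if rng.random() < 0.5 else "DOMAIN"
                segs.append((bounds[i], bounds[i + 1] - 1, k))
            rec = segmented("A" * n, segs)
            per_residue = np.empty(n, dtype=object)
            for s, e, k in segs:
                per_residue[s - 1 : e] = k
            for pos in rng.integers(1, n + 1, size=50):
                assert site_region_lookup(rec, int(pos)) == per_residue[pos - 1]


class TestEnrichmentTable:
    def test_in_id_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            EnrichmentTable({"total": (5, 4)})

    def test_clustered_plus_isolated_must_sum(self):
        with pytest.raises(ValidationError):
            EnrichmentTable(
                {"clustered": (2, 3), "isolated": (1, 1), "total": (4, 4)}
            )

    def test_all_sites_in_id_gives_100_percent(self):
        rec = segmented("TTTT", [(1, 4, "ID")], positives=(1, 2, 3, 4))
        table = build_enrichment_table([rec])
        assert table.percent_in_id("total") == 100.0
        assert table.percent_in_id("clustered") == 100.0

    def test_additivity_over_disjoint_record_sets(self, small_dataset):
        recs = small_dataset.records
        a, b = recs[:10], recs[10:]
        ta = build_enrichment_table(a)
        tb = build_enrichment_table(b)
        tall = build_enrichment_table(recs)
        for row in tall.counts:
            assert tuple(
                x + y for x, y in zip(ta.counts[row], tb.counts[row])
            ) == tall.counts[row]

    def test_missing_regions_error_lists_proteins(self):
        rec = mkrec("TTTT", (1,), protein_id="NOREG")
        with pytest.raises(ValidationError, match="NOREG"):
            build_enrichment_table([rec])


class TestReferenceCountArithmetic:
    """The packaged survey counts must reproduce the published
    percentages and densities exactly at printed precision."""

    def test_site_type_percentages(self):
        table = EnrichmentTable.from_counts(table_fixtures()["site_type"])
        assert table.percent_in_id("clustered") == 91.0
        assert table.percent_in_id("isolated") == 75.3
        assert table.percent_in_id("total") == 85.8
        assert table.percent_in_id("ser_thr") == 38.4
        assert table.percent_in_id("residues") == 30.5

    def test_density_ratios(self):
        table = EnrichmentTable.from_counts(table_fixtures()["site_type"])
        dens = format_density_report(derived_density_ratios(table))
        assert dens["sites_per_id_residue"] == 2.84
        assert dens["sites_per_residue"] == 1.01
        assert dens["sites_per_domain_residue"] == 0.21
        assert dens["sites_per_id_st"] == 14.4
        assert dens["sites_per_st"] == 6.43
        assert dens["sites_per_domain_st"] == 1.48
        assert dens["fold_id_over_all_residue"] == 2.8
        assert dens["fold_id_over_all_st"] == 2.2

    def test_zero_denominators_are_undefined_not_errors(self):
        table = EnrichmentTable.from_counts(
            {"total": (0, 0), "ser_thr": (0, 0), "residues": (0, 0)}
        )
        dens = derived_density_ratios(table)
        assert all(v is None for v in dens.values())

    def test_rounding_is_half_up(self):
        assert round_half_up(90.95, 1) == 91.0
        assert round_half_up(0.205, 2) == 0.21
        assert round_half_up(2.25, 1) == 2.3  # banker's rounding would give 2.2


class TestGlycanTable:
    def test_computed_from_records(self):
        recs = [
            segmented("TTSS", [(1, 2, "ID"), (3, 4, "DOMAIN")], positives=(1, 3)),
        ]
        recs[0].sites = [
            SiteAnnotation(1, "T", "GalNAc", "positive"),
            SiteAnnotation(3, "S", "GlcNAc", "positive"),
        ]
        df = build_glycan_enrichment_table(recs).set_index("glycan_type")
        assert df.loc["GalNAc", "o_sites_in_ID"] == 1
        assert df.loc["GlcNAc", "o_sites_in_ID"] == 0
        assert df.loc["GalNAc", "o_percent_in_ID"] == 100.0

    def test_reference_counts_reproduce_published_percentages(self):
        from oglysite.enrichment import glycan_table_from_counts

        df = glycan_table_from_counts(table_fixtures()["glycan"]).set_index("glycan_type")
        assert df.loc["GlcNAc", "o_percent_in_ID"] == 78.9
        assert df.loc["GlcNAc", "st_percent_in_ID"] == 77.1
        assert df.loc["Xyl", "o_percent_in_ID"] == 85.0
        assert df.loc["Glc", "o_percent_in_ID"] == 0.0
        assert df.loc["Hex", "o_percent_in_ID"] == 100.0
        assert df.loc["GalNAc", "o_percent_in_ID"] == 85.8


class TestPerProteinTrack:
    def test_sites_rendered_inside_id_span(self):
        # A coagulation-factor-like protein: six O-linked sites in one
        # disordered span.
        seq = ["A"] * 400
        for p in (299, 305, 308, 328, 329, 337):
            seq[p - 1] = "T" if p != 308 else "S"
        rec = segmented(
            "".join(seq),
            [(1, 280, "DOMAIN"), (281, 360, "ID"), (361, 400, "DOMAIN")],
            positives=(299, 305, 308, 328, 329, 337),
        )
        text = per_protein_track(rec)
        assert text.count(" ID") == 6
        assert "DOMAIN" not in [line.split()[-1] for line in text.splitlines()[1:] if line.startswith("site")]

    def test_protein_without_sites(self):
        rec = segmented("A" * 30, [(1, 30, "ID")])
        text = per_protein_track(rec)
        assert "site" not in text
        assert "i" * 30 in text

    def test_boundary_site_assigned_once(self):
        rec = segmented("A" * 9 + "T" + "A" * 10, [(1, 10, "ID"), (11, 20, "DOMAIN")],
                        positives=(10,))
        text = per_protein_track(rec)
        assert text.count("site T10") == 1
        assert "site T10 isolated ID" in text
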