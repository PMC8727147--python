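"""Ingest: reading, validation, filtering and pair deduplication."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virodiscover import (
    AssociationRecord,
    FilterConfig,
    apply_filters,
    dedupe_to_pairs,
    read_associations,
)
from virodiscover.ingest import DEFAULT_SCHEMA

from conftest import rec

CSV_HEADER = ",".join(DEFAULT_SCHEMA.values())


def write_csv(tmp_path, rows, header=CSV_HEADER):
    p = tmp_path / "assoc.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


def csv_row(species="Myotis myotis", virus="Virus A", year="2000", status="wild",
            resolution="ictv", detection="pcr"):
    return f"{species},Vespertilionidae,Chiroptera,{status},{virus},{resolution},{detection},{year},src"


class TestRead:
    def test_wellformed_rows_all_accepted(self, tmp_path):
        p = write_csv(tmp_path, [csv_row(virus=f"Virus {i}") for i in range(3)])
        result = read_associations(p)
        assert len(result.records) == 3
        assert result.rejected == []

    def test_malformed_year_rejected_others_kept(self, tmp_path):
        p = write_csv(tmp_path, [csv_row(year="20x8"), csv_row(virus="Virus B")])
        result = read_associations(p)
        assert len(result.records) == 1
        assert len(result.rejected) == 1
        assert "year" in result.rejected[0].reason

    def test_empty_virus_rows_rejected(self, tmp_path):
        # 10 rows of which 2 have an empty virus name -> 8 accepted
        rows = [csv_row(virus=f"Virus {i}") for i in range(8)]
        rows += [csv_row(virus=""), csv_row(virus="   ")]
        result = read_associations(write_csv(tmp_path, rows))
        assert len(result.records) == 8
        assert len(result.rejected) == 2

    def test_row_conservation(self, tmp_path):
        rows = [csv_row(), csv_row(year="bad"), csv_row(status="feral"), csv_row(virus="")]
        result = read_associations(write_csv(tmp_path, rows))
        assert len(result.records) + len(result.rejected) == len(rows)

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        header = CSV_HEADER.replace("virus_resolution,", "")
        p = tmp_path / "bad.csv"
        p.write_text(header + "\n")
        with pytest.raises(ValueError, match="virus_resolution"):
            read_associations(p)

    def test_schema_map_binds_foreign_headers(self, tmp_path):
        header = "Host,Fam,Ord,Status,Virus,Res,Det,Yr,Src"
        p = write_csv(tmp_path, ["Myotis myotis,V,Chiroptera,wild,Virus A,ictv,pcr,1999,s"], header)
        schema = {
            "host_species": "Host", "host_family": "Fam", "host_order": "Ord",
            "host_status": "Status", "virus": "Virus", "virus_resolution": "Res",
            "detection": "Det", "year": "Yr", "source": "Src",
        }
        result = read_associations(p, schema=schema)
        assert len(result.records) == 1
        assert result.records[0].year == 1999

    def test_year_outside_plausible_range_rejected(self, tmp_path):
        result = read_associations(write_csv(tmp_path, [csv_row(year="1850"), csv_row()]))
        assert len(result.records) == 1


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"species": " "},
            {"virus": ""},
            {"year": 1800},
            {"year": 2150},
            {"status": "feral"},
            {"resolution": "genbank"},
            {"detection": "culture"},
        ],
    )
    def test_invalid_record_raises(self, kwargs):
        with pytest.raises(ValueError):
            rec(**kwargs)

    def test_whitespace_normalized_case_preserved(self):
        r = rec(species="  Myotis   myotis ", virus=" Virus  A ")
        assert r.host_species == "Myotis myotis"
        assert r.virus == "Virus A"


class TestFilters:
    def test_wild_only(self, mixed_records):
        out = apply_filters(mixed_records, FilterConfig(require_resolved=False, year_max=2100))
        assert all(r.host_status.value == "wild" for r in out)
        assert not any(r.host_species == "Sus scrofa" for r in out)

    def test_detection_rule_drops_serology(self, mixed_records):
        cfg = FilterConfig(detection_rule="pcr_or_isolation_only")
        out = apply_filters(mixed_records, cfg)
        assert all(r.detection.value in ("pcr", "isolation") for r in out)

    def test_year_max_drops_post_window_record(self, mixed_records):
        out = apply_filters(mixed_records, FilterConfig(wild_only=False, require_resolved=False))
        assert not any(r.year == 2019 for r in out)
        out2 = apply_filters(mixed_records, FilterConfig(wild_only=False, require_resolved=False, year_max=2019))
        assert any(r.year == 2019 for r in out2)

    def test_resolution_filter(self, mixed_records):
        out = apply_filters(mixed_records, FilterConfig(wild_only=False))
        assert all(r.virus_resolution.value in ("ictv", "predict") for r in out)

    def test_all_disabled_is_identity(self, mixed_records):
        out = apply_filters(mixed_records, FilterConfig.permissive())
        assert out == mixed_records

    def test_pure_and_order_preserving(self, mixed_records):
        snapshot = list(mixed_records)
        out = apply_filters(mixed_records, FilterConfig())
        assert mixed_records == snapshot
        idx = [mixed_records.index(r) for r in out]
        assert idx == sorted(idx)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(year_min=2020, year_max=2018)
        with pytest.raises(ValueError):
            FilterConfig(detection_rule="serology_only")


class TestDedupe:
    def test_earliest_year_and_strongest_evidence(self):
        records = [
            rec(virus="Virus A", year=1975, detection="serology"),
            rec(virus="Virus A", year=1962, detection="isolation"),
        ]
        pairs = dedupe_to_pairs(records)
        assert len(pairs) == 1
        assert pairs.loc[0, "discovery_year"] == 1962
        assert pairs.loc[0, "detection_best"] == "isolation"

    def test_strict_year_tracks_first_pcr_or_isolation_report(self):
        records = [
            rec(virus="Virus A", year=1962, detection="serology"),
            rec(virus="Virus A", year=1975, detection="pcr"),
            rec(virus="Virus B", year=1980, detection="serology"),
        ]
        pairs = dedupe_to_pairs(records).set_index("virus")
        assert pairs.loc["Virus A", "discovery_year"] == 1962
        assert pairs.loc["Virus A", "strict_year"] == 1975
        assert pd.isna(pairs.loc["Virus B", "strict_year"])

    def test_five_records_three_pairs(self):
        records = [
            rec(virus="Virus A", year=1970),
            rec(virus="Virus A", year=1980),
            rec(virus="Virus B", year=1990),
            rec(species="Canis lupus", order="Carnivora", virus="Virus A", year=1995),
            rec(virus="Virus B", year=1985, detection="serology"),
        ]
        assert len(dedupe_to_pairs(records)) == 3

    def test_case_and_whitespace_insensitive_matching(self):
        records = [rec(virus="virus a", year=1990), rec(virus="Virus  A", year=1970)]
        pairs = dedupe_to_pairs(records)
        assert len(pairs) == 1
        assert pairs.loc[0, "discovery_year"] == 1970

    def test_idempotent(self, mixed_records):
        pairs1 = dedupe_to_pairs(mixed_records)
        records_back = [
            rec(species=row.host_species, family=row.host_family, order=row.host_order,
                virus=row.virus, year=int(row.discovery_year), detection=row.detection_best)
            for row in pairs1.itertuples()
        ]
        pairs2 = dedupe_to_pairs(records_back)
        pd.testing.assert_frame_equal(
            pairs1[["host_species", "virus", "discovery_year"]],
            pairs2[["host_species", "virus", "discovery_year"]],
        )

    def test_permutation_invariant(self, mixed_records):
        base = dedupe_to_pairs(mixed_records)
        for perm in itertools.islice(itertools.permutations(mixed_records), 0, 24, 5):
            pd.testing.assert_frame_equal(dedupe_to_pairs(list(perm)), base)

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_subset_monotonicity(self, data):
        """Adding records can only add pairs or lower discovery years."""
        years = st.integers(min_value=1930, max_value=2018)
        records = data.draw(
            st.lists(
                st.builds(
                    lambda v, y, d: rec(virus=f"Virus {v}", year=y, detection=d),
                    st.integers(0, 4), years, st.sampled_from(["serology", "pcr", "isolation"]),
                ),
                min_size=1, max_size=12,
            )
        )
        k = data.draw(st.integers(0, len(records)))
        sub, full = dedupe_to_pairs(records[:k]), dedupe_to_pairs(records)
        sub_i = sub.set_index(["host_species", "virus"])
        full_i = full.set_index(["host_species", "virus"])
        assert set(sub_i.index) <= set(full_i.index)
        for key in sub_i.index:
            assert full_i.loc[key, "discovery_year"] <= sub_i.loc[key, "discovery_year"]

    def test_empty_input(self):
        pairs = dedupe_to_pairs([])
        assert len(pairs) == 0
        assert list(pairs.columns[:5]) == [
            "host_species", "host_family", "host_order", "virus", "discovery_year"
        ]
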