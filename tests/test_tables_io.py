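"""Case and reference table I/O: validation, dialects, round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casepop.tables_io import (
    PopulationReference,
    ReferenceKind,
    TableValidationError,
    parse_band,
    read_cases,
    read_population_reference,
    validate_dataset,
    write_cases,
    write_population_reference,
)


class TestReadCases:
    def test_identity_read_with_missing_cells(self, case_csv):
        records = read_cases(case_csv)
        assert len(records) == 3
        assert records[0].birth_month == 2 and records[0].urban_birth is True
        assert records[1].birth_month is None  # empty cell stays missing
        assert records[1].born_abroad is None
        assert records[2].paternal_age is None

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "archival.csv"
        path.write_text("id,sexe,annee\nx,male,1890\n")
        records = read_cases(path, dialect={"id": "subject_id", "sexe": "sex", "annee": "birth_year"})
        assert records[0].subject_id == "x" and records[0].birth_year == 1890

    @pytest.mark.parametrize(
        "row, fragment",
        [
            ("bad,male,1890,13,,,,,,,", "birth_month"),
            ("bad,male,1890,,,,,,,4,2", "sibship_size"),
            ("bad,male,1890,,,,,200,,,", "paternal_age"),
            ("bad,male,1890,x,,,,,,,", "birth_month"),
        ],
    )
    def test_malformed_rows_name_row_and_field(self, tmp_path, row, fragment):
        path = tmp_path / "bad.csv"
        header = (
            "subject_id,sex,birth_year,birth_month,urban_birth,birthplace_population,"
            "born_abroad,paternal_age,maternal_age,birth_rank,sibship_size\n"
        )
        path.write_text(header + "ok,male,1890,,,,,,,,\n" + row + "\n")
        with pytest.raises(TableValidationError, match="row 1") as err:
            read_cases(path)
        assert fragment in str(err.value)

    def test_duplicate_subject_id(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("subject_id,sex,birth_year\nz,male,1890\nz,male,1891\n")
        with pytest.raises(TableValidationError, match="duplicate"):
            read_cases(path)

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "nocol.csv"
        path.write_text("subject_id,sex\nz,male\n")
        with pytest.raises(TableValidationError, match="birth_year"):
            read_cases(path)

    def test_inconsistent_urban_flag(self, record_factory):
        with pytest.raises(Exception, match="urban_birth"):
            record_factory(urban_birth=False, birthplace_population=10_000)

    def test_round_trip_cell_for_cell(self, case_csv, tmp_path):
        records = read_cases(case_csv)
        out = tmp_path / "out.csv"
        write_cases(records, out)
        assert read_cases(out) == records
        # and the canonical text form is a fixed point of read-then-write
        out2 = tmp_path / "out2.csv"
        write_cases(read_cases(out), out2)
        assert out.read_text() == out2.read_text()


class TestReferenceIO:
    def test_percent_dialect_monthly(self, tmp_path):
        path = tmp_path / "m.csv"
        cols = ",".join(f"m{m:02d}" for m in range(1, 13))
        path.write_text(f"year,{cols}\n1896," + ",".join(["10"] * 4 + ["7.5"] * 8) + "\n")
        ref = read_population_reference(path, "seasonality", "monthly_shares_by_year")
        assert ref.payload[1896][0] == pytest.approx(0.10)
        assert sum(ref.payload[1896]) == pytest.approx(1.0)

    def test_fraction_dialect_idempotent(self, tmp_path):
        path = tmp_path / "m.csv"
        cols = ",".join(f"m{m:02d}" for m in range(1, 13))
        vals = ",".join(["0.1"] * 4 + ["0.075"] * 8)
        path.write_text(f"year,{cols}\n1896,{vals}\n")
        ref = read_population_reference(path, "seasonality", "monthly_shares_by_year")
        out = tmp_path / "round.csv"
        write_population_reference(ref, out)
        ref2 = read_population_reference(out, "seasonality", "monthly_shares_by_year")
        assert ref2.payload == ref.payload

    def test_bad_share_sum_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        cols = ",".join(f"m{m:02d}" for m in range(1, 13))
        path.write_text(f"year,{cols}\n1896," + ",".join(["3"] * 12) + "\n")
        with pytest.raises(TableValidationError, match="neither"):
            read_population_reference(path, "seasonality", "monthly_shares_by_year")

    def test_census_grid_accepted(self, tmp_path):
        path = tmp_path / "u.csv"
        years = [1881, 1886, 1891, 1896, 1901, 1906, 1911]
        path.write_text("year,proportion\n" + "\n".join(f"{y},0.4" for y in years) + "\n")
        ref = read_population_reference(path, "urbanicity", "scalar_proportion_by_year")
        assert ref.year_grid == tuple(years)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(Exception, match="strictly increasing"):
            PopulationReference(
                factor="urbanicity",
                kind=ReferenceKind.scalar_proportion_by_year,
                year_grid=(1891, 1881),
                payload={1891: 0.4, 1881: 0.3},
            )

    def test_overlapping_bands_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text(
            "year,father_band,mother_band,share\n"
            "1901,25-34,25-29,0.5\n"
            "1901,30-39,25-29,0.5\n"
        )
        with pytest.raises(Exception, match="overlap"):
            read_population_reference(path, "paternal_age", "parental_age_crosstab_by_year")

    def test_crosstab_round_trip(self, tmp_path):
        path = tmp_path / "x.csv"
        path.write_text(
            "year,father_band,mother_band,share\n"
            "1901,25-29,25-29,0.25\n"
            "1901,30-34,25-29,0.25\n"
            "1901,25-29,30-34,0.25\n"
            "1901,30-34,30-34,0.25\n"
        )
        ref = read_population_reference(path, "paternal_age", "parental_age_crosstab_by_year")
        out = tmp_path / "round.csv"
        write_population_reference(ref, out)
        ref2 = read_population_reference(out, "paternal_age", "parental_age_crosstab_by_year")
        assert ref2.payload == ref.payload

    @pytest.mark.parametrize(
        "label, interval",
        [("35-39", (35, 40)), ("<25", (12, 25)), (">=50", (50, 81)), (">50", (51, 81))],
    )
    def test_parse_band(self, label, interval):
        assert parse_band(label) == interval


class TestValidateDataset:
    def test_per_factor_counts(self, full_records):
        report = validate_dataset(full_records)
        assert report["n_cases"] == 10
        assert all(f["n_with_data"] == 10 for f in report["factors"].values())

    def test_empty_case_list(self):
        report = validate_dataset([])
        assert report["n_cases"] == 0
        assert all(f["n_with_data"] == 0 for f in report["factors"].values())

    def test_partial_availability(self, record_factory):
        cases = [record_factory(subject_id=f"s{i}", urban_birth=(i < 4) or None) for i in range(6)]
        report = validate_dataset(cases)
        assert report["factors"]["urbanicity"]["n_with_data"] == 4
        assert report["factors"]["seasonality"]["n_with_data"] == 0
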