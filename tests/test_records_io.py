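"""records_io: CSV round-trips, validation, derived fields, complete cases."""

import numpy as np
import pandas as pd
import pytest

from vitalfit.records_io import (
    INJURIES,
    RAW_INJURY_COLUMNS,
    REFLEXES,
    SchemaError,
    complete_cases,
    derive_fields,
    read_records,
    write_records,
)

from conftest import make_recordset


HEADER = ("fish_id,trip_id,deployment_id,gear_type,sea_temp,depth,duration,"
          "total_catch,air_exposure,length,"
          + ",".join(REFLEXES) + ","
          + ",".join(RAW_INJURY_COLUMNS) + ",vitality,mortality")


def _row(fish_id, injuries="0,0,0,0", reflexes="0,0,0,0,0,0", length="23",
         vitality="A", mortality="0"):
    return (f"{fish_id},T01,T01_D1,BT2,12,30,90,800,10,{length},"
            f"{reflexes},{injuries},{vitality},{mortality}")


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "fish.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadRecords:
    def test_valid_rows_round_trip(self, tmp_path):
        path = write_csv(tmp_path, [_row("F1"), _row("F2", injuries="0,2,0,3"),
                                    _row("F3", mortality="1")])
        rs = read_records(path)
        assert rs.n == 3
        assert rs.validation.n_read == 3 and not rs.validation.errors
        # injuries arrived raw, so binary columns were derived
        assert rs.df.loc[1, list(INJURIES)].tolist() == [0, 1, 0, 1]

    def test_missing_mortality_column_is_fatal(self, tmp_path):
        header = HEADER.replace(",mortality", "")
        rows = [_row("F1").rsplit(",", 1)[0]]
        with pytest.raises(SchemaError, match="mortality"):
            read_records(write_csv(tmp_path, rows, header=header))

    def test_out_of_range_injury_rejected_with_diagnostic(self, tmp_path):
        path = write_csv(tmp_path, [_row("F1"), _row("F2", injuries="0,4,0,0")])
        rs = read_records(path)
        assert rs.n == 1
        (err,) = rs.validation.errors
        assert err.row == 1 and err.field == "bruising_body_raw"

    def test_missing_sentinels_become_nan(self, tmp_path):
        path = write_csv(tmp_path, [_row("F1", length=""), _row("F2", length="NA")])
        rs = read_records(path)
        assert rs.n == 2
        assert rs.df["length"].isna().all()

    def test_flip_reflexes(self, tmp_path):
        # file codes 1 = response present; flipping stores 1 = impaired
        path = write_csv(tmp_path, [_row("F1", reflexes="1,1,1,1,1,1")])
        rs = read_records(path, flip_reflexes=True)
        assert rs.df.loc[0, list(REFLEXES)].tolist() == [0] * 6

    def test_inconsistent_nesting_is_fatal(self, tmp_path):
        rows = [_row("F1"),
                _row("F2").replace("T01,T01_D1,BT2", "T02,T01_D1,OTB")]
        with pytest.raises(SchemaError, match="deployment"):
            read_records(write_csv(tmp_path, rows))

    def test_duplicate_fish_id_is_fatal(self, tmp_path):
        with pytest.raises(SchemaError, match="duplicate"):
            read_records(write_csv(tmp_path, [_row("F1"), _row("F1")]))

    def test_schema_map_renames_columns(self, tmp_path):
        header = HEADER.replace("sea_temp", "SST")
        path = write_csv(tmp_path, [_row("F1")], header=header)
        rs = read_records(path, schema={"sea_temp": "SST"})
        assert rs.df.loc[0, "sea_temp"] == 12.0


class TestWriteRoundTrip:
    def test_read_write_read_is_identity(self, tmp_path):
        path = write_csv(tmp_path, [_row("F1", injuries="1,0,3,0"),
                                    _row("F2", mortality="1", vitality="C")])
        rs1 = read_records(path)
        out = tmp_path / "out.csv"
        write_records(rs1, out)
        rs2 = read_records(out)
        pd.testing.assert_frame_equal(rs1.df, rs2.df)
        # and the second write is byte-identical
        out2 = tmp_path / "out2.csv"
        write_records(rs2, out2)
        assert out.read_bytes() == out2.read_bytes()


class TestDeriveFields:
    def test_injury_dichotomization(self):
        rs = make_recordset(np.zeros((1, 10)), [0])
        rs.df[list(RAW_INJURY_COLUMNS)] = [[0, 2, 0, 3]]
        out = derive_fields(rs)
        assert out.df.loc[0, list(INJURIES)].tolist() == [0, 1, 0, 1]

    def test_all_absent_stays_absent(self):
        rs = make_recordset(np.zeros((2, 10)), [0, 0])
        out = derive_fields(rs)
        assert (out.df[list(INJURIES)] == 0).all().all()

    def test_air_exposure_formula(self):
        # one third of the handling happens in air
        rs = make_recordset(np.zeros((1, 10)), [0])
        out = derive_fields(rs, deck_minutes=[9.0], handling_minutes=[3.0])
        assert out.df.loc[0, "air_exposure"] == 10.0

    def test_negative_time_rejected(self):
        rs = make_recordset(np.zeros((2, 10)), [0, 0])
        out = derive_fields(rs, deck_minutes=[5.0, -1.0],
                            handling_minutes=[3.0, 3.0])
        assert out.n == 1
        assert any(e.code == "negative_time" for e in out.validation.errors)

    def test_idempotent(self):
        rs = make_recordset(np.eye(10, dtype=int)[:4], [0, 1, 0, 1])
        once = derive_fields(rs)
        twice = derive_fields(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestCompleteCases:
    def test_drops_missing_length(self):
        rs = make_recordset(np.zeros((5, 10)), [0] * 5)
        rs.df.loc[2, "length"] = np.nan
        assert complete_cases(rs, ["length"]).n == 4

    def test_empty_covariates_keeps_complete_attribute_rows(self):
        rs = make_recordset(np.zeros((5, 10)), [0] * 5)
        rs.df.loc[1, "total_catch"] = np.nan  # not requested -> irrelevant
        assert complete_cases(rs, []).n == 5

    def test_unknown_covariate_is_fatal(self):
        rs = make_recordset(np.zeros((2, 10)), [0, 0])
        with pytest.raises(ValueError, match="unknown covariate"):
            complete_cases(rs, ["salinity"])

    def test_monotone_in_covariates(self, rng):
        rs = make_recordset(rng.integers(0, 2, (50, 10)),
                            rng.integers(0, 2, 50))
        for col in ("length", "total_catch", "air_exposure"):
            rs.df.loc[rs.df.sample(5, random_state=1).index, col] = np.nan
        sets = [[], ["length"], ["length", "total_catch"],
                ["length", "total_catch", "air_exposure"]]
        counts = [complete_cases(rs, s).n for s in sets]
        assert counts == sorted(counts, reverse=True)
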