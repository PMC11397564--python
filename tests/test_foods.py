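"""Domain types, unit conversion, and CSV round-tripping."""

import csv

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npmpfj import (FoodRecord, NutrientProfile, PointVector, read_food_table,
                    read_scored_table, salt_to_sodium, score_records,
                    write_scored_table)
from npmpfj.errors import AlignmentError, RowValidationError, SchemaError

HEADER = ("food_id,name,family,energy_kcal,satfat_g,sugars_g,sodium_mg,"
          "fvnl_pct,fvnl_concentrated,protein_g,fiber_g")


def _write(tmp_path, rows, header=HEADER):
    path = tmp_path / "foods.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestSaltToSodium:
    @pytest.mark.parametrize("salt_g,sodium_mg", [
        (7.0, 2756),   # the reference daily amount: 7 g NaCl = 2756 mg Na
        (0.0, 0),
        (2.54, 1000),  # direct inversion of 2.54 g salt per g sodium
    ])
    def test_known_conversions(self, salt_g, sodium_mg):
        assert salt_to_sodium(salt_g) == sodium_mg

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            salt_to_sodium(-0.1)


class TestNutrientProfile:
    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="sodium"):
            NutrientProfile(100, 1, 1, -5, 0, False, 1, 1)

    def test_fvnl_over_100_rejected(self):
        with pytest.raises(ValueError, match="fvnl"):
            NutrientProfile(100, 1, 1, 5, 101, False, 1, 1)


class TestPointVector:
    def test_identities_enforced(self):
        with pytest.raises(ValueError, match="baseline"):
            PointVector(1, 1, 1, 1, 0, 0, 0, baseline=5, final=5)
        with pytest.raises(ValueError, match="final"):
            PointVector(1, 1, 1, 1, 1, 0, 0, baseline=4, final=4)

    def test_component_ranges_enforced(self):
        with pytest.raises(ValueError, match="energy_pts"):
            PointVector.from_points(12, 0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError, match="v_pts"):
            PointVector.from_points(0, 0, 0, 0, 9, 0, 0)

    def test_from_points_computes_identities(self):
        pv = PointVector.from_points(2, 3, 2, 2, 1, 1, 1)
        assert pv.baseline == 9 and pv.final == 6
        assert pv.components() == (2, 3, 2, 2, 1, 1, 1)


class TestReadFoodTable:
    def test_well_formed_rows(self, tmp_path):
        path = _write(tmp_path, [
            "a,apple juice,beverages,46,0.1,9.6,4,100,false,0.1,0.2",
            "b,rye bread,breads,250,0.5,3.1,430,0,false,8.5,5.6",
            "c,pickles,pickles,30,0.1,2.5,1500,90,false,1.5,2",
        ])
        records = read_food_table(path)
        assert len(records) == 3
        assert records[0].profile.fvnl_pct == 100
        assert records[1].family == "breads"

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("food_id,name,energy_kcal\na,x,100\n")
        with pytest.raises(SchemaError, match="satfat_g"):
            read_food_table(path)

    def test_missing_sodium_is_row_error_listing_food_id(self, tmp_path):
        path = _write(tmp_path, [
            "ok1,water,beverages,0,0,0,1,0,false,0,0",
            "bad1,mystery,,100,1,1,,0,false,1,1",
        ])
        with pytest.raises(RowValidationError, match="bad1"):
            read_food_table(path)
        records, errors = read_food_table(path, errors="collect")
        assert [r.food_id for r in records] == ["ok1"]
        assert errors[0].food_id == "bad1" and "sodium" in errors[0].message

    def test_non_numeric_and_negative_are_row_errors(self, tmp_path):
        path = _write(tmp_path, [
            "n1,x,,abc,1,1,10,0,false,1,1",
            "n2,y,,100,1,1,-4,0,false,1,1",
        ])
        _, errors = read_food_table(path, errors="collect")
        assert {e.food_id for e in errors} == {"n1", "n2"}

    def test_duplicate_food_id_rejected(self, tmp_path):
        path = _write(tmp_path, [
            "dup,x,,100,1,1,10,0,false,1,1",
            "dup,y,,100,1,1,10,0,false,1,1",
        ])
        _, errors = read_food_table(path, errors="collect")
        assert len(errors) == 1 and "duplicate" in errors[0].message

    def test_salt_equivalent_column_converted(self, tmp_path):
        header = ("food_id,name,energy_kcal,satfat_g,sugars_g,salt_g,"
                  "fvnl_pct,fvnl_concentrated,protein_g,fiber_g")
        path = _write(tmp_path, ["s1,soy sauce analog,100,0.1,2,7,0,false,5,0"],
                      header=header)
        (rec,) = read_food_table(path)
        assert rec.profile.sodium == 2756

    def test_custom_schema_mapping(self, tmp_path):
        header = ("id,label,kcal,sf,ts,na,fv,fc,pr,df")
        path = _write(tmp_path, ["z,thing,100,1,1,10,0,false,1,1"], header=header)
        schema = {"food_id": "id", "name": "label", "energy": "kcal",
                  "saturated_fat": "sf", "total_sugars": "ts", "sodium": "na",
                  "fvnl_pct": "fv", "fvnl_concentrated": "fc",
                  "protein": "pr", "dietary_fiber": "df"}
        (rec,) = read_food_table(path, schema=schema)
        assert rec.food_id == "z" and rec.profile.energy == 100


class TestWriteScoredTable:
    def test_all_zero_food_row(self, tmp_path):
        rec = FoodRecord("z", "zero", NutrientProfile(0, 0, 0, 0, 0, False, 0, 0))
        pv = PointVector.from_points(0, 0, 0, 0, 0, 0, 0)
        out = tmp_path / "scored.csv"
        write_scored_table([rec], [pv], out)
        row = list(csv.DictReader(open(out)))[0]
        assert row["baseline"] == "0" and row["final"] == "0"

    def test_empty_records_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_scored_table([], [], out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("food_id,")

    def test_length_mismatch_raises(self, tmp_path):
        rec = FoodRecord("z", "zero", NutrientProfile(0, 0, 0, 0, 0, False, 0, 0))
        with pytest.raises(AlignmentError):
            write_scored_table([rec], [], tmp_path / "x.csv")

    def test_round_trip_synthetic_table(self, tmp_path, synthetic_records,
                                        synthetic_points):
        out = tmp_path / "rt.csv"
        write_scored_table(synthetic_records, synthetic_points, out)
        records2, points2, ratings2 = read_scored_table(out)
        assert records2 == synthetic_records
        assert points2 == synthetic_points
        assert all(r is None for r in ratings2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    energy=st.integers(0, 900),
    satfat=st.integers(0, 1000).map(lambda v: v / 10),
    sugars=st.integers(0, 990).map(lambda v: v / 10),
    sodium=st.integers(0, 4000),
    fvnl=st.integers(0, 1000).map(lambda v: v / 10),
    conc=st.booleans(),
    protein=st.integers(0, 600).map(lambda v: v / 10),
    fiber=st.integers(0, 300).map(lambda v: v / 10),
)
def test_round_trip_preserves_fields_at_declared_precision(
        tmp_path_factory, energy, satfat, sugars, sodium, fvnl, conc,
        protein, fiber):
    """Any record at declared precision (integer kcal/mg, one-decimal grams)
    survives write -> read bit-for-bit."""
    rec = FoodRecord("h1", "hypothesis food", NutrientProfile(
        energy, satfat, sugars, sodium, fvnl, conc, protein, fiber),
        family="fam", category=3)
    pv = score_records([rec])[0]
    path = tmp_path_factory.mktemp("rt") / "one.csv"
    write_scored_table([rec], [pv], path, ratings=[4.5])
    records2, points2, ratings2 = read_scored_table(path)
    assert records2 == [rec] and points2 == [pv] and ratings2 == [4.5]
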