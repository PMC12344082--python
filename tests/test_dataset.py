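import numpy as np
import pytest

from scsol.dataset import (
    BUILTIN_SYSTEMS,
    CO2DensityTable,
    IsothermCollection,
    SolubilityRecord,
    SolutePhysProps,
    builtin_dataset,
    density_lookup,
    load_solubility_table,
    mole_fraction_from_masses,
    save_solubility_table,
)
from scsol.errors import GridLookupError, SchemaError, ValidationError

GRID_T = {308.0, 318.0, 328.0, 338.0}
GRID_P = {12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0}


class TestBuiltinDataset:
    def test_binary_shape_and_grid(self, binary):
        assert len(binary) == 28
        assert {r.temperature for r in binary} == GRID_T
        assert {r.pressure for r in binary} == GRID_P
        assert all(r.cosolvent_fraction == 0 for r in binary)

    @pytest.mark.parametrize(
        "label, t, p, y, y3",
        [
            ("binary", 338, 30, 1.082e-4, 0.0),
            ("binary", 308, 12, 0.238e-4, 0.0),
            ("ethanol-3%", 338, 12, 1.225e-4, 0.03),
            ("ethanol-1%", 308, 12, 0.766e-4, 0.01),
        ],
    )
    def test_tabulated_values(self, label, t, p, y, y3):
        coll = builtin_dataset(label)
        rec = next(r for r in coll if r.temperature == t and r.pressure == p)
        assert rec.mole_fraction == pytest.approx(y, rel=1e-12)
        assert rec.cosolvent_fraction == y3

    def test_binary_density_at_338_30(self, binary):
        rec = next(r for r in binary if (r.temperature, r.pressure) == (338, 30))
        assert rec.co2_density == 809.6

    def test_ternary_reuses_binary_densities(self, binary, ethanol1, ethanol3):
        dens = {(r.temperature, r.pressure): r.co2_density for r in binary}
        for coll in (ethanol1, ethanol3):
            assert len(coll) == 28
            for r in coll:
                assert r.co2_density == dens[(r.temperature, r.pressure)]

    def test_pooled_ternary(self, ternary):
        assert len(ternary) == 56
        assert set(np.unique(ternary.cosolvent_fraction)) == {0.01, 0.03}

    def test_unknown_label_lists_valid(self):
        with pytest.raises(KeyError, match="binary"):
            builtin_dataset("nosuch")
        assert set(BUILTIN_SYSTEMS) >= {"binary", "ethanol-1%", "ethanol-3%"}


class TestRecordsAndCollections:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(temperature=-1, pressure=12, co2_density=700, mole_fraction=1e-4),
            dict(temperature=308, pressure=0, co2_density=700, mole_fraction=1e-4),
            dict(temperature=308, pressure=12, co2_density=0, mole_fraction=1e-4),
            dict(temperature=308, pressure=12, co2_density=700, mole_fraction=0.0),
            dict(temperature=308, pressure=12, co2_density=700, mole_fraction=1.0),
            dict(temperature=308, pressure=12, co2_density=700, mole_fraction=1e-4,
                 cosolvent_fraction=-0.01),
        ],
    )
    def test_record_invariants(self, kwargs):
        with pytest.raises(ValidationError):
            SolubilityRecord(**kwargs)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            IsothermCollection(())

    def test_duplicate_condition_rejected(self):
        rec = SolubilityRecord(308, 12, 700, 1e-4)
        with pytest.raises(ValidationError, match="duplicate"):
            IsothermCollection((rec, rec))

    def test_records_sorted_into_isotherms(self, binary):
        for t, iso in binary.isotherms().items():
            pressures = [r.pressure for r in iso]
            assert pressures == sorted(pressures)
            assert all(b > a for a, b in zip(pressures, pressures[1:]))

    def test_physprops_invariants(self):
        with pytest.raises(ValidationError):
            SolutePhysProps(
                molar_mass=211.21, boiling_temperature=900.0,
                critical_temperature=850.0, critical_pressure=2.45e6,
                acentric_factor=0.558, solid_molar_volume=335.4,
            )


class TestCsvIO:
    @pytest.mark.parametrize("label", ["binary", "ethanol-1%", "ethanol-3%"])
    def test_round_trip_is_lossless(self, label, tmp_path):
        coll = builtin_dataset(label)
        path = tmp_path / "table.csv"
        save_solubility_table(coll, path)
        back = load_solubility_table(path, system_label=label)
        assert back.records == coll.records

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_MPa,y2\n308,12,1e-5\n")
        with pytest.raises(SchemaError, match="rho_kg_m3"):
            load_solubility_table(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValidationError):
            load_solubility_table(path)

    def test_nonpositive_temperature_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "T_K,P_MPa,rho_kg_m3,y2,y3,sd\n308,12,700,1e-5,0,0\n-5,12,700,1e-5,0,0\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            load_solubility_table(path)

    def test_nonfinite_rows_rejected_with_report(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text(
            "T_K,P_MPa,rho_kg_m3,y2,y3,sd\n308,12,700,1e-5,0,0\n318,12,nan,1e-5,0,0\n"
        )
        with pytest.warns(UserWarning, match="rejected"):
            coll = load_solubility_table(path)
        assert len(coll) == 1

    def test_scale_hint_for_printed_tables(self, tmp_path):
        path = tmp_path / "scaled.csv"
        path.write_text("T_K,P_MPa,rho_kg_m3,y2\n308,12,768.4,0.238\n")
        coll = load_solubility_table(path, mole_fraction_scale=1e-4)
        assert coll.records[0].mole_fraction == pytest.approx(2.38e-5)

    def test_custom_schema_mapping(self, tmp_path):
        path = tmp_path / "custom.csv"
        path.write_text("temp,pres,dens,frac\n308,12,768.4,2.38e-5\n")
        coll = load_solubility_table(
            path,
            schema={"temperature": "temp", "pressure": "pres",
                    "co2_density": "dens", "mole_fraction": "frac"},
        )
        assert coll.records[0].co2_density == 768.4


class TestDensityLookup:
    @pytest.mark.parametrize("t, p, rho", [(308, 12, 768.4), (338, 12, 384.2)])
    def test_on_grid(self, t, p, rho):
        assert density_lookup(t, p) == rho

    def test_off_grid_errors_with_nearest(self):
        with pytest.raises(GridLookupError, match="nearest"):
            density_lookup(308, 11)

    def test_bilinear_interpolation_between_neighbours(self, binary):
        table = CO2DensityTable.from_collection(binary)
        lo = table.lookup(308, 12)
        hi = table.lookup(308, 15)
        mid = table.lookup(308, 13.5, interpolate=True)
        assert lo < mid < hi
        assert mid == pytest.approx((lo + hi) / 2)

    def test_interpolation_outside_hull_errors(self, binary):
        table = CO2DensityTable.from_collection(binary)
        with pytest.raises(GridLookupError):
            table.lookup(350, 12, interpolate=True)


class TestMoleFractionFromMasses:
    def test_nothing_dissolved(self):
        assert mole_fraction_from_masses(0.1, 0.1, 1.0) == 0.0

    def test_hand_computed_value(self):
        # 0.01 g of a 211.21 g/mol solute in 1 mol CO2
        y = mole_fraction_from_masses(0.10, 0.09, 1.0, 211.21)
        assert y == pytest.approx(4.734e-5, rel=1e-3)

    def test_negative_dissolution_rejected(self):
        with pytest.raises(ValidationError):
            mole_fraction_from_masses(0.10, 0.11, 1.0)
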