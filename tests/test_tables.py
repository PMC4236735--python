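import pytest

import kindraft as kd
from kindraft.tables import write_value_table


class TestValueTables:
    def test_flux_table_with_measured_constraints(self, tmp_path):
        # glucose uptake and ATP-maintenance rates as fixed reference values
        path = tmp_path / "fluxes.tsv"
        path.write_text("GLCpts\t0.2004\nATPM\t1.193\n")
        fluxes = kd.read_value_table(path, kind="flux")
        assert fluxes.values == {"GLCpts": 0.2004, "ATPM": 1.193}

    def test_comma_delimiter_and_header_autodetected(self, tmp_path):
        path = tmp_path / "fluxes.csv"
        path.write_text("name,value\nR1,1.5\nR2,2.5e-3\n")
        fluxes = kd.read_value_table(path, kind="flux")
        assert fluxes.values == {"R1": 1.5, "R2": 0.0025}

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(kd.read_value_table(path, kind="flux")) == 0

    @pytest.mark.parametrize("content", ["abc\tNaN\n", "abc\tinf\n", "abc\t1,5\n"])
    def test_malformed_numeric_rejected_with_line_number(self, tmp_path, content):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(kd.TableFormatError, match="line 1"):
            kd.read_value_table(path, kind="flux")

    def test_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("R1\t1.0\nR1\t2.0\n")
        with pytest.raises(kd.TableFormatError, match="duplicate"):
            kd.read_value_table(path, kind="flux")

    def test_negative_concentration_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("glc\t-0.5\n")
        with pytest.raises(kd.TableFormatError):
            kd.read_value_table(path, kind="concentration")

    def test_write_read_round_trip(self, tmp_path):
        fluxes = kd.FluxSet({"R1": 0.2004, "R2": 1.193, "R3": 1e-7})
        path = tmp_path / "rt.tsv"
        write_value_table(fluxes, path)
        assert kd.read_value_table(path, kind="flux").values == fluxes.values

    def test_xlsx_sheet_read_as_value_table(self, tmp_path):
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(["Name", "Value"])
        ws.append(["glc", 0.0556])
        ws.append(["pyr", 0.9])
        path = tmp_path / "conc.xlsx"
        wb.save(path)
        conc = kd.read_value_table(path, kind="concentration")
        assert conc.values == {"glc": 0.0556, "pyr": 0.9}


class TestRemovalLists:
    def test_order_preserved_comments_and_blanks_skipped(self, tmp_path):
        path = tmp_path / "remove.txt"
        path.write_text("# hub metabolites\nB\n\nC\n")
        assert kd.read_removal_list(path) == ["B", "C"]

    def test_duplicates_collapsed_with_warning(self, tmp_path):
        path = tmp_path / "remove.txt"
        path.write_text("B\nC\nB\n")
        with pytest.warns(UserWarning, match="duplicate"):
            assert kd.read_removal_list(path) == ["B", "C"]

    def test_effectively_empty_list_is_error(self, tmp_path):
        path = tmp_path / "remove.txt"
        path.write_text("# nothing here\n\n")
        with pytest.raises(kd.TableFormatError, match="empty"):
            kd.read_removal_list(path)


SBTAB_MINIMAL = (
    "!!SBtab TableType='Quantity' TableName='conc'\n"
    "!Name\t!Value\t!Unit\t!Identifiers:chebi\n"
    "glucose\t0.0556\tmM\tCHEBI:17234\n"
)


class TestSBtab:
    def test_minimal_quantity_table_parses_field_by_field(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(SBTAB_MINIMAL)
        table = kd.read_sbtab(path)
        assert table.table_type == "Quantity"
        assert table.columns == ["Name", "Value", "Unit", "Identifiers:chebi"]
        assert len(table.rows) == 1
        row = table.rows[0]
        assert row["Name"] == "glucose"
        assert row["Value"] == 0.0556
        assert row["Unit"] == "mM"
        assert row["Identifiers:chebi"] == "CHEBI:17234"

    def test_missing_declaration_line_is_format_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("!Name\t!Value\nx\t1\n")
        with pytest.raises(kd.TableFormatError, match="SBtab"):
            kd.read_sbtab(path)

    def test_unknown_table_type_named_in_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("!!SBtab TableType='Mystery'\n!Name\t!Value\n")
        with pytest.raises(kd.TableFormatError, match="Mystery"):
            kd.read_sbtab(path)

    def test_table_without_value_column_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("!!SBtab TableType='Quantity'\n!Name\t!Unit\nx\tmM\n")
        with pytest.raises(kd.TableFormatError, match="Value"):
            kd.read_sbtab(path)

    @pytest.mark.parametrize("rows", [
        [],
        [{"Name": "glc", "Value": 0.0556, "Unit": "mM"}],
        [{"Name": "glc", "Value": 1.0, "Unit": "mM"},
         {"Name": "pyr", "Value": 2.0, "Unit": "mM"}],
    ])
    def test_write_read_round_trip(self, tmp_path, rows):
        table = kd.DataTable("Quantity", ["Name", "Value", "Unit"], rows)
        path = tmp_path / "rt.tsv"
        kd.write_sbtab(table, path)
        back = kd.read_sbtab(path)
        assert back.table_type == table.table_type
        assert back.columns == table.columns
        assert back.rows == table.rows

    def test_time_series_rows_preserved_in_order(self, tmp_path):
        table = kd.DataTable(
            "Quantity", ["Name", "Value", "Time"],
            [{"Name": "glc", "Value": 1.0, "Time": 0.0},
             {"Name": "glc", "Value": 0.5, "Time": 10.0}],
        )
        path = tmp_path / "ts.tsv"
        kd.write_sbtab(table, path)
        back = kd.read_sbtab(path)
        assert [r["Time"] for r in back.rows] == [0.0, 10.0]


class TestTableToConcentrations:
    def test_quantity_table_maps_to_concentrations(self):
        table = kd.DataTable(
            "Quantity", ["Name", "Value", "Unit"],
            [{"Name": "glc", "Value": 0.0556, "Unit": "mM"},
             {"Name": "pyr", "Value": 0.9, "Unit": "mM"}],
        )
        conc = kd.table_to_concentrations(table)
        assert conc.values == {"glc": 0.0556, "pyr": 0.9}
        assert conc.unit == "mM"

    def test_time_series_directs_user_to_pick_a_time_point(self):
        table = kd.DataTable(
            "Quantity", ["Name", "Value", "Time"],
            [{"Name": "glc", "Value": 1.0, "Time": 0.0}],
        )
        with pytest.raises(kd.TableFormatError, match="time"):
            kd.table_to_concentrations(table)

    def test_duplicate_names_rejected(self):
        table = kd.DataTable(
            "Quantity", ["Name", "Value"],
            [{"Name": "glc", "Value": 1.0}, {"Name": "glc", "Value": 2.0}],
        )
        with pytest.raises(kd.TableFormatError, match="duplicate"):
            kd.table_to_concentrations(table)

    def test_negative_value_rejected(self):
        table = kd.DataTable(
            "Quantity", ["Name", "Value"], [{"Name": "glc", "Value": -1.0}]
        )
        with pytest.raises(kd.TableFormatError):
            kd.table_to_concentrations(table)
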