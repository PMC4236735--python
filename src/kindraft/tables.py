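"""Tabular workflow inputs: value tables, removal lists, and SBtab files.

Flux and concentration tables are two-column delimited text (name, value);
tab is the preferred delimiter with comma auto-detected, and an optional
header row is recognized when its second field is not numeric.  A single
worksheet of an ``.xlsx`` workbook is accepted in place of the delimited
text file.  The SBtab support implements the small dialect the workflow
needs: a ``!!SBtab`` declaration line with a ``TableType`` attribute, a
column line of ``!``-prefixed headers (including ``!Identifiers:chebi`` /
``!Identifiers:kegg``), and typed rows.
"""
from __future__ import annotations

import math
import os
import re
import warnings
from dataclasses import dataclass, field

from .errors import TableFormatError

TABLE_TYPES = ("Quantity", "Compound", "Reaction")


@dataclass
class FluxSet:
    """Named reference flux distribution (mM s^-1 by convention)."""

    values: dict[str, float]
    unit: str = "mM/s"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise TableFormatError(f"non-finite flux for {name!r}: {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()


@dataclass
class ConcentrationSet:
    """Named metabolite concentrations (mM by convention); non-negative."""

    values: dict[str, float]
    unit: str = "mM"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise TableFormatError(
                    f"concentration for {name!r} must be finite and >= 0, got {v}"
                )

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()


@dataclass
class DataTable:
    """Minimal SBtab-style table: a type, ordered columns, and row records."""

    table_type: str
    columns: list[str]
    rows: list[dict] = field(default_factory=list)
    name: str = ""

    def validate(self) -> None:
        if self.table_type not in TABLE_TYPES:
            raise TableFormatError(
                f"unknown TableType {self.table_type!r}; supported: "
                + ", ".join(TABLE_TYPES)
            )
        if "Name" not in self.columns or "Value" not in self.columns:
            raise TableFormatError("table must declare Name and Value columns")
        for i, row in enumerate(self.rows):
            missing = [c for c in self.columns if c not in row]
            if missing:
                raise TableFormatError(
                    f"row {i + 1} missing column(s): " + ", ".join(missing)
                )
        if "Time" not in self.columns:
            names = [row["Name"] for row in self.rows]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise TableFormatError(
                    "duplicate Name values: " + ", ".join(sorted(dupes))
                )


# ---------------------------------------------------------------------------
# plain value tables


def _read_rows(path: str | os.PathLike) -> list[tuple[int, list[str]]]:
    """Rows as (1-based line number, fields); handles .xlsx transparently."""
    path = os.fspath(path)
    if path.endswith(".xlsx"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        sheet = wb.worksheets[0]
        rows = []
        for i, row in enumerate(sheet.iter_rows(values_only=True), start=1):
            fields = ["" if v is None else str(v) for v in row]
            if any(f.strip() for f in fields):
                rows.append((i, fields))
        wb.close()
        return rows
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # tab preferred; fall back to comma only if no line is tab-delimited
    delimiter = "\t" if any("\t" in line for line in lines) else ","
    rows = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        rows.append((i, [f.strip() for f in line.split(delimiter or "\t")]))
    return rows


_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_number(text: str, line_no: int) -> float:
    if not _NUMBER.match(text.strip()):
        raise TableFormatError(f"line {line_no}: not a number: {text!r}")
    return float(text)


def read_value_table(
    path: str | os.PathLike, kind: str = "flux"
) -> FluxSet | ConcentrationSet:
    """Read a two-column (name, value) table as fluxes or concentrations."""
    if kind not in ("flux", "concentration"):
        raise ValueError(f"kind must be 'flux' or 'concentration', got {kind!r}")
    rows = _read_rows(path)
    if (
        len(rows) >= 2
        and len(rows[0][1]) >= 2
        and not _NUMBER.match(rows[0][1][1].strip())
    ):
        rows = rows[1:]  # header row
    values: dict[str, float] = {}
    unit = "mM/s" if kind == "flux" else "mM"
    for line_no, fields in rows:
        if len(fields) < 2:
            raise TableFormatError(f"line {line_no}: expected two columns")
        name = fields[0].strip()
        if name in values:
            raise TableFormatError(f"line {line_no}: duplicate name {name!r}")
        values[name] = _parse_number(fields[1], line_no)
    if kind == "flux":
        return FluxSet(values, unit=unit)
    return ConcentrationSet(values, unit=unit)


def write_value_table(
    data: FluxSet | ConcentrationSet, path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, value in data.items():
            fh.write(f"{name}\t{value!r}\n")


def read_removal_list(path: str | os.PathLike) -> list[str]:
    """One species identifier per line; '#' comments and blanks ignored.

    Order is preserved; duplicates are collapsed with a warning.  An empty
    effective list is an error (there is nothing to remove).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    result: list[str] = []
    for line in lines:
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        if entry in result:
            warnings.warn(f"duplicate removal entry {entry!r} collapsed")
            continue
        result.append(entry)
    if not result:
        raise TableFormatError(f"{os.fspath(path)}: removal list is empty")
    return result


# ---------------------------------------------------------------------------
# SBtab


_DECLARATION = re.compile(r"^!!SBtab\b")
_ATTR = re.compile(r"(\w+)=(['\"])(.*?)\2")


def read_sbtab(path: str | os.PathLike) -> DataTable:
    """Parse a flat SBtab file (declaration line + '!' column headers)."""
    rows = _read_rows(path)
    if not rows or not _DECLARATION.match(rows[0][1][0]):
        raise TableFormatError(
            f"{os.fspath(path)}: first line must be an '!!SBtab' declaration"
        )
    attrs = {m.group(1): m.group(3) for m in _ATTR.finditer(" ".join(rows[0][1]))}
    table_type = attrs.get("TableType", "")
    if table_type not in TABLE_TYPES:
        raise TableFormatError(
            f"unknown TableType {table_type!r}; supported: " + ", ".join(TABLE_TYPES)
        )
    if len(rows) < 2:
        raise TableFormatError("missing column declaration line")
    columns = []
    for header in rows[1][1]:
        header = header.strip()
        if not header:
            continue
        if not header.startswith("!"):
            raise TableFormatError(f"column header {header!r} must start with '!'")
        columns.append(header.lstrip("!"))
    records: list[dict] = []
    for line_no, fields in rows[2:]:
        record: dict = {}
        for column, value in zip(columns, fields):
            if column == "Value" or column == "Time":
                record[column] = _parse_number(value, line_no)
            else:
                record[column] = value.strip()
        for column in columns[len(fields):]:
            record[column] = ""
        records.append(record)
    table = DataTable(table_type, columns, records, name=attrs.get("TableName", ""))
    table.validate()
    return table


def write_sbtab(table: DataTable, path: str | os.PathLike) -> None:
    """Write a DataTable as a flat SBtab file that re-parses identically."""
    table.validate()
    with open(path, "w", encoding="utf-8") as fh:
        name = table.name or table.table_type
        fh.write(
            f"!!SBtab TableType='{table.table_type}' TableName='{name}'\n"
        )
        fh.write("\t".join("!" + c for c in table.columns) + "\n")
        for row in table.rows:
            fields = []
            for column in table.columns:
                value = row[column]
                fields.append(repr(value) if isinstance(value, float) else str(value))
            fh.write("\t".join(fields) + "\n")


def table_to_concentrations(table: DataTable) -> ConcentrationSet:
    """Turn a steady-state Quantity table into a ConcentrationSet."""
    table.validate()
    if table.table_type != "Quantity":
        raise TableFormatError(
            f"expected a Quantity table, got {table.table_type!r}"
        )
    if "Time" in table.columns:
        raise TableFormatError(
            "table is a time series; select a single time point first"
        )
    values: dict[str, float] = {}
    for row in table.rows:
        values[row["Name"]] = float(row["Value"])
    unit = ""
    if "Unit" in table.columns and table.rows:
        units = {row["Unit"] for row in table.rows}
        unit = units.pop() if len(units) == 1 else ""
    return ConcentrationSet(values, unit=unit or "mM")
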