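"""Spreadsheet I/O for GBA models.

Two dialects share one tabular layout:

* ``ods`` — a single OpenDocument spreadsheet with one sheet per tab
  (canonical interchange format).  Read/written with the standard library
  (zipfile + ElementTree) so no office suite dependency is needed.
* ``csv-bundle`` — a directory with one CSV file per tab (``M.csv`` ...),
  identical cell layout; convenient for hand-editing and diffing.

Tabs: ``M``, ``K``, ``KA``, ``KI``, ``kcat``, ``conditions``.

Numeric cells round-trip bit-exactly: floats are serialized with ``repr``.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
import xml.etree.ElementTree as ET
import zipfile
from pathlib import Path

import numpy as np

from .errors import ModelFormatError
from .model_core import (EXTERNAL_PREFIX, ConditionSet, GBAModel)

__all__ = ["read_model", "write_model", "TAB_NAMES"]

TAB_NAMES = ("M", "K", "KA", "KI", "kcat", "conditions")

_NS = {
    "office": "urn:oasis:names:tc:opendocument:xmlns:office:1.0",
    "table": "urn:oasis:names:tc:opendocument:xmlns:table:1.0",
    "text": "urn:oasis:names:tc:opendocument:xmlns:text:1.0",
}
_MIMETYPE = "application/vnd.oasis.opendocument.spreadsheet"

# ---------------------------------------------------------------------------
# low-level ODS: sheets <-> list-of-rows of (float | str | None)
# ---------------------------------------------------------------------------


def _q(prefix: str, name: str) -> str:
    return f"{{{_NS[prefix]}}}{name}"


def _read_ods_sheets(path: Path) -> dict[str, list[list[object]]]:
    with zipfile.ZipFile(path) as zf:
        root = ET.fromstring(zf.read("content.xml"))
    sheets: dict[str, list[list[object]]] = {}
    for table in root.iter(_q("table", "table")):
        name = table.get(_q("table", "name"), "")
        rows: list[list[object]] = []
        for tr in table.findall(_q("table", "table-row")):
            row: list[object] = []
            for cell in tr.findall(_q("table", "table-cell")):
                repeat = int(cell.get(_q("table", "number-columns-repeated"), "1"))
                value = _parse_ods_cell(cell)
                # huge trailing repeats are padding emitted by office suites
                repeat = min(repeat, 4096)
                row.extend([value] * repeat)
            while row and row[-1] is None:
                row.pop()
            nrep = int(tr.get(_q("table", "number-rows-repeated"), "1"))
            rows.extend([list(row)] * min(nrep, 4096))
        while rows and not rows[-1]:
            rows.pop()
        sheets[name] = rows
    return sheets


def _parse_ods_cell(cell) -> object:
    vtype = cell.get(_q("office", "value-type"))
    if vtype in ("float", "currency", "percentage"):
        return float(cell.get(_q("office", "value")))
    if vtype is None:
        return None
    # string (or anything else): concatenate the text:p payloads
    text = "".join(p.text or "" for p in cell.findall(_q("text", "p")))
    return text if text != "" else None


def _write_ods(path: Path, sheets: dict[str, list[list[object]]]) -> None:
    ET.register_namespace("office", _NS["office"])
    ET.register_namespace("table", _NS["table"])
    ET.register_namespace("text", _NS["text"])
    doc = ET.Element(_q("office", "document-content"),
                     {_q("office", "version"): "1.2"})
    body = ET.SubElement(doc, _q("office", "body"))
    ss = ET.SubElement(body, _q("office", "spreadsheet"))
    for name, rows in sheets.items():
        table = ET.SubElement(ss, _q("table", "table"),
                              {_q("table", "name"): name})
        ET.SubElement(table, _q("table", "table-column"))
        for row in rows:
            tr = ET.SubElement(table, _q("table", "table-row"))
            for value in row:
                if value is None:
                    ET.SubElement(tr, _q("table", "table-cell"))
                elif isinstance(value, (int, float)) and not isinstance(value, bool):
                    tc = ET.SubElement(tr, _q("table", "table-cell"), {
                        _q("office", "value-type"): "float",
                        _q("office", "value"): repr(float(value)),
                    })
                    ET.SubElement(tc, _q("text", "p")).text = repr(float(value))
                else:
                    tc = ET.SubElement(tr, _q("table", "table-cell"), {
                        _q("office", "value-type"): "string",
                    })
                    ET.SubElement(tc, _q("text", "p")).text = str(value)

    buf = _io.BytesIO()
    ET.ElementTree(doc).write(buf, xml_declaration=True, encoding="UTF-8")
    manifest = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<manifest:manifest '
        'xmlns:manifest="urn:oasis:names:tc:opendocument:xmlns:manifest:1.0" '
        'manifest:version="1.2">'
        f'<manifest:file-entry manifest:full-path="/" manifest:media-type="{_MIMETYPE}"/>'
        '<manifest:file-entry manifest:full-path="content.xml" '
        'manifest:media-type="text/xml"/>'
        "</manifest:manifest>"
    )
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(zipfile.ZipInfo("mimetype"), _MIMETYPE,
                    compress_type=zipfile.ZIP_STORED)
        zf.writestr("META-INF/manifest.xml", manifest)
        zf.writestr("content.xml", buf.getvalue())


# ---------------------------------------------------------------------------
# low-level CSV bundle
# ---------------------------------------------------------------------------


def _read_csv_sheets(path: Path) -> dict[str, list[list[object]]]:
    sheets = {}
    for tab in TAB_NAMES:
        f = path / f"{tab}.csv"
        if not f.exists():
            continue
        rows: list[list[object]] = []
        with open(f, newline="") as fh:
            for raw in csv.reader(fh):
                row: list[object] = []
                for cell in raw:
                    cell = cell.strip()
                    if cell == "":
                        row.append(None)
                    else:
                        try:
                            row.append(float(cell))
                        except ValueError:
                            row.append(cell)
                while row and row[-1] is None:
                    row.pop()
                rows.append(row)
        while rows and not rows[-1]:
            rows.pop()
        sheets[tab] = rows
    return sheets


def _write_csv_bundle(path: Path, sheets: dict[str, list[list[object]]]) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for tab, rows in sheets.items():
        with open(path / f"{tab}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in rows:
                writer.writerow([
                    "" if v is None
                    else (repr(float(v)) if isinstance(v, (int, float))
                          and not isinstance(v, bool) else str(v))
                    for v in row
                ])


# ---------------------------------------------------------------------------
# layout: sheets <-> (GBAModel, ConditionSet)
# ---------------------------------------------------------------------------


def _number(value, tab, row_label, col_label) -> float:
    """Interpret a raw cell as a number; empty cells become NaN (caught later
    by the integrity check), non-numeric text is a format error."""
    if value is None:
        return float("nan")
    if isinstance(value, float):
        return value
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ModelFormatError(
            f"non-parseable cell in tab {tab!r} at ({row_label!r}, {col_label!r}): "
            f"{value!r}", tab=tab, row=row_label, column=col_label) from None


def _parse_matrix_tab(sheets, tab) -> tuple[list[str], list[str], np.ndarray]:
    if tab not in sheets:
        raise ModelFormatError(f"missing tab: {tab}", tab=tab)
    rows = sheets[tab]
    if not rows:
        raise ModelFormatError(f"tab {tab!r} is empty", tab=tab)
    col_labels = [str(v) for v in rows[0][1:]]
    n_cols = len(col_labels)
    row_labels: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        label = "" if row[0] is None else str(row[0])
        cells = row[1:]
        if len(cells) > n_cols:
            raise ModelFormatError(
                f"ragged matrix in tab {tab!r}: row {label!r} (line {i}) has "
                f"{len(cells)} values, expected {n_cols}",
                tab=tab, row=label)
        cells = list(cells) + [None] * (n_cols - len(cells))
        row_labels.append(label)
        data.append([_number(v, tab, label, col_labels[j])
                     for j, v in enumerate(cells)])
    arr = np.array(data, dtype=float) if data else np.zeros((0, n_cols))
    return row_labels, col_labels, arr


def sheets_to_model(sheets: dict) -> tuple[GBAModel, ConditionSet]:
    """Assemble the domain objects from raw tab contents."""
    reactant_labels, reaction_labels, M = _parse_matrix_tab(sheets, "M")
    k_rows, k_cols, K = _parse_matrix_tab(sheets, "K")

    n_ext = sum(1 for lbl in reactant_labels if lbl.startswith(EXTERNAL_PREFIX))
    internal_labels = reactant_labels[n_ext:]

    KA = _parse_regulation_tab(sheets, "KA", internal_labels)
    KI = _parse_regulation_tab(sheets, "KI", internal_labels)

    kcat_rows, _, kcat = _parse_matrix_tab(sheets, "kcat")
    if len(kcat_rows) < 2:
        raise ModelFormatError(
            "tab 'kcat' must have rows 'kcat_f' and 'kcat_b'", tab="kcat")
    kcat_f, kcat_b = kcat[0], kcat[1]

    cond_rows, cond_labels, cond = _parse_matrix_tab(sheets, "conditions")
    if not cond_rows or cond_rows[0] != "rho":
        raise ModelFormatError(
            "tab 'conditions' must start with the 'rho' row", tab="conditions")
    rho = cond[0]
    ext_labels = cond_rows[1:]
    a = cond[1:] if cond.shape[0] > 1 else np.zeros((0, len(cond_labels)))

    model = GBAModel(reactant_labels, reaction_labels, M, K, KA, KI,
                     kcat_f, kcat_b)
    conditions = ConditionSet(cond_labels, rho, a, external_labels=ext_labels)
    return model, conditions


def _parse_regulation_tab(sheets, tab, internal_labels) -> np.ndarray:
    rows, cols, arr = _parse_matrix_tab(sheets, tab)
    keep, dropped = [], []
    for i, lbl in enumerate(rows):
        if lbl.startswith(EXTERNAL_PREFIX):
            if arr.size and np.any(arr[i] != 0):
                raise ModelFormatError(
                    f"tab {tab!r}: external row {lbl!r} must be all-zero "
                    "(regulation is defined for internal reactants only)",
                    tab=tab, row=lbl)
            dropped.append(lbl)
        else:
            keep.append(i)
    if dropped:
        warnings.warn(
            f"tab {tab}: dropping all-zero external rows {dropped}",
            stacklevel=2)
    return arr[keep] if len(rows) else arr


def model_to_sheets(model: GBAModel, conditions: ConditionSet) -> dict:
    """Lay the domain objects out as raw tab contents."""
    def matrix(row_labels, col_labels, arr):
        rows: list[list[object]] = [[None, *col_labels]]
        arr = np.atleast_2d(np.asarray(arr))
        for lbl, row in zip(row_labels, arr):
            rows.append([lbl, *[float(v) for v in row]])
        return rows

    ext = getattr(conditions, "external_labels", None)
    if ext is None:
        ext = model.external_labels
    sheets = {
        "M": matrix(model.reactant_labels, model.reaction_labels, model.M),
        "K": matrix(model.reactant_labels, model.reaction_labels, model.K),
        "KA": matrix(model.internal_labels, model.reaction_labels, model.KA),
        "KI": matrix(model.internal_labels, model.reaction_labels, model.KI),
        "kcat": matrix(["kcat_f", "kcat_b"], model.reaction_labels,
                       np.vstack([model.kcat_f, model.kcat_b])),
        "conditions": matrix(["rho", *ext], conditions.condition_labels,
                             np.vstack([np.asarray(conditions.rho)[None, :],
                                        np.atleast_2d(conditions.a)])
                             if np.asarray(conditions.a).size
                             else np.asarray(conditions.rho)[None, :]),
    }
    return sheets


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("ods", "csv-bundle"):
            raise ValueError(f"unknown dialect: {dialect!r}")
        return dialect
    if path.suffix.lower() == ".ods":
        return "ods"
    return "csv-bundle"


def read_model(path, dialect: str | None = None) -> tuple[GBAModel, ConditionSet]:
    """Read a GBA model + conditions from an ODS file or a CSV bundle.

    Labels and ordering are preserved exactly as stored; no validation is
    performed beyond parseability (run ``gba.validation.check_model`` next).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _infer_dialect(path, dialect)
    sheets = (_read_ods_sheets(path) if d == "ods"
              else _read_csv_sheets(path))
    return sheets_to_model(sheets)


def write_model(model: GBAModel, conditions: ConditionSet, path,
                dialect: str | None = None) -> None:
    """Write a GBA model + conditions; ``read_model`` round-trips bit-exactly."""
    path = Path(path)
    d = _infer_dialect(path, dialect)
    sheets = model_to_sheets(model, conditions)
    if d == "ods":
        _write_ods(path, sheets)
    else:
        _write_csv_bundle(path, sheets)
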