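"""Readers and writers for the supported table formats.

Grids travel as CSV/TSV (leading whitespace significant — it encodes
category indentation), HTML tables (thead/rowspan/colspan honored), or
the grid-JSON interchange format.  Writers are deterministic: rows,
columns and keys are emitted in a stable order.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Optional, Union

from lxml import etree, html as lxml_html

from .model import Cell, StructuralError, TableGrid, expand_spans

__all__ = ["read_table", "write_table", "FormatError",
           "grid_from_html", "grid_to_csv", "grid_to_html"]


class FormatError(ValueError):
    """Malformed input for the named format (with line/element context)."""


def read_table(
    path: Union[str, Path],
    format: Optional[str] = None,
    n_header_rows: int = 1,
    n_header_cols: int = 1,
    caption: str = "",
    footnotes: Optional[list[str]] = None,
) -> TableGrid:
    """Read a table file into a :class:`TableGrid`.

    ``format`` is one of csv, tsv, html, grid-json (inferred from the
    file suffix when omitted).  CSV/TSV cannot express header counts,
    captions or spans; ``n_header_rows``/``n_header_cols`` supply the
    header prefix and leading whitespace is preserved for indentation.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".html": "html",
                  ".htm": "html", ".json": "grid-json"}.get(
                      path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer table format from {path.name!r}")
    text = path.read_text(encoding="utf-8")
    if format == "grid-json":
        try:
            return TableGrid.from_json(text)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"{path.name}: invalid grid-JSON: {exc}") from exc
    if format in ("csv", "tsv"):
        return _grid_from_delimited(text, "\t" if format == "tsv" else ",",
                                    n_header_rows, n_header_cols, caption,
                                    footnotes or [], path.name)
    if format == "html":
        return grid_from_html(text, n_header_rows=n_header_rows,
                              n_header_cols=n_header_cols)
    raise FormatError(f"unknown table format {format!r}")


def _grid_from_delimited(text: str, delim: str, n_header_rows: int,
                         n_header_cols: int, caption: str,
                         footnotes: list[str], name: str) -> TableGrid:
    reader = csv.reader(_io.StringIO(text), delimiter=delim,
                        skipinitialspace=False)
    rows = [row for row in reader]
    while rows and not any(c.strip() for c in rows[-1]):
        rows.pop()
    if not rows:
        raise FormatError(f"{name}: empty table")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise StructuralError(
                f"{name}: ragged CSV: row {i + 1} has {len(row)} fields, "
                f"expected {width}")
    cells = [Cell(text=v, row=r, col=c)
             for r, row in enumerate(rows) for c, v in enumerate(row)]
    return TableGrid(cells=cells, n_rows=len(rows), n_cols=width,
                     n_header_rows=n_header_rows, n_header_cols=n_header_cols,
                     caption=caption, footnotes=list(footnotes))


def grid_from_html(text: str, n_header_rows: int = 1,
                   n_header_cols: int = 1) -> TableGrid:
    """Parse the first <table> element in an HTML fragment.

    thead rows become header rows (overriding ``n_header_rows``);
    rowspan/colspan are recorded on the cells.  The caption element and
    any <tfoot> cell texts become caption/footnotes.
    """
    try:
        doc = lxml_html.fromstring(text)
    except etree.ParserError as exc:
        raise FormatError(f"invalid HTML: {exc}") from exc
    tables = doc.xpath("//table")
    if not tables:
        raise FormatError("no <table> element found")
    table = tables[0]
    caption_el = table.find("caption")
    caption = (caption_el.text_content().strip() if caption_el is not None
               else "")
    footnotes = [td.text_content().strip()
                 for td in table.xpath("tfoot//td | tfoot//th")
                 if td.text_content().strip()]

    head_rows = table.xpath("thead/tr")
    body_rows = table.xpath("tbody/tr") or [
        tr for tr in table.xpath("tr") if tr not in head_rows]
    all_rows = list(head_rows) + list(body_rows)
    if head_rows:
        n_header_rows = len(head_rows)

    cells: list[Cell] = []
    occupied: set[tuple[int, int]] = set()
    for r, tr in enumerate(all_rows):
        c = 0
        for el in tr.xpath("td | th"):
            while (r, c) in occupied:
                c += 1
            rs = int(el.get("rowspan", 1) or 1)
            cs = int(el.get("colspan", 1) or 1)
            cells.append(Cell(text=el.text_content(), row=r, col=c,
                              row_span=rs, col_span=cs))
            for rr in range(r, r + rs):
                for cc in range(c, c + cs):
                    occupied.add((rr, cc))
            c += cs
    n_rows = len(all_rows)
    n_cols = max((c + 1 for _, c in occupied), default=0)
    return TableGrid(cells=cells, n_rows=n_rows, n_cols=n_cols,
                     n_header_rows=min(n_header_rows, max(n_rows - 1, 0)),
                     n_header_cols=n_header_cols,
                     caption=caption, footnotes=footnotes)


def grid_to_csv(grid: TableGrid, delim: str = ",") -> str:
    """Render an expanded grid as CSV (quoting preserves whitespace)."""
    mat = expand_spans(grid).cell_matrix()
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delim, quoting=csv.QUOTE_MINIMAL,
                        lineterminator="\n")
    for row in mat:
        writer.writerow(row)
    return buf.getvalue()


def grid_to_html(grid: TableGrid) -> str:
    """Render a grid as an HTML table with spans, caption and footnotes."""
    g = grid
    covered: set[tuple[int, int]] = set()
    by_pos = {(c.row, c.col): c for c in g.cells}
    for c in g.cells:
        for r in range(c.row, c.row + c.row_span):
            for k in range(c.col, c.col + c.col_span):
                if (r, k) != (c.row, c.col):
                    covered.add((r, k))
    out = ["<table>"]
    if g.caption:
        out.append(f"  <caption>{_esc(g.caption)}</caption>")
    def render_row(r: int, tag: str) -> str:
        tds = []
        for k in range(g.n_cols):
            if (r, k) in covered:
                continue
            cell = by_pos.get((r, k))
            text = _esc(cell.text) if cell else ""
            attrs = ""
            if cell and cell.row_span > 1:
                attrs += f' rowspan="{cell.row_span}"'
            if cell and cell.col_span > 1:
                attrs += f' colspan="{cell.col_span}"'
            tds.append(f"<{tag}{attrs}>{text}</{tag}>")
        return "    <tr>" + "".join(tds) + "</tr>"
    if g.n_header_rows:
        out.append("  <thead>")
        for r in range(g.n_header_rows):
            out.append(render_row(r, "th"))
        out.append("  </thead>")
    out.append("  <tbody>")
    for r in range(g.n_header_rows, g.n_rows):
        out.append(render_row(r, "td"))
    out.append("  </tbody>")
    if g.footnotes:
        out.append("  <tfoot>")
        for fn in g.footnotes:
            out.append(f'    <tr><td colspan="{g.n_cols}">{_esc(fn)}</td></tr>')
        out.append("  </tfoot>")
    out.append("</table>")
    return "\n".join(out)


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def write_table(grid: TableGrid, path: Union[str, Path],
                format: Optional[str] = None) -> None:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".html": "html",
                  ".json": "grid-json"}.get(path.suffix.lower(), "grid-json")
    if format == "grid-json":
        path.write_text(grid.to_json() + "\n", encoding="utf-8")
    elif format in ("csv", "tsv"):
        path.write_text(grid_to_csv(grid, "\t" if format == "tsv" else ","),
                        encoding="utf-8")
    elif format == "html":
        path.write_text(grid_to_html(grid) + "\n", encoding="utf-8")
    else:
        raise FormatError(f"unknown table format {format!r}")
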