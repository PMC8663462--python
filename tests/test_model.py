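"""Grid substrate: span expansion, indentation, interchange round-trips."""

import pytest
from random import Random

from tablescout.model import (
    Cell,
    StructuralError,
    TableGrid,
    expand_spans,
    grids_equal,
    indent_level,
)
from tablescout.synth import SyntheticSpec, generate_table, sample_article_style


def _grid(cells, n_rows, n_cols, **kw):
    kw.setdefault("n_header_rows", 1)
    kw.setdefault("n_header_cols", 0 if n_cols == 1 else 1)
    return TableGrid(cells, n_rows, n_cols, **kw)


class TestExpandSpans:
    def test_colspan_replicates_text(self):
        g = TableGrid(
            [Cell("", 0, 0), Cell("Arm A", 0, 1, col_span=2),
             Cell("x", 1, 0), Cell("1", 1, 1), Cell("2", 1, 2)],
            2, 3)
        mat = expand_spans(g).cell_matrix()
        assert mat[0][1] == "Arm A" and mat[0][2] == "Arm A"

    def test_spanless_grid_unchanged(self):
        g = TableGrid([Cell(str(i), r, c) for i, (r, c) in
                       enumerate((r, c) for r in range(2) for c in range(2))],
                      2, 2)
        assert grids_equal(expand_spans(g), g)

    def test_rowspan_covers_each_position_exactly_once(self):
        # oracle: enumerate covered positions of the sparse layout
        sparse = [Cell("h0", 0, 0), Cell("h1", 0, 1), Cell("h2", 0, 2),
                  Cell("tall", 1, 0, row_span=2),
                  Cell("a", 1, 1), Cell("b", 1, 2),
                  Cell("c", 2, 1), Cell("d", 2, 2)]
        covered = {}
        for cell in sparse:
            for r in range(cell.row, cell.row + cell.row_span):
                for k in range(cell.col, cell.col + cell.col_span):
                    assert (r, k) not in covered
                    covered[(r, k)] = cell.text
        g = expand_spans(TableGrid(sparse, 3, 3))
        assert len(g.cells) == 9
        for cell in g.cells:
            assert cell.text == covered[(cell.row, cell.col)]
            assert cell.row_span == cell.col_span == 1

    def test_idempotent(self):
        g = TableGrid([Cell("", 0, 0), Cell("A", 0, 1, col_span=2),
                       Cell("x", 1, 0), Cell("1", 1, 1), Cell("2", 1, 2)],
                      2, 3)
        once = expand_spans(g)
        assert grids_equal(expand_spans(once), once)

    def test_overlap_reports_coordinates(self):
        g = TableGrid([Cell("a", 0, 0, col_span=2), Cell("b", 0, 1),
                       Cell("x", 1, 0), Cell("y", 1, 1)], 2, 2)
        with pytest.raises(StructuralError, match=r"\(0,1\)"):
            expand_spans(g)

    def test_span_outside_grid_rejected(self):
        g = TableGrid([Cell("a", 0, 0, col_span=3), Cell("x", 1, 0),
                       Cell("y", 1, 1)], 2, 2)
        with pytest.raises(StructuralError):
            expand_spans(g)


@pytest.mark.parametrize("text,level", [
    ("Age", 0), ("  Yes", 1), ("\tYes", 1), ("    Deep", 2),
    ("  Indented", 1), (" Single", 0), ("", 0),
])
def test_indent_level(text, level):
    assert indent_level(text) == level


def test_grid_json_roundtrip_on_generated_tables():
    spec = SyntheticSpec()
    rng = Random(5)
    for _ in range(25):
        style = sample_article_style(spec, rng)
        grid, _ = generate_table(spec, rng, style=style)
        back = TableGrid.from_json(grid.to_json())
        assert grids_equal(grid, back)


def test_header_prefix_invariants():
    with pytest.raises(ValueError):
        TableGrid([Cell("a", 0, 0)], 1, 1, n_header_rows=1, n_header_cols=0)
    with pytest.raises(ValueError):
        TableGrid([Cell("a", 0, 0)], 0, 1)


def test_arm_and_timepoint_invariants():
    from tablescout.model import Arm, ArmLabelKind, TimePoint, TimePointLabelKind
    with pytest.raises(ValueError):
        Arm("X", ArmLabelKind.FULL_NAME, size=10)  # size without source
    with pytest.raises(ValueError):
        TimePoint("Baseline", TimePointLabelKind.PRE_POST, unit="month")
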