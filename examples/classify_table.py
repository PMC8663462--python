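"""Classify a table's measurement-context structure.

Builds two small grids by hand — a 1x1 baseline table (elements on rows,
arms on columns, sizes embedded in the arm headers) and a 2x1 outcome
table (arms nested in elements on rows, time points on columns) — and
shows which context kinds the detectors assign to each axis.
"""

from tablescout import (
    Cell,
    TableGrid,
    assign_context_kinds,
    classify_structure,
)

baseline = TableGrid(
    cells=[
        Cell("Characteristic", 0, 0),
        Cell("Placebo (n=25)", 0, 1), Cell("HFNC (n=40)", 0, 2),
        Cell("Age, y, mean ± SD", 1, 0),
        Cell("53.2 ± 9.1", 1, 1), Cell("51.8 ± 8.7", 1, 2),
        Cell("Mortality, n (%)", 2, 0),
        Cell("2 (8.0)", 2, 1), Cell("3 (7.5)", 2, 2),
    ],
    n_rows=3, n_cols=3, n_header_rows=1, n_header_cols=1,
    caption="Baseline characteristics of the study arms.",
)

outcome = TableGrid(
    cells=[
        Cell("", 0, 0), Cell("Baseline", 0, 1), Cell("6 months", 0, 2),
        Cell("Pain score", 1, 0), Cell("", 1, 1), Cell("", 1, 2),
        Cell("  Placebo (n=25)", 2, 0),
        Cell("6.1 ± 1.2", 2, 1), Cell("4.9 ± 1.4", 2, 2),
        Cell("  HFNC (n=40)", 3, 0),
        Cell("6.0 ± 1.1", 3, 1), Cell("3.2 ± 1.5", 3, 2),
    ],
    n_rows=4, n_cols=3, n_header_rows=1, n_header_cols=1,
    caption="Pain outcomes.",
)

for name, grid in [("baseline", baseline), ("outcome", outcome)]:
    assignment = assign_context_kinds(grid)
    structure = classify_structure(assignment)
    rows = "+".join(k.value for k in structure.row_kinds)
    cols = "+".join(k.value for k in structure.col_kinds)
    print(f"{name} table:")
    print(f"  rows carry: {rows}; columns carry: {cols}")
    print(f"  class {structure.cls.value}  ({structure.sublayout})")
    sizes = [a.arm_size for a in assignment.annotations
             if a.arm_size is not None]
    print(f"  arm sizes found in headers: {sizes}\n")

print("The class counts context kinds per axis: one kind on each axis is")
print("1x1; two nested kinds on rows is 2x1; two on columns is 1x2.")
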