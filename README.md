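# tablescout

Structure and statistic-format recognition for tables in the comparative
clinical literature.

Most of the quantitative evidence in a randomized controlled trial report
lives in its tables, and extracting it means answering three questions
about every cell: *what* is being measured (the data element), *for whom*
(the arm), and *when* (the time point). `tablescout` is a toolkit for
people building or studying automated data extraction for systematic
reviews. It provides:

- **A table model** — a rectangular cell grid with header prefixes,
  row/column spans, captions and footnotes, read from CSV/TSV, HTML, or a
  grid-JSON interchange format.
- **Measurement-context detection** — detectors for embedded arm sizes
  ("Placebo [n=25]"), intervention-label styles (full name, abbreviation,
  control/experimental, coded), time-point labels ("6-month follow-up",
  "Pre/Post", "t_2"), and category-label placement (indented under the
  header, separate array, slash-joined in one cell).
- **Layout classification** — each table axis carries an ordered list of
  context kinds; the (rows × columns) pair maps onto a taxonomy of
  **1×1**, **2×1** and **1×2** contexts covering fifteen named
  sub-layouts (e.g. "TPs nested in DEs on rows, arms on columns"), with
  stratified and comparative-only tables classified as "other".
- **A statistic-format grammar** — a catalog of the printed micro-formats
  for continuous (mean ± SD, mean (SD), median (IQR; p25–p75), …),
  dichotomous (n (%), n/(N−n), …) and categorical metrics, with exact
  parsing, rendering, declaration matching ("Data are presented as mean ±
  SD") and array-level inference.
- **Count arithmetic** — consistency checking of printed percentages
  against round-half-up(100·n/N), and denominator derivation: the set of
  N with round(100·n/N) equal to the printed percentage, which recovers
  missing arm sizes from n (%) metrics.
- **Corpus tagging and summaries** — a fixed hierarchical tag vocabulary,
  Boolean tag queries (AND/OR/NOT, parent tags match descendants), and
  frequency tables with 95% **Wilson score intervals**
  (no continuity correction):

  center = (p̂ + z²/2n)/(1 + z²/n), half-width = z/(1 + z²/n) ·
  √(p̂(1−p̂)/n + z²/4n²).

- **A synthetic table generator** — annotated RCT baseline/outcome tables
  whose layout, label and format distributions default to frequencies
  observed in published trials, with full ground truth for every rendered
  metric. The generator is the oracle for the whole pipeline: on
  noise-free tables, extraction recovers layout, context, arm sizes and
  metric constituents exactly.

## Worked example

```python
from tablescout import (Cell, TableGrid, extract_table,
                        FORMATS_BY_ID, parse_metric, derive_denominator,
                        wilson_ci)

grid = TableGrid(
    cells=[
        Cell("Characteristic", 0, 0),
        Cell("Placebo (n=25)", 0, 1), Cell("HFNC (n=40)", 0, 2),
        Cell("Age, y, mean ± SD", 1, 0),
        Cell("53.2 ± 9.1", 1, 1), Cell("51.8 ± 8.7", 1, 2),
        Cell("Mortality, n (%)", 2, 0),
        Cell("2 (8.0)", 2, 1), Cell("3 (7.5)", 2, 2),
    ],
    n_rows=3, n_cols=3, n_header_rows=1, n_header_cols=1,
    caption="Baseline characteristics of the study arms.")

result = extract_table(grid)
print(result.structure.cls.value, "|", result.structure.sublayout)
print([(a.label, a.size) for a in result.arms])
m = result.metrics[2]
print(m.context.data_element.name, m.context.arm.label, m.stats.to_dict())
```

prints

```
1x1 | DEs on rows, arms on columns
[('Placebo', 25), ('HFNC', 40)]
Mortality Placebo {'kind': 'dichotomous', 'n': 2, 'n_total': None, 'pct': 8.0}
```

The table is a 1×1 context (data elements label the rows, arms the
columns), the arm sizes were read out of the intervention headers, and
the mortality cell parsed into its subset count and percentage using the
n (%) format declared in its row header.

Two more one-liners show the statistics side:

```python
>>> parse_metric("2/59 (3.4%)", FORMATS_BY_ID["n_slash_n_pct"]).to_dict()
{'kind': 'dichotomous', 'n': 2, 'n_total': 59, 'pct': 3.4}
>>> sorted(derive_denominator(n=2, pct=3.4, decimals=1, n_max=1000))
[58, 59]
>>> wilson_ci(66, 78).rounded_pct(0)
(75.0, 91.0)
```

A printed "2/59 (3.4%)" decomposes into subset, total and percentage;
conversely a bare "2 (3.4%)" pins the missing denominator down to
{58, 59}; and 66-of-78 articles with a property gives the 95% score
interval 75%–91%.

The `examples/` directory holds one short narrative script per
capability (metric parsing, table classification, the full extraction
pipeline, corpus tagging and summaries, ground-truth round-trips), and
the `tablescout` command exposes the same operations from the shell
(`parse`, `classify`, `tag`, `summarize`, `generate`, `query`).

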