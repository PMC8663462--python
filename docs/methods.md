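# Methods

This note documents the models and procedures behind `tablescout`: what
each component assumes, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical and design
choices a maintainer would want spelled out.

## The table model

A table is a rectangular grid of cells after span expansion; header rows
and header columns form a prefix of the grid (rows `0..h-1`, columns
`0..k-1`). Coordinates are 0-based and row-major. Span expansion
replicates a spanning cell's text into every covered position; it is
idempotent, rejects overlapping spans naming the offending coordinates,
and fills uncovered positions with empty cells. Rotation and
multi-page overflow are metadata flags carried from the reader, not
detected — the package never sees page images.

Indentation carries meaning: category labels nest under their
categorical data-element header by leading whitespace. One tab, two
spaces, or a pair of non-breaking spaces count as one indent level.
There is no published convention for this metric; two spaces per level
matches common CSV/HTML exports and is cheap to change.

## Measurement context

Every descriptive statistic acquires meaning from a measurement context:
the combination of a **data element** (the characteristic measured), an
**arm** (the intervention group), and a **time point**. A table shows at
most a few of these kinds on its axes; the rest must come from captions,
footnotes or the article text.

Header cells are scored by detectors:

- *Arm size*: `(n=K)`, `[n=K]`, `N = K` and trailing `, n=K`, flexible
  in case and spacing. Stripping the size never otherwise alters the
  label, so strip-and-rerender is idempotent.
- *Time point*: an amount plus a unit from the time lexicon
  ("6-month follow-up" → amount 6, unit month), the pre/post lexicon
  (baseline, follow-up, before/after, …), or incremental patterns
  (`t_2`, `Visit 3`, roman numerals).
- *Intervention label style*: control/experimental terms; an
  abbreviation heuristic (≤6 characters, ≥2 uppercase, single token, not
  a known intervention name) or a user-supplied abbreviation list; full
  names from the intervention lexicon or long/multi-word labels; coded
  labels ("Group A") and the rest are "alternate". "Placebo" is
  classified as a full intervention name rather than a control term; the
  control lexicon is a plain-text file, so corpora that treat placebo
  arms as controls can override it.

Each nesting level of each axis (header rows for columns; indentation
levels, extra header columns, and group-header rows for rows) is
labelled by majority vote of its cells, with precedence arm-size >
time-point > intervention lexicon and data element as the fallback for
unscored levels. Ties follow the same precedence. Nesting is recognized
from spanning header cells, indentation, or a repeating label cycle;
when a header is both spanned and indented, spans win — a choice, since
no counting rule for that case is published.

Two kinds fused in a single header cell ("Baseline BMI",
"Placebo (n=25), 6 months") mark the axis *embedded*. A label is only
split when the remainder is not itself a time expression, so pure time
labels like "6-month follow-up" never split.

The (row kinds, column kinds, embedded) triple maps onto the taxonomy:
**1×1** (one kind per axis), **2×1** (two nested kinds on rows), **1×2**
(two on columns), with fifteen named sub-layouts; stratified tables
(subgroup labels such as sex or site on an axis — detected best-effort
from a subgroup lexicon, or asserted by the caller) and tables reporting
only comparative statistics (all value columns match an inferential
lexicon: p-values, differences, ratios) are "other". More than two
kinds on an axis is "other" with reason `unsupported_depth`. A single
pooled column ("All patients (n=64)") is still an arm axis but is not
arm-level breakout.

## The statistic-format grammar

Each printed micro-format is a token pattern over numeric placeholders
(MEAN, SD, MEDIAN, P25, P75, MIN, MAX, N, N_TOTAL, PCT, CI_LO, CI_HI)
and literal delimiters. The catalog holds fourteen continuous formats
(seven mean-family, seven median-family), six dichotomous, two
categorical, and the extension format `n/N (%)` for fully explicit
subset/total/percentage strings. Two bookkeeping notes:

- `n/(N−n)` prints the complement count; the parser exposes an internal
  REST placeholder and folds it back into `n_total = n + rest`.
- "Median (IQR)" keeps its own id with the same token shape as the
  dash-separated quartile variant; the printed names are distinct even
  where the semantics coincide, and inference tie-breaks by catalog
  order (the mean-CI format sits last among continuous formats because
  its shape `x (a-b)` collides with the median/range family).

Parsing normalizes unicode first (`+/-` and U+00B1 to ±; minus, en- and
em-dashes to `-`; non-breaking spaces collapsed), accepts `to` and comma
as interval separators, and binds every placeholder in order or fails
with the furthest-match position — never a partial result. The decimal
separator is `.` only. Count placeholders accept integers only, which
is also the typographic prior used for disambiguation (below).
Rendering is the exact inverse at a fixed printed precision, so
render→parse round-trips recover every tuple.

Format resolution for a metric array uses, in order: a declaration in
the array's own header ("Age, y, mean ± SD" — comma-splitting is
bracket-aware so "median [IQR; 25th percentile, 75th percentile]"
survives); constituent column headers (Mean | SD); declarations scanned
from footnotes or descriptions; and finally inference over the array's
cells. Among candidates matching every cell, typographic agreement
ranks first: count formats pair with integer-leading cells, continuous
formats with decimal-leading cells, and a leading-percentage format
requires the % sign; remaining ties fall back to candidate order. A
single number with no declaration anywhere is reported "uninferable"
rather than guessed.

Percentage arithmetic uses round-half-up at the printed number of
decimals (how authors round): a printed percentage is *consistent* iff
it equals round-half-up(100·n/N, d), and denominator derivation returns
every N in [n, n_max] satisfying that relation (vectorized; exact for
the ranges involved, since quotients of small integers stay far from
rounding boundaries relative to double precision).

## Tags, queries and summaries

Tags are path-like ids in a fixed hierarchy (structure, context, metric
families); a child implies its parent and tagging operations close over
ancestors, so assignments are valid by construction. A table with no
descriptive statistics gets no structure tags. Within one table the
*lower* classification wins for format/units location (a footnote
declaration outranks a header one); across tables the article unions
everything, so an article can legitimately carry both location tags.

Boolean queries use NOT > AND > OR precedence with parentheses; a
parent tag matches when any descendant is present. Frequency summaries
count per article, per table, or per *relevant* article (denominator
restricted to articles holding the tag's parent), and attach 95% Wilson
score intervals **without continuity correction** — the variant that
reproduces printed intervals such as 66/78 → 75%–91% and 4/99 →
1.6%–9.9%, which the corrected interval does not. Reported percentages
round half-up to the printed precision.

The high-information-density classification is the conjunction:
baseline or outcomes in a table; arm sizes reported; intervention
labels full-name or abbreviation (droppable via a flag); units reported
where relevant (or no unit-relevant elements); statistic format
declared.

## The synthetic generator

The generator emulates RCT baseline/outcome tables at the observed
frequencies: seventeen layout buckets (fifteen named sub-layouts plus
stratified and comparative-only) with the dominant
elements-on-rows/arms-on-columns layout at 90/174; arm sizes embedded
50, separate array 6, description-only 1, absent 20 (of 77);
intervention label styles 26/25/23/3; time-point styles 24/22/6; format
declarations in header 35, footnote 30, absent 12; units in header 55,
footnote 9, with 64/75 of continuous-metric articles unit-relevant;
category-label placements 35/7/7/1; article composition from the
both/baseline-only/outcome-only/none margins (61/5/11/1 of 78) with
extra-table probabilities giving ≈174 tables per 78 articles.

Style attributes are sampled once per article (authors are consistent);
the layout is sampled per table. Formats are sampled per article and
family; each continuous element is median-family with probability
22/95, which makes the per-element marginal exactly proportional to the
combined observed counts. True values are drawn from per-element normal
summaries (the generator emits summaries only, never patient-level
records); counts are binomial in the arm size, and every rendered
percentage is computed by the same half-up rule the checker verifies,
so consistency holds by construction. All randomness flows through one
`random.Random` stream — integer/uniform draws only, no iteration-order
dependence — so corpora are byte-identical across platforms for a fixed
seed.

Deliberate modelling choices, with their consequences:

- *Separate-array constituents* (Mean | SD or n | % sub-columns) render
  only in layouts whose column axis carries arms/time points; elsewhere
  the parenthesized sibling format substitutes. The marginal frequency
  distortion is well inside the 3-standard-error band used by the
  recovery tests.
- *Undeclared articles* (no format declaration anywhere) draw from the
  self-identifying subset of formats — those whose rendered shape is
  unique under the integer-count/decimal-continuous convention. The
  colliding family (mean with CI, median with range, unspecified IQR)
  appears only in declaring articles. Rationale: an author who prints
  `14 (10-18)` with no note relies on the reader knowing the
  convention; a noise-free recovery contract over strings that even a
  human cannot disambiguate would be vacuous.
- *Pooled (no-breakout) baseline tables* are generated as a variant of
  the dominant layout, with probability conditional on that layout so
  that both the layout distribution and the 2-in-67 no-breakout rate
  hold exactly.
- *Participant-level tables* (1 of 174 observed) are present in the tag
  vocabulary but generated with probability 0 by default: their row
  axis is a participant identifier, which is none of the three context
  kinds, so no layout ground truth can be assigned.
- *Unindented ("same array") category labels* are rendered but ground
  truth records what the table shows — sibling rows indistinguishable
  from dichotomous elements — because no syntactic cue separates them.
- Arm names come from a small intervention pool that also seeds the
  default detection lexicon. On real corpora, bare full-name arm
  detection requires a domain lexicon (or size/label cues); this
  coupling is what lets noise-free recovery be exact, and it is the
  main thing passing tests do *not* establish about wild data. The
  same applies to the caption conventions used for baseline/outcome
  role detection and for single-element arm×time tables.

Noise knobs (`missing_cell_prob`, `unicode_variant_prob`,
`rounding_decimals`) default to the noise-free setting; the recovery
contract is stated for that setting, and the typographic prior degrades
gracefully but not perfectly at 0 rendered decimals.

## Verification and problem sizes

The round-trip verifier compares extraction output against ground truth
cell by cell: layout class and named sub-layout, axis kinds, embedded
flag, rendered arm sizes, and every metric's format and constituents at
printed precision (floats compared at 1e-9, which is exact for values
re-parsed from their own rendering). The test suite runs 500 noise-free
tables for the recovery contract (a few seconds), a ≈1050-table corpus
for layout/format frequency recovery at 3 binomial standard errors
(format frequencies are counted per relevant article, the unit the
observed distributions are stated in), a 78-article corpus for the
density-rate product check, exhaustive denominator-derivation
equivalence against a rational-arithmetic oracle (n ≤ 50, every
1-decimal percentage, N ≤ 1000), and 1000 random Boolean expressions
against a truth-table oracle. These sizes keep the full suite under
half a minute while leaving the statistical bands meaningful.

## Known limitations

- Detection quality on real tables is bounded by the lexicons; the
  shipped ones are deliberately small.
- Abbreviations are not resolved against article full text; supply a
  lexicon if you have one.
- Inferential statistics (p-values, effect sizes with CIs beyond the
  mean-CI format) are recognized only to classify comparative-only
  tables, never parsed.
- Multi-page tables are honored as a flag; reconstruction across pages
  is out of scope, as is any PDF or image ingestion.
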