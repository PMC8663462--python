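"""End-to-end table extraction: grid in, classified metrics out.

Runs the full pipeline on one table: expand the grid, assign context
kinds to both axes, classify the structure, recover arms (with sizes),
time points and data elements from the headers, resolve each data
element's statistic format (declared in its header, implied by
constituent columns, declared in a footnote, or inferred from the metric
array), and parse every body cell into its constituent statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import formats as F
from .context import (
    ContextAssignment,
    assign_context_kinds,
    classify_structure,
    classify_intervention_label,
    classify_timepoint_label,
    detect_arm_size,
    detect_category_structure,
    parse_de_label,
    split_embedded_parts,
)
from .formats import (
    CATALOG,
    CategoryLabelPlacement,
    MetricKind,
    ParseError,
    StatisticFormat,
    categorical_equivalent,
    parse_metric,
    scan_declarations,
)
from .lexicons import DEFAULT, Lexicons
from .model import (
    Arm,
    ArmSizeSource,
    ContextKind,
    ContextStructure,
    DataElement,
    DataElementKind,
    MeasurementContext,
    StructureClass,
    TableGrid,
    TimePoint,
    TimePointLabelKind,
    expand_spans,
    indent_level,
)

__all__ = ["ExtractedMetric", "ExtractionResult", "extract_table"]


@dataclass
class ExtractedMetric:
    """One parsed metric anchored at a grid cell."""

    row: int
    col: int
    raw_text: str
    context: MeasurementContext
    stats: object
    format: StatisticFormat
    provenance: str  # "declared" | "constituent" | "inferred"
    category: Optional[str] = None


@dataclass
class ExtractionResult:
    grid: TableGrid
    assignment: ContextAssignment
    structure: ContextStructure
    arms: list[Arm] = field(default_factory=list)
    time_points: list[TimePoint] = field(default_factory=list)
    data_elements: list[DataElement] = field(default_factory=list)
    metrics: list[ExtractedMetric] = field(default_factory=list)
    role: Optional[str] = None  # "baseline" | "outcome"
    secondary_only: bool = False
    format_in_header: bool = False
    format_in_footnote: bool = False
    units_in_header: bool = False
    units_in_footnote: bool = False
    category_placements: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "structure": {
                "cls": self.structure.cls.value,
                "row_kinds": [k.value for k in self.structure.row_kinds],
                "col_kinds": [k.value for k in self.structure.col_kinds],
                "embedded": self.structure.embedded,
                "other_reason": (self.structure.other_reason.value
                                 if self.structure.other_reason else None),
                "sublayout": self.structure.sublayout,
            },
            "role": self.role,
            "arms": [
                {"label": a.label, "label_kind": a.label_kind.value,
                 "size": a.size,
                 "size_source": a.size_source.value if a.size_source else None}
                for a in self.arms
            ],
            "time_points": [
                {"label": t.label, "label_kind": t.label_kind.value,
                 "amount": t.amount, "unit": t.unit}
                for t in self.time_points
            ],
            "data_elements": [
                {"name": d.name, "kind": d.kind.value, "unit": d.unit,
                 "categories": d.categories}
                for d in self.data_elements
            ],
            "metrics": [
                {
                    "row": m.row, "col": m.col, "text": m.raw_text,
                    "format": m.format.id, "provenance": m.provenance,
                    "category": m.category,
                    "data_element": m.context.data_element.name,
                    "arm": m.context.arm.label if m.context.arm else None,
                    "time_point": (m.context.time_point.label
                                   if m.context.time_point else None),
                    "stats": m.stats.to_dict(),
                }
                for m in self.metrics
            ],
            "warnings": list(self.warnings),
        }


_UNITS_FOOTNOTE_RE = re.compile(r"^\s*units?\s*:", re.IGNORECASE)


def _caption_de_name(caption: str) -> str:
    text = caption.split(":", 1)[1] if ":" in caption else caption
    cut = text.casefold().find(" by ")
    if cut >= 0:
        text = text[:cut]
    text = text.strip().rstrip(".")
    return text or "table metric"


def _caption_role(caption: str, lexicons: Lexicons) -> tuple[Optional[str], bool]:
    c = caption.casefold()
    secondary = "secondary outcome" in c and "primary" not in c
    if any(t in c for t in lexicons.outcome_caption):
        return "outcome", secondary
    if any(t in c for t in lexicons.baseline_caption):
        return "baseline", False
    return None, False


def _integer_first(text: str) -> Optional[bool]:
    m = re.search(r"\d+(\.\d+)?", F.normalize_text(text))
    if not m:
        return None
    return m.group(1) is None


_COUNT_KINDS = (MetricKind.DICHOTOMOUS, MetricKind.CATEGORICAL)


def _resolve_array_format(
    cells: list[str],
    declared: list[StatisticFormat],
) -> Optional[tuple[StatisticFormat, str]]:
    """Pick the format for one metric array.

    Candidates are the declared formats when any were found, otherwise the
    whole catalog.  Among candidates matching the cells, typographic
    agreement ranks first: count formats pair with integer-leading cells,
    continuous formats with decimal-leading cells (counts are printed as
    integers; continuous summaries carry decimals).  Remaining ties fall
    back to candidate order.
    """
    texts = [t for t in cells if t and t.strip()]
    if not texts:
        return None
    pool = declared if declared else [f for f in CATALOG if not f.multi_array]
    provenance = "declared" if declared else "inferred"
    res = F.infer_format(texts, candidates=pool)
    if res is None or res.score == 0.0:
        if declared:  # declared formats may not cover this array; infer
            return _resolve_array_format(cells, [])
        return None
    candidates = [res.format] + res.ties
    first_flags = [f for f in (_integer_first(t) for t in texts) if f is not None]
    all_int = bool(first_flags) and all(first_flags)
    has_pct_sign = all("%" in t for t in texts)

    def rank(fmt: StatisticFormat) -> tuple[int, int]:
        if fmt.placeholders[0] is F.Placeholder.PCT:
            agree = has_pct_sign  # a leading percentage shows its % sign
        else:
            is_count = fmt.metric_kind in _COUNT_KINDS
            agree = (is_count and all_int) or (not is_count and not all_int)
        return (0 if agree else 1, pool.index(fmt))

    return min(candidates, key=rank), provenance


def _make_time_point(label: str, lexicons: Lexicons) -> TimePoint:
    res = classify_timepoint_label(label, lexicons)
    if res is None:
        return TimePoint(label=label.strip(),
                         label_kind=TimePointLabelKind.INCREMENTAL)
    kind, amount, unit = res
    return TimePoint(label=label.strip(), label_kind=kind,
                     amount=amount, unit=unit)


def extract_table(grid: TableGrid, lexicons: Lexicons = DEFAULT) -> ExtractionResult:
    """Run the full extraction pipeline on one table."""
    g = expand_spans(grid)
    a = assign_context_kinds(g, lexicons)
    structure = classify_structure(a)
    mat = g.cell_matrix()
    data_rows = [r for r in range(g.n_header_rows, g.n_rows)]
    data_cols = [c for c in range(g.n_header_cols, g.n_cols)]
    res = ExtractionResult(grid=g, assignment=a, structure=structure)
    res.role, res.secondary_only = _caption_role(g.caption, lexicons)
    warnings = res.warnings

    footnote_decls: list[StatisticFormat] = []
    for fn in g.footnotes:
        if _UNITS_FOOTNOTE_RE.match(fn):
            res.units_in_footnote = True
            continue
        footnote_decls.extend(scan_declarations(fn))
    res.format_in_footnote = bool(footnote_decls)

    if structure.cls is StructureClass.OTHER and \
            structure.other_reason is not None and \
            structure.other_reason.value == "comparative_only":
        warnings.append("W_COMPARATIVE_ONLY: inferential columns are not parsed")
        return res

    arms: dict[str, Arm] = {}
    time_points: dict[str, TimePoint] = {}

    def get_arm(raw_label: str, source_hint: ArmSizeSource = ArmSizeSource.EMBEDDED) -> Arm:
        label, size = detect_arm_size(raw_label)
        if label not in arms:
            arms[label] = Arm(
                label=label,
                label_kind=classify_intervention_label(label, lexicons=lexicons),
                size=size,
                size_source=source_hint if size is not None else None,
            )
        return arms[label]

    def get_tp(raw_label: str) -> TimePoint:
        key = raw_label.strip()
        if key not in time_points:
            time_points[key] = _make_time_point(raw_label, lexicons)
        return time_points[key]

    # ---- column contexts -------------------------------------------------
    col_arm: dict[int, Optional[Arm]] = {c: None for c in data_cols}
    col_tp: dict[int, Optional[TimePoint]] = {c: None for c in data_cols}
    col_de: dict[int, Optional[dict]] = {c: None for c in data_cols}
    col_embedded = a.embedded and len(a.col_levels) == 2 and \
        a.col_levels[0].labels == a.col_levels[1].labels
    seen_levels = a.col_levels[:1] if col_embedded else a.col_levels
    for i, c in enumerate(data_cols):
        if c in a.size_array_cols:
            continue
        if col_embedded:
            label = a.col_levels[0].labels[i]
            if not label.strip():
                continue
            parts = split_embedded_parts(label, lexicons)
            if parts is None:
                warnings.append(f"W_EMBEDDED_SPLIT: cell text {label!r}")
                continue
            time_text, rest = parts
            col_tp[c] = get_tp(time_text)
            if a.col_levels[0].kind is ContextKind.ARM:
                col_arm[c] = get_arm(rest)
            else:
                name, unit, fmt = parse_de_label(rest)
                col_de[c] = {"name": name, "unit": unit, "fmt": fmt}
            continue
        for lv in seen_levels:
            label = lv.labels[i]
            if not label.strip():
                continue
            if lv.kind is ContextKind.ARM:
                col_arm[c] = get_arm(label)
            elif lv.kind is ContextKind.TIME_POINT:
                col_tp[c] = get_tp(label)
            else:
                name, unit, fmt = parse_de_label(label.strip())
                col_de[c] = {"name": name, "unit": unit, "fmt": fmt}
                if unit:
                    res.units_in_header = True
                if fmt is not None:
                    res.format_in_header = True

    # ---- row contexts ----------------------------------------------------
    # Each metric row maps to (de descriptor | None, arm | None, tp | None,
    # category label | None); group-header rows carry declarations only.
    row_ctx: dict[int, dict] = {}
    row_is_metric: dict[int, bool] = {}
    two_level_rows = len(a.row_levels) == 2
    row_embedded = a.embedded and two_level_rows and not col_embedded
    size_rows = set(a.size_array_rows)

    if g.n_header_cols == 0:
        for r in data_rows:
            row_ctx[r] = {"de": None, "arm": None, "tp": None, "cat": None}
            row_is_metric[r] = True
    elif row_embedded:
        for r in data_rows:
            if r in size_rows:
                continue
            label = mat[r][0]
            if not label.strip():
                continue
            parts = split_embedded_parts(label, lexicons)
            if parts is None:
                warnings.append(f"W_EMBEDDED_SPLIT: cell text {label!r}")
                continue
            time_text, rest = parts
            name, unit, fmt = parse_de_label(rest)
            if unit:
                res.units_in_header = True
            if fmt is not None:
                res.format_in_header = True
            row_ctx[r] = {"de": {"name": name, "unit": unit, "fmt": fmt},
                          "arm": None, "tp": get_tp(time_text), "cat": None}
            row_is_metric[r] = True
    elif two_level_rows:
        outer_kind = a.row_levels[0].kind
        inner_kind = a.row_levels[1].kind
        current_outer: Optional[str] = None
        for r in data_rows:
            if r in size_rows:
                continue
            label = mat[r][0]
            if not label.strip():
                continue
            if indent_level(label) == 0:
                current_outer = label.strip()
                row_is_metric[r] = False
                if outer_kind is ContextKind.DATA_ELEMENT:
                    name, unit, fmt = parse_de_label(current_outer)
                    if unit:
                        res.units_in_header = True
                    if fmt is not None:
                        res.format_in_header = True
                continue
            ctx = {"de": None, "arm": None, "tp": None, "cat": None}
            for kind, lab in ((outer_kind, current_outer),
                              (inner_kind, label.strip())):
                if lab is None:
                    continue
                if kind is ContextKind.ARM:
                    ctx["arm"] = get_arm(lab)
                elif kind is ContextKind.TIME_POINT:
                    ctx["tp"] = get_tp(lab)
                else:
                    name, unit, fmt = parse_de_label(lab)
                    ctx["de"] = {"name": name, "unit": unit, "fmt": fmt}
            row_ctx[r] = ctx
            row_is_metric[r] = True
    else:
        kind = a.row_levels[0].kind
        if kind in (ContextKind.ARM, ContextKind.TIME_POINT):
            for r in data_rows:
                if r in size_rows or not mat[r][0].strip():
                    continue
                lab = mat[r][0].strip()
                ctx = {"de": None, "arm": None, "tp": None, "cat": None}
                if kind is ContextKind.ARM:
                    ctx["arm"] = get_arm(lab)
                else:
                    ctx["tp"] = get_tp(lab)
                row_ctx[r] = ctx
                row_is_metric[r] = True
        else:
            label_rows = [r for r in data_rows if r not in size_rows]
            labels = [mat[r][0] for r in label_rows]
            secondary = ([mat[r][1] for r in label_rows]
                         if g.n_header_cols >= 2 else None)
            groups = detect_category_structure(labels, secondary)
            cat_of: dict[int, tuple] = {}
            in_cell_of: dict[int, "object"] = {}
            for grp in groups:
                res.category_placements.add(grp.placement)
                if grp.placement == "in_cell":
                    in_cell_of[label_rows[grp.header_index]] = grp
                else:
                    for idx, cat in zip(grp.category_indices, grp.categories):
                        cat_of[label_rows[idx]] = (grp, cat)
            # for separate-array categories the header row is also the
            # first category row, so it stays a metric row
            group_headers = {
                label_rows[grp.header_index]
                for grp in groups if grp.placement == "same_array_indented"
            }
            header_fmt_of: dict[int, Optional[StatisticFormat]] = {}
            for grp in groups:
                hr = label_rows[grp.header_index]
                _, unit, fmt = parse_de_label(mat[hr][0].strip())
                header_fmt_of[hr] = fmt
                if fmt is not None:
                    res.format_in_header = True
            for r in label_rows:
                raw = mat[r][0]
                if r in cat_of:
                    grp, cat = cat_of[r]
                    hr = label_rows[grp.header_index]
                    row_ctx[r] = {"de": {"name": grp.name, "unit": None,
                                         "fmt": header_fmt_of.get(hr),
                                         "group": grp},
                                  "arm": None, "tp": None, "cat": cat}
                    row_is_metric[r] = True
                    continue
                if not raw.strip():
                    continue
                if r in group_headers:
                    row_is_metric[r] = False
                    grp = next(gp for gp in groups
                               if label_rows[gp.header_index] == r)
                    name, unit, fmt = parse_de_label(raw.strip())
                    if unit:
                        res.units_in_header = True
                    if fmt is not None:
                        res.format_in_header = True
                    row_ctx[r] = {"de": {"name": name, "unit": unit,
                                         "fmt": fmt, "group": grp},
                                  "arm": None, "tp": None, "cat": None}
                    continue
                name, unit, fmt = parse_de_label(raw.strip())
                if unit:
                    res.units_in_header = True
                if fmt is not None:
                    res.format_in_header = True
                ctx = {"de": {"name": name, "unit": unit, "fmt": fmt},
                       "arm": None, "tp": None, "cat": None}
                if r in in_cell_of:
                    ctx["de"]["group"] = in_cell_of[r]
                    ctx["de"]["name"] = in_cell_of[r].name
                row_ctx[r] = ctx
                row_is_metric[r] = True

    # ---- separate-array arm sizes ---------------------------------------
    for r in size_rows:
        for c in data_cols:
            txt = mat[r][c].strip()
            if txt.isdigit() and col_arm[c] is not None:
                arm = col_arm[c]
                if arm.size is None:
                    arm.size = int(txt)
                    arm.size_source = ArmSizeSource.SEPARATE_ARRAY
    for c in a.size_array_cols:
        for r, ctx in row_ctx.items():
            txt = mat[r][c].strip()
            if txt.isdigit() and ctx.get("arm") is not None:
                arm = ctx["arm"]
                if arm.size is None:
                    arm.size = int(txt)
                    arm.size_source = ArmSizeSource.SEPARATE_ARRAY

    # ---- constituent columns (separate-array statistic formats) ----------
    constituent_pairs: dict[int, int] = {}
    constituent_fmt: Optional[StatisticFormat] = None
    if a.constituent_labels is not None:
        labels = [l.casefold() for l in a.constituent_labels]
        if "sd" in labels:
            constituent_fmt = F.FORMATS_BY_ID["mean_sd_separate_arrays"]
            primary_names, companion_names = {"mean"}, {"sd"}
        else:
            constituent_fmt = F.FORMATS_BY_ID["n_pct_separate_arrays"]
            primary_names, companion_names = {"n", "no."}, {"%"}
        for i, c in enumerate(data_cols):
            if labels[i] in primary_names:
                for j in range(i + 1, len(data_cols)):
                    if labels[j] in companion_names:
                        constituent_pairs[c] = data_cols[j]
                        break
        res.format_in_header = True

    # ---- assemble metrics ------------------------------------------------
    de_objs: dict[str, DataElement] = {}
    arrays: dict[str, list[tuple[int, int, str, dict, dict]]] = {}

    companion_cols = set(constituent_pairs.values())
    for r in data_rows:
        if not row_is_metric.get(r, False):
            continue
        for c in data_cols:
            if c in a.size_array_cols or c in companion_cols:
                continue
            text = mat[r][c]
            if not text.strip():
                continue
            rctx = row_ctx[r]
            de_desc = rctx["de"] if rctx["de"] is not None else col_de[c]
            if de_desc is None:
                # arm x time layouts name their single data element in the
                # caption ("Outcomes: pain score by study arm ...")
                de_desc = {"name": _caption_de_name(g.caption), "unit": None,
                           "fmt": None}
            key = de_desc["name"].casefold()
            arrays.setdefault(key, []).append((r, c, text, de_desc, rctx))

    for key, items in arrays.items():
        de_desc = items[0][3]
        grp = de_desc.get("group")
        is_categorical = grp is not None
        in_cell = is_categorical and grp.placement == "in_cell"
        declared: list[StatisticFormat] = []
        if constituent_fmt is not None:
            fmt, provenance = constituent_fmt, "constituent"
        elif in_cell:
            resolved = _resolve_in_cell_format(
                [t for _, _, t, _, _ in items], de_desc.get("fmt"),
                grp.categories)
            if resolved is None:
                # not actually slash-joined categories; fall back to a
                # plain metric array
                grp, is_categorical, in_cell = None, False, None
                resolved = _resolve_array_format(
                    [t for _, _, t, _, _ in items], [])
                if resolved is None:
                    warnings.append(
                        f"W_UNINFERABLE: data element {de_desc['name']!r}")
                    continue
            fmt, provenance = resolved
        else:
            if de_desc.get("fmt") is not None:
                declared = [de_desc["fmt"]]
            elif footnote_decls:
                declared = footnote_decls
            resolved = _resolve_array_format([t for _, _, t, _, _ in items],
                                             declared)
            if resolved is None:
                warnings.append(f"W_UNINFERABLE: data element {de_desc['name']!r}")
                continue
            fmt, provenance = resolved

        if is_categorical:
            fmt = categorical_equivalent(fmt)
        if key not in de_objs:
            if is_categorical:
                kind = DataElementKind.CATEGORICAL
                cats = list(grp.categories)
            elif fmt.metric_kind in _COUNT_KINDS:
                kind, cats = DataElementKind.DICHOTOMOUS, None
            else:
                kind, cats = DataElementKind.CONTINUOUS, None
            de_objs[key] = DataElement(name=de_desc["name"], kind=kind,
                                       unit=de_desc.get("unit"),
                                       categories=cats)
        de_obj = de_objs[key]

        for r, c, text, _, rctx in items:
            arm = rctx["arm"] or col_arm[c]
            tp = rctx["tp"] or col_tp[c]
            ctx = MeasurementContext(data_element=de_obj, arm=arm, time_point=tp)
            try:
                if constituent_fmt is not None and c in constituent_pairs:
                    comp_text = mat[r][constituent_pairs[c]]
                    stats = _parse_constituent_pair(fmt, text, comp_text)
                elif is_categorical and grp.placement == "in_cell":
                    stats = parse_metric(text, fmt,
                                         category_labels=grp.categories,
                                         label_placement=CategoryLabelPlacement.IN_CELL)
                else:
                    stats = parse_metric(text, fmt)
            except (ParseError, ValueError) as exc:
                warnings.append(f"W_PARSE_FAIL: cell ({r},{c}) {text!r}: {exc}")
                continue
            res.metrics.append(ExtractedMetric(
                row=r, col=c, raw_text=text, context=ctx, stats=stats,
                format=fmt, provenance=provenance, category=rctx["cat"],
            ))

    res.arms = list(arms.values())
    res.time_points = list(time_points.values())
    res.data_elements = list(de_objs.values())
    if not res.metrics and not warnings:
        warnings.append("W_NO_METRICS: table reports no descriptive statistics")
    return res


def _resolve_in_cell_format(
    cells: list[str],
    declared: Optional[StatisticFormat],
    categories: list[str],
) -> Optional[tuple[StatisticFormat, str]]:
    """Resolve slash-joined categorical cells ("11/9" for labels M/F)."""
    if declared is not None:
        return categorical_equivalent(declared), "declared"
    texts = [t for t in cells if t and t.strip()]
    for fid in ("cat_n", "cat_n_pct"):
        fmt = F.FORMATS_BY_ID[fid]
        try:
            for t in texts:
                parse_metric(t, fmt, category_labels=categories)
            return fmt, "inferred"
        except (ParseError, ValueError):
            continue
    return None


def _parse_constituent_pair(
    fmt: StatisticFormat, primary_text: str, companion_text: str
):
    primary = F.normalize_text(primary_text)
    companion = F.normalize_text(companion_text)
    if fmt.id == "mean_sd_separate_arrays":
        return F.ContinuousStats(central_kind="mean",
                                 mean=float(primary),
                                 sd=float(companion) if companion else None)
    n = int(primary)
    pct = float(companion.rstrip("%")) if companion else None
    return F.DichotomousStats(n=n, pct=pct)
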