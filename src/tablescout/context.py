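"""Measurement-context detection and table-structure classification.

Header text carries the signals that tell rows from columns apart: arm
labels (often with embedded sizes, "Placebo [n=25]"), time-point labels
("Baseline", "6 months", "t_2"), and data-element labels (the fallback
when nothing else fires).  Each header level of each axis is scored by
these detectors; the resulting (row kinds, column kinds) pair is mapped
onto the named sub-layouts of the 1x1/2x1/1x2 taxonomy, with stratified
and comparative-only tables classified as "other".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .lexicons import DEFAULT, Lexicons
from .model import (
    ArmLabelKind,
    Cell,
    ContextKind,
    ContextStructure,
    OtherReason,
    StructureClass,
    TableGrid,
    TimePointLabelKind,
    expand_spans,
    indent_level,
)
from .formats import parse_format_declaration, StatisticFormat

__all__ = [
    "detect_arm_size",
    "classify_intervention_label",
    "classify_timepoint_label",
    "detect_category_structure",
    "assign_context_kinds",
    "classify_structure",
    "ContextAssignment",
    "AxisLevel",
    "HeaderAnnotation",
    "LAYOUTS",
    "layout_tag",
    "HeaderlessError",
    "parse_de_label",
    "CategoryGroup",
]


class HeaderlessError(ValueError):
    """The grid declares no header rows and no header columns."""


# ---------------------------------------------------------------------------
# Cell-level detectors
# ---------------------------------------------------------------------------

_ARM_SIZE_RES = [
    re.compile(r"[\[(]\s*n\s*=\s*(\d+)\s*[\])]", re.IGNORECASE),
    re.compile(r",\s*n\s*=\s*(\d+)\s*$", re.IGNORECASE),
    re.compile(r"\bn\s*=\s*(\d+)", re.IGNORECASE),
]


def detect_arm_size(text: str) -> tuple[str, Optional[int]]:
    """Split an embedded arm size out of a header label.

    Recognizes "(n=K)", "[n=K]", "N = K" and trailing ", n=K" with
    flexible case and spacing.  Returns the label with the size expression
    removed (trimmed) and the size, or ``(text.strip(), None)`` when no
    size expression is present.  Labels without a size pattern are never
    altered beyond trimming.
    """
    for rx in _ARM_SIZE_RES:
        m = rx.search(text)
        if m:
            label = (text[: m.start()] + text[m.end():]).strip()
            label = label.rstrip(",;- ").strip()
            return label, int(m.group(1))
    return text.strip(), None


_ALTERNATE_RE = re.compile(
    r"^(group|arm|cohort)\s+([a-z0-9]|[ivx]+)$", re.IGNORECASE
)


def classify_intervention_label(
    label: str,
    known_full_names: Optional[Sequence[str]] = None,
    known_abbreviations: Optional[Sequence[str]] = None,
    lexicons: Lexicons = DEFAULT,
) -> ArmLabelKind:
    """Classify how an arm header names its intervention.

    Control/experimental-style terms come from the control lexicon;
    abbreviations from a short-all-caps heuristic or a supplied list; full
    names from the intervention lexicon or a long multi-word label.  Coded
    labels like "Group A" and anything else are "alternate".  "Placebo" is
    a full intervention name here, not a control term (the control lexicon
    is configurable if a corpus uses it that way).
    """
    label, _ = detect_arm_size(label)
    key = label.casefold()
    if not key:
        return ArmLabelKind.ALTERNATE
    full_names = {t.casefold() for t in known_full_names} if known_full_names else lexicons.interventions
    if key in lexicons.control_terms:
        return ArmLabelKind.CONTROL_EXPERIMENTAL
    if _ALTERNATE_RE.match(label):
        return ArmLabelKind.ALTERNATE
    if known_abbreviations and key in {t.casefold() for t in known_abbreviations}:
        return ArmLabelKind.ABBREVIATION
    token = label.replace(".", "")
    if (
        len(token) <= 6
        and sum(ch.isupper() for ch in token) >= 2
        and " " not in token
        and key not in full_names
    ):
        return ArmLabelKind.ABBREVIATION
    if key in full_names or " " in label or "-" in label:
        return ArmLabelKind.FULL_NAME
    if len(label) >= 7 and label.isalpha():
        return ArmLabelKind.FULL_NAME
    return ArmLabelKind.ALTERNATE


_UNIT_CANON = {
    "minute": "minute", "minutes": "minute", "min": "minute",
    "hour": "hour", "hours": "hour", "h": "hour", "hr": "hour", "hrs": "hour",
    "day": "day", "days": "day", "d": "day",
    "week": "week", "weeks": "week", "wk": "week", "wks": "week",
    "month": "month", "months": "month", "mo": "month", "mos": "month",
    "year": "year", "years": "year", "y": "year", "yr": "year", "yrs": "year",
}

_NUM_UNIT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*-?\s*([a-z]+)")
_UNIT_NUM_RE = re.compile(r"\b([a-z]+)\s*-?\s*(\d+(?:\.\d+)?)")
_INCREMENTAL_RE = re.compile(
    r"^(?:t|tp|visit|period|phase|time)[ _-]?(\d+|[ivx]+)$", re.IGNORECASE
)
_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5, "vi": 6, "vii": 7,
          "viii": 8, "ix": 9, "x": 10}


def classify_timepoint_label(
    text: str, lexicons: Lexicons = DEFAULT
) -> Optional[tuple[TimePointLabelKind, Optional[float], Optional[str]]]:
    """Recognize a time-point header label.

    Returns ``(unit_of_time, amount, unit)`` when an amount of time with a
    unit is present ("6-month follow-up" -> (unit_of_time, 6, "month")),
    ``(pre_post, None, None)`` for the pre/post lexicon (baseline,
    follow-up, before/after), ``(incremental, k, None)`` for ordered
    labels like "t_2" or "Visit 3", and ``None`` when no rule fires.
    """
    t = text.strip().casefold()
    if not t:
        return None
    for rx, order in ((_NUM_UNIT_RE, "nu"), (_UNIT_NUM_RE, "un")):
        for m in rx.finditer(t):
            word = m.group(2) if order == "nu" else m.group(1)
            num = m.group(1) if order == "nu" else m.group(2)
            if word in lexicons.time_units:
                amount = float(num)
                return (TimePointLabelKind.UNIT_OF_TIME,
                        int(amount) if amount.is_integer() else amount,
                        _UNIT_CANON.get(word, word))
    if t in lexicons.pre_post or (
        "/" in t and all(p.strip() in lexicons.pre_post for p in t.split("/"))
    ):
        return (TimePointLabelKind.PRE_POST, None, None)
    m = _INCREMENTAL_RE.match(text.strip())
    if m:
        token = m.group(1).lower()
        amount = int(token) if token.isdigit() else _ROMAN.get(token)
        return (TimePointLabelKind.INCREMENTAL, amount, None)
    return None


# ---------------------------------------------------------------------------
# Data-element labels and category structure
# ---------------------------------------------------------------------------

def parse_de_label(label: str) -> tuple[str, Optional[str], Optional[StatisticFormat]]:
    """Split a data-element header into (name, unit, declared format).

    Published headers append units and format declarations after commas:
    "Age, y, mean ± SD" or "Mortality, n (%)".  Trailing comma segments
    that resolve as format declarations are taken as such; a remaining
    short segment is the unit.
    """
    parts = [p.strip() for p in label.split(",")]
    name = parts[0]
    unit: Optional[str] = None
    fmt: Optional[StatisticFormat] = None
    used = len(parts)
    # a declaration may itself contain commas ("n, %"; bracketed IQR
    # variants), so try progressively shorter trailing joins first
    for i in range(1, len(parts)):
        candidate = parse_format_declaration(", ".join(parts[i:]))
        if candidate is not None:
            fmt = candidate
            used = i
            break
    for seg in parts[1:used]:
        if unit is None and seg and len(seg) <= 12:
            unit = seg
    return name, unit, fmt


_IN_CELL_RE = re.compile(r"\s((?:[A-Za-z]{1,12}/)+[A-Za-z]{1,12})\s*$")
_IN_CELL_EXCLUDE = {"n", "N", "%"}


def _in_cell_categories(token: str) -> Optional[list[str]]:
    """Category labels from a slash-joined header suffix ("M/F").

    Each part must start with an uppercase letter, which separates
    category lists from slashed units ("ng/mL", "beats/min").
    """
    parts = token.split("/")
    if any(p in _IN_CELL_EXCLUDE or not p[0].isupper() for p in parts):
        return None
    return parts


@dataclass
class CategoryGroup:
    """A categorical data element and the positions of its category rows."""

    header_index: int          # index into the header array
    name: str
    category_indices: list[int] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)
    placement: str = "same_array_indented"  # CategoryLabelPlacement value


def detect_category_structure(
    header_array: Sequence[str],
    secondary_array: Optional[Sequence[str]] = None,
) -> list[CategoryGroup]:
    """Group category labels under their categorical data element.

    Indented labels group under the nearest preceding less-indented label
    (same_array_indented).  A delimited secondary array supplies
    separate_array labels.  Slash-joined labels inside one header
    ("Gender M/F") are in_cell.  Flat arrays yield no groups.
    """
    groups: list[CategoryGroup] = []
    open_group: Optional[CategoryGroup] = None
    base_indent = 0
    for i, raw in enumerate(header_array):
        ind = indent_level(raw)
        text = raw.strip()
        if secondary_array is not None and i < len(secondary_array) and \
                secondary_array[i].strip():
            sec = secondary_array[i].strip()
            if groups and groups[-1].placement == "separate_array" and \
                    not text:
                groups[-1].category_indices.append(i)
                groups[-1].categories.append(sec)
                continue
            if text:
                g = CategoryGroup(i, parse_de_label(text)[0],
                                  [i], [sec], "separate_array")
                groups.append(g)
                open_group = None
                continue
        if ind > base_indent and open_group is not None:
            open_group.category_indices.append(i)
            open_group.categories.append(text)
            continue
        open_group = None
        name_part = parse_de_label(text)[0]
        m = _IN_CELL_RE.search(" " + name_part)
        cats = _in_cell_categories(m.group(1)) if m else None
        if cats is not None:
            name = (" " + name_part)[: m.start() + 1].strip().rstrip(",")
            groups.append(CategoryGroup(i, name or name_part, [i], cats,
                                        "in_cell"))
            continue
        open_group = CategoryGroup(i, parse_de_label(text)[0])
        groups.append(open_group)
    return [g for g in groups if g.categories]


# ---------------------------------------------------------------------------
# Axis analysis
# ---------------------------------------------------------------------------

@dataclass
class HeaderAnnotation:
    row: int
    col: int
    detected_kinds: set[ContextKind] = field(default_factory=set)
    arm_size: Optional[int] = None
    timepoint_kind: Optional[TimePointLabelKind] = None
    intervention_kind: Optional[ArmLabelKind] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.arm_size is not None and self.arm_size <= 0:
            raise ValueError("arm_size must be positive")


@dataclass
class AxisLevel:
    """One nesting level of one axis: a label for every data position."""

    kind: ContextKind
    labels: list[str]              # per data row/column, size expressions kept
    embedded_with: Optional[ContextKind] = None


@dataclass
class ContextAssignment:
    """Ordered context kinds per axis plus the detector by-products."""

    row_levels: list[AxisLevel]
    col_levels: list[AxisLevel]
    embedded: bool = False
    stratified: bool = False
    comparative_only: bool = False
    pooled: bool = False
    constituent_labels: Optional[list[str]] = None  # per data col, if split
    size_array_rows: list[int] = field(default_factory=list)
    size_array_cols: list[int] = field(default_factory=list)
    annotations: list[HeaderAnnotation] = field(default_factory=list)
    n_header_rows: int = 1
    n_header_cols: int = 1

    @property
    def row_kinds(self) -> list[ContextKind]:
        return [lv.kind for lv in self.row_levels]

    @property
    def col_kinds(self) -> list[ContextKind]:
        return [lv.kind for lv in self.col_levels]


_CONSTITUENT_TOKENS = {"mean", "sd", "median", "iqr", "n", "%", "no."}


def _is_arm_label(label: str, lexicons: Lexicons) -> bool:
    stripped, size = detect_arm_size(label)
    if size is not None:
        return True
    kind = classify_intervention_label(stripped, lexicons=lexicons)
    if kind in (ArmLabelKind.CONTROL_EXPERIMENTAL, ArmLabelKind.ABBREVIATION):
        return True
    if kind is ArmLabelKind.ALTERNATE and _ALTERNATE_RE.match(stripped):
        return True
    return stripped.casefold() in lexicons.interventions


def _vote(label: str, lexicons: Lexicons) -> tuple[ContextKind, int]:
    """(kind, priority) for one header label; priority breaks level ties.

    Detector precedence: embedded arm-size pattern (3) > time-point
    lexicon (2) > intervention/arm lexicon (1) > data-element fallback (0).
    """
    stripped, size = detect_arm_size(label)
    if size is not None:
        return ContextKind.ARM, 3
    if classify_timepoint_label(stripped, lexicons) is not None:
        return ContextKind.TIME_POINT, 2
    if _is_arm_label(stripped, lexicons):
        return ContextKind.ARM, 1
    return ContextKind.DATA_ELEMENT, 0


def _score_level(labels: Sequence[str], lexicons: Lexicons) -> ContextKind:
    votes: dict[ContextKind, list[int]] = {}
    for lab in labels:
        if not lab.strip():
            continue
        kind, prio = _vote(lab, lexicons)
        votes.setdefault(kind, []).append(prio)
    if not votes:
        return ContextKind.DATA_ELEMENT
    best = max(votes.items(), key=lambda kv: (len(kv[1]), max(kv[1])))
    return best[0]


def _is_subgroup_level(labels: Sequence[str], lexicons: Lexicons) -> bool:
    hits = 0
    nonempty = 0
    for lab in labels:
        stripped, _ = detect_arm_size(lab)
        if not stripped:
            continue
        nonempty += 1
        if stripped.casefold() in lexicons.subgroup_terms:
            hits += 1
    return nonempty > 0 and hits * 2 >= nonempty


def _split_embedded(
    label: str, lexicons: Lexicons
) -> Optional[tuple[ContextKind, ContextKind]]:
    """Detect two context kinds fused in one header cell.

    "Placebo, baseline" -> (ARM, TIME_POINT); "Baseline BMI" ->
    (DATA_ELEMENT, TIME_POINT).  Returns the canonical outer/inner pair or
    None.
    """
    parts = split_embedded_parts(label, lexicons)
    if parts is None:
        return None
    _, rest = parts
    if _is_arm_label(rest, lexicons):
        return (ContextKind.ARM, ContextKind.TIME_POINT)
    return (ContextKind.DATA_ELEMENT, ContextKind.TIME_POINT)


def split_embedded_parts(
    label: str, lexicons: Lexicons = DEFAULT
) -> Optional[tuple[str, str]]:
    """Split a fused header label into (time part, remainder).

    "Placebo (n=25), baseline" -> ("baseline", "Placebo (n=25)");
    "Baseline BMI, kg/m2" -> ("Baseline", "BMI, kg/m2").  Returns None
    for labels with no recognizable time component and for pure time
    labels (where the remainder is itself a time expression, as in
    "6-month follow-up").
    """
    stripped = label.strip()

    def is_time(text: str) -> bool:
        return classify_timepoint_label(text, lexicons) is not None

    def token_split(text: str) -> Optional[tuple[str, str]]:
        tokens = text.split()
        for cut in (1, 2):
            if len(tokens) > cut:
                head = " ".join(tokens[:cut])
                tail = " ".join(tokens[cut:])
                if is_time(head) and tail and not is_time(tail):
                    return head, tail
        return None

    def is_pure_time(text: str) -> bool:
        # "baseline" is pure; "1 year heart rate" merely contains a time
        return is_time(text) and token_split(text) is None

    parts = [p.strip() for p in re.split(r"[;]| at ", stripped) if p.strip()]
    if len(parts) == 1:
        parts = [p.strip() for p in stripped.split(",") if p.strip()]
    time_idx = [i for i, p in enumerate(parts) if is_pure_time(p)]
    if time_idx and len(parts) > 1:
        rest_parts = [p for i, p in enumerate(parts) if i != time_idx[0]]
        if not all(is_time(p) for p in rest_parts):
            return parts[time_idx[0]], ", ".join(rest_parts)
        return None
    return token_split(stripped)


def _runs(labels: Sequence[str]) -> list[str]:
    out: list[str] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def assign_context_kinds(
    grid: TableGrid, lexicons: Lexicons = DEFAULT
) -> ContextAssignment:
    """Label every header level of both axes with a context kind.

    The grid is expanded first.  Column levels are the header rows
    (outermost first, constituent-name rows like "Mean | SD" excluded);
    row levels come from indentation under the first header column plus
    any additional header columns that score as context.  Each level is
    labelled by majority vote of the cell detectors, with data element as
    the fallback kind; single-level axes are probed for embedded pairs.
    """
    g = expand_spans(grid)
    if g.n_header_rows == 0 and g.n_header_cols == 0:
        raise HeaderlessError("table declares no header rows or columns")
    mat = [[c.text for c in row] for row in _as_matrix(g)]
    data_cols = list(range(g.n_header_cols, g.n_cols))
    data_rows = list(range(g.n_header_rows, g.n_rows))
    annotations: list[HeaderAnnotation] = []

    # ---- column axis ----
    col_levels: list[AxisLevel] = []
    constituent_labels: Optional[list[str]] = None
    header_rows = list(range(g.n_header_rows))
    kept_rows: list[int] = []
    for r in header_rows:
        labels = [mat[r][c] for c in data_cols]
        uniq = {l.strip().casefold() for l in labels if l.strip()}
        if uniq and uniq <= _CONSTITUENT_TOKENS and len(uniq) >= 2:
            constituent_labels = [l.strip() for l in labels]
        else:
            kept_rows.append(r)
    for r in kept_rows:
        labels = [mat[r][c] for c in data_cols]
        col_levels.append(AxisLevel(
            kind=_score_level(_runs([l for l in labels if l.strip()]), lexicons),
            labels=labels,
        ))
        for c in data_cols:
            if mat[r][c].strip():
                annotations.append(_annotate(r, c, mat[r][c], lexicons))
    if not col_levels:
        col_levels.append(AxisLevel(kind=ContextKind.DATA_ELEMENT,
                                    labels=["" for _ in data_cols]))

    # ---- row axis ----
    if g.n_header_cols == 0:
        size_array_rows: list[int] = []
        row_levels = [AxisLevel(kind=ContextKind.DATA_ELEMENT,
                                labels=["" for _ in data_rows])]
    else:
        size_array_rows = [
            r for r in data_rows
            if mat[r][0].strip().casefold() in lexicons.size_array_terms
        ]
        label_rows = [r for r in data_rows if r not in size_array_rows]
        col0 = [mat[r][0] for r in data_rows]
        outer_labels = [mat[r][0] for r in label_rows
                        if indent_level(mat[r][0]) == 0 and mat[r][0].strip()]
        inner_labels = [mat[r][0] for r in label_rows
                        if indent_level(mat[r][0]) > 0 and mat[r][0].strip()]
        inner_kind: Optional[ContextKind] = None
        outer_kind = _score_level(_runs(outer_labels), lexicons) if outer_labels \
            else ContextKind.DATA_ELEMENT
        if inner_labels:
            k = _score_level(inner_labels, lexicons)
            if k in (ContextKind.ARM, ContextKind.TIME_POINT):
                inner_kind = k
            elif outer_kind in (ContextKind.ARM, ContextKind.TIME_POINT):
                # data elements nested under arm/time group headers;
                # indented DE labels under a DE header are categories, not
                # a nesting level, and stay single-level
                inner_kind = ContextKind.DATA_ELEMENT
        if inner_kind is not None:
            row_levels = [AxisLevel(kind=outer_kind, labels=col0),
                          AxisLevel(kind=inner_kind, labels=col0)]
        else:
            row_levels = [AxisLevel(kind=outer_kind, labels=col0)]
        for r in data_rows:
            if mat[r][0].strip():
                annotations.append(_annotate(r, 0, mat[r][0], lexicons))
    # extra header columns that score as context become additional levels
    for c in range(1, g.n_header_cols):
        labels = [mat[r][c] for r in data_rows if mat[r][c].strip()]
        if labels:
            k = _score_level(labels, lexicons)
            if k in (ContextKind.ARM, ContextKind.TIME_POINT):
                row_levels.append(AxisLevel(kind=k,
                                            labels=[mat[r][c] for r in data_rows]))

    # ---- embedded detection on single-level axes ----
    embedded = False
    if len(col_levels) == 1:
        pairs = [_split_embedded(l, lexicons)
                 for l in _runs([l for l in col_levels[0].labels if l.strip()])]
        hits = [p for p in pairs if p is not None]
        if hits and 2 * len(hits) >= len(pairs):
            outer, inner = hits[0]
            col_levels = [
                AxisLevel(outer, col_levels[0].labels, embedded_with=inner),
                AxisLevel(inner, col_levels[0].labels, embedded_with=outer),
            ]
            embedded = True
    if not embedded and len(row_levels) == 1:
        pairs = [_split_embedded(l, lexicons)
                 for l in _runs([l for l in row_levels[0].labels if l.strip()])]
        hits = [p for p in pairs if p is not None]
        if hits and 2 * len(hits) >= len(pairs):
            outer, inner = hits[0]
            row_levels = [
                AxisLevel(outer, row_levels[0].labels, embedded_with=inner),
                AxisLevel(inner, row_levels[0].labels, embedded_with=outer),
            ]
            embedded = True

    # ---- separate-array size columns (a leaf column labelled "n") ----
    size_array_cols = [
        c for i, c in enumerate(data_cols)
        if col_levels and col_levels[-1].labels[i].strip().casefold()
        in lexicons.size_array_terms
    ]

    # ---- stratified / comparative / pooled flags ----
    stratified = any(
        _is_subgroup_level(_runs([l for l in lv.labels if l.strip()]), lexicons)
        for lv in col_levels + row_levels
    )
    leaf_col_labels = [l.strip().casefold()
                       for i, l in enumerate(col_levels[-1].labels if col_levels else [])
                       if l.strip() and data_cols[i] not in size_array_cols]
    comparative_only = bool(leaf_col_labels) and all(
        l in lexicons.comparative_terms for l in leaf_col_labels
    )
    pooled = False
    for lv in col_levels + row_levels:
        if lv.kind is ContextKind.ARM:
            uniq = {detect_arm_size(l)[0].casefold()
                    for l in lv.labels if l.strip()}
            if uniq and uniq <= lexicons.pooled_terms:
                pooled = True
    # a single pooled column that scored as data-element fallback
    if len(col_levels) == 1 and col_levels[0].kind is ContextKind.DATA_ELEMENT:
        uniq = {detect_arm_size(l)[0].casefold()
                for l in col_levels[0].labels if l.strip()}
        if uniq and uniq <= lexicons.pooled_terms:
            col_levels[0].kind = ContextKind.ARM
            pooled = True

    return ContextAssignment(
        row_levels=row_levels,
        col_levels=col_levels,
        embedded=embedded,
        stratified=stratified,
        comparative_only=comparative_only,
        pooled=pooled,
        constituent_labels=constituent_labels,
        size_array_rows=size_array_rows,
        size_array_cols=size_array_cols,
        annotations=annotations,
        n_header_rows=g.n_header_rows,
        n_header_cols=g.n_header_cols,
    )


def _as_matrix(g: TableGrid) -> list[list[Cell]]:
    mat: list[list[Cell]] = [[None] * g.n_cols for _ in range(g.n_rows)]  # type: ignore
    for c in g.cells:
        mat[c.row][c.col] = c
    return mat


def _annotate(row: int, col: int, text: str, lexicons: Lexicons) -> HeaderAnnotation:
    ann = HeaderAnnotation(row=row, col=col)
    stripped, size = detect_arm_size(text)
    if size is not None:
        ann.arm_size = size
        ann.detected_kinds.add(ContextKind.ARM)
    tp = classify_timepoint_label(stripped, lexicons)
    if tp is not None:
        ann.timepoint_kind = tp[0]
        ann.detected_kinds.add(ContextKind.TIME_POINT)
    elif _is_arm_label(stripped, lexicons):
        ann.intervention_kind = classify_intervention_label(stripped, lexicons=lexicons)
        ann.detected_kinds.add(ContextKind.ARM)
    if not ann.detected_kinds:
        ann.detected_kinds.add(ContextKind.DATA_ELEMENT)
        _, unit, _ = parse_de_label(stripped)
        ann.unit = unit
    return ann


# ---------------------------------------------------------------------------
# Structure classification
# ---------------------------------------------------------------------------

_D, _A, _T = ContextKind.DATA_ELEMENT, ContextKind.ARM, ContextKind.TIME_POINT

#: The 15 named sub-layouts: (row kinds, col kinds, embedded) -> (name, tag id)
LAYOUTS: dict[tuple[tuple[ContextKind, ...], tuple[ContextKind, ...], bool],
              tuple[str, str]] = {
    ((_D,), (_A,), False): ("DEs on rows, arms on columns",
                            "context/1x1/de_rows_arm_cols"),
    ((_A,), (_D,), False): ("Arms on rows, DEs on columns",
                            "context/1x1/arm_rows_de_cols"),
    ((_A,), (_T,), False): ("Arms on rows, TPs on columns",
                            "context/1x1/arm_rows_tp_cols"),
    ((_T,), (_A,), False): ("TPs on rows, arms on columns",
                            "context/1x1/tp_rows_arm_cols"),
    ((_D, _T), (_A,), False): ("TPs nested in DEs on rows, arms on columns",
                               "context/2x1/tp_in_de_rows_arm_cols"),
    ((_D, _A), (_T,), False): ("Arms nested in DEs on rows, TPs on columns",
                               "context/2x1/arm_in_de_rows_tp_cols"),
    ((_A, _D), (_T,), False): ("DEs nested in arms on rows, TPs on columns",
                               "context/2x1/de_in_arm_rows_tp_cols"),
    ((_T, _A), (_D,), False): ("Arms nested in TPs on rows, DEs on columns",
                               "context/2x1/arm_in_tp_rows_de_cols"),
    ((_D, _T), (_A,), True): ("DEs and TPs embedded in rows, arms on columns",
                              "context/2x1/de_tp_embedded_rows_arm_cols"),
    ((_A, _T), (_D,), False): ("TPs nested in arms on rows, DEs on columns",
                               "context/2x1/tp_in_arm_rows_de_cols"),
    ((_T, _D), (_A,), False): ("DEs nested in TPs on rows, arms on columns",
                               "context/2x1/de_in_tp_rows_arm_cols"),
    ((_D,), (_A, _T), False): ("DEs on rows, TPs nested in arms on columns",
                               "context/1x2/de_rows_tp_in_arm_cols"),
    ((_D,), (_T, _A), False): ("DEs on rows, arms nested in TPs on columns",
                               "context/1x2/de_rows_arm_in_tp_cols"),
    ((_A,), (_D, _T), False): ("Arms on rows, TPs nested in DEs on columns",
                               "context/1x2/arm_rows_tp_in_de_cols"),
    ((_D,), (_A, _T), True): ("DEs on rows, arms and TPs embedded on columns",
                              "context/1x2/de_rows_arm_tp_embedded_cols"),
}

_SHORT = {_D: "DE", _A: "ARM", _T: "TP"}


def classify_structure(
    assignment: ContextAssignment,
    has_arm_level_data: bool = True,
    only_comparative: Optional[bool] = None,
    stratified: Optional[bool] = None,
) -> ContextStructure:
    """Map an axis assignment onto the 1x1/2x1/1x2/other taxonomy.

    ``only_comparative`` and ``stratified`` override the assignment's own
    detection when given.  Unmatched (row kinds, col kinds) pairs keep
    their class but record the kinds verbatim as the sub-layout; axes with
    more than two kinds are "other"/unsupported_depth.
    """
    strat = assignment.stratified if stratified is None else stratified
    comp = assignment.comparative_only if only_comparative is None else only_comparative
    rk = tuple(assignment.row_kinds)
    ck = tuple(assignment.col_kinds)
    if comp:
        return ContextStructure(list(rk), list(ck), assignment.embedded,
                                StructureClass.OTHER,
                                OtherReason.COMPARATIVE_ONLY,
                                "Only reports comparative statistics")
    if strat:
        return ContextStructure(list(rk), list(ck), assignment.embedded,
                                StructureClass.OTHER, OtherReason.STRATIFIED,
                                "Stratified reporting")
    if len(rk) > 2 or len(ck) > 2:
        return ContextStructure(list(rk), list(ck), assignment.embedded,
                                StructureClass.OTHER,
                                OtherReason.UNSUPPORTED_DEPTH,
                                _verbatim(rk, ck))
    named = LAYOUTS.get((rk, ck, assignment.embedded))
    cls = {(1, 1): StructureClass.ONE_BY_ONE,
           (2, 1): StructureClass.TWO_BY_ONE,
           (1, 2): StructureClass.ONE_BY_TWO}.get((len(rk), len(ck)))
    if cls is None:
        return ContextStructure(list(rk), list(ck), assignment.embedded,
                                StructureClass.OTHER,
                                OtherReason.UNSUPPORTED_DEPTH,
                                _verbatim(rk, ck))
    return ContextStructure(list(rk), list(ck), assignment.embedded, cls,
                            None, named[0] if named else _verbatim(rk, ck))


def _verbatim(rk: tuple, ck: tuple) -> str:
    left = "+".join(_SHORT[k] for k in rk) or "none"
    right = "+".join(_SHORT[k] for k in ck) or "none"
    return f"{left} rows x {right} cols"


def layout_tag(structure: ContextStructure) -> Optional[str]:
    """The hierarchy tag id for a classified structure, if it has one."""
    if structure.cls is StructureClass.OTHER:
        if structure.other_reason is None:
            return None
        return f"context/other/{structure.other_reason.value}"
    key = (tuple(structure.row_kinds), tuple(structure.col_kinds),
           structure.embedded)
    named = LAYOUTS.get(key)
    return named[1] if named else f"context/{structure.cls.value}"
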