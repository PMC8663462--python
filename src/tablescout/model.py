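"""Core data model for clinical tables and their measurement context.

A published trial table is modelled as a rectangular grid of cells
(:class:`TableGrid`).  Every descriptive statistic in the body of such a
table acquires its meaning from a *measurement context*: the combination of
a data element (the characteristic being measured), a patient arm, and a
time point.  Which of those three context kinds label the rows and which
label the columns determines the table's structural class (1x1, 2x1, 1x2,
or an "other" structure such as stratified reporting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class StructuralError(ValueError):
    """Raised for malformed grids (overlapping spans, ragged rows, ...)."""


# ---------------------------------------------------------------------------
# Context vocabulary
# ---------------------------------------------------------------------------

class ContextKind(str, Enum):
    """The three kinds of measurement context a table axis can carry."""

    DATA_ELEMENT = "data_element"
    ARM = "arm"
    TIME_POINT = "time_point"


class DataElementKind(str, Enum):
    CONTINUOUS = "continuous"
    DICHOTOMOUS = "dichotomous"
    CATEGORICAL = "categorical"


class ArmLabelKind(str, Enum):
    FULL_NAME = "full_name"
    ABBREVIATION = "abbreviation"
    CONTROL_EXPERIMENTAL = "control_experimental"
    ALTERNATE = "alternate"


class ArmSizeSource(str, Enum):
    EMBEDDED = "embedded"
    SEPARATE_ARRAY = "separate_array"
    DESCRIPTION = "description"


class TimePointLabelKind(str, Enum):
    UNIT_OF_TIME = "unit_of_time"
    PRE_POST = "pre_post"
    INCREMENTAL = "incremental"


@dataclass
class DataElement:
    """A characteristic or quality being measured (e.g. mortality, BMI)."""

    name: str
    kind: DataElementKind
    unit: Optional[str] = None
    categories: Optional[list[str]] = None

    def __post_init__(self) -> None:
        has_cats = bool(self.categories)
        if (self.kind is DataElementKind.CATEGORICAL) != has_cats:
            raise ValueError(
                "categories must be non-empty iff the element is categorical"
            )


@dataclass
class Arm:
    """A subset of participants assigned one intervention."""

    label: str
    label_kind: ArmLabelKind
    size: Optional[int] = None
    size_source: Optional[ArmSizeSource] = None

    def __post_init__(self) -> None:
        if (self.size is None) != (self.size_source is None):
            raise ValueError("size_source must be set iff size is set")
        if self.size is not None and self.size <= 0:
            raise ValueError("arm size must be positive")


@dataclass
class TimePoint:
    """A moment of measurement (e.g. baseline, 6-month follow-up)."""

    label: str
    label_kind: TimePointLabelKind
    amount: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label_kind is not TimePointLabelKind.UNIT_OF_TIME:
            if self.amount is not None and self.label_kind is TimePointLabelKind.PRE_POST:
                raise ValueError("amount/unit only valid for unit_of_time labels")
            if self.unit is not None:
                raise ValueError("amount/unit only valid for unit_of_time labels")


@dataclass
class MeasurementContext:
    """What a single metric measures: element, optionally arm and time."""

    data_element: DataElement
    arm: Optional[Arm] = None
    time_point: Optional[TimePoint] = None


class StructureClass(str, Enum):
    ONE_BY_ONE = "1x1"
    TWO_BY_ONE = "2x1"
    ONE_BY_TWO = "1x2"
    OTHER = "other"


class OtherReason(str, Enum):
    STRATIFIED = "stratified"
    COMPARATIVE_ONLY = "comparative_only"
    UNSUPPORTED_DEPTH = "unsupported_depth"


@dataclass
class ContextStructure:
    """Which context kinds label each table dimension, and the class.

    ``row_kinds``/``col_kinds`` are ordered outermost-first.  ``embedded``
    marks layouts where two kinds are fused inside single header cells
    (e.g. a row labelled "Baseline BMI").
    """

    row_kinds: list[ContextKind]
    col_kinds: list[ContextKind]
    embedded: bool = False
    cls: StructureClass = StructureClass.OTHER
    other_reason: Optional[OtherReason] = None
    sublayout: Optional[str] = None

    def __post_init__(self) -> None:
        nr, nc = len(self.row_kinds), len(self.col_kinds)
        if self.cls is StructureClass.ONE_BY_ONE and (nr, nc) != (1, 1):
            raise ValueError("1x1 requires exactly one kind per axis")
        if self.cls is StructureClass.TWO_BY_ONE and (nr, nc) != (2, 1):
            raise ValueError("2x1 requires two row kinds and one column kind")
        if self.cls is StructureClass.ONE_BY_TWO and (nr, nc) != (1, 2):
            raise ValueError("1x2 requires one row kind and two column kinds")
        if (self.other_reason is not None) != (self.cls is StructureClass.OTHER):
            raise ValueError("other_reason is set iff cls is OTHER")


# ---------------------------------------------------------------------------
# Grid substrate
# ---------------------------------------------------------------------------

def indent_level(text: str) -> int:
    """Leading-whitespace depth of a cell's text.

    One tab, two spaces, or one pair of non-breaking spaces count as one
    level; published tables nest category labels under their categorical
    data element header this way.
    """
    level = 0
    spaces = 0
    for ch in text:
        if ch == "\t":
            level += 1
        elif ch in (" ", "\u00a0"):
            spaces += 1
            if spaces == 2:
                level += 1
                spaces = 0
        else:
            break
    return level


@dataclass
class Cell:
    text: str
    row: int
    col: int
    row_span: int = 1
    col_span: int = 1

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("cell coordinates are 0-based and non-negative")
        if self.row_span < 1 or self.col_span < 1:
            raise ValueError("spans must be >= 1")

    @property
    def indent_level(self) -> int:
        return indent_level(self.text)


@dataclass
class TableGrid:
    """A rectangular cell grid with header prefixes, caption and footnotes.

    Header rows and header columns form a prefix of the grid (rows
    ``0..n_header_rows-1`` and columns ``0..n_header_cols-1``).  ``rotated``
    and ``multipage`` are metadata flags carried from the reader.
    """

    cells: list[Cell]
    n_rows: int
    n_cols: int
    n_header_rows: int = 1
    n_header_cols: int = 1
    caption: str = ""
    footnotes: list[str] = field(default_factory=list)
    rotated: bool = False
    multipage: bool = False

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (0 <= self.n_header_rows < self.n_rows):
            raise ValueError("n_header_rows must satisfy 0 <= h < n_rows")
        if not (0 <= self.n_header_cols < self.n_cols):
            raise ValueError("n_header_cols must satisfy 0 <= h < n_cols")

    # -- expansion ---------------------------------------------------------

    def is_expanded(self) -> bool:
        if any(c.row_span != 1 or c.col_span != 1 for c in self.cells):
            return False
        return len(self.cells) == self.n_rows * self.n_cols

    def cell_matrix(self) -> list[list[str]]:
        """Dense text matrix of an expanded grid."""
        g = expand_spans(self)
        mat = [["" for _ in range(g.n_cols)] for _ in range(g.n_rows)]
        for c in g.cells:
            mat[c.row][c.col] = c.text
        return mat

    # -- grid-JSON interchange --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_header_rows": self.n_header_rows,
            "n_header_cols": self.n_header_cols,
            "caption": self.caption,
            "footnotes": list(self.footnotes),
            "flags": {"rotated": self.rotated, "multipage": self.multipage},
            "cells": [
                {
                    "text": c.text,
                    "row": c.row,
                    "col": c.col,
                    "row_span": c.row_span,
                    "col_span": c.col_span,
                }
                for c in sorted(self.cells, key=lambda c: (c.row, c.col))
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableGrid":
        flags = d.get("flags", {})
        return cls(
            cells=[
                Cell(
                    text=c["text"],
                    row=c["row"],
                    col=c["col"],
                    row_span=c.get("row_span", 1),
                    col_span=c.get("col_span", 1),
                )
                for c in d["cells"]
            ],
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            n_header_rows=d.get("n_header_rows", 1),
            n_header_cols=d.get("n_header_cols", 1),
            caption=d.get("caption", ""),
            footnotes=list(d.get("footnotes", [])),
            rotated=bool(flags.get("rotated", False)),
            multipage=bool(flags.get("multipage", False)),
        )

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("ensure_ascii", False)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "TableGrid":
        return cls.from_dict(json.loads(text))


def expand_spans(grid: TableGrid) -> TableGrid:
    """Replicate spanned cells into every covered grid position.

    Returns a rectangular grid in which every (row, col) position holds
    exactly one cell with row_span = col_span = 1 and the spanning cell's
    text.  Overlapping spans raise :class:`StructuralError` naming the
    offending coordinates; uncovered positions become empty cells.
    Idempotent on already-expanded grids.
    """
    owner: dict[tuple[int, int], Cell] = {}
    for c in grid.cells:
        if c.row + c.row_span > grid.n_rows or c.col + c.col_span > grid.n_cols:
            raise StructuralError(
                f"cell at ({c.row},{c.col}) spans outside the {grid.n_rows}x{grid.n_cols} grid"
            )
        for r in range(c.row, c.row + c.row_span):
            for k in range(c.col, c.col + c.col_span):
                if (r, k) in owner:
                    o = owner[(r, k)]
                    raise StructuralError(
                        f"overlapping spans at ({r},{k}): cells ({o.row},{o.col}) and ({c.row},{c.col})"
                    )
                owner[(r, k)] = c
    cells = [
        Cell(text=owner[(r, k)].text if (r, k) in owner else "", row=r, col=k)
        for r in range(grid.n_rows)
        for k in range(grid.n_cols)
    ]
    return replace(grid, cells=cells, footnotes=list(grid.footnotes))


# ---------------------------------------------------------------------------
# Tag assignments and article records
# ---------------------------------------------------------------------------

class TagScope(str, Enum):
    PER_TABLE = "per_table"
    PER_ARTICLE = "per_article"


@dataclass
class TagAssignment:
    """A set of tag identifiers from the fixed tagging hierarchy.

    Tag ids are path-like ("baseline_in_table/arm_level_breakout"); a child
    tag implies the presence of its parent.  Validation lives in
    :mod:`tablescout.hierarchy`.
    """

    scope: TagScope
    tags: set[str] = field(default_factory=set)

    def add(self, *tag_ids: str) -> None:
        self.tags.update(tag_ids)


@dataclass
class AnnotatedTable:
    """A grid together with everything the pipeline derived from it."""

    grid: TableGrid
    structure: Optional[ContextStructure] = None
    metrics: list = field(default_factory=list)  # list[ExtractedMetric]
    tags: Optional[TagAssignment] = None


@dataclass
class ArticleRecord:
    article_id: str
    tables: list[AnnotatedTable] = field(default_factory=list)
    article_tags: TagAssignment = field(
        default_factory=lambda: TagAssignment(TagScope.PER_ARTICLE)
    )

    def __post_init__(self) -> None:
        if self.article_tags.scope is not TagScope.PER_ARTICLE:
            raise ValueError("article_tags must have per_article scope")


def grids_equal(a: TableGrid, b: TableGrid) -> bool:
    """Field-exact equality used by round-trip tests."""
    return a.to_dict() == b.to_dict()
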