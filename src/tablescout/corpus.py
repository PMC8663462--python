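"""Corpus tagging, Boolean tag queries and frequency summaries.

Tables are tagged from their extraction results; articles union the tags
of their tables.  Frequencies of tags across a corpus are summarized with
Wilson score CIs, and arbitrary Boolean expressions over tags (AND, OR,
NOT, parentheses; a parent tag matches when any descendant is present)
select article subsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .extract import ExtractionResult
from .formats import MetricKind
from .hierarchy import HIERARCHY, close_under_parents
from .model import (
    ArticleRecord,
    ContextKind,
    StructureClass,
    TagAssignment,
    TagScope,
)
from .context import layout_tag
from .proportions import ProportionCI, wilson_ci

__all__ = [
    "tag_table",
    "tag_article",
    "boolean_query",
    "QuerySyntaxError",
    "FrequencyRow",
    "DenominatorRule",
    "frequency_table",
    "density_classifier",
    "tag_matches",
]


_FORMAT_FAMILY = {
    MetricKind.CONTINUOUS_MEAN: "continuous",
    MetricKind.CONTINUOUS_MEDIAN: "continuous",
    MetricKind.DICHOTOMOUS: "dichotomous",
    MetricKind.CATEGORICAL: "categorical",
}


def tag_table(result: ExtractionResult) -> TagAssignment:
    """Emit the per-table tag assignment from an extraction result.

    A table with no descriptive statistics (and no comparative-only
    structure) gets an empty assignment.  The format/units location tags
    apply the lower-classification-wins rule: a footnote declaration
    outranks a header declaration within one table.
    """
    tags: set[str] = set()
    s = result.structure
    comparative = (
        s.cls is StructureClass.OTHER
        and s.other_reason is not None
        and s.other_reason.value == "comparative_only"
    )
    if not result.metrics and not comparative:
        return TagAssignment(TagScope.PER_TABLE, set())

    lt = layout_tag(s)
    if lt is not None:
        tags.add(lt)

    has_arms = (
        ContextKind.ARM in s.row_kinds or ContextKind.ARM in s.col_kinds
    ) and not result.assignment.pooled
    if comparative:
        # no descriptive statistics: context tag only
        pass
    elif result.role == "baseline":
        tags.add("baseline_in_table")
        if has_arms:
            tags.add("baseline_in_table/arm_level_breakout")
        elif result.metrics:
            tags.add("baseline_in_table/no_arm_level_breakout")
    elif result.role == "outcome":
        tags.add("outcomes_in_table")
        if result.secondary_only:
            tags.add("outcomes_in_table/secondary_only")
        elif has_arms:
            tags.add("outcomes_in_table/arm_level_breakout")

    if result.grid.rotated:
        tags.add("table_features/rotated")
    if result.grid.multipage:
        tags.add("table_features/multipage")

    for arm in result.arms:
        if arm.size is not None and arm.size_source is not None:
            tags.add(f"arm_size/{arm.size_source.value}")
        tags.add(f"intervention_labels/{arm.label_kind.value}")
    for tp in result.time_points:
        tags.add(f"timepoint_labels/{tp.label_kind.value}")

    # lower-classification-wins: footnote outranks header within a table
    if result.format_in_footnote:
        tags.add("format_location/in_description_or_footnotes")
    elif result.format_in_header:
        tags.add("format_location/in_header")
    if result.units_in_footnote:
        tags.add("units_location/in_description_or_footnotes")
    elif result.units_in_header:
        tags.add("units_location/in_header")

    for m in result.metrics:
        tags.add(f"formats/{_FORMAT_FAMILY[m.format.metric_kind]}/{m.format.id}")
    for placement in result.category_placements:
        tags.add(f"category_labels/{placement}")

    return TagAssignment(TagScope.PER_TABLE, close_under_parents(tags))


def tag_article(
    table_tags: Sequence[TagAssignment],
    arm_size_in_description: bool = False,
    units_not_relevant: bool = False,
) -> TagAssignment:
    """Union per-table tags into the article-level assignment.

    ``arm_size_in_description`` records an arm size stated only in the
    article text (not recoverable from any table); ``units_not_relevant``
    marks articles whose continuous data elements are unitless (or that
    report no continuous data).
    """
    tags: set[str] = set()
    for t in table_tags:
        if t.scope is not TagScope.PER_TABLE:
            raise ValueError("tag_article expects per-table assignments")
        tags |= t.tags
    if arm_size_in_description:
        tags.add("arm_size/description")
    if units_not_relevant and not any(
        t.startswith("units_location/") for t in tags
    ):
        tags.add("units_location/not_relevant")
    return TagAssignment(TagScope.PER_ARTICLE, close_under_parents(tags))


# ---------------------------------------------------------------------------
# Boolean tag queries
# ---------------------------------------------------------------------------

class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def tag_matches(tag: str, tag_set: set[str]) -> bool:
    """A tag matches when it or any descendant is present."""
    prefix = tag + "/"
    return any(t == tag or t.startswith(prefix) for t in tag_set)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_][A-Za-z0-9_/\-]*)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            stripped = expr[pos:].lstrip()
            if not stripped:
                break
            raise QuerySyntaxError(
                f"unexpected character {stripped[0]!r}",
                len(expr) - len(stripped),
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent with NOT > AND > OR precedence."""

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return (self.tokens[self.i][1] if self.i < len(self.tokens)
                else len(self.expr))

    def take(self) -> str:
        tok = self.peek()
        self.i += 1
        return tok  # type: ignore

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise QuerySyntaxError(f"unexpected token {self.peek()!r}", self.pos())
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() is not None and self.peek().upper() == "OR":
            self.take()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() is not None and self.peek().upper() == "AND":
            self.take()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() is not None and self.peek().upper() == "NOT":
            self.take()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of expression", self.pos())
        if tok == "(":
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                raise QuerySyntaxError("expected ')'", self.pos())
            self.take()
            return node
        if tok == ")" or tok.upper() in ("AND", "OR", "NOT"):
            raise QuerySyntaxError(f"unexpected token {tok!r}", self.pos())
        self.take()
        return ("tag", tok)


def _eval(node, tag_set: set[str]) -> bool:
    op = node[0]
    if op == "tag":
        return tag_matches(node[1], tag_set)
    if op == "not":
        return not _eval(node[1], tag_set)
    if op == "and":
        return _eval(node[1], tag_set) and _eval(node[2], tag_set)
    return _eval(node[1], tag_set) or _eval(node[2], tag_set)


def boolean_query(expr: str, corpus: Iterable[ArticleRecord]) -> list[str]:
    """Article ids whose per-article tag set satisfies the expression."""
    tree = _Parser(expr).parse()
    return [a.article_id for a in corpus
            if _eval(tree, a.article_tags.tags)]


# ---------------------------------------------------------------------------
# Frequency summaries
# ---------------------------------------------------------------------------

class DenominatorRule(str, Enum):
    PER_ARTICLE = "per_article"
    PER_TABLE = "per_table"
    PER_RELEVANT_ARTICLE = "per_relevant_article"


@dataclass
class FrequencyRow:
    tag: str
    k: int
    n: int
    rule: DenominatorRule
    proportion: float
    ci: ProportionCI

    def __post_init__(self) -> None:
        if self.k > self.n:
            raise ValueError("numerator must not exceed denominator")


def frequency_table(
    corpus: Sequence[ArticleRecord],
    tags: Sequence[str],
    rule: DenominatorRule = DenominatorRule.PER_ARTICLE,
    conf: float = 0.95,
) -> list[FrequencyRow]:
    """Tag frequencies across a corpus with score-interval CIs.

    ``per_article`` counts articles holding the tag over all articles;
    ``per_table`` counts tagged tables over all tagged tables;
    ``per_relevant_article`` restricts the denominator to articles that
    hold the tag's parent (articles for which the classification applies
    at all).  Rows whose denominator class is empty are omitted.
    """
    rows: list[FrequencyRow] = []
    table_sets = [
        t.tags.tags for a in corpus for t in a.tables
        if t.tags is not None and t.tags.tags
    ]
    for tag in tags:
        if rule is DenominatorRule.PER_TABLE:
            n = len(table_sets)
            k = sum(tag_matches(tag, s) for s in table_sets)
        elif rule is DenominatorRule.PER_RELEVANT_ARTICLE:
            parent = HIERARCHY.get(tag)
            relevant = [a for a in corpus
                        if parent is None or tag_matches(parent, a.article_tags.tags)]
            n = len(relevant)
            k = sum(tag_matches(tag, a.article_tags.tags) for a in relevant)
        else:
            n = len(corpus)
            k = sum(tag_matches(tag, a.article_tags.tags) for a in corpus)
        if n == 0:
            import warnings as _warnings
            _warnings.warn(f"empty denominator class for tag {tag!r}; row omitted")
            continue
        rows.append(FrequencyRow(
            tag=tag, k=k, n=n, rule=rule, proportion=k / n,
            ci=wilson_ci(k, n, conf),
        ))
    return rows


# ---------------------------------------------------------------------------
# High-information-density classification
# ---------------------------------------------------------------------------

def density_classifier(
    article: "ArticleRecord | TagAssignment",
    require_intervention_labels: bool = True,
) -> bool:
    """Does the article present maximal extraction-relevant information?

    True iff the article reports baseline or outcomes in a table, reports
    arm sizes, labels interventions by full name or abbreviation (clause
    dropped when ``require_intervention_labels`` is False), reports units
    for unit-relevant metrics, and declares its statistic formats.
    """
    tags = article.tags if isinstance(article, TagAssignment) \
        else article.article_tags.tags
    clauses = [
        tag_matches("baseline_in_table", tags) or
        tag_matches("outcomes_in_table", tags),
        tag_matches("arm_size", tags),
        tag_matches("units_location", tags),
        tag_matches("format_location", tags),
    ]
    if require_intervention_labels:
        clauses.append(
            tag_matches("intervention_labels/full_name", tags)
            or tag_matches("intervention_labels/abbreviation", tags)
        )
    return all(clauses)
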