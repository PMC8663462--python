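"""The fixed tagging vocabulary for tables and articles.

Tags are path-like identifiers ("baseline_in_table/arm_level_breakout");
a child tag always implies its parent.  The vocabulary covers three
families:

* structural attributes — where baseline and outcome data appear, with
  what arm-level breakout, plus table features (rotated, multipage);
* measurement-context attributes — the 1x1/2x1/1x2/other class with its
  named sub-layout, how arm sizes are reported, and the styles of
  intervention and time-point labels;
* metric attributes — where statistic formats and units are declared,
  which catalog formats occur, and how category labels are placed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .formats import CATALOG, MetricKind
from .model import TagAssignment

__all__ = ["HIERARCHY", "PARENT", "validate_tags", "is_known_tag",
           "descendants", "TagViolation"]


def _build() -> dict[str, Optional[str]]:
    h: dict[str, Optional[str]] = {}

    def add(tag: str) -> None:
        parent = tag.rsplit("/", 1)[0] if "/" in tag else None
        if parent is not None and parent not in h:
            add(parent)
        h[tag] = parent

    for root, children in {
        "baseline_in_table": ["arm_level_breakout", "participant_level",
                              "no_arm_level_breakout"],
        "outcomes_in_table": ["arm_level_breakout", "participant_level",
                              "secondary_only"],
        "table_features": ["rotated", "multipage"],
        "arm_size": ["embedded", "separate_array", "description"],
        "intervention_labels": ["full_name", "abbreviation",
                                "control_experimental", "alternate"],
        "timepoint_labels": ["unit_of_time", "pre_post", "incremental"],
        "format_location": ["in_header", "in_description_or_footnotes"],
        "units_location": ["in_header", "in_description_or_footnotes",
                           "not_relevant"],
        "category_labels": ["separate_array", "same_array",
                            "same_array_indented", "in_cell"],
    }.items():
        add(root)
        for c in children:
            add(f"{root}/{c}")

    # context classes and their named sub-layouts
    sublayouts = {
        "1x1": ["de_rows_arm_cols", "arm_rows_de_cols", "arm_rows_tp_cols",
                "tp_rows_arm_cols"],
        "2x1": ["tp_in_de_rows_arm_cols", "arm_in_de_rows_tp_cols",
                "de_in_arm_rows_tp_cols", "arm_in_tp_rows_de_cols",
                "de_tp_embedded_rows_arm_cols", "tp_in_arm_rows_de_cols",
                "de_in_tp_rows_arm_cols"],
        "1x2": ["de_rows_tp_in_arm_cols", "de_rows_arm_in_tp_cols",
                "arm_rows_tp_in_de_cols", "de_rows_arm_tp_embedded_cols"],
        "other": ["stratified", "comparative_only", "unsupported_depth"],
    }
    add("context")
    for cls, names in sublayouts.items():
        add(f"context/{cls}")
        for name in names:
            add(f"context/{cls}/{name}")

    # observed statistic formats, grouped by metric family
    add("formats")
    for family in ("continuous", "dichotomous", "categorical"):
        add(f"formats/{family}")
    family_of = {
        MetricKind.CONTINUOUS_MEAN: "continuous",
        MetricKind.CONTINUOUS_MEDIAN: "continuous",
        MetricKind.DICHOTOMOUS: "dichotomous",
        MetricKind.CATEGORICAL: "categorical",
    }
    for f in CATALOG:
        add(f"formats/{family_of[f.metric_kind]}/{f.id}")
    return h


HIERARCHY: dict[str, Optional[str]] = _build()
PARENT = HIERARCHY  # alias: maps tag id -> parent id (None for roots)


def is_known_tag(tag: str) -> bool:
    return tag in HIERARCHY


def descendants(tag: str) -> set[str]:
    return {t for t in HIERARCHY if t == tag or t.startswith(tag + "/")}


@dataclass(frozen=True)
class TagViolation:
    tag: str
    problem: str  # "unknown_tag" | "missing_parent"
    detail: str


def validate_tags(tags: TagAssignment) -> list[TagViolation]:
    """Check hierarchy membership and parent implication.

    Returns an empty list iff every tag exists in the vocabulary and every
    tag's parent is also present.  Unknown identifiers are reported as
    violations, never raised.
    """
    out: list[TagViolation] = []
    for tag in sorted(tags.tags):
        if tag not in HIERARCHY:
            out.append(TagViolation(tag, "unknown_tag",
                                    f"{tag!r} is not in the tagging vocabulary"))
            continue
        parent = HIERARCHY[tag]
        if parent is not None and parent not in tags.tags:
            out.append(TagViolation(tag, "missing_parent",
                                    f"{tag!r} requires its parent {parent!r}"))
    return out


def close_under_parents(tag_ids: Iterable[str]) -> set[str]:
    """Add every ancestor of each tag (tagging ops use this to keep
    assignments valid by construction)."""
    out: set[str] = set()
    for t in tag_ids:
        while t is not None:
            out.add(t)
            t = HIERARCHY.get(t)
    return out
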