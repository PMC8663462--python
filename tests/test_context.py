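"""Header detectors and context-structure classification."""

import pytest
from random import Random

from tablescout.context import (
    LAYOUTS,
    assign_context_kinds,
    classify_intervention_label,
    classify_structure,
    classify_timepoint_label,
    detect_arm_size,
    detect_category_structure,
    layout_tag,
    parse_de_label,
)
from tablescout.model import (
    ArmLabelKind,
    Cell,
    ContextKind,
    OtherReason,
    StructureClass,
    TableGrid,
    TimePointLabelKind,
)

D, A, T = ContextKind.DATA_ELEMENT, ContextKind.ARM, ContextKind.TIME_POINT


class TestArmSize:
    @pytest.mark.parametrize("text,label,size", [
        ("Placebo [n=25]", "Placebo", 25),
        ("HFNC (n=40)", "HFNC", 40),
        ("Control", "Control", None),
        ("Treatment, n=31", "Treatment", 31),
        ("N = 12 intervention", "intervention", 12),
    ])
    def test_examples(self, text, label, size):
        assert detect_arm_size(text) == (label, size)

    def test_never_alters_sizeless_labels(self, rng):
        words = ["Placebo", "Standard care", "Group A", "HFNC", "Control"]
        for _ in range(100):
            lab = rng.choice(words)
            out, size = detect_arm_size(lab)
            assert size is None and out == lab

    def test_strip_then_rerender_is_idempotent(self):
        label, size = detect_arm_size("Placebo [n=25]")
        rerendered = f"{label} (n={size})"
        assert detect_arm_size(rerendered) == (label, size)


@pytest.mark.parametrize("label,kind", [
    ("Control", ArmLabelKind.CONTROL_EXPERIMENTAL),
    ("Treatment", ArmLabelKind.CONTROL_EXPERIMENTAL),
    ("HFNC", ArmLabelKind.ABBREVIATION),
    ("Group A", ArmLabelKind.ALTERNATE),
    ("Placebo", ArmLabelKind.FULL_NAME),
    ("High-flow nasal cannula", ArmLabelKind.FULL_NAME),
])
def test_classify_intervention_label(label, kind):
    assert classify_intervention_label(label) == kind


@pytest.mark.parametrize("text,expected", [
    ("6-month follow-up", (TimePointLabelKind.UNIT_OF_TIME, 6, "month")),
    ("t_2", (TimePointLabelKind.INCREMENTAL, 2, None)),
    ("Baseline", (TimePointLabelKind.PRE_POST, None, None)),
    ("Week 4", (TimePointLabelKind.UNIT_OF_TIME, 4, "week")),
    ("Visit 3", (TimePointLabelKind.INCREMENTAL, 3, None)),
    ("Pre/Post", (TimePointLabelKind.PRE_POST, None, None)),
    ("Age, y", None),
    ("Placebo", None),
])
def test_classify_timepoint_label(text, expected):
    assert classify_timepoint_label(text) == expected


class TestCategoryStructure:
    def test_indented_categories_group_under_header(self):
        groups = detect_category_structure(["Smoking", "  Yes", "  No"])
        assert len(groups) == 1
        g = groups[0]
        assert (g.name, g.categories, g.placement) == \
            ("Smoking", ["Yes", "No"], "same_array_indented")

    def test_slash_joined_labels_in_one_cell(self):
        groups = detect_category_structure(["Gender M/F"])
        assert groups[0].name == "Gender"
        assert groups[0].categories == ["M", "F"]
        assert groups[0].placement == "in_cell"

    def test_flat_list_has_no_groups(self):
        assert detect_category_structure(["Age", "BMI"]) == []

    def test_unit_slash_is_not_in_cell(self):
        assert detect_category_structure(["Heart rate, beats/min"]) == []

    def test_secondary_array(self):
        groups = detect_category_structure(
            ["Smoking status", "", ""], ["Never", "Former", "Current"])
        assert groups[0].placement == "separate_array"
        assert groups[0].categories == ["Never", "Former", "Current"]


def test_parse_de_label_with_comma_bearing_declaration():
    name, unit, fmt = parse_de_label("Diabetes, n, %")
    assert (name, unit, fmt.id) == ("Diabetes", None, "n_comma_pct")
    name, unit, fmt = parse_de_label("Age, y, mean ± SD")
    assert (name, unit, fmt.id) == ("Age", "y", "mean_pm_sd")


def _classify(cells, n_rows, n_cols, n_header_rows=1):
    g = TableGrid(cells, n_rows, n_cols, n_header_rows, 1)
    a = assign_context_kinds(g)
    return a, classify_structure(a)


class TestAssignAndClassify:
    def test_elements_on_rows_arms_on_columns(self, baseline_grid):
        a, s = assign_context_kinds(baseline_grid), None
        s = classify_structure(a)
        assert (a.row_kinds, a.col_kinds) == ([D], [A])
        assert s.cls is StructureClass.ONE_BY_ONE
        assert s.sublayout == "DEs on rows, arms on columns"

    def test_arms_nested_in_elements(self):
        cells = [Cell("", 0, 0), Cell("Baseline", 0, 1), Cell("6 months", 0, 2),
                 Cell("Pain score", 1, 0), Cell("", 1, 1), Cell("", 1, 2),
                 Cell("  Placebo (n=25)", 2, 0),
                 Cell("6.1 ± 1.2", 2, 1), Cell("4.9 ± 1.4", 2, 2),
                 Cell("  HFNC (n=40)", 3, 0),
                 Cell("6.0 ± 1.1", 3, 1), Cell("3.2 ± 1.5", 3, 2)]
        a, s = _classify(cells, 4, 3)
        assert (a.row_kinds, a.col_kinds) == ([D, A], [T])
        assert s.sublayout == "Arms nested in DEs on rows, TPs on columns"

    def test_embedded_time_in_row_labels(self):
        cells = [Cell("", 0, 0), Cell("Placebo (n=25)", 0, 1),
                 Cell("HFNC (n=40)", 0, 2),
                 Cell("Baseline systolic blood pressure", 1, 0),
                 Cell("132.1 ± 9.0", 1, 1), Cell("131.4 ± 8.2", 1, 2),
                 Cell("Follow-up systolic blood pressure", 2, 0),
                 Cell("128.8 ± 8.1", 2, 1), Cell("120.9 ± 7.7", 2, 2)]
        a, s = _classify(cells, 3, 3)
        assert a.embedded and (a.row_kinds, a.col_kinds) == ([D, T], [A])
        assert s.cls is StructureClass.TWO_BY_ONE

    def test_nested_column_headers_via_spans(self):
        cells = [Cell("", 0, 0), Cell("Placebo (n=25)", 0, 1, col_span=2),
                 Cell("HFNC (n=40)", 0, 3, col_span=2),
                 Cell("", 1, 0), Cell("Baseline", 1, 1), Cell("6 months", 1, 2),
                 Cell("Baseline", 1, 3), Cell("6 months", 1, 4),
                 Cell("Pain score, mean ± SD", 2, 0),
                 Cell("6.1 ± 1.2", 2, 1), Cell("4.9 ± 1.4", 2, 2),
                 Cell("6.0 ± 1.1", 2, 3), Cell("3.2 ± 1.5", 2, 4)]
        a, s = _classify(cells, 3, 5, n_header_rows=2)
        assert (a.row_kinds, a.col_kinds) == ([D], [A, T])
        assert s.sublayout == "DEs on rows, TPs nested in arms on columns"

    def test_comparative_only_detection(self):
        cells = [Cell("Outcome", 0, 0), Cell("Mean difference (95% CI)", 0, 1),
                 Cell("P value", 0, 2),
                 Cell("Pain score", 1, 0), Cell("-1.7 (-2.3 to -1.1)", 1, 1),
                 Cell("0.001", 1, 2)]
        a, s = _classify(cells, 2, 3)
        assert a.comparative_only
        assert s.other_reason is OtherReason.COMPARATIVE_ONLY

    def test_stratified_detection_via_subgroup_lexicon(self):
        cells = [Cell("", 0, 0), Cell("Male (n=30)", 0, 1),
                 Cell("Female (n=34)", 0, 2),
                 Cell("Age, y, mean ± SD", 1, 0),
                 Cell("50.2 ± 8.8", 1, 1), Cell("52.0 ± 9.3", 1, 2)]
        a, s = _classify(cells, 2, 3)
        assert a.stratified and s.other_reason is OtherReason.STRATIFIED

    def test_pooled_single_column_is_not_breakout(self):
        cells = [Cell("", 0, 0), Cell("All patients (n=64)", 0, 1),
                 Cell("Age, y, mean ± SD", 1, 0), Cell("50.2 ± 8.8", 1, 1)]
        a, s = _classify(cells, 2, 2)
        assert a.pooled and a.col_kinds == [A]

    def test_caller_override_forces_other(self, baseline_grid):
        a = assign_context_kinds(baseline_grid)
        s = classify_structure(a, stratified=True)
        assert s.cls is StructureClass.OTHER
        assert s.other_reason is OtherReason.STRATIFIED


class TestLayoutTaxonomy:
    def test_fifteen_distinct_named_layouts(self):
        names = [name for name, _ in LAYOUTS.values()]
        assert len(LAYOUTS) == len(set(names)) == 15

    def test_class_matches_axis_counts(self):
        from tablescout.context import ContextAssignment, AxisLevel
        for (rk, ck, emb), (name, tag) in LAYOUTS.items():
            assignment = ContextAssignment(
                row_levels=[AxisLevel(k, []) for k in rk],
                col_levels=[AxisLevel(k, []) for k in ck],
                embedded=emb)
            s = classify_structure(assignment)
            assert s.sublayout == name and layout_tag(s) == tag
            expected = {(1, 1): StructureClass.ONE_BY_ONE,
                        (2, 1): StructureClass.TWO_BY_ONE,
                        (1, 2): StructureClass.ONE_BY_TWO}[(len(rk), len(ck))]
            assert s.cls is expected

    def test_unsupported_depth(self):
        from tablescout.context import ContextAssignment, AxisLevel
        assignment = ContextAssignment(
            row_levels=[AxisLevel(k, []) for k in (D, A, T)],
            col_levels=[AxisLevel(A, [])])
        s = classify_structure(assignment)
        assert s.other_reason is OtherReason.UNSUPPORTED_DEPTH

    def test_unnamed_pair_recorded_verbatim(self):
        from tablescout.context import ContextAssignment, AxisLevel
        assignment = ContextAssignment(row_levels=[AxisLevel(D, [])],
                                       col_levels=[AxisLevel(T, [])])
        s = classify_structure(assignment)
        assert s.cls is StructureClass.ONE_BY_ONE
        assert s.sublayout == "DE rows x TP cols"
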