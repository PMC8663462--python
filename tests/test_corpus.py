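"""Corpus tagging, Boolean queries, frequency summaries, density."""

import pytest
from random import Random

from tablescout.corpus import (
    DenominatorRule,
    QuerySyntaxError,
    boolean_query,
    density_classifier,
    frequency_table,
    tag_article,
    tag_matches,
    tag_table,
)
from tablescout.extract import extract_table
from tablescout.hierarchy import close_under_parents
from tablescout.model import (
    AnnotatedTable,
    ArticleRecord,
    Cell,
    TableGrid,
    TagAssignment,
    TagScope,
)


def _article(article_id, tags, table_tags=()):
    return ArticleRecord(
        article_id=article_id,
        tables=[AnnotatedTable(grid=None,
                               tags=TagAssignment(TagScope.PER_TABLE, set(t)))
                for t in table_tags],
        article_tags=TagAssignment(TagScope.PER_ARTICLE,
                                   close_under_parents(tags)),
    )


class TestTagTable:
    def test_baseline_table_with_embedded_sizes(self, baseline_grid):
        tags = tag_table(extract_table(baseline_grid)).tags
        assert {"baseline_in_table", "baseline_in_table/arm_level_breakout",
                "context/1x1/de_rows_arm_cols", "arm_size/embedded",
                "format_location/in_header"} <= tags

    def test_comparative_only_table(self):
        cells = [Cell("Outcome", 0, 0), Cell("Mean difference (95% CI)", 0, 1),
                 Cell("P value", 0, 2),
                 Cell("Pain score", 1, 0), Cell("-1.7 (-2.3 to -1.1)", 1, 1),
                 Cell("0.001", 1, 2)]
        g = TableGrid(cells, 2, 3, 1, 1, caption="Comparison of outcomes.")
        tags = tag_table(extract_table(g)).tags
        assert "context/other/comparative_only" in tags
        assert "outcomes_in_table" not in tags

    def test_table_without_statistics_is_untagged(self):
        cells = [Cell("A", 0, 0), Cell("B", 0, 1),
                 Cell("note", 1, 0), Cell("", 1, 1)]
        g = TableGrid(cells, 2, 2, 1, 1, caption="Study flow.")
        assert tag_table(extract_table(g)).tags == set()

    def test_footnote_outranks_header_within_table(self):
        cells = [Cell("", 0, 0), Cell("Control (n=30)", 0, 1),
                 Cell("Age, y, mean ± SD", 1, 0), Cell("50.2 ± 8.8", 1, 1)]
        g = TableGrid(cells, 2, 2, 1, 1,
                      caption="Baseline characteristics.",
                      footnotes=["Data are presented as mean ± SD."])
        tags = tag_table(extract_table(g)).tags
        assert "format_location/in_description_or_footnotes" in tags
        assert "format_location/in_header" not in tags


class TestTagArticle:
    def test_union_across_tables_keeps_both_locations(self):
        t1 = TagAssignment(TagScope.PER_TABLE, close_under_parents(
            {"format_location/in_header"}))
        t2 = TagAssignment(TagScope.PER_TABLE, close_under_parents(
            {"format_location/in_description_or_footnotes"}))
        tags = tag_article([t1, t2]).tags
        assert {"format_location/in_header",
                "format_location/in_description_or_footnotes"} <= tags

    def test_description_arm_size_flag(self):
        tags = tag_article([], arm_size_in_description=True).tags
        assert {"arm_size", "arm_size/description"} <= tags

    def test_units_not_relevant_only_when_no_units_seen(self):
        t = TagAssignment(TagScope.PER_TABLE, close_under_parents(
            {"units_location/in_header"}))
        tags = tag_article([t], units_not_relevant=True).tags
        assert "units_location/not_relevant" not in tags


class TestBooleanQuery:
    def test_and_query(self):
        corpus = [
            _article("a", {"outcomes_in_table",
                           "formats/continuous/mean_pm_sd"}),
            _article("b", {"outcomes_in_table"}),
            _article("c", {"formats/continuous/mean_pm_sd"}),
        ]
        got = boolean_query(
            "outcomes_in_table AND formats/continuous/mean_pm_sd", corpus)
        assert got == ["a"]

    def test_parent_matches_descendants(self):
        corpus = [_article("a", {"baseline_in_table/arm_level_breakout"})]
        assert boolean_query("baseline_in_table", corpus) == ["a"]

    def test_not_on_empty_corpus(self):
        assert boolean_query("NOT x", []) == []

    def test_syntax_error_carries_position(self):
        with pytest.raises(QuerySyntaxError):
            boolean_query("a AND (b OR", [])
        with pytest.raises(QuerySyntaxError):
            boolean_query("AND a", [])

    def test_against_truth_table_oracle(self):
        """Random expressions evaluate identically to direct tree
        evaluation over random tag sets."""
        rng = Random(77)
        tags = [f"tag{i}" for i in range(6)]

        def random_tree(depth):
            if depth == 0 or rng.random() < 0.35:
                return ("tag", rng.choice(tags))
            op = rng.choice(["and", "or", "not"])
            if op == "not":
                return ("not", random_tree(depth - 1))
            return (op, random_tree(depth - 1), random_tree(depth - 1))

        def render(node):
            if node[0] == "tag":
                return node[1]
            if node[0] == "not":
                return f"NOT ({render(node[1])})"
            return f"({render(node[1])} {node[0].upper()} {render(node[2])})"

        def evaluate(node, present):
            if node[0] == "tag":
                return node[1] in present
            if node[0] == "not":
                return not evaluate(node[1], present)
            if node[0] == "and":
                return evaluate(node[1], present) and evaluate(node[2], present)
            return evaluate(node[1], present) or evaluate(node[2], present)

        for _ in range(400):
            tree = random_tree(4)
            present = {t for t in tags if rng.random() < 0.5}
            article = _article("x", set())
            article.article_tags.tags = set(present)
            got = boolean_query(render(tree), [article]) == ["x"]
            assert got == evaluate(tree, present)


class TestFrequencyTable:
    def _corpus_with_tag_count(self, tag, k, n):
        return [
            _article(f"a{i}", {tag} if i < k else set())
            for i in range(n)
        ]

    def test_known_counts_give_printed_interval(self):
        corpus = self._corpus_with_tag_count("baseline_in_table", 66, 78)
        row, = frequency_table(corpus, ["baseline_in_table"])
        assert (row.k, row.n) == (66, 78)
        assert row.ci.rounded_pct(0) == (75.0, 91.0)

    def test_single_article(self):
        corpus = self._corpus_with_tag_count("baseline_in_table", 1, 1)
        row, = frequency_table(corpus, ["baseline_in_table"])
        assert (row.k, row.n, row.proportion) == (1, 1, 1.0)

    def test_numerators_invariant_under_permutation(self):
        corpus = self._corpus_with_tag_count("baseline_in_table", 20, 50)
        fwd, = frequency_table(corpus, ["baseline_in_table"])
        rev, = frequency_table(list(reversed(corpus)), ["baseline_in_table"])
        assert (fwd.k, fwd.n) == (rev.k, rev.n)

    def test_per_table_counts_tables(self):
        corpus = [_article("a", {"table_features/rotated"},
                           table_tags=[{"table_features",
                                        "table_features/rotated"},
                                       {"baseline_in_table"}])]
        row, = frequency_table(corpus, ["table_features/rotated"],
                               DenominatorRule.PER_TABLE)
        assert (row.k, row.n) == (1, 2)

    def test_per_relevant_article_excludes_untagged_parent(self):
        corpus = [
            _article("a", {"arm_size/embedded"}),
            _article("b", {"arm_size/separate_array"}),
            _article("c", {"baseline_in_table"}),  # no arm_size at all
        ]
        row, = frequency_table(corpus, ["arm_size/embedded"],
                               DenominatorRule.PER_RELEVANT_ARTICLE)
        assert (row.k, row.n) == (1, 2)

    def test_empty_denominator_row_omitted(self):
        with pytest.warns(UserWarning):
            rows = frequency_table([], ["baseline_in_table"])
        assert rows == []


class TestDensityClassifier:
    FULL = {"baseline_in_table", "arm_size/embedded",
            "intervention_labels/full_name", "units_location/in_header",
            "format_location/in_header"}

    def test_all_properties_true(self):
        assert density_classifier(_article("a", self.FULL))

    def test_missing_arm_size_fails(self):
        tags = self.FULL - {"arm_size/embedded"}
        assert not density_classifier(_article("a", tags))

    def test_intervention_clause_droppable(self):
        tags = (self.FULL - {"intervention_labels/full_name"}) | \
            {"intervention_labels/alternate"}
        assert not density_classifier(_article("a", tags))
        assert density_classifier(_article("a", tags),
                                  require_intervention_labels=False)

    def test_units_not_relevant_satisfies_units_clause(self):
        tags = (self.FULL - {"units_location/in_header"}) | \
            {"units_location/not_relevant"}
        assert density_classifier(_article("a", tags))


def test_tag_matches_prefix_semantics():
    tags = {"context/1x1/de_rows_arm_cols"}
    assert tag_matches("context", tags)
    assert tag_matches("context/1x1", tags)
    assert not tag_matches("context/2x1", tags)
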