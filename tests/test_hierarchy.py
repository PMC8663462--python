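"""Tag vocabulary: membership, parent implication, closure."""

from random import Random

from tablescout.hierarchy import (
    HIERARCHY,
    close_under_parents,
    validate_tags,
)
from tablescout.model import TagAssignment, TagScope


def _assign(tags):
    return TagAssignment(TagScope.PER_ARTICLE, set(tags))


def test_parent_present_is_valid():
    tags = _assign({"baseline_in_table",
                    "baseline_in_table/arm_level_breakout"})
    assert validate_tags(tags) == []


def test_child_without_parent_is_one_violation():
    out = validate_tags(_assign({"baseline_in_table/arm_level_breakout"}))
    assert len(out) == 1
    assert out[0].problem == "missing_parent"
    assert "baseline_in_table" in out[0].detail


def test_unknown_tag_is_violation_not_exception():
    out = validate_tags(_assign({"flux_capacitor"}))
    assert [v.problem for v in out] == ["unknown_tag"]


def test_random_sets_against_bruteforce_oracle():
    """Violations equal an exhaustive evaluation of both rules."""
    rng = Random(99)
    universe = sorted(HIERARCHY) + ["bogus/one", "unknown"]
    for _ in range(300):
        tags = set(rng.sample(universe, rng.randint(0, 12)))
        got = {(v.tag, v.problem) for v in validate_tags(_assign(tags))}
        expected = set()
        for t in sorted(tags):
            if t not in HIERARCHY:
                expected.add((t, "unknown_tag"))
            else:
                parent = HIERARCHY[t]
                if parent is not None and parent not in tags:
                    expected.add((t, "missing_parent"))
        assert got == expected


def test_closure_makes_any_known_set_valid():
    rng = Random(7)
    universe = sorted(HIERARCHY)
    for _ in range(50):
        tags = close_under_parents(rng.sample(universe, 8))
        assert validate_tags(_assign(tags)) == []
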