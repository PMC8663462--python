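"""Synthetic generator: determinism, internal consistency, ground truth."""

from random import Random

import pytest

from tablescout.formats import DichotomousStats, check_consistency
from tablescout.synth import (
    SyntheticSpec,
    generate_corpus,
    generate_table,
    sample_article_style,
)
from tablescout.verify import verify_roundtrip


def test_same_seed_gives_byte_identical_corpora():
    a = generate_corpus(n_articles=8, seed=42)
    b = generate_corpus(n_articles=8, seed=42)
    ga = [t.grid.to_json() for art in a for t in art.record.tables]
    gb = [t.grid.to_json() for art in b for t in art.record.tables]
    assert ga == gb
    assert [sorted(art.record.article_tags.tags) for art in a] == \
        [sorted(art.record.article_tags.tags) for art in b]


def test_different_seeds_differ():
    a = generate_corpus(n_articles=8, seed=1)
    b = generate_corpus(n_articles=8, seed=2)
    ga = [t.grid.to_json() for art in a for t in art.record.tables]
    gb = [t.grid.to_json() for art in b for t in art.record.tables]
    assert ga != gb


def test_distributions_normalized(spec):
    for dist in (spec.layout_dist, spec.continuous_format_dist,
                 spec.dichotomous_format_dist, spec.arm_size_placement_dist,
                 spec.composition_dist):
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)


def test_rendered_percentages_are_consistent_by_construction(small_corpus):
    """Every ground-truth count with a percentage satisfies the half-up
    consistency relation against its arm size."""
    checked = 0
    for art in small_corpus:
        for truth in art.truth.tables:
            sizes = {a["label"]: a["size"] for a in truth.arms}
            for cell in truth.cells:
                st = cell.stats
                if st.get("kind") != "dichotomous" or st.get("pct") is None \
                        or st.get("n") is None:
                    continue
                total = st.get("n_total") or sizes.get(cell.arm)
                if total is None:
                    continue
                d = DichotomousStats(n=st["n"], n_total=total, pct=st["pct"])
                assert check_consistency(d, 1), (cell.text, total)
                checked += 1
    assert checked > 50


def test_every_nonempty_body_cell_has_ground_truth(small_corpus):
    from tablescout.model import expand_spans
    for art in small_corpus:
        for tbl, truth in zip(art.record.tables, art.truth.tables):
            if truth.other_reason == "comparative_only":
                continue
            g = expand_spans(tbl.grid)
            truth_pos = {(c.row, c.col) for c in truth.cells}
            # every truth position holds a non-empty cell
            mat = g.cell_matrix()
            for r, c in truth_pos:
                assert mat[r][c].strip(), (art.truth.article_id, r, c)


def test_forced_layout_is_respected(spec):
    rng = Random(0)
    style = sample_article_style(spec, rng)
    lid = "context/2x1/tp_in_de_rows_arm_cols"
    grid, truth = generate_table(spec, rng, style=style, layout_id=lid)
    assert truth.layout_id == lid
    assert verify_roundtrip(grid, truth) == []


def test_missing_time_points_raise(spec):
    rng = Random(0)
    style = sample_article_style(spec, rng)
    style.tp_labels = []
    with pytest.raises(ValueError, match="time points"):
        generate_table(spec, rng, style=style,
                       layout_id="context/2x1/tp_in_de_rows_arm_cols")


def test_noise_free_roundtrip_sample(spec):
    rng = Random(2024)
    for _ in range(60):
        style = sample_article_style(spec, rng)
        role = "baseline" if rng.random() < 0.5 else "outcome"
        grid, truth = generate_table(spec, rng, style=style, role=role)
        assert verify_roundtrip(grid, truth) == [], truth.layout_id


def test_missing_cell_noise_drops_metrics(spec):
    from dataclasses import replace
    from tablescout.synth import NoiseSpec
    noisy = replace(spec, noise=NoiseSpec(missing_cell_prob=0.5))
    rng = Random(3)
    style = sample_article_style(noisy, rng)
    grid, truth = generate_table(noisy, rng, style=style,
                                 layout_id="context/1x1/de_rows_arm_cols")
    clean_rng = Random(3)
    style2 = sample_article_style(spec, clean_rng)
    grid2, truth2 = generate_table(spec, clean_rng, style=style2,
                                   layout_id="context/1x1/de_rows_arm_cols")
    assert len(truth.cells) < len(truth2.cells)


def test_article_tags_are_hierarchy_valid(small_corpus):
    from tablescout.hierarchy import validate_tags
    for art in small_corpus:
        assert validate_tags(art.record.article_tags) == []
        for t in art.record.tables:
            assert validate_tags(t.tags) == []
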