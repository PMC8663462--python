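"""Statistic-format catalog: parsing, rendering, inference, arithmetic."""

from fractions import Fraction

import pytest
from random import Random

from tablescout import formats as F
from tablescout.formats import (
    CATALOG,
    FORMATS_BY_ID,
    ContinuousStats,
    DichotomousStats,
    ParseError,
    Placeholder as P,
    check_consistency,
    derive_denominator,
    infer_format,
    parse_format_declaration,
    parse_metric,
    render_metric,
    round_half_up,
)


class TestParseMetric:
    def test_subset_total_percentage(self):
        m = parse_metric("2/59 (3.4%)", FORMATS_BY_ID["n_slash_n_pct"])
        assert (m.n, m.n_total, m.pct) == (2, 59, 3.4)

    def test_mean_pm_sd(self):
        m = parse_metric("12.4 ± 2.3", FORMATS_BY_ID["mean_pm_sd"])
        assert (m.mean, m.sd) == (12.4, 2.3)

    def test_ascii_plus_minus_variant(self):
        m = parse_metric("12.4 +/- 2.3", FORMATS_BY_ID["mean_pm_sd"])
        assert (m.mean, m.sd) == (12.4, 2.3)

    def test_median_range(self):
        m = parse_metric("14 (10-18)", FORMATS_BY_ID["median_range"])
        assert (m.median, m.min, m.max) == (14.0, 10.0, 18.0)

    def test_en_dash_interval(self):
        m = parse_metric("14 (10–18)", FORMATS_BY_ID["median_range"])
        assert (m.min, m.max) == (10.0, 18.0)

    def test_in_cell_categorical_with_labels(self):
        m = parse_metric("11/9", FORMATS_BY_ID["cat_n"],
                         category_labels=["M", "F"])
        assert [(lab, n) for lab, n, _ in m.entries] == [("M", 11), ("F", 9)]

    def test_rest_format_recovers_total(self):
        m = parse_metric("3/(27)", FORMATS_BY_ID["n_over_rest"])
        assert (m.n, m.n_total) == (3, 30)

    def test_mismatch_reports_furthest_position(self):
        with pytest.raises(ParseError) as e:
            parse_metric("12.4 ± x", FORMATS_BY_ID["mean_pm_sd"])
        assert e.value.position >= 6

    def test_trailing_text_is_an_error_not_partial(self):
        with pytest.raises(ParseError):
            parse_metric("12.4 ± 2.3 extra", FORMATS_BY_ID["mean_pm_sd"])

    def test_count_placeholder_rejects_decimals(self):
        with pytest.raises(ParseError):
            parse_metric("12.4 (30.0)", FORMATS_BY_ID["n_pct"])


@pytest.mark.parametrize("text,expected_id", [
    ("mean ± SD", "mean_pm_sd"),
    ("Mean±SD", "mean_pm_sd"),
    ("mean (SD)", "mean_sd_paren"),
    ("Median (IQR)", "median_iqr_unspecified"),
    ("median (IQR; 25th percentile-75th percentile)", "median_iqr_dash"),
    ("n (%)", "n_pct"),
    ("n, %", "n_comma_pct"),
    ("n/N (%)", "n_slash_n_pct"),
    ("flux capacitance", None),
])
def test_parse_format_declaration(text, expected_id):
    fmt = parse_format_declaration(text)
    assert (fmt.id if fmt else None) == expected_id


class TestInferFormat:
    def test_unanimous_match(self):
        res = infer_format(["12.4 ± 2.3", "8.1 ± 1.9"])
        assert res.format.id == "mean_pm_sd" and res.score == 1.0

    def test_integer_paren_is_ambiguous_with_tie_reported(self):
        res = infer_format(["30 (75)", "3 (8)"])
        ids = {res.format.id} | {t.id for t in res.ties}
        assert res.score == 1.0
        assert {"mean_sd_paren", "n_pct"} <= ids
        # catalog order resolves the winner deterministically
        assert res.format.id == "mean_sd_paren"

    def test_two_numbers_in_parens_excludes_mean_sd(self):
        res = infer_format(["14 (10-18)"])
        assert res.format.metric_kind.value == "continuous_median"
        assert "mean_sd_paren" not in {t.id for t in res.ties}

    def test_uninferable(self):
        assert infer_format(["not a metric"]) is None


class TestCountArithmetic:
    def test_worked_percentage_is_consistent(self):
        assert check_consistency(DichotomousStats(2, 59, 3.4), 1)

    def test_zero_numerator(self):
        assert check_consistency(DichotomousStats(0, 10, 0.0), 1)

    def test_inconsistent_percentage(self):
        assert not check_consistency(DichotomousStats(30, 40, 74.9), 1)

    def test_denominator_candidates_for_worked_metric(self):
        assert derive_denominator(2, 3.4, 1, 1000) == {58, 59}

    def test_exact_half(self):
        assert derive_denominator(5, 50.0, 1, 100) == {10}

    def test_against_exact_fraction_oracle(self):
        def oracle(n, pct, decimals, n_max):
            # floor(100*n*scale/N + 1/2) in exact integer arithmetic
            target = Fraction(str(pct))
            scale = 10 ** decimals
            return {
                N for N in range(max(n, 1), n_max + 1)
                if Fraction((200 * n * scale + N) // (2 * N), scale) == target
            }
        assert derive_denominator(1, 0.5, 1, 1000) == oracle(1, 0.5, 1, 1000)
        assert derive_denominator(7, 21.2, 1, 500) == oracle(7, 21.2, 1, 500)

    def test_soundness_when_pct_produced_by_rounding(self, rng):
        for _ in range(200):
            N = rng.randint(1, 800)
            n = rng.randint(0, N)
            if n == 0:
                continue
            pct = round_half_up(100 * n / N, 1)
            assert N in derive_denominator(n, pct, 1, 1000)


def _admissible_values(rng, fmt):
    vals = {}
    for ph in fmt.placeholders:
        if ph in (P.N, P.N_TOTAL, P.REST):
            vals[ph] = rng.randrange(0, 500)
        else:
            vals[ph] = round(rng.uniform(0.1, 99.9), 1)
    if P.P25 in vals and P.P75 in vals:
        lo, hi = sorted((vals[P.P25], vals[P.P75]))
        vals[P.P25], vals[P.P75] = lo, hi
        if P.MEDIAN in vals:
            vals[P.MEDIAN] = round((lo + hi) / 2, 1)
    if P.MIN in vals and P.MAX in vals:
        lo, hi = sorted((vals[P.MIN], vals[P.MAX]))
        vals[P.MIN], vals[P.MAX] = lo, hi
        if P.MEDIAN in vals:
            vals[P.MEDIAN] = round((lo + hi) / 2, 1)
    if P.CI_LO in vals and P.CI_HI in vals:
        lo, hi = sorted((vals[P.CI_LO], vals[P.CI_HI]))
        vals[P.CI_LO], vals[P.CI_HI] = lo, hi
    if P.N in vals and P.N_TOTAL in vals:
        vals[P.N_TOTAL] = vals[P.N] + rng.randrange(1, 100)
    if P.PCT in vals:
        if P.N in vals and P.N_TOTAL in vals:
            vals[P.PCT] = round_half_up(100 * vals[P.N] / vals[P.N_TOTAL], 1)
        else:
            vals[P.PCT] = round(rng.uniform(0.1, 100.0), 1)
    return vals


@pytest.mark.parametrize("fmt", [f for f in CATALOG if not f.multi_array],
                         ids=lambda f: f.id)
def test_render_parse_roundtrip(fmt, rng):
    """Rendering then parsing recovers every tuple at printed precision."""
    for _ in range(100):
        vals = _admissible_values(rng, fmt)
        text = render_metric(fmt, vals, 1, pct_sign=rng.random() < 0.5)
        parsed = parse_metric(text, fmt)
        d = parsed.to_dict()
        back = {
            P.MEAN: d.get("mean"), P.SD: d.get("sd"),
            P.MEDIAN: d.get("median"), P.P25: d.get("p25"),
            P.P75: d.get("p75"), P.MIN: d.get("min"), P.MAX: d.get("max"),
            P.CI_LO: d.get("ci_lo"), P.CI_HI: d.get("ci_hi"),
            P.N: d.get("n"), P.PCT: d.get("pct"),
        }
        for ph, v in vals.items():
            if ph is P.N_TOTAL:
                assert d.get("n_total") == v
            elif ph is P.REST:
                assert d.get("n_total") == vals[P.N] + v
            else:
                assert back[ph] == pytest.approx(float(v), abs=1e-9), \
                    (fmt.id, text, ph)


def test_catalog_ids_unique_and_families_covered():
    ids = [f.id for f in CATALOG]
    assert len(ids) == len(set(ids)) == 23
    kinds = {f.metric_kind.value for f in CATALOG}
    assert kinds == {"continuous_mean", "continuous_median",
                     "dichotomous", "categorical"}
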