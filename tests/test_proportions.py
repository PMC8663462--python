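"""Wilson score intervals: closed form, boundaries, cross-checks."""

import math

import pytest
from random import Random
from statsmodels.stats.proportion import proportion_confint

from tablescout.proportions import wilson_ci


def test_matches_statsmodels_wilson_to_1e9():
    rng = Random(4)
    for _ in range(200):
        n = rng.randint(1, 500)
        k = rng.randint(0, n)
        ci = wilson_ci(k, n)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert ci.lower == pytest.approx(float(lo), abs=1e-9)
        assert ci.upper == pytest.approx(float(hi), abs=1e-9)


def test_independent_closed_form():
    # independent re-derivation of the score interval
    from scipy.stats import norm
    k, n, conf = 22, 52, 0.95
    z = float(norm.ppf(1 - (1 - conf) / 2))
    p = k / n
    centre = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    ci = wilson_ci(k, n, conf)
    assert ci.lower == pytest.approx(centre - half, abs=1e-12)
    assert ci.upper == pytest.approx(centre + half, abs=1e-12)


def test_boundary_cases_exact():
    assert wilson_ci(0, 10).lower == 0.0
    assert wilson_ci(10, 10).upper == 1.0
    ci = wilson_ci(0, 10)
    assert 0.0 < ci.upper < 1.0


def test_interval_contains_p_hat_and_is_ordered():
    rng = Random(11)
    for _ in range(100):
        n = rng.randint(1, 300)
        k = rng.randint(0, n)
        ci = wilson_ci(k, n)
        assert 0.0 <= ci.lower <= ci.p_hat <= ci.upper <= 1.0


def test_width_shrinks_with_n_at_fixed_proportion():
    widths = []
    for n in (10, 20, 40, 80, 160, 320):
        k = int(round(0.3 * n))
        ci = wilson_ci(k, n)
        widths.append(ci.upper - ci.lower)
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_domain_errors():
    with pytest.raises(ValueError):
        wilson_ci(1, 0)
    with pytest.raises(ValueError):
        wilson_ci(5, 3)


def test_rounded_pct_uses_half_up():
    ci = wilson_ci(66, 78)
    assert ci.rounded_pct(0) == (75.0, 91.0)
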