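"""Synthetic RCT table and corpus generation with ground truth.

Generates annotated baseline/outcome tables whose layout, label and
statistic-format distributions default to the observed frequencies in the
comparative clinical literature: layouts proportional to the table-survey
counts (the dominant layout being data elements on rows and arms on
columns), arm-size reporting mostly embedded in intervention headers,
statistic formats dominated by mean ± SD and n (%), and so on.  Every
rendered metric carries ground truth (context, format id, constituent
values at printed precision), making the generator the oracle for the
detection and parsing pipeline.

Style attributes (arm labelling, size placement, format declaration
location, category-label placement) are sampled once per article and
shared by its tables, mirroring journal/author consistency; layouts are
sampled per table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from random import Random
from typing import Optional

from . import formats as F
from .formats import Placeholder as P
from .formats import StatisticFormat, render_metric, round_half_up
from .hierarchy import close_under_parents
from .model import Cell, TableGrid, TagAssignment, TagScope, ArticleRecord, AnnotatedTable

__all__ = [
    "NoiseSpec", "SyntheticSpec", "ArticleStyle", "CellTruth", "TableTruth",
    "ArticleTruth", "SyntheticArticle", "generate_table", "generate_corpus",
    "sample_article_style", "LAYOUT_DEFS",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _norm(d: dict) -> dict:
    total = float(sum(d.values()))
    if total <= 0:
        raise ValueError("distribution weights must sum to a positive value")
    return {k: v / total for k, v in d.items()}


@dataclass
class NoiseSpec:
    missing_cell_prob: float = 0.0
    unicode_variant_prob: float = 0.0
    rounding_decimals: int = 1


def _default_layout_dist() -> dict:
    return {
        "context/1x1/de_rows_arm_cols": 90,
        "context/1x1/arm_rows_de_cols": 5,
        "context/1x1/arm_rows_tp_cols": 2,
        "context/1x1/tp_rows_arm_cols": 2,
        "context/2x1/tp_in_de_rows_arm_cols": 18,
        "context/2x1/arm_in_de_rows_tp_cols": 8,
        "context/2x1/de_in_arm_rows_tp_cols": 2,
        "context/2x1/arm_in_tp_rows_de_cols": 2,
        "context/2x1/de_tp_embedded_rows_arm_cols": 2,
        "context/2x1/tp_in_arm_rows_de_cols": 1,
        "context/2x1/de_in_tp_rows_arm_cols": 1,
        "context/1x2/de_rows_tp_in_arm_cols": 16,
        "context/1x2/de_rows_arm_in_tp_cols": 5,
        "context/1x2/arm_rows_tp_in_de_cols": 3,
        "context/1x2/de_rows_arm_tp_embedded_cols": 2,
        "context/other/stratified": 8,
        "context/other/comparative_only": 7,
    }


def _default_continuous_dist() -> dict:
    # mean family then median family, weights as observed per article
    return {
        "mean_pm_sd": 41, "mean_sd_paren": 25, "mean_sd_separate_arrays": 2,
        "mean_bare": 2, "mean_sd_space": 1, "mean_ci": 1, "mean_pm_sd_range": 1,
        "median_iqr_dash": 11, "median_range": 4, "median_iqr_bracket": 3,
        "median_iqr_bracket_comma": 1, "median_iqr_to": 1,
        "median_iqr_unspecified": 1, "min_max_median": 1,
    }


_MEDIAN_IDS = {"median_iqr_dash", "median_range", "median_iqr_bracket",
               "median_iqr_bracket_comma", "median_iqr_to",
               "median_iqr_unspecified", "min_max_median"}


@dataclass
class SyntheticSpec:
    """Generative configuration; defaults follow the observed frequencies."""

    layout_dist: dict = field(default_factory=_default_layout_dist)
    continuous_format_dist: dict = field(default_factory=_default_continuous_dist)
    dichotomous_format_dist: dict = field(default_factory=lambda: {
        "n_pct": 30, "n_bare": 3, "n_over_rest": 3, "pct_bare": 3,
        "n_comma_pct": 2, "n_pct_separate_arrays": 1})
    categorical_format_dist: dict = field(default_factory=lambda: {
        "cat_n_pct": 40, "cat_n": 8})
    arm_size_placement_dist: dict = field(default_factory=lambda: {
        "embedded": 50, "separate_array": 6, "description": 1, "none": 20})
    intervention_label_dist: dict = field(default_factory=lambda: {
        "control_experimental": 26, "abbreviation": 25, "full_name": 23,
        "alternate": 3})
    timepoint_label_dist: dict = field(default_factory=lambda: {
        "pre_post": 24, "unit_of_time": 22, "incremental": 6})
    format_location_dist: dict = field(default_factory=lambda: {
        "header": 35, "footnote": 30, "none": 12})
    units_location_dist: dict = field(default_factory=lambda: {
        "header": 55, "footnote": 9})
    category_placement_dist: dict = field(default_factory=lambda: {
        "same_array_indented": 35, "separate_array": 7, "in_cell": 7,
        "same_array": 1})
    composition_dist: dict = field(default_factory=lambda: {
        "both": 61, "baseline_only": 5, "outcome_only": 11, "none": 1})
    units_relevant_prob: float = 64 / 75
    extra_baseline_table_prob: float = 1 / 66
    extra_outcome_table_prob: float = 35 / 72
    rotated_prob: float = 6 / 174
    multipage_prob: float = 5 / 174
    # pooled (no-breakout) baseline reporting is a variant of the dominant
    # elements-on-rows/arms-on-columns layout; the probability is
    # conditional on that layout so the overall rate stays 2 per 67
    # baseline tables without disturbing the layout distribution
    baseline_no_breakout_prob: float = (2 / 67) / (90 / 174)
    outcome_secondary_only_prob: float = 2 / 107
    participant_level_prob: float = 0.0
    n_arms_dist: dict = field(default_factory=lambda: {2: 0.7, 3: 0.3})
    arm_size_range: tuple = (20, 200)
    n_baseline_elements_range: tuple = (4, 8)
    n_outcome_elements_range: tuple = (3, 6)
    n_time_points_range: tuple = (2, 3)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("layout_dist", "continuous_format_dist",
                     "dichotomous_format_dist", "categorical_format_dist",
                     "arm_size_placement_dist", "intervention_label_dist",
                     "timepoint_label_dist", "format_location_dist",
                     "units_location_dist", "category_placement_dist",
                     "composition_dist", "n_arms_dist"):
            setattr(self, name, _norm(getattr(self, name)))
        assert abs(sum(self.layout_dist.values()) - 1.0) < 1e-9


def _weighted(rng: Random, dist: dict):
    x = rng.random()
    acc = 0.0
    items = list(dist.items())
    for key, w in items:
        acc += w
        if x < acc:
            return key
    return items[-1][0]


# ---------------------------------------------------------------------------
# Domain pools
# ---------------------------------------------------------------------------

_BASELINE_CONT = [
    ("Age", "y", 52.0, 12.0),
    ("Body mass index", "kg/m2", 27.2, 4.1),
    ("Systolic blood pressure", "mm Hg", 131.0, 12.0),
    ("Heart rate", "beats/min", 76.0, 10.0),
    ("Serum creatinine", "mg/dL", 1.0, 0.3),
    ("Waist circumference", "cm", 94.0, 11.0),
]
_UNITLESS_CONT = [
    ("Pain score", None, 6.2, 1.8),
    ("Quality of life score", None, 55.0, 14.0),
    ("Symptom severity score", None, 12.4, 4.8),
    ("Anxiety score", None, 9.1, 3.2),
]
_OUTCOME_CONT = [
    ("Hospital stay", "d", 6.4, 2.9),
    ("Six-minute walk distance", "m", 420.0, 80.0),
    ("Forced expiratory volume", "L", 2.6, 0.7),
    ("Serum ferritin", "ng/mL", 88.0, 30.0),
]
_BASELINE_DICH = [
    ("Male sex", 0.55), ("Diabetes", 0.22), ("Current smoker", 0.31),
    ("Hypertension", 0.38), ("Prior surgery", 0.18),
]
_OUTCOME_DICH = [
    ("Mortality", 0.08), ("Treatment success", 0.62),
    ("Adverse events", 0.20), ("Readmission", 0.12), ("Infection", 0.09),
]
_CATEGORICAL = [
    ("Smoking status", ["Never", "Former", "Current"]),
    ("Disease severity", ["Mild", "Moderate", "Severe"]),
]
_IN_CELL_DE = ("Sex", ["M", "F"])

_FULL_NAME_ARMS = ["Placebo", "Standard care", "Oseltamivir", "Dexamethasone",
                   "Metformin", "Atorvastatin", "Acupuncture"]
_ABBREV_ARMS = [("High-flow nasal cannula", "HFNC"),
                ("Continuous positive airway pressure", "CPAP"),
                ("Cognitive behavioural therapy", "CBT"),
                ("Pulmonary rehabilitation", "PR"),
                ("Intravenous iron", "IVI")]
_CONTROL_ARMS = [["Control", "Treatment", "Intervention"],
                 ["Control", "Experimental", "Intervention"]]
_ALTERNATE_ARMS = ["Group A", "Group B", "Group C"]
_STRATA = [("Male", "Female"), ("Site A", "Site B")]

_PRE_POST_SETS = [["Baseline", "Follow-up", "Final"],
                  ["Pre", "Post"], ["Before", "After"]]
_UNIT_TIME_SETS = [["6 months", "12 months", "24 months"],
                   ["4 weeks", "8 weeks", "12 weeks"],
                   ["24 hours", "48 hours"], ["1 year", "2 years"]]
_INCREMENTAL_SETS = [["T1", "T2", "T3"], ["Visit 1", "Visit 2", "Visit 3"]]

# header text used when a format is declared in a data-element header
_HEADER_DECL = {
    "mean_pm_sd": "mean ± SD",
    "mean_sd_paren": "mean (SD)",
    "mean_bare": "mean",
    "mean_sd_space": "mean SD",
    "mean_ci": "mean (CI)",
    "mean_pm_sd_range": "mean ± SD (range)",
    "median_iqr_dash": "median (IQR; 25th percentile-75th percentile)",
    "median_range": "median (range)",
    "median_iqr_bracket": "median [IQR; 25th percentile-75th percentile]",
    "median_iqr_bracket_comma": "median [IQR; 25th percentile, 75th percentile]",
    "median_iqr_to": "median (IQR; 25th percentile to 75th percentile)",
    "median_iqr_unspecified": "median (IQR)",
    "min_max_median": "min-max (median)",
    "n_pct": "n (%)",
    "n_bare": "n",
    "n_over_rest": "n/(N-n)",
    "pct_bare": "%",
    "n_comma_pct": "n, %",
    "n_slash_n_pct": "n/N (%)",
    "cat_n_pct": "n (%)",
    "cat_n": "n",
}

# footnote phrasing per format (scanned back by declaration detection)
_FOOTNOTE_DECL = dict(_HEADER_DECL)
_FOOTNOTE_DECL.update({
    "mean_bare": "means",
    "n_bare": "numbers of patients",
    "pct_bare": "percentages",
})

# formats whose rendered pattern is ambiguous without a declaration
# (identical token shape to another format under the integer-count vs
# decimal-continuous convention); undeclared articles avoid them
_NOT_SELF_IDENTIFYING = {"mean_ci", "median_range", "median_iqr_unspecified",
                         "mean_sd_separate_arrays", "n_pct_separate_arrays"}


# ---------------------------------------------------------------------------
# Layout descriptors
# ---------------------------------------------------------------------------

#: layout tag id -> (row axis tokens, col axis tokens)
LAYOUT_DEFS: dict[str, tuple[list[str], list[str]]] = {
    "context/1x1/de_rows_arm_cols": (["de"], ["arm"]),
    "context/1x1/arm_rows_de_cols": (["arm"], ["de"]),
    "context/1x1/arm_rows_tp_cols": (["arm"], ["tp"]),
    "context/1x1/tp_rows_arm_cols": (["tp"], ["arm"]),
    "context/2x1/tp_in_de_rows_arm_cols": (["de", "tp"], ["arm"]),
    "context/2x1/arm_in_de_rows_tp_cols": (["de", "arm"], ["tp"]),
    "context/2x1/de_in_arm_rows_tp_cols": (["arm", "de"], ["tp"]),
    "context/2x1/arm_in_tp_rows_de_cols": (["tp", "arm"], ["de"]),
    "context/2x1/de_tp_embedded_rows_arm_cols": (["de+tp"], ["arm"]),
    "context/2x1/tp_in_arm_rows_de_cols": (["arm", "tp"], ["de"]),
    "context/2x1/de_in_tp_rows_arm_cols": (["tp", "de"], ["arm"]),
    "context/1x2/de_rows_tp_in_arm_cols": (["de"], ["arm", "tp"]),
    "context/1x2/de_rows_arm_in_tp_cols": (["de"], ["tp", "arm"]),
    "context/1x2/arm_rows_tp_in_de_cols": (["arm"], ["de", "tp"]),
    "context/1x2/de_rows_arm_tp_embedded_cols": (["de"], ["arm+tp"]),
    "context/other/stratified": (["de"], ["strata"]),
    "context/other/comparative_only": (["de"], ["comparative"]),
}

_KIND_OF = {"de": "data_element", "arm": "arm", "tp": "time_point"}

_SINGLE_DE_LAYOUTS = {"context/1x1/arm_rows_tp_cols",
                      "context/1x1/tp_rows_arm_cols"}

# layouts whose column axis can host constituent sub-columns
_CONSTITUENT_OK_COLS = (["arm"], ["tp"], ["arm", "tp"], ["tp", "arm"],
                        ["arm+tp"])


# ---------------------------------------------------------------------------
# Article style
# ---------------------------------------------------------------------------

@dataclass
class ArticleStyle:
    label_kind: str
    arm_labels: list[str]
    arm_sizes: list[int]
    size_placement: str
    tp_kind: str
    tp_labels: list[str]
    mean_fmt: str
    median_fmt: str
    dich_fmt: str
    cat_fmt: str
    fmt_placement: str
    units_relevant: bool
    units_placement: str
    cat_placement: str


def sample_article_style(spec: SyntheticSpec, rng: Random) -> ArticleStyle:
    label_kind = _weighted(rng, spec.intervention_label_dist)
    n_arms = _weighted(rng, spec.n_arms_dist)
    if label_kind == "control_experimental":
        arm_labels = rng.choice(_CONTROL_ARMS)[:n_arms]
    elif label_kind == "abbreviation":
        pairs = rng.sample(_ABBREV_ARMS, n_arms)
        arm_labels = [abbr for _, abbr in pairs]
    elif label_kind == "full_name":
        arm_labels = rng.sample(_FULL_NAME_ARMS, n_arms)
    else:
        arm_labels = _ALTERNATE_ARMS[:n_arms]
    arm_sizes = [rng.randint(*spec.arm_size_range) for _ in arm_labels]

    tp_kind = _weighted(rng, spec.timepoint_label_dist)
    tp_sets = {"pre_post": _PRE_POST_SETS, "unit_of_time": _UNIT_TIME_SETS,
               "incremental": _INCREMENTAL_SETS}[tp_kind]
    tp_labels = list(rng.choice(tp_sets))

    fmt_placement = _weighted(rng, spec.format_location_dist)

    def pick(dist: dict, allowed=None) -> str:
        d = dict(dist)
        if allowed is not None:
            d = {k: v for k, v in d.items() if k in allowed}
        return _weighted(rng, _norm(d))

    if fmt_placement == "none":
        ok = set(F.FORMATS_BY_ID) - _NOT_SELF_IDENTIFYING
        mean_fmt = pick(spec.continuous_format_dist,
                        {k for k in ok if k not in _MEDIAN_IDS})
        median_fmt = pick(spec.continuous_format_dist,
                          ok & _MEDIAN_IDS)
        dich_fmt = pick(spec.dichotomous_format_dist, ok)
        cat_fmt = pick(spec.categorical_format_dist, ok)
    else:
        mean_fmt = pick(spec.continuous_format_dist,
                        set(spec.continuous_format_dist) - _MEDIAN_IDS)
        median_fmt = pick(spec.continuous_format_dist, _MEDIAN_IDS)
        dich_fmt = pick(spec.dichotomous_format_dist)
        cat_fmt = pick(spec.categorical_format_dist)
        if fmt_placement == "footnote" and mean_fmt == "mean_ci" and \
                median_fmt in ("median_iqr_dash", "median_range",
                               "median_iqr_unspecified"):
            # table-level declarations cannot separate two formats with an
            # identical printed shape; switch to the bracketed variant
            median_fmt = "median_iqr_bracket"

    return ArticleStyle(
        label_kind=label_kind,
        arm_labels=arm_labels,
        arm_sizes=arm_sizes,
        size_placement=_weighted(rng, spec.arm_size_placement_dist),
        tp_kind=tp_kind,
        tp_labels=tp_labels,
        mean_fmt=mean_fmt,
        median_fmt=median_fmt,
        dich_fmt=dich_fmt,
        cat_fmt=cat_fmt,
        fmt_placement=fmt_placement,
        units_relevant=rng.random() < spec.units_relevant_prob,
        units_placement=_weighted(rng, spec.units_location_dist),
        cat_placement=_weighted(rng, spec.category_placement_dist),
    )


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    row: int
    col: int
    text: str
    de: Optional[str]
    arm: Optional[str]
    tp: Optional[str]
    category: Optional[str]
    format_id: str
    stats: dict


@dataclass
class TableTruth:
    layout_id: str
    cls: str
    row_kinds: list[str]
    col_kinds: list[str]
    embedded: bool
    other_reason: Optional[str]
    sublayout: Optional[str]
    role: str
    secondary_only: bool
    pooled: bool
    arms: list[dict]
    time_points: list[str]
    cells: list[CellTruth] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)


@dataclass
class ArticleTruth:
    article_id: str
    style: ArticleStyle
    tables: list[TableTruth] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)


@dataclass
class SyntheticArticle:
    record: ArticleRecord
    truth: ArticleTruth


# ---------------------------------------------------------------------------
# Value synthesis
# ---------------------------------------------------------------------------

def _rv(x: float, d: int) -> float:
    """Value at printed precision (exactly what rendering will show)."""
    return float(f"{x:.{d}f}")


def _binom(rng: Random, n: int, p: float) -> int:
    return sum(rng.random() < p for _ in range(n))


def _continuous_values(rng: Random, fmt: StatisticFormat, mu: float,
                       sigma: float, n: int, d: int) -> dict:
    mean = rng.gauss(mu, sigma * 0.2)
    sd = sigma * rng.uniform(0.8, 1.2)
    half_ci = 1.96 * sd / math.sqrt(max(n, 2))
    raw = {
        P.MEAN: mean, P.SD: sd, P.MEDIAN: mean,
        P.P25: mean - 0.67 * sd, P.P75: mean + 0.67 * sd,
        P.MIN: mean - 2.5 * sd, P.MAX: mean + 2.5 * sd,
        P.CI_LO: mean - half_ci, P.CI_HI: mean + half_ci,
    }
    return {ph: _rv(raw[ph], d) for ph in fmt.placeholders}


def _dichotomous_values(rng: Random, fmt: StatisticFormat, size: int,
                        p: float, d: int) -> dict:
    n = _binom(rng, size, p)
    vals: dict = {}
    for ph in fmt.placeholders:
        if ph is P.N:
            vals[ph] = n
        elif ph is P.N_TOTAL:
            vals[ph] = size
        elif ph is P.REST:
            vals[ph] = size - n
        elif ph is P.PCT:
            vals[ph] = _rv(round_half_up(100.0 * n / size, d), d)
    if not vals:  # pct-only format
        vals[P.PCT] = _rv(round_half_up(100.0 * n / size, d), d)
    return vals


def _truth_stats(fmt: StatisticFormat, vals: dict) -> dict:
    return F._stats_from_values(fmt, vals).to_dict()


# ---------------------------------------------------------------------------
# Table generation
# ---------------------------------------------------------------------------

@dataclass
class _DE:
    name: str
    kind: str  # continuous | dichotomous | categorical
    unit: Optional[str] = None
    categories: Optional[list[str]] = None
    mu: float = 0.0
    sigma: float = 1.0
    p: float = 0.3
    fmt: Optional[StatisticFormat] = None


def _sample_des(spec: SyntheticSpec, rng: Random, style: ArticleStyle,
                role: str, allow_categorical: bool,
                force_family: Optional[str]) -> list[_DE]:
    d: list[_DE] = []
    cont_pool = list(_BASELINE_CONT if role == "baseline" else _OUTCOME_CONT)
    if not style.units_relevant:
        cont_pool = []
    cont_pool = cont_pool + list(_UNITLESS_CONT)
    dich_pool = list(_BASELINE_DICH if role == "baseline" else _OUTCOME_DICH)
    lo, hi = (spec.n_baseline_elements_range if role == "baseline"
              else spec.n_outcome_elements_range)
    total = rng.randint(lo, hi)

    if force_family == "continuous":
        chosen = rng.sample(cont_pool, min(total, len(cont_pool)))
        for name, unit, mu, sigma in chosen:
            d.append(_DE(name, "continuous", unit, None, mu, sigma,
                         fmt=F.FORMATS_BY_ID[style.mean_fmt]))
        return d
    if force_family == "dichotomous":
        chosen = rng.sample(dich_pool, min(total, len(dich_pool)))
        for name, p in chosen:
            d.append(_DE(name, "dichotomous", p=p,
                         fmt=F.FORMATS_BY_ID[style.dich_fmt]))
        return d

    n_cont = min(rng.randint(1, max(1, total - 1)), len(cont_pool))
    n_cat = 0
    if allow_categorical and rng.random() < 0.55:
        n_cat = 1
    n_dich = max(1, total - n_cont - n_cat)
    for name, unit, mu, sigma in rng.sample(cont_pool, n_cont):
        fid = style.median_fmt if rng.random() < 22 / 95 else style.mean_fmt
        d.append(_DE(name, "continuous", unit, None, mu, sigma,
                     fmt=F.FORMATS_BY_ID[fid]))
    for name, p in rng.sample(dich_pool, min(n_dich, len(dich_pool))):
        d.append(_DE(name, "dichotomous", p=p,
                     fmt=F.FORMATS_BY_ID[style.dich_fmt]))
    if n_cat:
        cat_fmt = F.FORMATS_BY_ID[style.cat_fmt]
        if style.cat_placement == "in_cell":
            name, cats = _IN_CELL_DE
        else:
            name, cats = rng.choice(_CATEGORICAL)
        d.append(_DE(name, "categorical", None, list(cats), fmt=cat_fmt))
    rng.shuffle(d)
    return d


def _de_label(de: _DE, style: ArticleStyle, declare: bool) -> str:
    parts = [de.name]
    if de.kind == "categorical" and style.cat_placement == "in_cell":
        parts = [f"{de.name} {'/'.join(de.categories)}"]
    if de.kind == "continuous" and de.unit and style.units_placement == "header":
        parts.append(de.unit)
    if declare and de.fmt is not None:
        fid = de.fmt.id
        if not de.fmt.multi_array:  # constituent headers declare themselves
            parts.append(_HEADER_DECL[fid])
    return ", ".join(parts)


def _arm_header(label: str, size: int, style: ArticleStyle, rng: Random) -> str:
    if style.size_placement != "embedded":
        return label
    return f"{label} ({'n='}{size})" if rng.random() < 0.7 else f"{label} [n={size}]"


def generate_table(
    spec: SyntheticSpec,
    rng: Random,
    style: Optional[ArticleStyle] = None,
    role: str = "baseline",
    layout_id: Optional[str] = None,
    secondary_only: bool = False,
    no_breakout: bool = False,
) -> tuple[TableGrid, TableTruth]:
    """Generate one annotated table.

    ``style`` carries the article-level conventions (sampled fresh when
    omitted); ``layout_id`` forces a sub-layout (sampled from the layout
    distribution when omitted).
    """
    if style is None:
        style = sample_article_style(spec, rng)
    if layout_id is None:
        layout_id = _weighted(rng, spec.layout_dist)
    no_breakout = no_breakout and \
        layout_id == "context/1x1/de_rows_arm_cols"
    row_axis, col_axis = LAYOUT_DEFS[layout_id]
    d = spec.noise.rounding_decimals
    stratified = col_axis == ["strata"]
    comparative = col_axis == ["comparative"]
    single_de = layout_id in _SINGLE_DE_LAYOUTS
    pct_sign = style.fmt_placement == "none"

    # constituent (separate-array) formats: eligible layouts only; other
    # layouts substitute the parenthesized sibling format
    constituent: Optional[str] = None
    eff_style = style
    eligible = (not stratified and not comparative and not single_de
                and not no_breakout and col_axis in _CONSTITUENT_OK_COLS)
    if style.mean_fmt == "mean_sd_separate_arrays" and eligible:
        constituent = "mean_sd"
    elif style.dich_fmt == "n_pct_separate_arrays" and eligible:
        constituent = "n_pct"
    if style.mean_fmt == "mean_sd_separate_arrays" and constituent != "mean_sd":
        eff_style = replace(eff_style, mean_fmt="mean_sd_paren")
    if style.dich_fmt == "n_pct_separate_arrays" and constituent != "n_pct":
        eff_style = replace(eff_style, dich_fmt="n_pct")
    style_r = eff_style
    if constituent is not None and "arm" in row_axis and \
            style_r.size_placement == "separate_array":
        # a bare "n" column is indistinguishable from a constituent column;
        # embed the sizes in the arm labels instead
        style_r = replace(style_r, size_placement="embedded")

    fmt_placement = style_r.fmt_placement
    if single_de and fmt_placement == "header":
        fmt_placement = "footnote"

    allow_categorical = (row_axis == ["de"] and not comparative
                         and constituent is None)
    force_family = {"mean_sd": "continuous", "n_pct": "dichotomous"}.get(
        constituent or "")
    des = _sample_des(spec, rng, style_r, role, allow_categorical, force_family)
    if single_de:
        des = des[:1]
        if des[0].kind != "continuous":
            name, unit, mu, sigma = rng.choice(_UNITLESS_CONT)
            des = [_DE(name, "continuous", unit, None, mu, sigma,
                       fmt=F.FORMATS_BY_ID[style_r.mean_fmt])]

    needs_tp = any("tp" in t for t in row_axis + col_axis)
    n_tp = min(rng.randint(*spec.n_time_points_range), len(style_r.tp_labels))
    tps = style_r.tp_labels[:n_tp] if needs_tp else []
    if needs_tp and not tps:
        raise ValueError("layout requires time points but none are configured")

    if no_breakout:
        total = sum(style_r.arm_sizes)
        arm_items = [("All patients", total)]
    elif stratified:
        strata = rng.choice(_STRATA)
        total = sum(style_r.arm_sizes)
        s0 = rng.randint(total // 3, 2 * total // 3)
        arm_items = [(strata[0], s0), (strata[1], total - s0)]
    else:
        arm_items = list(zip(style_r.arm_labels, style_r.arm_sizes))

    header_decl = fmt_placement == "header" and not comparative

    # ---- leaf columns ----------------------------------------------------
    # each leaf: (arm_idx|None, tp_idx|None, de_idx|None, constituent role)
    leaves: list[tuple] = []
    axis_items = {
        "arm": list(range(len(arm_items))),
        "strata": list(range(len(arm_items))),
        "tp": list(range(len(tps))),
        "de": list(range(len(des))),
        "comparative": [0, 1],
    }
    if col_axis in (["arm"], ["strata"], ["tp"], ["de"], ["comparative"]):
        for i in axis_items[col_axis[0]]:
            leaves.append({col_axis[0]: i})
    elif col_axis == ["arm+tp"]:
        for ai in axis_items["arm"]:
            for ti in axis_items["tp"]:
                leaves.append({"arm": ai, "tp": ti})
    else:  # two nested levels
        outer, inner = col_axis
        for oi in axis_items[outer]:
            for ii in axis_items[inner]:
                leaves.append({outer: oi, inner: ii})

    if constituent is not None:
        expanded = []
        for leaf in leaves:
            expanded.append({**leaf, "part": "primary"})
            expanded.append({**leaf, "part": "companion"})
        leaves = expanded

    n_header_rows = (2 if len(col_axis) == 2 and col_axis != ["arm+tp"] else 1)
    if constituent is not None:
        n_header_rows += 1
    n_header_cols = 1
    if (allow_categorical and style_r.cat_placement == "separate_array"
            and any(de.kind == "categorical" for de in des)):
        n_header_cols = 2

    # ---- rows ------------------------------------------------------------
    # each row: ("group", label) | ("metric", de_idx|None, arm_idx|None,
    #            tp_idx|None, category|None)
    rows: list[tuple] = []
    if row_axis == ["de"]:
        for di, de in enumerate(des):
            if de.kind == "categorical" and \
                    style_r.cat_placement == "same_array_indented":
                rows.append(("group", di, None, None, None))
                for cat in de.categories:
                    rows.append(("metric", di, None, None, cat))
            elif de.kind == "categorical" and \
                    style_r.cat_placement == "separate_array":
                for k, cat in enumerate(de.categories):
                    rows.append(("metric", di, None, None, cat))
            elif de.kind == "categorical" and \
                    style_r.cat_placement == "same_array":
                rows.append(("group", di, None, None, None))
                for cat in de.categories:
                    rows.append(("metric", di, None, None, cat))
            else:  # plain row (in_cell categorical renders in one row)
                rows.append(("metric", di, None, None, None))
    elif row_axis == ["de+tp"]:
        for di in range(len(des)):
            for ti in range(len(tps)):
                rows.append(("metric", di, None, ti, None))
    elif row_axis in (["arm"], ["tp"]):
        which = row_axis[0]
        for i in axis_items[which]:
            rows.append(("metric", None, i if which == "arm" else None,
                         i if which == "tp" else None, None))
    else:  # two nested levels on rows
        outer, inner = row_axis
        for oi in axis_items[outer]:
            rows.append(("group-" + outer, oi))
            for ii in axis_items[inner]:
                spec_row = {"de": None, "arm": None, "tp": None}
                spec_row[outer] = oi
                spec_row[inner] = ii
                rows.append(("metric", spec_row["de"], spec_row["arm"],
                             spec_row["tp"], None))

    size_row = (style_r.size_placement == "separate_array"
                and not stratified and not comparative and not no_breakout
                and ("arm" in col_axis or col_axis == ["arm+tp"]))
    size_col = (style_r.size_placement == "separate_array"
                and not stratified and not comparative and not no_breakout
                and "arm" in row_axis)

    n_rows = n_header_rows + len(rows) + (1 if size_row else 0)
    n_cols = n_header_cols + len(leaves) + (1 if size_col else 0)

    cells: list[Cell] = []
    truth_cells: list[CellTruth] = []
    footnotes: list[str] = []

    # ---- column headers --------------------------------------------------
    def leaf_col(j: int) -> int:
        return n_header_cols + (1 if size_col else 0) + j

    if size_col:
        cells.append(Cell("n", n_header_rows - 1, n_header_cols))

    if len(col_axis) == 2 and col_axis != ["arm+tp"]:
        outer, inner = col_axis
        per = len(leaves) // len(axis_items[outer])
        j = 0
        for oi in axis_items[outer]:
            text = _axis_label(outer, oi, arm_items, tps, des, style_r, rng,
                               header_decl)
            cells.append(Cell(text, 0, leaf_col(j), 1, per))
            j += per
        row1 = 1
        for j, leaf in enumerate(leaves):
            if constituent is not None and leaf.get("part") == "companion":
                continue
            ii = leaf[inner]
            text = _axis_label(inner, ii, arm_items, tps, des, style_r, rng,
                               header_decl)
            span = 2 if constituent is not None else 1
            cells.append(Cell(text, row1, leaf_col(j), 1, span))
    else:
        seen_span: set[int] = set()
        for j, leaf in enumerate(leaves):
            if j in seen_span:
                continue
            if constituent is not None and leaf.get("part") == "companion":
                continue
            if col_axis == ["arm+tp"]:
                ai, ti = leaf["arm"], leaf["tp"]
                label, size = arm_items[ai]
                text = f"{_arm_header(label, size, style_r, rng)}, {tps[ti]}"
            elif comparative:
                text = ["Mean difference (95% CI)", "P value"][leaf["comparative"]]
            else:
                key = col_axis[0]
                text = _axis_label(key, leaf[key], arm_items, tps, des,
                                   style_r, rng, header_decl)
            span = 2 if constituent is not None else 1
            if span == 2:
                seen_span.add(j + 1)
            cells.append(Cell(text, 0, leaf_col(j), 1, span))
    if constituent is not None:
        names = ("Mean", "SD") if constituent == "mean_sd" else ("n", "%")
        for j, leaf in enumerate(leaves):
            cells.append(Cell(names[0] if leaf["part"] == "primary" else names[1],
                              n_header_rows - 1, leaf_col(j)))

    # ---- row headers and body -------------------------------------------
    r0 = n_header_rows
    if size_row:
        cells.append(Cell("No. of patients", r0, 0))
        for j, leaf in enumerate(leaves):
            if constituent is not None and leaf.get("part") == "companion":
                continue
            ai = leaf.get("arm")
            if ai is not None:
                cells.append(Cell(str(arm_items[ai][1]), r0, leaf_col(j)))
        r0 += 1

    arm_rendered = [False] * len(arm_items)
    used_formats: list[StatisticFormat] = []

    for k, rowdef in enumerate(rows):
        r = r0 + k
        tag = rowdef[0]
        if tag.startswith("group-") or tag == "group":
            if tag == "group":
                di = rowdef[1]
                de = des[di]
                declare = header_decl and de.kind == "categorical"
                cells.append(Cell(_de_label(de, style_r, declare), r, 0))
            else:
                which = tag.split("-", 1)[1]
                oi = rowdef[1]
                text = _axis_label(which, oi, arm_items, tps, des, style_r,
                                   rng, header_decl)
                if which == "arm":
                    arm_rendered[oi] = True
                cells.append(Cell(text, r, 0))
            continue
        _, di, ai, ti, cat = rowdef
        # row label
        if row_axis == ["de"]:
            de = des[di]
            if cat is not None and style_r.cat_placement == "same_array_indented":
                cells.append(Cell("  " + cat, r, 0))
            elif cat is not None and style_r.cat_placement == "separate_array":
                if de.categories[0] == cat:
                    cells.append(Cell(_de_label(de, style_r, header_decl), r, 0))
                cells.append(Cell(cat, r, 1))
            elif cat is not None:  # same_array, unindented
                cells.append(Cell(cat, r, 0))
            else:
                cells.append(Cell(_de_label(de, style_r, header_decl), r, 0))
        elif row_axis == ["de+tp"]:
            de = des[di]
            base = _de_label(de, style_r, header_decl)
            cells.append(Cell(f"{tps[ti]} {base[0].lower() + base[1:]}", r, 0))
        elif row_axis in (["arm"], ["tp"]):
            if ai is not None:
                label, size = arm_items[ai]
                cells.append(Cell(_arm_header(label, size, style_r, rng), r, 0))
                arm_rendered[ai] = True
            else:
                cells.append(Cell(tps[ti], r, 0))
        else:  # nested rows: indented inner label
            inner = row_axis[1]
            if inner == "arm":
                label, size = arm_items[ai]
                cells.append(Cell("  " + _arm_header(label, size, style_r, rng),
                                  r, 0))
                arm_rendered[ai] = True
            elif inner == "tp":
                cells.append(Cell("  " + tps[ti], r, 0))
            else:
                de = des[di]
                cells.append(Cell("  " + _de_label(de, style_r, header_decl),
                                  r, 0))
        if size_col:
            if ai is not None:
                cells.append(Cell(str(arm_items[ai][1]), r, n_header_cols))

        # body cells
        if comparative:
            de = des[di]
            diff = _rv(rng.gauss(0, de.sigma * 0.3), d)
            lo = _rv(diff - 0.5 * de.sigma, d)
            hi = _rv(diff + 0.5 * de.sigma, d)
            cells.append(Cell(f"{diff} ({lo} to {hi})", r, leaf_col(0)))
            cells.append(Cell(f"{_rv(rng.uniform(0.001, 0.9), 2)}", r, leaf_col(1)))
            continue
        for j, leaf in enumerate(leaves):
            if constituent is not None and leaf.get("part") == "companion":
                continue
            c_di = leaf.get("de", di)
            c_ai = leaf.get("arm", leaf.get("strata", ai))
            c_ti = leaf.get("tp", ti)
            if c_di is None and single_de:
                c_di = 0
            if c_di is None:
                continue
            de = des[c_di]
            if de.kind == "categorical" and cat is None and \
                    style_r.cat_placement != "in_cell":
                continue  # category values live on the category rows
            arm_label, arm_size = (arm_items[c_ai] if c_ai is not None
                                   else (None, sum(s for _, s in arm_items)))
            tp_label = tps[c_ti] if c_ti is not None else None
            if rng.random() < spec.noise.missing_cell_prob:
                continue
            text, fmt_used, stats = _render_cell(
                rng, de, style_r, constituent, cat, arm_size, d, pct_sign)
            if constituent is not None:
                comp_val = stats.pop("__companion__")
                cells.append(Cell(text, r, leaf_col(j)))
                cells.append(Cell(comp_val, r, leaf_col(j + 1)))
            else:
                cells.append(Cell(_maybe_unicode_noise(text, rng, spec), r,
                                  leaf_col(j)))
            used_formats.append(fmt_used)
            # unindented ("same array") category labels are not
            # distinguishable from sibling data elements without semantic
            # knowledge; ground truth records what the table itself shows
            same_array_cat = (cat is not None and
                              style_r.cat_placement == "same_array")
            truth_cells.append(CellTruth(
                row=r, col=leaf_col(j), text=text,
                de=cat if same_array_cat else de.name,
                arm=arm_label, tp=tp_label,
                category=None if same_array_cat else cat,
                format_id=fmt_used.id, stats=stats,
            ))

    # ---- caption and footnotes ------------------------------------------
    role_word = "Baseline characteristics" if role == "baseline" else "Outcomes"
    if single_de:
        caption = f"{role_word}: {des[0].name} by study arm and time point."
    elif stratified:
        caption = f"{role_word} stratified by subgroup."
    elif comparative:
        caption = "Comparison of outcomes between study arms."
    elif secondary_only:
        caption = "Secondary outcomes."
    elif role == "baseline":
        caption = "Baseline characteristics of the study arms."
    else:
        caption = "Primary and secondary outcomes."

    if fmt_placement == "footnote" and used_formats:
        decls = []
        for f in used_formats:
            if f.multi_array:
                continue  # constituent column headers declare themselves
            base = {"cat_n_pct": "n_pct", "cat_n": "n_bare"}.get(f.id, f.id)
            phrase = _FOOTNOTE_DECL[base]
            if phrase not in decls:
                decls.append(phrase)
        footnotes.append("Data are presented as " + " or ".join(decls) + ".")
    if style_r.units_placement == "footnote":
        united = [de for de in des if de.kind == "continuous" and de.unit]
        if united and not comparative:
            footnotes.append("Units: " + "; ".join(
                f"{de.name.lower()} in {de.unit}" for de in united) + ".")

    grid = TableGrid(
        cells=cells, n_rows=n_rows, n_cols=n_cols,
        n_header_rows=n_header_rows, n_header_cols=n_header_cols,
        caption=caption, footnotes=footnotes,
        rotated=rng.random() < spec.rotated_prob,
        multipage=rng.random() < spec.multipage_prob,
    )

    truth = _build_truth(layout_id, role, secondary_only, no_breakout,
                         stratified, comparative, grid, style_r, arm_items,
                         arm_rendered, tps, des, used_formats, truth_cells,
                         fmt_placement, constituent, header_decl)
    return grid, truth


def _axis_label(kind: str, i: int, arm_items, tps, des, style: ArticleStyle,
                rng: Random, header_decl: bool) -> str:
    if kind in ("arm", "strata"):
        label, size = arm_items[i]
        if kind == "strata":
            return f"{label} (n={size})"
        return _arm_header(label, size, style, rng)
    if kind == "tp":
        return tps[i]
    return _de_label(des[i], style, header_decl)


def _render_cell(rng: Random, de: _DE, style: ArticleStyle,
                 constituent: Optional[str], cat: Optional[str],
                 arm_size: int, d: int, pct_sign: bool):
    """Returns (text, format, truth-stats dict)."""
    if constituent == "mean_sd":
        fmt = F.FORMATS_BY_ID["mean_sd_separate_arrays"]
        vals = _continuous_values(rng, F.FORMATS_BY_ID["mean_pm_sd"],
                                  de.mu, de.sigma, arm_size, d)
        stats = F.ContinuousStats(central_kind="mean", mean=vals[P.MEAN],
                                  sd=vals[P.SD]).to_dict()
        stats["__companion__"] = f"{vals[P.SD]:.{d}f}"
        return f"{vals[P.MEAN]:.{d}f}", fmt, stats
    if constituent == "n_pct":
        fmt = F.FORMATS_BY_ID["n_pct_separate_arrays"]
        n = _binom(rng, arm_size, de.p)
        pct = _rv(round_half_up(100.0 * n / arm_size, d), d)
        stats = F.DichotomousStats(n=n, pct=pct).to_dict()
        stats["__companion__"] = f"{pct:.{d}f}"
        return str(n), fmt, stats
    fmt = de.fmt
    if de.kind == "continuous":
        vals = _continuous_values(rng, fmt, de.mu, de.sigma, arm_size, d)
        return (render_metric(fmt, vals, d, pct_sign=False), fmt,
                _truth_stats(fmt, vals))
    if de.kind == "dichotomous":
        vals = _dichotomous_values(rng, fmt, arm_size, de.p, d)
        # a bare percentage is printed with its % sign: without it the
        # number is indistinguishable from a bare mean
        sign = pct_sign or fmt.id == "pct_bare"
        return (render_metric(fmt, vals, d, pct_sign=sign), fmt,
                _truth_stats(fmt, vals))
    # categorical
    if cat is None:  # in_cell: whole distribution in one cell
        ns = _cat_counts(rng, arm_size, len(de.categories))
        chunks = []
        entries = []
        for lab, n in zip(de.categories, ns):
            if fmt.id == "cat_n_pct":
                pct = _rv(round_half_up(100.0 * n / arm_size, d), d)
                chunks.append(render_metric(fmt, {P.N: n, P.PCT: pct}, d,
                                            pct_sign=pct_sign))
                entries.append({"label": lab, "n": n, "pct": pct})
            else:
                chunks.append(str(n))
                entries.append({"label": lab, "n": n, "pct": None})
        stats = {"kind": "categorical", "label_placement": "in_cell",
                 "entries": entries}
        return "/".join(chunks), fmt, stats
    # one category row: a count (optionally with percentage)
    share = 1.0 / len(de.categories)
    n = _binom(rng, arm_size, share)
    if fmt.id == "cat_n_pct":
        pct = _rv(round_half_up(100.0 * n / arm_size, d), d)
        vals = {P.N: n, P.PCT: pct}
    else:
        vals = {P.N: n}
    if style.cat_placement == "same_array":
        fmt = F.FORMATS_BY_ID[{"cat_n_pct": "n_pct", "cat_n": "n_bare"}[fmt.id]]
    return (render_metric(fmt, vals, d, pct_sign=pct_sign), fmt,
            _truth_stats(fmt, vals))


def _cat_counts(rng: Random, total: int, k: int) -> list[int]:
    remaining = total
    out = []
    for i in range(k - 1):
        n = _binom(rng, remaining, 1.0 / (k - i))
        out.append(n)
        remaining -= n
    out.append(remaining)
    return out


def _maybe_unicode_noise(text: str, rng: Random, spec: SyntheticSpec) -> str:
    if rng.random() < spec.noise.unicode_variant_prob:
        return text.replace("±", "+/-").replace("-", "–")
    return text


def _build_truth(layout_id, role, secondary_only, no_breakout, stratified,
                 comparative, grid, style, arm_items, arm_rendered, tps, des,
                 used_formats, truth_cells, fmt_placement, constituent,
                 header_decl) -> TableTruth:
    from .context import LAYOUTS
    from .model import ContextKind as K

    row_axis, col_axis = LAYOUT_DEFS[layout_id]
    if layout_id.startswith("context/other/"):
        cls, other_reason, sublayout = "other", layout_id.rsplit("/", 1)[1], None
        row_kinds = ["data_element"]
        col_kinds = ["arm"] if stratified else []
        embedded = False
    else:
        def kinds(axis):
            out = []
            for tok in axis:
                if tok in ("de+tp",):
                    out += ["data_element", "time_point"]
                elif tok in ("arm+tp",):
                    out += ["arm", "time_point"]
                else:
                    out.append(_KIND_OF[tok])
            return out
        row_kinds, col_kinds = kinds(row_axis), kinds(col_axis)
        embedded = "de+tp" in row_axis or "arm+tp" in col_axis
        cls = layout_id.split("/")[1]
        other_reason = None
        key = (tuple(K(k) for k in row_kinds), tuple(K(k) for k in col_kinds),
               embedded)
        sublayout = LAYOUTS[key][0]

    tags: set[str] = set()
    if not comparative:
        if role == "baseline":
            tags.add("baseline_in_table")
            tags.add("baseline_in_table/no_arm_level_breakout" if no_breakout
                     else "baseline_in_table/arm_level_breakout")
        else:
            tags.add("outcomes_in_table")
            if secondary_only:
                tags.add("outcomes_in_table/secondary_only")
            else:
                tags.add("outcomes_in_table/arm_level_breakout")
    tags.add(layout_id)
    if grid.rotated:
        tags.add("table_features/rotated")
    if grid.multipage:
        tags.add("table_features/multipage")
    arms_truth = []
    any_arm = any(arm_rendered) or (not stratified and not comparative
                                    and not no_breakout)
    if not stratified and not comparative:
        for (label, size), rendered in zip(arm_items, arm_rendered):
            placement = (style.size_placement
                         if style.size_placement in ("embedded", "separate_array")
                         else None)
            arms_truth.append({"label": label if not no_breakout else "All patients",
                               "size": size,
                               "rendered_size": placement})
        if not no_breakout:
            tags.add(f"intervention_labels/{style.label_kind}")
            if style.size_placement in ("embedded", "separate_array"):
                tags.add(f"arm_size/{style.size_placement}")
    if tps and not comparative:
        tags.add(f"timepoint_labels/{style.tp_kind}")
    if not comparative and used_formats:
        if constituent is not None or (header_decl and fmt_placement == "header"):
            tags.add("format_location/in_header")
        elif fmt_placement == "footnote":
            tags.add("format_location/in_description_or_footnotes")
        fam = {"continuous_mean": "continuous", "continuous_median": "continuous",
               "dichotomous": "dichotomous", "categorical": "categorical"}
        for f in used_formats:
            tags.add(f"formats/{fam[f.metric_kind.value]}/{f.id}")
        united = [de for de in des if de.kind == "continuous" and de.unit]
        if united:
            tags.add("units_location/in_header"
                     if style.units_placement == "header"
                     else "units_location/in_description_or_footnotes")
        if any(de.kind == "categorical" for de in des):
            tags.add(f"category_labels/{style.cat_placement}")

    return TableTruth(
        layout_id=layout_id, cls=cls, row_kinds=row_kinds, col_kinds=col_kinds,
        embedded=embedded, other_reason=other_reason, sublayout=sublayout,
        role=role, secondary_only=secondary_only, pooled=no_breakout,
        arms=arms_truth, time_points=list(tps), cells=truth_cells,
        tags=close_under_parents(tags),
    )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(
    spec: Optional[SyntheticSpec] = None,
    n_articles: int = 78,
    seed: Optional[int] = None,
) -> list[SyntheticArticle]:
    """Generate a corpus of annotated articles, deterministically per seed."""
    spec = spec if spec is not None else SyntheticSpec()
    rng = Random(seed if seed is not None else spec.seed)
    out: list[SyntheticArticle] = []
    for i in range(n_articles):
        article_id = f"A{i + 1:04d}"
        style = sample_article_style(spec, rng)
        composition = _weighted(rng, spec.composition_dist)
        roles: list[str] = []
        if composition in ("both", "baseline_only"):
            roles += ["baseline"] * (1 + (rng.random() <
                                          spec.extra_baseline_table_prob))
        if composition in ("both", "outcome_only"):
            roles += ["outcome"] * (1 + (rng.random() <
                                         spec.extra_outcome_table_prob))
        tables: list[AnnotatedTable] = []
        truths: list[TableTruth] = []
        for role in roles:
            secondary = (role == "outcome" and
                         rng.random() < spec.outcome_secondary_only_prob)
            no_break = (role == "baseline" and
                        rng.random() < spec.baseline_no_breakout_prob)
            grid, truth = generate_table(spec, rng, style=style, role=role,
                                         secondary_only=secondary,
                                         no_breakout=no_break)
            tables.append(AnnotatedTable(
                grid=grid,
                tags=TagAssignment(TagScope.PER_TABLE, set(truth.tags)),
            ))
            truths.append(truth)

        article_tags: set[str] = set()
        for t in truths:
            article_tags |= t.tags
        has_tables = any(
            t for t in truths
            if "baseline_in_table" in t.tags or "outcomes_in_table" in t.tags
        )
        if style.size_placement == "description" and has_tables:
            article_tags.add("arm_size/description")
        has_continuous_units = any(
            tag.startswith("units_location/") for tag in article_tags)
        if has_tables and not has_continuous_units:
            article_tags.add("units_location/not_relevant")
        article_tags = close_under_parents(article_tags)

        record = ArticleRecord(
            article_id=article_id,
            tables=tables,
            article_tags=TagAssignment(TagScope.PER_ARTICLE, set(article_tags)),
        )
        truth = ArticleTruth(article_id=article_id, style=style,
                             tables=truths, tags=set(article_tags))
        out.append(SyntheticArticle(record=record, truth=truth))
    return out
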