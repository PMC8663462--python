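"""Statistic-format catalog and parsing of descriptive-statistic strings.

Descriptive statistics in trial tables are printed in compact
micro-formats: ``12.4 ± 2.3`` (mean ± SD), ``14 (10-18)`` (median and
range), ``2/59 (3.4%)`` (subset, total and percentage).  Each format is a
fixed token pattern over numeric placeholders and literal delimiters.  The
catalog enumerates the formats observed for continuous, dichotomous and
categorical metrics; the parser binds every placeholder to a number or
fails with the furthest-match position, never returning a partial result.

Arithmetic helpers close the loop between counts and percentages:
``check_consistency`` verifies that a printed percentage equals the
half-up-rounded ratio, and ``derive_denominator`` recovers the candidate
total population sizes behind an ``n`` / ``%`` pair, which is how missing
arm sizes can be reconstructed from count metrics.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MetricKind",
    "Placeholder",
    "StatisticFormat",
    "ContinuousStats",
    "DichotomousStats",
    "CategoricalStats",
    "CategoryLabelPlacement",
    "CATALOG",
    "FORMATS_BY_ID",
    "ParseError",
    "parse_metric",
    "render_metric",
    "parse_format_declaration",
    "scan_declarations",
    "infer_format",
    "InferenceResult",
    "check_consistency",
    "derive_denominator",
    "round_half_up",
    "normalize_text",
    "categorical_equivalent",
]


# ---------------------------------------------------------------------------
# Numeric helpers
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 0) -> float:
    """Round to ``decimals`` places with ties away from zero upward.

    This matches how authors round printed percentages (2/59 -> 3.4%),
    unlike banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def normalize_text(text: str) -> str:
    """Normalize unicode variants before parsing.

    ``+/-`` and U+00B1 unify to ``±``; minus/en/em dashes to ``-``;
    non-breaking spaces to plain spaces; whitespace runs collapse.
    """
    text = unicodedata.normalize("NFC", text)
    text = text.replace("+/-", "±").replace("+/−", "±")
    for dash in ("−", "–", "—"):
        text = text.replace(dash, "-")
    text = text.replace(" ", " ")
    return re.sub(r"\s+", " ", text).strip()


# ---------------------------------------------------------------------------
# Tokens and formats
# ---------------------------------------------------------------------------

class MetricKind(str, Enum):
    CONTINUOUS_MEAN = "continuous_mean"
    CONTINUOUS_MEDIAN = "continuous_median"
    DICHOTOMOUS = "dichotomous"
    CATEGORICAL = "categorical"


class Placeholder(str, Enum):
    MEAN = "MEAN"
    SD = "SD"
    MEDIAN = "MEDIAN"
    P25 = "P25"
    P75 = "P75"
    MIN = "MIN"
    MAX = "MAX"
    N = "N"
    N_TOTAL = "N_TOTAL"
    PCT = "PCT"
    CI_LO = "CI_LO"
    CI_HI = "CI_HI"
    # REST is the "N - n" remainder printed by the n/(N-n) format; the
    # parser folds it back into n_total = n + rest.
    REST = "REST"


_INT_PLACEHOLDERS = {Placeholder.N, Placeholder.N_TOTAL, Placeholder.REST}

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?")
_INT_RE = re.compile(r"\d+")


@dataclass(frozen=True)
class StatisticFormat:
    """One printed micro-format: an id, a metric kind and a token pattern.

    ``pattern`` mixes :class:`Placeholder` members with literal delimiter
    strings.  ``multi_array`` formats split their constituents across two
    parallel arrays (e.g. a "Mean" column and an "SD" column); their
    pattern covers the primary array only and ``companion`` names the
    placeholder carried by the second array.
    """

    id: str
    metric_kind: MetricKind
    pattern: tuple
    display_name: str
    multi_array: bool = False
    companion: Optional[Placeholder] = None

    def __post_init__(self) -> None:
        phs = [t for t in self.pattern if isinstance(t, Placeholder)]
        if not self.pattern or len(phs) != len(set(phs)):
            raise ValueError(f"format {self.id}: empty pattern or duplicate placeholder")

    @property
    def placeholders(self) -> tuple[Placeholder, ...]:
        return tuple(t for t in self.pattern if isinstance(t, Placeholder))


P = Placeholder

# Catalog order is the deterministic tie-break for inference: continuous
# formats first (mean family, then median family, with the textually
# ambiguous mean-CI format last among continuous), then dichotomous,
# categorical, and the n/N (%) extension.
CATALOG: tuple[StatisticFormat, ...] = (
    StatisticFormat("mean_pm_sd", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN, "±", P.SD), "Mean ± SD"),
    StatisticFormat("mean_sd_paren", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN, "(", P.SD, ")"), "Mean (SD)"),
    StatisticFormat("mean_sd_separate_arrays", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN,), "Mean and SD in separate arrays",
                    multi_array=True, companion=P.SD),
    StatisticFormat("mean_bare", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN,), "Mean"),
    StatisticFormat("mean_sd_space", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN, P.SD), "Mean SD"),
    StatisticFormat("mean_pm_sd_range", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN, "±", P.SD, "(", P.MIN, "-", P.MAX, ")"),
                    "Mean ± SD (range; min-max)"),
    StatisticFormat("median_iqr_dash", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "(", P.P25, "-", P.P75, ")"),
                    "Median (IQR; 25th percentile-75th percentile)"),
    StatisticFormat("median_range", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "(", P.MIN, "-", P.MAX, ")"),
                    "Median (range, min-max)"),
    StatisticFormat("median_iqr_bracket", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "[", P.P25, "-", P.P75, "]"),
                    "Median [IQR; 25th percentile-75th percentile]"),
    StatisticFormat("median_iqr_bracket_comma", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "[", P.P25, ",", P.P75, "]"),
                    "Median [IQR; 25th percentile, 75th percentile]"),
    StatisticFormat("median_iqr_to", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "(", P.P25, "to", P.P75, ")"),
                    "Median (IQR; 25th percentile to 75th percentile)"),
    # Printed as "Median (IQR)": same token shape as the dash variant, kept
    # as a distinct id because the literature prints it as its own format.
    StatisticFormat("median_iqr_unspecified", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MEDIAN, "(", P.P25, "-", P.P75, ")"),
                    "Median (IQR)"),
    StatisticFormat("min_max_median", MetricKind.CONTINUOUS_MEDIAN,
                    (P.MIN, "-", P.MAX, "(", P.MEDIAN, ")"),
                    "Min-Max (median)"),
    StatisticFormat("mean_ci", MetricKind.CONTINUOUS_MEAN,
                    (P.MEAN, "(", P.CI_LO, "-", P.CI_HI, ")"),
                    "Mean (CI; lower-higher)"),
    StatisticFormat("n_pct", MetricKind.DICHOTOMOUS,
                    (P.N, "(", P.PCT, ")"), "n (%)"),
    StatisticFormat("n_bare", MetricKind.DICHOTOMOUS,
                    (P.N,), "n"),
    StatisticFormat("n_over_rest", MetricKind.DICHOTOMOUS,
                    (P.N, "/", "(", P.REST, ")"), "n/(N-n)"),
    StatisticFormat("pct_bare", MetricKind.DICHOTOMOUS,
                    (P.PCT,), "%"),
    StatisticFormat("n_comma_pct", MetricKind.DICHOTOMOUS,
                    (P.N, ",", P.PCT), "n, %"),
    StatisticFormat("n_pct_separate_arrays", MetricKind.DICHOTOMOUS,
                    (P.N,), "n and % in separate arrays",
                    multi_array=True, companion=P.PCT),
    StatisticFormat("cat_n_pct", MetricKind.CATEGORICAL,
                    (P.N, "(", P.PCT, ")"), "n (%)"),
    StatisticFormat("cat_n", MetricKind.CATEGORICAL,
                    (P.N,), "n"),
    StatisticFormat("n_slash_n_pct", MetricKind.DICHOTOMOUS,
                    (P.N, "/", P.N_TOTAL, "(", P.PCT, ")"), "n/N (%)"),
)

FORMATS_BY_ID: dict[str, StatisticFormat] = {f.id: f for f in CATALOG}

_CAT_EQUIV = {"n_pct": "cat_n_pct", "n_bare": "cat_n"}


def categorical_equivalent(fmt: StatisticFormat) -> StatisticFormat:
    """The categorical sibling of a count format (n (%) or bare n)."""
    return FORMATS_BY_ID.get(_CAT_EQUIV.get(fmt.id, fmt.id), fmt)


# ---------------------------------------------------------------------------
# Parsed-statistic containers
# ---------------------------------------------------------------------------

@dataclass
class ContinuousStats:
    central_kind: str  # "mean" | "median"
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    p25: Optional[float] = None
    p75: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.central_kind not in ("mean", "median"):
            raise ValueError("central_kind must be 'mean' or 'median'")
        if self.p25 is not None and self.p75 is not None and self.p25 > self.p75:
            raise ValueError("p25 must not exceed p75")
        if (self.p25 is not None and self.median is not None and self.p25 > self.median) or (
            self.p75 is not None and self.median is not None and self.median > self.p75
        ):
            raise ValueError("median must lie within [p25, p75]")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError("min must not exceed max")
        if self.ci_lo is not None and self.ci_hi is not None and self.ci_lo > self.ci_hi:
            raise ValueError("ci_lo must not exceed ci_hi")

    def to_dict(self) -> dict:
        return {
            "kind": "continuous",
            "central_kind": self.central_kind,
            "mean": self.mean, "sd": self.sd, "median": self.median,
            "p25": self.p25, "p75": self.p75, "min": self.min, "max": self.max,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
        }


@dataclass
class DichotomousStats:
    """Subset count, total population and percentage (n/N, %).

    ``n`` is None only for the bare-percentage format, which prints no
    count at all.
    """

    n: Optional[int]
    n_total: Optional[int] = None
    pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 0:
            raise ValueError("n must be non-negative")
        if self.n_total is not None:
            if self.n_total <= 0:
                raise ValueError("n_total must be positive")
            if self.n is not None and self.n > self.n_total:
                raise ValueError("n must not exceed n_total")
        if self.pct is not None and not (0.0 <= self.pct <= 100.0):
            raise ValueError("pct must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {"kind": "dichotomous", "n": self.n, "n_total": self.n_total,
                "pct": self.pct}


class CategoryLabelPlacement(str, Enum):
    SEPARATE_ARRAY = "separate_array"
    SAME_ARRAY = "same_array"
    SAME_ARRAY_INDENTED = "same_array_indented"
    IN_CELL = "in_cell"


@dataclass
class CategoricalStats:
    """Per-category counts; one entry per category label."""

    entries: list[tuple]  # (label, n, pct-or-None)
    label_placement: CategoryLabelPlacement = CategoryLabelPlacement.SAME_ARRAY_INDENTED

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("entries must be non-empty")
        labels = [e[0] for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("category labels must be distinct")

    def to_dict(self) -> dict:
        return {
            "kind": "categorical",
            "label_placement": self.label_placement.value,
            "entries": [
                {"label": lab, "n": n, "pct": pct} for lab, n, pct in self.entries
            ],
        }


ParsedMetric = "ContinuousStats | DichotomousStats | CategoricalStats"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Pattern mismatch; carries the furthest position reached."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(message)
        self.position = position


def _match_pattern(text: str, pattern: Sequence) -> dict[Placeholder, float]:
    """Consume ``text`` with the token pattern; all input must be used."""
    pos = 0
    values: dict[Placeholder, float] = {}
    for token in pattern:
        while pos < len(text) and text[pos] == " ":
            pos += 1
        if isinstance(token, Placeholder):
            regex = _INT_RE if token in _INT_PLACEHOLDERS else _NUM_RE
            m = regex.match(text, pos)
            if not m:
                raise ParseError(
                    f"expected a number for {token.value} at position {pos} in {text!r}",
                    pos,
                )
            raw = m.group(0)
            pos = m.end()
            if token is Placeholder.PCT:
                probe = pos
                while probe < len(text) and text[probe] == " ":
                    probe += 1
                if probe < len(text) and text[probe] == "%":
                    pos = probe + 1
            values[token] = int(raw) if token in _INT_PLACEHOLDERS else float(raw)
        else:
            if not text.startswith(token, pos):
                raise ParseError(
                    f"expected {token!r} at position {pos} in {text!r}", pos
                )
            pos += len(token)
    while pos < len(text) and text[pos] == " ":
        pos += 1
    if pos != len(text):
        raise ParseError(f"unmatched trailing text at position {pos} in {text!r}", pos)
    return values


def _stats_from_values(
    fmt: StatisticFormat, values: dict[Placeholder, float]
) -> "ContinuousStats | DichotomousStats":
    if fmt.metric_kind in (MetricKind.CONTINUOUS_MEAN, MetricKind.CONTINUOUS_MEDIAN):
        central = "mean" if fmt.metric_kind is MetricKind.CONTINUOUS_MEAN else "median"
        return ContinuousStats(
            central_kind=central,
            mean=values.get(P.MEAN),
            sd=values.get(P.SD),
            median=values.get(P.MEDIAN),
            p25=values.get(P.P25),
            p75=values.get(P.P75),
            min=values.get(P.MIN),
            max=values.get(P.MAX),
            ci_lo=values.get(P.CI_LO),
            ci_hi=values.get(P.CI_HI),
        )
    n = int(values[P.N]) if P.N in values else None
    n_total = values.get(P.N_TOTAL)
    if P.REST in values:
        n_total = (n or 0) + int(values[P.REST])
    pct = values.get(P.PCT)
    return DichotomousStats(
        n=n, n_total=int(n_total) if n_total is not None else None, pct=pct
    )


def parse_metric(
    text: str,
    fmt: StatisticFormat,
    category_labels: Optional[Sequence[str]] = None,
    label_placement: CategoryLabelPlacement = CategoryLabelPlacement.IN_CELL,
):
    """Parse one cell's text against a catalog format.

    For categorical formats with ``category_labels`` and slash-joined
    values ("11/9" with labels M/F), each slash-separated chunk is parsed
    with the per-category pattern and paired with its label in order.
    """
    text = normalize_text(text)
    if not text:
        raise ParseError("empty metric text", 0)
    if fmt.metric_kind is MetricKind.CATEGORICAL and category_labels:
        chunks = [c.strip() for c in text.split("/")]
        if len(chunks) != len(category_labels):
            raise ParseError(
                f"{len(category_labels)} categories but {len(chunks)} values in {text!r}"
            )
        entries = []
        for lab, chunk in zip(category_labels, chunks):
            values = _match_pattern(chunk, fmt.pattern)
            entries.append((lab, int(values[P.N]), values.get(P.PCT)))
        return CategoricalStats(entries=entries, label_placement=label_placement)
    values = _match_pattern(text, fmt.pattern)
    return _stats_from_values(fmt, values)


# ---------------------------------------------------------------------------
# Rendering (inverse of parsing; used by the synthetic generator)
# ---------------------------------------------------------------------------

_TIGHT_BEFORE = {")", "]", ",", "%"}
_TIGHT_AFTER = {"(", "["}


def _fmt_number(token: Placeholder, value, decimals: int, pct_sign: bool) -> str:
    if token in _INT_PLACEHOLDERS:
        return str(int(value))
    s = f"{float(value):.{decimals}f}"
    if token is Placeholder.PCT and pct_sign:
        s += "%"
    return s


def render_metric(
    fmt: StatisticFormat,
    values: dict[Placeholder, float],
    decimals: int = 1,
    pct_sign: bool = False,
) -> str:
    """Render placeholder values in a format's printed form.

    The inverse of :func:`parse_metric` at the printed precision: numbers
    are fixed to ``decimals`` places (counts stay integers) and delimiters
    follow the conventions of the printed formats ("12.4 ± 2.3",
    "14.0 (10.0-18.0)", "2/59 (3.4%)").
    """
    parts: list[str] = []
    prev: Optional[str] = None
    for token in fmt.pattern:
        if isinstance(token, Placeholder):
            if token not in values:
                raise ValueError(f"missing value for {token.value} in {fmt.id}")
            piece = _fmt_number(token, values[token], decimals, pct_sign)
        else:
            piece = token
        if prev is None:
            parts.append(piece)
        else:
            tight = (
                piece in _TIGHT_BEFORE
                or prev in _TIGHT_AFTER
                or piece == "/"
                or prev == "/"
                or piece == "-"
                or prev == "-"
            )
            parts.append(piece if tight else " " + piece)
        prev = piece
    return "".join(parts)


# ---------------------------------------------------------------------------
# Declaration matching
# ---------------------------------------------------------------------------

_FILLER_RE = re.compile(
    r"\b(data are presented as|data are|values are|presented as|expressed as|"
    r"reported as|shown as|given as)\b"
)

_SYNONYMS = [
    (re.compile(r"standard deviations?"), "sd"),
    (re.compile(r"interquartile ranges?"), "iqr"),
    (re.compile(r"25th percentile"), "p25"),
    (re.compile(r"75th percentile"), "p75"),
    (re.compile(r"confidence intervals?"), "ci"),
    (re.compile(r"95% ?ci"), "ci"),
    (re.compile(r"number of (patients|participants|subjects)"), "n"),
    (re.compile(r"\bno\.\b"), "n"),
    (re.compile(r"percentages?|per cent|percent"), "%"),
]


def _declaration_key(text: str) -> str:
    t = normalize_text(text).casefold()
    t = _FILLER_RE.sub(" ", t)
    for rx, rep in _SYNONYMS:
        t = rx.sub(rep, t)
    t = re.sub(r"[;:.]", " ", t)
    t = re.sub(r"\s+", "", t)
    return t


# Alias keys in _declaration_key space.  Order within a value list does not
# matter; lookup is exact on the whole (normalized) declaration text.
_DECLARATION_ALIASES: dict[str, tuple[str, ...]] = {
    "mean_pm_sd": ("mean±sd", "means±sd", "mean±standarddeviation"),
    "mean_sd_paren": ("mean(sd)",),
    "mean_bare": ("mean", "means"),
    "mean_sd_space": ("meansd",),
    "mean_ci": ("mean(ci)", "mean(ci lower-higher)".replace(" ", ""),),
    "mean_pm_sd_range": ("mean±sd(range)", "mean±sd(range min-max)".replace(" ", "")),
    "median_iqr_unspecified": ("median(iqr)",),
    "median_iqr_dash": ("median(iqrp25-p75)", "median(p25-p75)"),
    "median_iqr_bracket": ("median[iqrp25-p75]", "median[p25-p75]"),
    "median_iqr_bracket_comma": ("median[iqrp25,p75]", "median[p25,p75]"),
    "median_iqr_to": ("median(iqrp25top75)", "median(p25top75)"),
    "median_range": ("median(range)", "median(range,min-max)", "median(min-max)"),
    "min_max_median": ("min-max(median)",),
    "n_pct": ("n(%)",),
    "n_bare": ("n",),
    "n_over_rest": ("n/(n-n)",),
    "pct_bare": ("%",),
    "n_comma_pct": ("n,%",),
    "n_slash_n_pct": ("n/n(%)",),
    "mean_sd_separate_arrays": ("meanandsdinseparatearrays",),
    "n_pct_separate_arrays": ("nand%inseparatearrays",),
}

_ALIAS_LOOKUP: dict[str, StatisticFormat] = {}
for _fid, _keys in _DECLARATION_ALIASES.items():
    for _k in _keys:
        _ALIAS_LOOKUP.setdefault(_k, FORMATS_BY_ID[_fid])
for _f in CATALOG:
    if _f.metric_kind is not MetricKind.CATEGORICAL:
        _ALIAS_LOOKUP.setdefault(_declaration_key(_f.display_name), _f)


def parse_format_declaration(text: str) -> Optional[StatisticFormat]:
    """Resolve a header/footnote format declaration to a catalog format.

    Case-insensitive and punctuation-tolerant: "mean (SD)", "Mean±SD" and
    "n (%)" all resolve.  Returns ``None`` when the text is not a
    declaration ("undeclared"); callers may fall back to inference.
    """
    return _ALIAS_LOOKUP.get(_declaration_key(text))


_SCAN_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("mean_pm_sd_range", re.compile(r"mean\s*±\s*sd\s*\(range[^)]*\)")),
    ("mean_pm_sd", re.compile(r"mean\s*±\s*(sd|standard deviation)")),
    ("mean_sd_paren", re.compile(r"mean\s*\(\s*sd\s*\)")),
    ("mean_ci", re.compile(r"mean\s*\(\s*(95% ?)?ci[^)]*\)")),
    ("median_iqr_bracket_comma", re.compile(r"median\s*\[\s*iqr[^\]]*,[^\]]*\]")),
    ("median_iqr_bracket", re.compile(r"median\s*\[\s*iqr[^\]]*\]")),
    ("median_iqr_to", re.compile(r"median\s*\(\s*iqr[^)]*\bto\b[^)]*\)")),
    ("median_iqr_dash", re.compile(r"median\s*\(\s*iqr\s*[;,]?\s*25[^)]*\)")),
    ("median_range", re.compile(r"median\s*\(\s*range[^)]*\)")),
    ("median_iqr_unspecified", re.compile(r"median\s*\(\s*iqr\s*\)")),
    ("min_max_median", re.compile(r"min\s*-\s*max\s*\(\s*median\s*\)")),
    ("n_slash_n_pct", re.compile(r"\bn\s*/\s*n\s*\(\s*%\s*\)")),
    ("n_over_rest", re.compile(r"\bn\s*/\s*\(\s*n\s*-\s*n\s*\)")),
    ("n_comma_pct", re.compile(r"\bn\s*,\s*%")),
    ("n_pct", re.compile(r"\bn\s*\(\s*%\s*\)")),
    ("mean_sd_space", re.compile(r"\bmean\s+sd\b")),
    ("mean_bare", re.compile(r"\bmeans?\b")),
    ("n_bare", re.compile(r"\bn(umber)?s? of (patients|participants|subjects)\b")),
    ("pct_bare", re.compile(r"\bpercentages?\b|(?<![\w(])%(?!\s*\))")),
]


def scan_declarations(text: str) -> list[StatisticFormat]:
    """Find all format declarations inside free text (footnote, caption).

    Longer, more specific patterns win over substrings they contain; the
    result preserves first-occurrence order and is deduplicated.
    """
    t = normalize_text(text).casefold()
    taken: list[tuple[int, int]] = []
    hits: list[tuple[int, str]] = []
    for fid, rx in _SCAN_PATTERNS:
        for m in rx.finditer(t):
            span = m.span()
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            taken.append(span)
            hits.append((span[0], fid))
    hits.sort()
    seen: set[str] = set()
    out: list[StatisticFormat] = []
    for _, fid in hits:
        if fid not in seen:
            seen.add(fid)
            out.append(FORMATS_BY_ID[fid])
    return out


# ---------------------------------------------------------------------------
# Inference from metric arrays
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    format: StatisticFormat
    score: float
    ties: list[StatisticFormat] = field(default_factory=list)


def _cell_matches(text: str, fmt: StatisticFormat) -> bool:
    try:
        _match_pattern(normalize_text(text), fmt.pattern)
        return True
    except ParseError:
        return False


def infer_format(
    cells: Sequence[str],
    candidates: Optional[Sequence[StatisticFormat]] = None,
) -> Optional[InferenceResult]:
    """Infer the statistic format from a metric array's cell texts.

    Every candidate format is matched against every non-empty cell; the
    format matching the largest fraction wins, ties resolved by catalog
    order and reported in ``ties``.  Returns ``None`` ("uninferable") when
    no format matches any cell.
    """
    texts = [c for c in cells if c and c.strip()]
    if not texts:
        raise ValueError("infer_format requires at least one non-empty cell")
    pool = [f for f in (candidates if candidates is not None else CATALOG)
            if not f.multi_array]
    best: Optional[StatisticFormat] = None
    best_score = 0.0
    ties: list[StatisticFormat] = []
    for fmt in pool:
        score = sum(_cell_matches(t, fmt) for t in texts) / len(texts)
        if score > best_score:
            best, best_score, ties = fmt, score, []
        elif score == best_score and score > 0 and best is not None:
            ties.append(fmt)
    if best is None:
        return None
    return InferenceResult(format=best, score=best_score, ties=ties)


# ---------------------------------------------------------------------------
# Count/percentage arithmetic
# ---------------------------------------------------------------------------

def check_consistency(d: DichotomousStats, decimals: int = 1) -> bool:
    """True iff the printed percentage equals round-half-up(100 n/N)."""
    if d.n_total is None or d.pct is None:
        raise ValueError("n, n_total and pct must all be present")
    return abs(round_half_up(100.0 * d.n / d.n_total, decimals) - d.pct) < 1e-9


def derive_denominator(
    n: int, pct: float, decimals: int = 1, n_max: int = 1000
) -> set[int]:
    """All totals N in [max(n,1), n_max] whose rounded percentage is pct.

    Inverts the n (%) format to recover candidate arm sizes: every N with
    round-half-up(100 n/N, decimals) == pct.  May be empty (the printed
    percentage matches no denominator) or contain several candidates.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not (0.0 < pct <= 100.0):
        raise ValueError("pct must lie in (0, 100]")
    lo = max(n, 1)
    if lo > n_max:
        return set()
    Ns = np.arange(lo, n_max + 1, dtype=np.int64)
    scale = 10.0 ** decimals
    rounded = np.floor(100.0 * n * scale / Ns + 0.5) / scale
    hit = np.abs(rounded - pct) < 1e-9
    return set(int(v) for v in Ns[hit])
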