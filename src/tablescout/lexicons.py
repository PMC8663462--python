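"""Term lexicons driving the header detectors.

Each lexicon is a plain-text file, one term per line, matched
case-insensitively.  Users can point any detector at their own files; the
defaults shipped with the package cover the conventions common in RCT
reports (time units, pre/post terms, control-arm labels, subgroup names)
plus a small intervention-name list that seeds the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


def load_lexicon(path) -> frozenset[str]:
    """Read a one-term-per-line lexicon file (case-folded, '#' comments)."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse(text)


def _parse(text: str) -> frozenset[str]:
    terms = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.casefold())
    return frozenset(terms)


def _builtin(name: str) -> frozenset[str]:
    data = resources.files("tablescout").joinpath("lexicon_data").joinpath(name)
    return _parse(data.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class Lexicons:
    """Bundle of all term lists used by context detection."""

    time_units: frozenset[str] = field(default_factory=lambda: _builtin("time_units.txt"))
    pre_post: frozenset[str] = field(default_factory=lambda: _builtin("pre_post.txt"))
    control_terms: frozenset[str] = field(default_factory=lambda: _builtin("control_terms.txt"))
    interventions: frozenset[str] = field(default_factory=lambda: _builtin("interventions.txt"))
    subgroup_terms: frozenset[str] = field(default_factory=lambda: _builtin("subgroup_terms.txt"))
    pooled_terms: frozenset[str] = field(default_factory=lambda: _builtin("pooled_terms.txt"))
    comparative_terms: frozenset[str] = field(default_factory=lambda: _builtin("comparative_terms.txt"))
    size_array_terms: frozenset[str] = field(default_factory=lambda: _builtin("size_array_terms.txt"))
    baseline_caption: frozenset[str] = field(default_factory=lambda: _builtin("baseline_caption.txt"))
    outcome_caption: frozenset[str] = field(default_factory=lambda: _builtin("outcome_caption.txt"))


DEFAULT = Lexicons()
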