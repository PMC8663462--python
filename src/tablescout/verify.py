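"""Ground-truth verification of the extraction pipeline.

Compares an extraction result against the generator's ground truth for
the same table and reports every disagreement as a human-readable string
(empty list = perfect recovery).  Used by the round-trip tests and handy
when tuning detector lexicons against new synthetic conditions.
"""

from __future__ import annotations

from typing import Optional

from .extract import ExtractionResult, extract_table
from .model import TableGrid
from .synth import TableTruth

__all__ = ["verify_roundtrip", "compare_extraction"]


def _num_eq(a, b, tol: float = 1e-9) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return abs(float(a) - float(b)) <= tol


def _stats_eq(a: dict, b: dict) -> bool:
    if set(a) != set(b):
        return False
    for k in a:
        va, vb = a[k], b[k]
        if k == "entries":
            if len(va) != len(vb):
                return False
            for ea, eb in zip(va, vb):
                if ea["label"] != eb["label"] or not _num_eq(ea["n"], eb["n"]) \
                        or not _num_eq(ea.get("pct"), eb.get("pct")):
                    return False
        elif isinstance(va, (int, float)) or isinstance(vb, (int, float)):
            if not _num_eq(va, vb):
                return False
        elif va != vb:
            return False
    return True


def _fold(x: Optional[str]) -> Optional[str]:
    return x.strip().casefold() if isinstance(x, str) else x


def compare_extraction(result: ExtractionResult, truth: TableTruth) -> list[str]:
    """All disagreements between an extraction result and ground truth."""
    issues: list[str] = []
    s = result.structure

    if s.cls.value != truth.cls:
        issues.append(f"class: got {s.cls.value}, truth {truth.cls}")
    if truth.cls == "other":
        got_reason = s.other_reason.value if s.other_reason else None
        if got_reason != truth.other_reason:
            issues.append(f"other_reason: got {got_reason}, truth {truth.other_reason}")
    else:
        got_rk = [k.value for k in s.row_kinds]
        got_ck = [k.value for k in s.col_kinds]
        if got_rk != truth.row_kinds or got_ck != truth.col_kinds:
            issues.append(
                f"kinds: got {got_rk}x{got_ck}, truth {truth.row_kinds}x{truth.col_kinds}")
        if s.embedded != truth.embedded:
            issues.append(f"embedded: got {s.embedded}, truth {truth.embedded}")
        if truth.sublayout is not None and s.sublayout != truth.sublayout:
            issues.append(f"sublayout: got {s.sublayout!r}, truth {truth.sublayout!r}")

    if truth.cls != "other":
        by_label = {_fold(a.label): a for a in result.arms}
        for at in truth.arms:
            got = by_label.get(_fold(at["label"]))
            if at.get("rendered_size") is not None:
                if got is None:
                    issues.append(f"arm {at['label']!r} not recovered")
                elif got.size != at["size"]:
                    issues.append(
                        f"arm {at['label']!r} size: got {got.size}, truth {at['size']}")

    got_metrics = {(m.row, m.col): m for m in result.metrics}
    for ct in truth.cells:
        m = got_metrics.pop((ct.row, ct.col), None)
        if m is None:
            issues.append(f"cell ({ct.row},{ct.col}) {ct.text!r}: no metric extracted")
            continue
        if m.format.id != ct.format_id:
            issues.append(
                f"cell ({ct.row},{ct.col}): format {m.format.id} != {ct.format_id}")
        got_stats = m.stats.to_dict()
        if not _stats_eq(got_stats, ct.stats):
            issues.append(
                f"cell ({ct.row},{ct.col}): stats {got_stats} != {ct.stats}")
        if ct.de is not None and truth.cls != "other" and \
                _fold(m.context.data_element.name) != _fold(ct.de):
            issues.append(
                f"cell ({ct.row},{ct.col}): data element "
                f"{m.context.data_element.name!r} != {ct.de!r}")
        got_arm = _fold(m.context.arm.label) if m.context.arm else None
        if truth.cls != "other" and not truth.pooled and \
                got_arm != _fold(ct.arm):
            issues.append(f"cell ({ct.row},{ct.col}): arm {got_arm!r} != {ct.arm!r}")
        got_tp = _fold(m.context.time_point.label) if m.context.time_point else None
        if got_tp != _fold(ct.tp):
            issues.append(f"cell ({ct.row},{ct.col}): time point "
                          f"{got_tp!r} != {ct.tp!r}")
        if _fold(m.category) != _fold(ct.category):
            issues.append(f"cell ({ct.row},{ct.col}): category "
                          f"{m.category!r} != {ct.category!r}")
    for (r, c), m in got_metrics.items():
        issues.append(f"cell ({r},{c}) {m.raw_text!r}: spurious metric")
    return issues


def verify_roundtrip(grid: TableGrid, truth: TableTruth) -> list[str]:
    """Extract a generated table and compare against its ground truth."""
    return compare_extraction(extract_table(grid), truth)
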