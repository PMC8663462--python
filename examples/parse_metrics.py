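"""Parse descriptive-statistic strings into their constituents.

Builds a handful of metric strings in the micro-formats used by trial
tables, parses each against the format catalog, checks count/percentage
consistency, and recovers candidate denominators from an n (%) pair.
"""

from tablescout import (
    FORMATS_BY_ID,
    check_consistency,
    derive_denominator,
    infer_format,
    parse_format_declaration,
    parse_metric,
)

print("— parsing with a known format —")
for text, fmt_id in [
    ("2/59 (3.4%)", "n_slash_n_pct"),
    ("12.4 ± 2.3", "mean_pm_sd"),
    ("14 (10-18)", "median_range"),
    ("3/(27)", "n_over_rest"),
]:
    stats = parse_metric(text, FORMATS_BY_ID[fmt_id])
    print(f"  {text!r:18} [{fmt_id}] -> {stats.to_dict()}")

print("\n— declarations found in headers/footnotes —")
for decl in ["mean ± SD", "Median (IQR)", "n (%)", "flux capacitance"]:
    fmt = parse_format_declaration(decl)
    print(f"  {decl!r:20} -> {fmt.id if fmt else 'undeclared'}")

print("\n— inferring the format from a metric array —")
res = infer_format(["12.4 ± 2.3", "8.1 ± 1.9", "15.0 ± 3.2"])
print(f"  unanimous column -> {res.format.id} (score {res.score})")
res = infer_format(["30 (75)", "3 (8)"])
print(f"  ambiguous integers -> {res.format.id}, "
      f"ties: {[t.id for t in res.ties]}")

print("\n— count/percentage arithmetic —")
m = parse_metric("2/59 (3.4%)", FORMATS_BY_ID["n_slash_n_pct"])
print(f"  3.4% consistent with 2/59 at 1 decimal: "
      f"{check_consistency(m, decimals=1)}")
cands = derive_denominator(n=2, pct=3.4, decimals=1, n_max=1000)
print(f"  denominators N with round(100*2/N, 1) == 3.4: {sorted(cands)}")
print("  (the printed percentage pins the missing arm size down to "
      f"{len(cands)} candidates)")
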