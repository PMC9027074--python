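"""Group statistics, dose–response correlation and report tables.

Groups are summarised by unweighted means with t-based 95% confidence
intervals ("NE" when the variance is zero or n < 2), compared with
Kruskal–Wallis omnibus tests (alpha = 0.05) followed by pairwise
Mann–Whitney post hoc tests only when the omnibus is significant.
Dose–response uses Spearman (default) or Pearson correlation of memantine
concentration against a metric, with an exact permutation p-value for
small samples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("nmdasim")

__all__ = [
    "GroupSummary",
    "group_mean_ci",
    "summarize_groups",
    "DoseResponse",
    "dose_response",
    "report",
]

ALPHA = 0.05

#: metrics carried into the report tables, with display rounding
REPORT_METRICS: dict[str, int] = {
    "shannon_rqa_bits": 3,
    "h_signal_bits": 3,
    "lyap_direct": 3,
    "lyap_time": 0,
    "d2": 3,
    "te_in_to_s_bits": 3,
    "mi_bits": 3,
    "n_spikes": 0,
    "LTP": 3,
    "LTP_time_ms": 0,
}


def group_mean_ci(values, confidence: float = 0.95):
    """Unweighted mean with a t-based CI; (mean, None, None) marks a CI
    that is not estimable (n < 2 or zero variance)."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if v.size == 0:
        return None, None, None
    mean = float(v.mean())
    if v.size < 2 or np.allclose(v, v[0]):
        return mean, None, None
    half = stats.t.ppf(0.5 + confidence / 2, v.size - 1) * v.std(ddof=1) / math.sqrt(v.size)
    return mean, mean - float(half), mean + float(half)


@dataclass
class GroupSummary:
    """Per-group mean/CI for every metric, plus the member rows."""

    label: str
    n: int
    stats: dict  # metric -> (mean, lo, hi)
    members: pd.DataFrame

    def mean(self, metric: str):
        return self.stats.get(metric, (None, None, None))[0]


def summarize_groups(
    results: pd.DataFrame,
    group_col: str = "group",
    metrics: list[str] | None = None,
) -> tuple[list[GroupSummary], dict]:
    """Summarise a result table by group and test between-group differences.

    Returns the per-group summaries and a per-metric omnibus dict
    ``{metric: {"kruskal_p": p, "posthoc": {(g1, g2): p, ...}}}``; post hoc
    pairwise Mann–Whitney tests run only when the Kruskal–Wallis omnibus is
    significant at alpha = 0.05.
    """
    if results.empty:
        raise ValueError("empty result table")
    if metrics is None:
        metrics = [
            c for c in results.columns
            if results[c].dtype.kind in "fiu"
            and c not in ("seed", "concentration_uM")
        ]
    groups = list(dict.fromkeys(results[group_col]))
    summaries = []
    for g in groups:
        sub = results[results[group_col] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} has no rows")
        summaries.append(
            GroupSummary(
                label=g,
                n=len(sub),
                stats={m: group_mean_ci(sub[m]) for m in metrics if m in sub},
                members=sub,
            )
        )

    omnibus: dict = {}
    if len(groups) >= 2:
        for m in metrics:
            samples = [
                s.members[m].dropna().to_numpy()
                for s in summaries
                if m in s.members and s.members[m].notna().any()
            ]
            if len(samples) < 2 or any(len(x) == 0 for x in samples):
                continue
            try:
                _, p = stats.kruskal(*samples)
            except ValueError:  # all values identical across groups
                p = 1.0
            entry: dict = {"kruskal_p": float(p), "posthoc": {}}
            if p < ALPHA:
                for (i, a), (j, b) in itertools.combinations(enumerate(summaries), 2):
                    xa = a.members[m].dropna()
                    xb = b.members[m].dropna()
                    if len(xa) and len(xb):
                        _, pp = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                        entry["posthoc"][(a.label, b.label)] = float(pp)
            omnibus[m] = entry
    return summaries, omnibus


@dataclass(frozen=True)
class DoseResponse:
    metric: str
    r: float
    p: float
    method: str
    n: int
    note: str = ""


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def dose_response(
    concentration,
    values,
    metric: str = "",
    method: str = "spearman",
    max_exact_n: int = 10,
) -> DoseResponse:
    """Correlation of memantine concentration with a metric.

    For n <= ``max_exact_n`` the two-sided p-value is exact, enumerating
    all permutations of the metric values; otherwise the scipy asymptotic
    p is used. Constant metrics yield an undefined (NaN) coefficient with
    a note.
    """
    x = np.asarray(concentration, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return DoseResponse(metric, float("nan"), 1.0, method, len(x), "constant variable")

    r_obs = _corr(x, y, method)
    if len(x) <= max_exact_n:
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_corr(x, np.asarray(perm), method)) >= abs(r_obs) - 1e-12:
                count += 1
        p = count / total
    else:
        if method == "spearman":
            p = float(stats.spearmanr(x, y).pvalue)
        else:
            p = float(stats.pearsonr(x, y).pvalue)
    return DoseResponse(metric, float(r_obs), float(p), method, len(x))


# ----------------------------------------------------------------------
# report rendering

_ROW_ORDER = [
    ("Control model", "group"),
    ("AD model", "group"),
    ("mild", "condition"),
    ("moderate", "condition"),
    ("advanced", "condition"),
    ("Memantine treatment model", "group"),
]


def _fmt(value, decimals: int) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "NE"
    if decimals == 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def report(results: pd.DataFrame, metrics: dict[str, int] | None = None) -> dict[str, pd.DataFrame]:
    """Render the condition grid as report tables.

    ``table1``: per-condition and per-group means of the complexity /
    information / transmission metrics, rounded for display (3 decimals
    for entropies and exponents, integers for Lyapunov time and counts).
    ``table2`` / ``table3``: Spearman dose–response of each metric against
    memantine concentration over the treated rows. Re-rendering the same
    results is byte-identical.
    """
    metrics = metrics or {
        k: d for k, d in REPORT_METRICS.items() if k in results.columns
    }
    missing = [m for m in metrics if m not in results.columns]
    for m in missing:
        log.warning("report: metric column %r missing; rendered blank", m)

    rows = []
    group_means = {}
    for g in results["group"].unique():
        sub = results[results["group"] == g]
        group_means[g] = {m: group_mean_ci(sub[m])[0] for m in metrics if m in sub}
    condition_means = {}
    for c in results["condition"].unique():
        sub = results[results["condition"] == c]
        condition_means[c] = {m: group_mean_ci(sub[m])[0] for m in metrics if m in sub}

    def emit(label, source):
        vals = source.get(label, {})
        rows.append(
            {"row": label, **{m: _fmt(vals.get(m), d) for m, d in metrics.items()}}
        )

    for label, kind in _ROW_ORDER:
        if kind == "group" and label in group_means:
            emit(label, group_means)
        elif kind == "condition" and label in condition_means:
            emit(label, condition_means)
    # therapy condition rows in concentration order
    therapy = (
        results[results["condition"].str.contains(r"\+")]
        .groupby("condition")["concentration_uM"].first().sort_values()
    )
    for c in therapy.index:
        emit(c, condition_means)

    table1 = pd.DataFrame(rows)

    treated = results[results["concentration_uM"] > 0]
    corr_rows = []
    for m in metrics:
        if m not in treated.columns or treated.empty:
            continue
        sub = treated[["concentration_uM", m]].dropna()
        if len(sub) < 3:
            continue
        dr = dose_response(sub["concentration_uM"], sub[m], metric=m)
        corr_rows.append(
            {"metric": m, "R": round(dr.r, 2) if np.isfinite(dr.r) else "NE",
             "p_value": dr.p, "n": dr.n, "method": dr.method}
        )
    corr = pd.DataFrame(corr_rows)
    complexity = {"shannon_rqa_bits", "h_signal_bits", "lyap_direct", "lyap_time", "d2",
                  "tau", "m_star"}
    table2 = corr[corr["metric"].isin(complexity)].reset_index(drop=True) if not corr.empty else corr
    table3 = corr[~corr["metric"].isin(complexity)].reset_index(drop=True) if not corr.empty else corr
    return {"table1": table1, "table2": table2, "table3": table3}


def render_text(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for name, df in tables.items():
        parts.append(f"== {name} ==")
        parts.append(df.to_string(index=False) if not df.empty else "(empty)")
        parts.append("")
    return "\n".join(parts)
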