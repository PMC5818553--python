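"""Grouped summaries, hypothesis tests with Bonferroni families, and table
rendering in the "value ± SD (n, N)" convention.

*Bouton grain* pools every bouton; *NMJ grain* first averages the boutons of
each terminal, then treats NMJ means as the observations.  Base statistics
(Kruskal-Wallis, t, one-way ANOVA) come from scipy; the Bonferroni family is
the declared list of comparisons, with adjusted p = min(1, m * p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedSummary",
    "TestResult",
    "aggregate",
    "bonferroni",
    "stars",
    "run_tests",
    "format_cell",
    "render_tables",
]


@dataclass
class GroupedSummary:
    bouton: pd.DataFrame  # per-group mean/sd/sem over boutons
    nmj: pd.DataFrame     # per-group mean/sd/sem over NMJ means


@dataclass
class TestResult:
    test: str
    comparison: tuple[str, str]
    raw_p: float
    adjusted_p: float
    stars: str
    note: str = ""


def _summarize(g: pd.DataFrame, value: str, count_nmjs: bool) -> dict:
    vals = g[value].dropna()
    n = len(vals)
    return {
        "mean": vals.mean() if n else np.nan,
        "sd": vals.std(ddof=1) if n > 1 else np.nan,
        "sem": vals.sem(ddof=1) if n > 1 else np.nan,
        "n": n,
        "N": g["nmj_id"].nunique() if count_nmjs else n,
    }


def aggregate(df: pd.DataFrame, keys: Sequence[str],
              value: str = "max_dff") -> GroupedSummary:
    """Two-grain summary of ``value`` grouped by ``keys``.

    NMJ grain averages within each (keys, nmj_id) cell first, then
    summarizes those means; its ``n`` is the bouton count, ``N`` the NMJ
    count (``N <= n``).
    """

    keys = list(keys)
    bouton_rows, nmj_rows = [], []
    for key_vals, g in df.groupby(keys, dropna=False):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        base = dict(zip(keys, key_vals))
        bouton_rows.append(base | _summarize(g, value, count_nmjs=True))
        nmj_means = g.dropna(subset=[value]).groupby("nmj_id")[value].mean()
        nmj_rows.append(base | {
            "mean": nmj_means.mean() if len(nmj_means) else np.nan,
            "sd": nmj_means.std(ddof=1) if len(nmj_means) > 1 else np.nan,
            "sem": nmj_means.sem(ddof=1) if len(nmj_means) > 1 else np.nan,
            "n": int(g[value].notna().sum()),
            "N": len(nmj_means),
        })
    return GroupedSummary(bouton=pd.DataFrame(bouton_rows),
                          nmj=pd.DataFrame(nmj_rows))


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, m * p) for a family of m comparisons."""

    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 levels."""

    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fisher_lsd(groups: dict[str, np.ndarray],
                pair: tuple[str, str]) -> float:
    """Pairwise p from the pooled within-group variance of a one-way ANOVA."""

    all_groups = list(groups.values())
    n_tot = sum(len(g) for g in all_groups)
    k = len(all_groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in all_groups) / (n_tot - k)
    a, b = groups[pair[0]], groups[pair[1]]
    se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
    t = (a.mean() - b.mean()) / se
    return float(2 * stats.t.sf(abs(t), n_tot - k))


def run_tests(
    groups: dict[str, np.ndarray],
    plan: Sequence[tuple[str, str]],
    test: str = "kruskal_wallis_bonferroni",
) -> list[TestResult]:
    """Run a declared family of pairwise comparisons.

    ``test`` is one of ``kruskal_wallis_bonferroni``, ``t_test``,
    ``t_test_bonferroni``, ``anova_fisher_lsd``.  The Bonferroni family size
    is the number of comparisons in ``plan``; LSD and plain t tests report
    the raw p unchanged.  Degenerate groups (fewer than 2 observations) skip
    the comparison with a reason.
    """

    m = len(plan)
    results = []
    for pair in plan:
        a = np.asarray(groups.get(pair[0], ()), dtype=float)
        b = np.asarray(groups.get(pair[1], ()), dtype=float)
        if len(a) < 2 or len(b) < 2:
            results.append(TestResult(test, pair, float("nan"), float("nan"),
                                      "", note="skipped: degenerate group"))
            continue
        if test == "kruskal_wallis_bonferroni":
            raw = float(stats.kruskal(a, b).pvalue)
            adj = bonferroni(raw, m)
        elif test == "t_test":
            raw = float(stats.ttest_ind(a, b).pvalue)
            adj = raw
        elif test == "t_test_bonferroni":
            raw = float(stats.ttest_ind(a, b).pvalue)
            adj = bonferroni(raw, m)
        elif test == "anova_fisher_lsd":
            raw = _fisher_lsd(groups, pair)
            adj = raw
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(TestResult(test, pair, raw, adj, stars(adj)))
    return results


def format_cell(mean: float, sd: float, n: int, N: int,
                decimals: int = 2) -> str:
    """Render one table cell as "mean ± SD (n, N)" with 2 decimals."""

    return f"{mean:.{decimals}f} ± {sd:.{decimals}f} ({n}, {N})"


def render_tables(
    summary: pd.DataFrame,
    tests: Sequence[TestResult] = (),
    keys: Sequence[str] | None = None,
    star_map: dict | None = None,
) -> tuple[pd.DataFrame, str]:
    """Machine CSV frame + human-readable text table with star annotations.

    ``star_map`` optionally maps a tuple of key values to the stars to append
    to that cell; otherwise stars from ``tests`` are listed below the table.
    """

    df = summary.copy()
    keys = list(keys) if keys else [c for c in df.columns
                                    if c not in ("mean", "sd", "sem", "n", "N")]
    cells = []
    for _, row in df.iterrows():
        cell = format_cell(row["mean"], row["sd"], int(row["n"]), int(row["N"]))
        if star_map:
            key = tuple(row[k] for k in keys)
            cell += star_map.get(key, "")
        cells.append(cell)
    df["cell"] = cells

    lines = [" | ".join(str(row[k]) for k in keys) + " : " + row["cell"]
             for _, row in df.iterrows()]
    for t in tests:
        if t.note:
            lines.append(f"{t.comparison[0]} vs {t.comparison[1]}: {t.note}")
        else:
            lines.append(f"{t.comparison[0]} vs {t.comparison[1]}: "
                         f"p = {t.adjusted_p:.3g} {t.stars}")
    return df, "\n".join(lines)
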