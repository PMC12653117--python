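"""Assumption-gated treatment comparison.

Every response is first gated: per-group Shapiro-Wilk normality and a
median-centered Levene (Brown-Forsythe) homogeneity check, both at a
configurable level (default 0.05).  If all pass, the route is one-way
ANOVA with Tukey HSD pairwise comparisons; otherwise Kruskal-Wallis with
Dunn's rank-based pairwise test, Holm-adjusted.  Either way the pairwise
significance pattern is summarised as a compact letter display: groups
sharing a letter are not significantly different at the chosen level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GATE_ALPHA = 0.05


@dataclass
class ComparisonResult:
    response: str
    groups: list[str]
    route: str  # "anova_tukey" | "kruskal_dunn"
    normality_p: dict[str, float]
    homogeneity_p: float
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, p_adj
    letters: dict[str, str]
    notes: list[str] = field(default_factory=list)


def dunn_test(samples: list[np.ndarray], labels: list[str], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post-hoc test on pooled ranks, with tie correction.

    The z statistic for groups a, b compares mean ranks against the
    standard error sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)) where T is the
    tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    pooled = np.concatenate(samples)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            var = (n_tot * (n_tot + 1) / 12.0 - tie) * (1.0 / sizes[a] + 1.0 / sizes[b])
            if var <= 0:  # fully tied data
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": labels[a], "group2": labels[b], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust == "none" or df.empty:
        df["p_adj"] = df.get("p_raw", [])
    else:
        df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    return df


def letter_display(pairwise: pd.DataFrame, groups: list[str], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Start from one letter covering all groups; for every significant pair
    split each letter set containing both members into two sets, each
    dropping one member; absorb sets contained in others; assign letters
    alphabetically in group order.
    """
    sets: list[set[str]] = [set(groups)]
    sig = pairwise[pairwise["p_adj"] < alpha]
    for _, row in sig.iterrows():
        a, b = row["group1"], row["group2"]
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets that are subsets of another
        sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    # order letter sets by the earliest group they contain
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for k, s in enumerate(sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[k % len(alphabet)]
    return letters


def compare_groups(
    values,
    group_labels,
    alpha: float = 0.05,
    gate_alpha: float = GATE_ALPHA,
    response: str = "response",
    dunn_adjust: str = "holm",
    posthoc: bool = True,
    force_route: str | None = None,
) -> ComparisonResult:
    """Run the full gated comparison cascade on one response variable.

    ``posthoc=False`` skips the pairwise tests and letter display and
    returns only the gate and omnibus results (useful when simulating the
    cascade's omnibus operating characteristics in bulk).
    ``force_route`` bypasses the assumption gate and pins the route to
    ``"anova_tukey"`` or ``"kruskal_dunn"``; the gate p-values are still
    computed and reported.
    """
    if force_route not in (None, "anova_tukey", "kruskal_dunn"):
        raise ValueError(f"unknown route {force_route!r}")
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray([str(g) for g in group_labels])
    keep = np.isfinite(values)
    values, group_labels = values[keep], group_labels[keep]
    groups = [str(g) for g in dict.fromkeys(group_labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    samples = [values[group_labels == g] for g in groups]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")

    notes: list[str] = []
    normality_p: dict[str, float] = {}
    normal_ok = True
    for g, s in zip(groups, samples):
        if np.ptp(s) == 0:
            normality_p[g] = float("nan")
            normal_ok = False
            notes.append(f"group {g!r} has zero variance; forced nonparametric route")
        elif s.size < 3:
            normality_p[g] = float("nan")
            normal_ok = False
            notes.append(f"group {g!r} too small for Shapiro-Wilk; forced nonparametric route")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.shapiro(s).pvalue)
            normality_p[g] = p
            normal_ok &= p >= gate_alpha
    try:
        hom_p = float(stats.levene(*samples, center="median").pvalue)
    except ValueError:
        hom_p = float("nan")
    hom_ok = np.isfinite(hom_p) and hom_p >= gate_alpha

    parametric = normal_ok and hom_ok
    if force_route is not None:
        if force_route == "anova_tukey" and not normal_ok:
            # a zero-variance/too-small group cannot take the parametric route
            notes.append("requested anova_tukey route unavailable; gate kept nonparametric")
        else:
            parametric = force_route == "anova_tukey"
            notes.append(f"route forced to {force_route}")
    empty_pairwise = pd.DataFrame(columns=["group1", "group2", "p_adj"])
    if parametric:
        route = "anova_tukey"
        stat, p = stats.f_oneway(*samples)
        if posthoc:
            res = stats.tukey_hsd(*samples)
            rows = [
                {"group1": groups[a], "group2": groups[b], "p_adj": float(res.pvalue[a, b])}
                for a in range(len(groups))
                for b in range(a + 1, len(groups))
            ]
            pairwise = pd.DataFrame(rows)
        else:
            pairwise = empty_pairwise
    else:
        route = "kruskal_dunn"
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:  # all observations identical
            stat, p = 0.0, 1.0
            notes.append("all observations identical; Kruskal-Wallis undefined, p set to 1")
        if posthoc:
            pairwise = dunn_test(samples, groups, adjust=dunn_adjust)[["group1", "group2", "p_adj"]]
        else:
            pairwise = empty_pairwise
    letters = letter_display(pairwise, groups, alpha) if posthoc else {}
    return ComparisonResult(
        response, groups, route, normality_p, hom_p, float(stat), float(p), pairwise, letters, notes
    )


def compare_table(df: pd.DataFrame, value_col: str, group_col: str, response: str | None = None, **kw) -> ComparisonResult:
    """Convenience wrapper for long-format tables (value, group)."""
    return compare_groups(
        df[value_col].to_numpy(), df[group_col].to_numpy(), response=response or value_col, **kw
    )
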