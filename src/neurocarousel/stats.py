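"""Group-comparison layer: normality-gated omnibus tests with post hocs.

The decision rule mirrors common practice in behavioral pharmacology:
Shapiro-Wilk on every group decides between a one-way ANOVA with Tukey's
multiple comparisons (all groups normal) and a Kruskal-Wallis test with
Dunn's multiple comparisons (any group non-normal).  Post hoc tests run
only when the omnibus test is significant.  Summaries are mean +/- SEM.

Dunn's z statistics are computed directly from the pooled mid-ranks with
the standard tie correction; adjustment is Bonferroni over all pairs by
default (Holm available).  Tukey uses the studentized-range distribution
with the Tukey-Kramer correction for unequal group sizes.  The balanced
two-way mixed ANOVA (group between, day within) is a convenience without
sphericity correction; unbalanced designs are directed to dedicated
mixed-model tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "normality_gate",
    "anova_tukey",
    "kw_dunn",
    "rm_anova_balanced",
    "correlate",
    "mean_sem",
    "analyze_metric",
    "groups_from_table",
]

ALPHA_DEFAULT = 0.05


@dataclass
class StatReport:
    """Result of one omnibus test plus optional post hoc pairs.

    ``posthoc`` rows are dicts with keys ``pair``, ``statistic``, ``p_raw``
    (absent for Tukey, whose p is already family-wise) and ``p_adj``.
    ``gate`` records the per-group Shapiro-Wilk outcomes when the
    normality gate ran.  ``effects`` holds the per-effect F tables of the
    mixed ANOVA.
    """

    test: str
    statistic: float
    df: tuple
    p: float
    posthoc: list[dict] = field(default_factory=list)
    gate: dict | None = None
    effects: dict | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p value {self.p} outside [0, 1]")

    def significant(self, alpha: float = ALPHA_DEFAULT) -> bool:
        return bool(self.p < alpha)


def _as_groups(groups: dict) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        out[label] = arr
    return out


def groups_from_table(table: pd.DataFrame, metric: str,
                      group_col: str = "group", metric_col: str = "metric",
                      value_col: str = "value") -> dict[str, np.ndarray]:
    """Slice one metric out of a tidy table into ``{group: values}``."""
    sub = table[table[metric_col] == metric]
    return {g: d[value_col].to_numpy(dtype=float) for g, d in sub.groupby(group_col)}


def normality_gate(groups: dict, alpha: float = ALPHA_DEFAULT) -> tuple[str, dict]:
    """Shapiro-Wilk on every group; ``parametric`` iff all groups pass.

    Each group needs n >= 3; a zero-variance group has no defined W and is
    an error.  Returns the route and the per-group (W, p) outcomes.
    """
    groups = _as_groups(groups)
    outcomes = {}
    route = "parametric"
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has n={len(vals)} < 3")
        if np.ptp(vals) == 0:
            raise ValueError(f"group {label!r} has zero variance; normality undefined")
        w, p = sps.shapiro(vals)
        outcomes[label] = {"W": float(w), "p": float(p), "normal": bool(p > alpha)}
        if p <= alpha:
            route = "nonparametric"
    return route, outcomes


def anova_tukey(groups: dict, alpha: float = ALPHA_DEFAULT) -> StatReport:
    """One-way fixed-effects ANOVA; Tukey HSD on all pairs when significant.

    Zero within-group variance with unequal means yields an infinite F
    (flagged via ``statistic = inf``, p = 0).
    """
    groups = _as_groups(groups)
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df = (k - 1, n_total - k)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    if ssw == 0:
        if ssb == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
    report = StatReport("one-way ANOVA", f_stat, df, p)
    if report.significant(alpha) and ssw > 0:
        res = sps.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(k), 2):
            report.posthoc.append({
                "pair": (labels[i], labels[j]),
                "statistic": float(res.statistic[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            })
        report.posthoc.sort(key=lambda r: r["p_adj"])
    return report


def _kruskal_h(arrays: list[np.ndarray]) -> tuple[float, float, int]:
    """Tie-corrected H, its chi-square p and total N (H = 0 when all tied)."""
    n_total = sum(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, n_total
    h, p = sps.kruskal(*arrays)
    return float(h), float(p), n_total


def kw_dunn(groups: dict, alpha: float = ALPHA_DEFAULT,
            adjust: str = "bonferroni") -> StatReport:
    """Kruskal-Wallis omnibus; Dunn's pairwise z tests when significant.

    Dunn's statistic for groups i, j is the mid-rank mean difference over
    ``sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j))`` with
    ``T = sum(t^3 - t)`` over tied values; two-sided normal p, adjusted by
    Bonferroni (default) or Holm over all pairs.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = _as_groups(groups)
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    h, p, n_total = _kruskal_h(arrays)
    if n_total < 3:
        raise ValueError("Kruskal-Wallis needs N >= 3")
    report = StatReport("Kruskal-Wallis", h, (len(arrays) - 1,), p)
    if report.significant(alpha):
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        sizes = [len(a) for a in arrays]
        bounds = np.cumsum([0] + sizes)
        mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]
        _, counts = np.unique(pooled, return_counts=True)
        tie_sum = float(np.sum(counts**3 - counts))
        var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
        pairs = list(itertools.combinations(range(len(arrays)), 2))
        raw = []
        for i, j in pairs:
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw.append((z, 2.0 * sps.norm.sf(abs(z))))
        m = len(pairs)
        if adjust == "bonferroni":
            adj = [min(1.0, pr * m) for _, pr in raw]
        else:  # holm step-down
            order = np.argsort([pr for _, pr in raw])
            adj = [0.0] * m
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, min(1.0, (m - rank) * raw[idx][1]))
                adj[idx] = running
        for (i, j), (z, pr), pa in zip(pairs, raw, adj):
            report.posthoc.append({
                "pair": (labels[i], labels[j]),
                "statistic": float(z),
                "p_raw": float(pr),
                "p_adj": float(pa),
            })
        report.posthoc.sort(key=lambda r: r["p_adj"])
    return report


def rm_anova_balanced(table: pd.DataFrame, dv: str = "value",
                      subject: str = "animal", within: str = "day",
                      between: str = "group") -> StatReport:
    """Balanced two-way mixed ANOVA (group between, day within subjects).

    Requires a complete design (every subject measured on every day; group
    sizes may differ); no sphericity correction is applied.  The headline
    statistic/p is the group x day interaction; ``effects`` carries all
    three F tables.  Missing cells raise with a pointer to dedicated
    mixed-model tooling.  Degenerate zero-variance numerators give F = 0
    (p = 1); a zero error term with a non-zero effect gives F = inf (p = 0).
    """
    pivot = table.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="size")
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValueError(
            "design is incomplete or has duplicate cells; use a mixed-effects "
            "model (e.g. statsmodels MixedLM or lme4) for unbalanced data"
        )
    data = table.pivot_table(index=[between, subject], columns=within, values=dv)
    vals = data.to_numpy(dtype=float)
    grp = data.index.get_level_values(between)
    a = grp.nunique()
    n_subj, b = vals.shape
    if a < 2 or b < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")
    grand = vals.mean()
    subj_means = vals.mean(axis=1)
    day_means = vals.mean(axis=0)
    group_sizes = pd.Series(np.ones(n_subj), index=grp).groupby(level=0).sum()
    cell_means = data.groupby(level=0).mean().to_numpy()          # a x b
    group_means = cell_means.mean(axis=1)
    ng = group_sizes.to_numpy()
    ss_group = b * np.sum(ng * (group_means - grand) ** 2)
    ss_between_subj = b * np.sum((subj_means - grand) ** 2)
    ss_subj_err = ss_between_subj - ss_group
    ss_day = n_subj * np.sum((day_means - grand) ** 2)
    ss_inter = np.sum(ng[:, None] * (cell_means - group_means[:, None]
                                     - day_means[None, :] + grand) ** 2)
    ss_within_subj = np.sum((vals - subj_means[:, None]) ** 2)
    ss_err = ss_within_subj - ss_day - ss_inter
    df_subj_err = n_subj - a
    df_err = (n_subj - a) * (b - 1)

    def f_test(ss_num, df_num, ss_den, df_den):
        if ss_num <= 1e-12 * max(abs(grand), 1.0) ** 2:
            return 0.0, 1.0
        if ss_den <= 0:
            return float("inf"), 0.0
        f = (ss_num / df_num) / (ss_den / df_den)
        return float(f), float(sps.f.sf(f, df_num, df_den))

    effects = {}
    for name, (ssn, dfn, ssd, dfd) in {
        "group": (ss_group, a - 1, ss_subj_err, df_subj_err),
        "day": (ss_day, b - 1, ss_err, df_err),
        "interaction": (ss_inter, (a - 1) * (b - 1), ss_err, df_err),
    }.items():
        f, p = f_test(ssn, dfn, ssd, dfd)
        effects[name] = {"F": f, "df": (dfn, dfd), "p": p}
    inter = effects["interaction"]
    return StatReport("two-way mixed ANOVA (balanced, uncorrected)",
                      inter["F"], inter["df"], inter["p"], effects=effects)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between two paired per-animal metrics with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error (sample sd over sqrt(n)); SEM is NaN for n=1."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one value")
    if vals.size == 1:
        return float(vals[0]), float("nan")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def analyze_metric(groups: dict, alpha: float = ALPHA_DEFAULT,
                   dunn_adjust: str = "bonferroni") -> StatReport:
    """Full chain: Shapiro-Wilk gate, then ANOVA+Tukey or KW+Dunn."""
    route, gate = normality_gate(groups, alpha)
    if route == "parametric":
        report = anova_tukey(groups, alpha)
    else:
        report = kw_dunn(groups, alpha, dunn_adjust)
    report.gate = {"route": route, "shapiro": gate}
    return report
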