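"""Treatment-effect statistics for replicate-level soil tables.

Percent changes between group means, one-way ANOVA with Fisher's LSD
compact letter display (protected LSD: pairwise tests only after a
significant omnibus F), and Pearson correlation matrices with the usual
star annotation (* p<0.05, ** p<0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "LetterDisplay",
    "CorrelationMatrix",
    "percent_change",
    "one_way_anova",
    "lsd_letters",
    "pearson_matrix",
    "stats_report",
]

#: F value reported when the within-group mean square is exactly zero but
#: group means differ (perfect separation); p is then reported as 0.
_SEPARATED_F = math.inf


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    mse: float


@dataclass
class LetterDisplay:
    letters: dict[str, str]
    alpha: float
    significant_pairs: set[frozenset] = field(default_factory=set)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    flagged: list[str] = field(default_factory=list)


def percent_change(control_mean: float, treatment_mean: float) -> float:
    """Signed percent change of a treatment mean relative to control.

    ``100 * (treatment - control) / control``; the control mean must be
    strictly positive.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be strictly positive")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def _grouped(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g]
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way between/within decomposition.

    Requires at least two groups with at least two observations each.
    Perfect separation (zero pooled within-group variance but differing
    means) is reported as F = inf, p = 0; identical data throughout is an
    error (the statistic is undefined).
    """
    by = _grouped(values, groups)
    if len(by) < 2:
        raise ValueError("need at least two groups")
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    allv = np.concatenate(list(by.values()))
    n, k = len(allv), len(by)
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    if ss_between + ss_within == 0:
        raise ValueError("zero total variance: F statistic undefined")
    df_b, df_w = k - 1, n - k
    msb, msw = ss_between / df_b, ss_within / df_w
    if msw == 0:
        f_stat, p = _SEPARATED_F, 0.0
    else:
        f_stat = msb / msw
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(v.mean()) for g, v in by.items()},
        group_sizes={g: int(len(v)) for g, v in by.items()},
        mse=float(msw),
    )


def lsd_letters(values, groups, alpha: float = 0.05) -> LetterDisplay:
    """Compact letter display from protected Fisher's LSD.

    If the omnibus ANOVA is non-significant at ``alpha`` every group is
    labelled "a".  Otherwise pairwise t tests use the pooled MSE and the
    within-group degrees of freedom, and letters are assembled with the
    insert-and-absorb algorithm: two groups share a letter iff their
    comparison is non-significant.  Letters follow descending group
    means.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(values, groups)
    order = sorted(anova.group_means, key=anova.group_means.get, reverse=True)

    if anova.p >= alpha:
        return LetterDisplay(letters={g: "a" for g in order}, alpha=alpha)

    sig: set[frozenset] = set()
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            if anova.mse == 0:
                different = anova.group_means[gi] != anova.group_means[gj]
            else:
                se = math.sqrt(
                    anova.mse * (1 / anova.group_sizes[gi] + 1 / anova.group_sizes[gj])
                )
                t = abs(anova.group_means[gi] - anova.group_means[gj]) / se
                different = 2 * stats.t.sf(t, anova.df_within) < alpha
            if different:
                sig.add(frozenset((gi, gj)))

    # insert-and-absorb on the significance graph
    sets: list[set[str]] = [set(order)]
    for pair in sig:
        a, b = tuple(pair)
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        sets = [s for s in new_sets if s]
        sets = [s for i, s in enumerate(sets)
                if not any(s < t or (s == t and i > j) for j, t in enumerate(sets))]

    pos = {g: i for i, g in enumerate(order)}
    sets.sort(key=lambda s: min(pos[g] for g in s))
    letters = {g: "" for g in order}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    letters = {g: "".join(sorted(v)) for g, v in letters.items()}
    return LetterDisplay(letters=letters, alpha=alpha, significant_pairs=sig)


def pearson_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix with two-sided t-test p-values.

    Constant variables yield undefined correlations: their pairs are set
    to NaN and the variable name is recorded in ``flagged`` rather than
    silently zeroed.  Star thresholds: * p<0.05, ** p<0.01 (raw, no
    multiplicity correction — matching the conventional heatmap display).
    """
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    data = table[variables].astype(float)
    if len(data) < 3:
        raise ValueError("need at least 3 complete observations")
    p_count = len(variables)
    r = np.eye(p_count)
    p = np.zeros((p_count, p_count))
    flagged = [v for v in variables if data[v].nunique() <= 1]
    for i in range(p_count):
        for j in range(i + 1, p_count):
            vi, vj = variables[i], variables[j]
            if vi in flagged or vj in flagged:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(data[vi], data[vj])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    np.fill_diagonal(stars, "")
    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        stars=pd.DataFrame(stars, index=idx, columns=idx),
        flagged=flagged,
    )


def stats_report(table: pd.DataFrame, group: str = "treatment",
                 alpha: float = 0.05) -> dict:
    """Full per-variable ANOVA + letters + correlation report as a dict.

    Used by the CLI ``stats`` subcommand; JSON-serializable.
    """
    variables = [c for c in table.columns
                 if c not in (group, "replicate")
                 and pd.api.types.is_numeric_dtype(table[c])]
    report: dict = {"alpha": alpha, "variables": {}}
    for v in variables:
        anova = one_way_anova(table[v], table[group])
        letters = lsd_letters(table[v], table[group], alpha)
        report["variables"][v] = {
            "F": anova.F,
            "df": [anova.df_between, anova.df_within],
            "p": anova.p,
            "group_means": anova.group_means,
            "letters": letters.letters,
        }
    corr = pearson_matrix(table, variables)
    report["correlation"] = {
        "variables": variables,
        "r": corr.r.to_numpy().tolist(),
        "p": corr.p.to_numpy().tolist(),
        "stars": corr.stars.to_numpy().tolist(),
        "flagged": corr.flagged,
    }
    return report
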