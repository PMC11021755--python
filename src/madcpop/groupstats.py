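"""Group-comparison statistics for missingness analyses.

Missing-locus counts differ in both mean and variance across species, so the
layer is: Levene's test for variance homogeneity, Welch's heteroscedastic
one-way ANOVA, and the Games–Howell post-hoc test (studentized-range p-values
with Welch–Satterthwaite degrees of freedom) summarised as a compact letter
display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {g: values[groups == g] for g in pd.unique(groups)}


def levene_test(values, groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances (one-way ANOVA on absolute
    deviations from each group's center)."""
    arrays = _group_arrays(values, groups)
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("levene_test needs >=2 groups with >=2 observations each")
    w, p = stats.levene(*arrays.values(), center=center)
    return float(w), float(p)


@dataclass
class WelchAnovaResult:
    f_star: float
    df1: float
    df2: float
    p_value: float


def welch_anova(values, groups) -> WelchAnovaResult:
    """Welch's (1951) heteroscedastic one-way ANOVA.

    Group weights are n_i/s_i²; the statistic is the weighted between-group
    mean square over a correction term, with df1 = k−1 and fractional df2.
    """
    arrays = _group_arrays(values, groups)
    k = len(arrays)
    if k < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("welch_anova needs >=2 groups with >=2 observations each")
    n = np.array([len(a) for a in arrays.values()], dtype=float)
    m = np.array([a.mean() for a in arrays.values()])
    s2 = np.array([a.var(ddof=1) for a in arrays.values()])
    if (s2 == 0).any():
        raise ValueError("welch_anova: zero within-group variance")
    w = n / s2
    W = w.sum()
    mw = (w * m).sum() / W
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    f_star = ((w * (m - mw) ** 2).sum() / (k - 1)) / (1 + 2 * (k - 2) / (k**2 - 1) * tmp)
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(stats.f.sf(f_star, df1, df2))
    return WelchAnovaResult(float(f_star), df1, df2, p)


def _compact_letters(groups: list[str], significant: set[tuple[str, str]], means: dict[str, float]) -> dict[str, str]:
    """Insert-and-absorb compact letter display over the significance graph."""
    order = sorted(groups, key=lambda g: means[g])
    letters: list[set[str]] = [set(order)]
    for a, b in sorted(significant):
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                s1, s2 = s - {a}, s - {b}
                for cand in (s1, s2):
                    if cand and not any(cand <= other for other in letters):
                        letters.append(cand)
        letters = [s for s in letters if not any(s < other for other in letters if other is not s)]
    # order letter groups by the smallest group mean they contain
    letters.sort(key=lambda s: min(means[g] for g in s))
    assignment: dict[str, str] = {g: "" for g in groups}
    for ch, s in zip(ascii_lowercase, letters):
        for g in order:
            if g in s:
                assignment[g] += ch
    return assignment


def games_howell(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games–Howell pairwise comparisons after Welch's ANOVA.

    Per pair: t = |x̄_i − x̄_j| / sqrt(s_i²/n_i + s_j²/n_j), Welch–Satterthwaite
    df, and a studentized-range p-value with q = t·√2 at k groups.  A compact
    letter display (column ``letters``) marks groups not significantly
    different at ``alpha``.
    """
    arrays = _group_arrays(values, groups)
    k = len(arrays)
    if k < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("games_howell needs >=2 groups with >=2 observations each")
    names = list(arrays)
    n = {g: len(arrays[g]) for g in names}
    m = {g: float(arrays[g].mean()) for g in names}
    s2 = {g: float(arrays[g].var(ddof=1)) for g in names}
    if any(v == 0 for v in s2.values()):
        raise ValueError("games_howell: zero within-group variance")
    rows = []
    significant: set[tuple[str, str]] = set()
    for a, b in combinations(names, 2):
        se = np.sqrt(s2[a] / n[a] + s2[b] / n[b])
        diff = m[a] - m[b]
        t = abs(diff) / se
        df = (s2[a] / n[a] + s2[b] / n[b]) ** 2 / (
            (s2[a] / n[a]) ** 2 / (n[a] - 1) + (s2[b] / n[b]) ** 2 / (n[b] - 1)
        )
        p = float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))
        if p < alpha:
            significant.add(tuple(sorted((a, b))))
        rows.append({"group_a": a, "group_b": b, "mean_diff": diff, "se": se, "df": df, "p_value": p})
    table = pd.DataFrame(rows)
    letters = _compact_letters(names, significant, m)
    table.attrs["letters"] = letters
    return table


def missingness_vs_fst(missing_by_species: pd.Series, fst_to_reference: pd.Series) -> tuple[pd.DataFrame, float]:
    """Species ordered by FST to the panel's design species, with the Spearman
    rank correlation between mean missingness and that FST."""
    if set(missing_by_species.index) != set(fst_to_reference.index):
        raise ValueError("species keys of missingness and FST inputs differ")
    if len(missing_by_species) < 2:
        raise ValueError("missingness_vs_fst needs >=2 species")
    df = pd.DataFrame(
        {"mean_missing": missing_by_species, "fst_to_reference": fst_to_reference}
    ).sort_values("fst_to_reference")
    rho = float(stats.spearmanr(df["fst_to_reference"], df["mean_missing"]).statistic)
    return df, rho
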