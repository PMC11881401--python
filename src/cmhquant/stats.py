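"""Cohort statistics: group means ± SEM, one-/two-way ANOVA with Tukey
multiple comparisons, Pearson correlations, and fold-changes.

Conventions follow the usual reporting style of hypertension cohort
studies: SEM uses the sample standard deviation (n−1), two-way designs
decompose infusion × drug with type-II sums of squares, pairwise p-values
are Tukey-HSD adjusted, and significance stars map * < 0.05, ** < 0.01,
*** < 0.001, **** < 0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "pearson_correlation",
    "anova_tukey",
    "fold_change",
    "significance_stars",
]

GROUPS = ("PBS-CTL", "AngII-CTL", "PBS-Tel", "AngII-Tel", "PBS-PLX", "AngII-PLX")


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float | None
    variable: str


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_groups(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> list[GroupSummary]:
    """Per-group mean ± SEM of one variable.

    SEM = sample sd (n−1 denominator) / sqrt(n); with a single animal in a
    group the SEM is undefined and reported as missing with a warning.
    """
    out = []
    for group, sub in table.groupby(group_col, sort=False):
        vals = sub[variable].to_numpy(dtype=float)
        n = len(vals)
        if n == 1:
            warnings.warn(f"group {group}: n=1, SEM undefined")
            sem = None
        else:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
        out.append(
            GroupSummary(group=str(group), n=n, mean=float(vals.mean()), sem=sem, variable=variable)
        )
    return out


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed p from the t transform
    (n−2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def anova_tukey(
    table: pd.DataFrame,
    response: str,
    factors: list[str] | str,
    group_col: str = "group",
) -> dict:
    """ANOVA with Tukey-HSD pairwise comparisons.

    One factor → one-way ANOVA; two factors → two-way with interaction,
    type-II sums of squares (robust to the mildly unbalanced group sizes of
    these cohorts).  Tukey comparisons always run on ``group_col`` so each
    group pair gets an adjusted p and a star string.

    Returns ``{"anova": DataFrame, "tukey": DataFrame}``.
    """
    if isinstance(factors, str):
        factors = [factors]
    data = table.copy()
    for f in factors + [group_col]:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} is degenerate (fewer than 2 levels)")
    counts = data.groupby(group_col)[response].count()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 observations")

    clean = {f: f"F{i}" for i, f in enumerate(factors)}
    data = data.rename(columns=clean | {response: "Y"})
    terms = [f"C({clean[f]})" for f in factors]
    formula = "Y ~ " + " + ".join(terms)
    if len(factors) == 2:
        formula += f" + {terms[0]}:{terms[1]}"
    model = ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={f"C({v})": k for k, v in clean.items()})

    tuk = pairwise_tukeyhsd(
        endog=table[response].to_numpy(dtype=float),
        groups=table[group_col].to_numpy(),
    )
    tukey = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    tukey["p-adj"] = np.asarray(tuk.pvalues, dtype=float)
    tukey["stars"] = [significance_stars(p) for p in tukey["p-adj"]]
    return {"anova": anova, "tukey": tukey}


def fold_change(mean_a: float, mean_b: float, decimals: int = 1) -> float:
    """Ratio of group means a/b, rounded to the reporting precision
    (one decimal by default)."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    return round(mean_a / mean_b, decimals)
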