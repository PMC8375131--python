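"""Group comparisons for spheroid endpoints.

Implements the comparisons used for growth rates, invaded areas and
maximum invasion radii: fixed-effects two-way ANOVA with Tukey or Sidak
post-hoc tests on the cell means, the unpaired two-tailed Student
t-test (pooled by default, Welch available), and the minimum difference
excludable at a given alpha from two observed samples (delta_min).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_ALPHA = 0.05

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001."""
    for cut, sym in STAR_LEVELS:
        if p < cut:
            return sym
    return ""


@dataclass
class GroupSample:
    """One group's measurements (k, invaded area, or r_max_invasion)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 1:
            raise ValueError("a group needs at least one value")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def var(self) -> float:
        return float(self.values.var(ddof=1)) if self.n > 1 else np.nan


@dataclass
class ComparisonResult:
    """One pairwise comparison with raw and adjusted p-values."""

    pair: tuple[str, str]
    statistic: float
    p_value: float            # adjusted p where an adjustment applies
    significant: bool
    stars: str
    p_raw: float | None = None
    method: str = ""
    note: str = ""


def _assign(p: float, alpha: float) -> tuple[bool, str]:
    return (p < alpha, stars(p))


def two_way_anova_posthoc(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factorA",
    factor_b: str = "factorB",
    method: str = "tukey",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Two-way fixed-effects ANOVA with interaction, plus post-hoc tests.

    The omnibus model is ``value ~ A + B + A:B``; post-hoc comparisons
    are made between every pair of design cells (A-level x B-level)
    using the residual mean square, adjusted by Tukey's studentized
    range or by the Sidak correction ``1 - (1 - p)^m``.

    Returns
    -------
    (anova_table, comparisons)
    """
    if method not in ("tukey", "sidak"):
        raise ValueError("method must be 'tukey' or 'sidak'")
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    df = data[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].astype(str).unique())
    levels_b = sorted(df[factor_b].astype(str).unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby([factor_a, factor_b], sort=True)[value].size()
    missing = [
        (a, b) for a in levels_a for b in levels_b
        if (a, b) not in counts.index
    ]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    work = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=work).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the omnibus "
                         "test (need >= 2 observations per cell)")

    cells = df.groupby([factor_a, factor_b], sort=True)[value]
    labels = [f"{a}:{b}" for (a, b) in cells.groups.keys()]
    means = cells.mean().to_numpy()
    ns = cells.size().to_numpy()
    k = len(labels)
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)

    results: list[ComparisonResult] = []
    for i, j in pairs:
        diff = means[i] - means[j]
        note = ""
        if mse <= 0:
            # degenerate: zero residual variance
            p_raw = 1.0 if diff == 0 else 0.0
            stat = 0.0 if diff == 0 else np.inf
            note = "zero residual variance"
            p_adj = p_raw
        elif method == "tukey":
            se_q = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            stat = abs(diff) / se_q
            p_raw = float(sps.studentized_range.sf(stat, k, df_resid))
            p_adj = p_raw  # studentized range is already family-wise
        else:  # sidak
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            stat = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(stat), df_resid))
            p_adj = float(min(1.0, 1.0 - (1.0 - p_raw) ** m))
        sig, sym = _assign(p_adj, alpha)
        results.append(ComparisonResult(
            pair=(labels[i], labels[j]), statistic=float(stat),
            p_value=p_adj, significant=sig, stars=sym, p_raw=p_raw,
            method=method, note=note,
        ))
    return anova_table, results


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak correction of raw p-values: ``1 - (1 - p)^m``."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size if m is None else m
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def t_test_unpaired(
    a: GroupSample, b: GroupSample,
    variant: str = "pooled", alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Unpaired two-tailed t-test between two groups.

    ``variant`` is ``"pooled"`` (classical Student, the default; valid
    under equal variances and any sample sizes) or ``"welch"``.
    Zero-variance degenerate inputs follow the documented conventions:
    identical constant groups give p = 1, constant groups with unequal
    means give p = 0 with a note.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    note = ""
    va = a.values.var(ddof=1)
    vb = b.values.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean == b.mean:
            stat, p = 0.0, 1.0
            note = "zero variance, equal means: p = 1 by convention"
        else:
            stat = np.inf if a.mean > b.mean else -np.inf
            p = 0.0
            note = "zero variance, unequal means: p -> 0"
    else:
        stat, p = sps.ttest_ind(a.values, b.values,
                                equal_var=(variant == "pooled"))
        stat, p = float(stat), float(p)
    sig, sym = _assign(p, alpha)
    return ComparisonResult(
        pair=(a.label, b.label), statistic=stat, p_value=p,
        significant=sig, stars=sym, p_raw=p,
        method=f"t-test ({variant}, two-tailed)", note=note,
    )


def min_excludable_difference(
    a: GroupSample, b: GroupSample,
    alpha: float = DEFAULT_ALPHA, variant: str = "pooled",
) -> float:
    """Minimum difference excludable at ``alpha``, as % of the control mean.

    ``delta_min = t_{1-alpha/2, df} * sqrt(s_a^2/n_a + s_b^2/n_b)``,
    with ``df = n_a + n_b - 2`` for the pooled variant or the
    Welch-Satterthwaite df otherwise; group ``a`` is the control whose
    mean sets the percentage scale.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.mean == 0:
        raise ValueError("zero control mean: percentage scale undefined")
    va, vb = a.var, b.var
    if variant == "pooled":
        df = a.n + b.n - 2
    elif variant == "welch":
        num = (va / a.n + vb / b.n) ** 2
        den = (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        df = num / den
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    delta = t_crit * np.sqrt(va / a.n + vb / b.n)
    return float(100.0 * delta / abs(a.mean))
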