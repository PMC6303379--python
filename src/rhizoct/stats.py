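"""Univariate statistics: ANOVA, Tukey HSD with letters, Box-Cox, percent change.

These reproduce the summary layer of a rhizosheath experiment: two-way
ANOVA (cultivar × carbon, or soil zone × carbon within cultivar) with
Type-II sums of squares, Tukey Honest Significant Differences with a
compact letter display (groups sharing a letter are not significantly
different), Box-Cox normalisation chosen by profile likelihood, and the
rhizosheath-vs-bulk percent changes that feed the path models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    table: pd.DataFrame
    residuals: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def _check_cells(table: pd.DataFrame, factors: list[str], min_n: int) -> None:
    levels = [table[f].unique() for f in factors]
    sizes = table.groupby(factors, observed=True).size()
    import itertools

    for combo in itertools.product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        n = int(sizes.get(key, 0))
        if n < min_n:
            cell = ", ".join(f"{f}={v}" for f, v in zip(factors, combo))
            raise StatsError(f"design cell ({cell}) has {n} observations, needs >= {min_n}")


def _diagnostics(residuals: np.ndarray) -> dict:
    out = {"residual_variance": float(np.var(residuals, ddof=1)) if residuals.size > 1 else 0.0}
    out["zero_residual_variance"] = out["residual_variance"] <= 1e-12 * max(1.0, float(np.abs(residuals).max() ** 2))
    if not out["zero_residual_variance"] and residuals.size >= 3:
        try:
            out["shapiro_p"] = float(scipy.stats.shapiro(residuals).pvalue)
        except ValueError:
            out["shapiro_p"] = np.nan
    else:
        out["shapiro_p"] = np.nan
    return out


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> AnovaResult:
    """Two-way ANOVA with Type-II sums of squares.

    On a balanced design Type-II equals Type-I/III. Requires >= 2 levels per
    factor and >= 2 observations per cell (empty cells are reported by
    name). Residual diagnostics (Shapiro normality p, zero-variance flag)
    ride along in ``diagnostics``.
    """
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has fewer than 2 levels")
    _check_cells(table, [factor_a, factor_b], 2)
    op = "*" if interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))"
    fit = smf.ols(formula, data=table).fit()
    resid = np.asarray(fit.resid)
    diag = _diagnostics(resid)
    if diag["zero_residual_variance"]:
        # all-equal observations: F is undefined; report a NaN table rather than crash
        terms = [factor_a, factor_b] + ([f"{factor_a}:{factor_b}"] if interaction else []) + ["Residual"]
        tab = pd.DataFrame(
            {"df": np.nan, "sum_sq": 0.0, "F": np.nan, "PR(>F)": np.nan},
            index=terms,
        )
        return AnovaResult(table=tab, residuals=resid, diagnostics=diag)
    tab = anova_lm(fit, typ=2)
    rename = {}
    for idx in tab.index:
        clean = idx.replace(f"C(Q('{factor_a}'))", factor_a).replace(f"C(Q('{factor_b}'))", factor_b)
        rename[idx] = clean
    tab = tab.rename(index=rename)
    return AnovaResult(table=tab, residuals=resid, diagnostics=diag)


def one_way_anova(table: pd.DataFrame, response: str, factor: str) -> AnovaResult:
    """One-way ANOVA (Type-II table via OLS)."""
    if table[factor].nunique() < 2:
        raise StatsError(f"factor {factor!r} has fewer than 2 levels")
    fit = smf.ols(f"Q('{response}') ~ C(Q('{factor}'))", data=table).fit()
    resid = np.asarray(fit.resid)
    diag = _diagnostics(resid)
    if diag["zero_residual_variance"]:
        tab = pd.DataFrame({"df": np.nan, "sum_sq": 0.0, "F": np.nan, "PR(>F)": np.nan}, index=[factor, "Residual"])
        return AnovaResult(table=tab, residuals=resid, diagnostics=diag)
    tab = anova_lm(fit, typ=2).rename(index={f"C(Q('{factor}'))": factor})
    return AnovaResult(table=tab, residuals=resid, diagnostics=diag)


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def compact_letter_display(groups: list[str], means: dict[str, float], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; ties in letter
    ordering are broken by group mean descending. The display is internally
    consistent: every significant pair differs in all letters, every
    non-significant pair shares one.
    """
    order = sorted(groups, key=lambda g: -means[g])
    columns: list[set] = [set(order)]
    for g1, g2 in [tuple(sorted(p, key=lambda g: -means[g])) for p in significant]:
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                a, b = set(col), set(col)
                a.discard(g2)
                b.discard(g1)
                for new in (a, b):
                    if new and not any(new <= c for c in columns):
                        columns.append(new)
        # absorb: drop columns that are subsets of others
        columns = [c for c in columns if not any(c < d for d in columns)]
    # letter columns ordered by their best (highest) mean
    columns.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def tukey_hsd(table: pd.DataFrame, response: str, grouping: str, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons plus compact letter display."""
    groups = table[grouping].unique().tolist()
    if len(groups) < 2:
        raise StatsError(f"Tukey HSD needs >= 2 groups in {grouping!r}")
    res = pairwise_tukeyhsd(endog=table[response], groups=table[grouping], alpha=alpha)
    pairwise = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    pairwise["p-adj"] = res.pvalues
    pairwise["reject"] = res.reject
    means = table.groupby(grouping)[response].mean().to_dict()
    significant = {
        frozenset((row["group1"], row["group2"])) for _, row in pairwise.iterrows() if row["reject"]
    }
    letters = compact_letter_display(groups, means, significant)
    # internal consistency check of the display
    for _, row in pairwise.iterrows():
        l1, l2 = set(letters[row["group1"]]), set(letters[row["group2"]])
        shared = bool(l1 & l2)
        if bool(row["reject"]) == shared:
            raise RuntimeError("inconsistent compact letter display (internal error)")
    return TukeyResult(pairwise=pairwise, letters=letters, alpha=alpha)


def boxcox_select(y: np.ndarray, lam_range: tuple[float, float] = (-3.0, 3.0), step: float = 0.01) -> tuple[float, np.ndarray]:
    """Box-Cox λ by profile log-likelihood on a grid, and the transformed data.

    The transform is (y^λ − 1)/λ, log y at λ = 0 (the λ → 0 limit).
    Non-positive data are refused with a shift suggestion.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        shift = float(-y.min() + 1e-6 * max(1.0, float(np.ptp(y))))
        raise StatsError(f"Box-Cox requires y > 0; consider shifting by +{shift:.6g}")
    grid = np.arange(lam_range[0], lam_range[1] + step / 2, step)
    ll = np.array([scipy.stats.boxcox_llf(lam, y) for lam in grid])
    lam = float(grid[np.argmax(ll)])
    return lam, boxcox_transform(y, lam)


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def percent_change(rhizo_value: float, bulk_value: float) -> float:
    """100 × (rhizosheath − bulk) / bulk; signed."""
    if bulk_value == 0:
        raise StatsError("percent change undefined for zero bulk value")
    return 100.0 * (rhizo_value - bulk_value) / bulk_value


def maybe_boxcox(table: pd.DataFrame, response: str, residuals: np.ndarray, alpha: float = 0.05):
    """Apply Box-Cox when ANOVA residuals fail Shapiro normality (p < α).

    Returns (table, transformed_flag, lambda or None); the transformed
    response replaces the original column in a copy of the table.
    """
    diag = _diagnostics(np.asarray(residuals))
    p = diag.get("shapiro_p", np.nan)
    if np.isnan(p) or p >= alpha:
        return table, False, None
    lam, transformed = boxcox_select(table[response].to_numpy())
    out = table.copy()
    out[response] = transformed
    return out, True, lam
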