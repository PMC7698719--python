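"""Group comparisons and imaging-histology correlation reporting.

Pearson correlations carry two-sided p-values from the t-distribution with
n − 2 degrees of freedom and 95 % confidence intervals from the Fisher
z-transform.  Group comparisons cover the designs used for Table-1-shaped
data: two-way ANOVA with Bonferroni-adjusted pairwise contrasts, one-way
ANOVA with Tukey's HSD, and a pooled-variance two-sided t-test.  The
correlation screen performs no multiplicity adjustment by default (matching
the source analysis); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


@dataclass
class CorrelationResult:
    imaging: str
    histology: str
    n: int
    r: float
    p: float
    ci_low: float
    ci_high: float
    significant: bool

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation requires n >= 3")
        if not (self.ci_low - 1e-12 <= self.r <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain r")


def pearson_with_ci(x: Sequence[float], y: Sequence[float], alpha: float = ALPHA,
                    imaging: str = "x", histology: str = "y") -> CorrelationResult:
    """Sample Pearson r with t-test p-value and Fisher-z confidence interval.

    For n = 3 the Fisher interval is undefined (zero degrees of freedom in z);
    the uninformative interval (-1, 1) is reported.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y: correlation undefined")

    r, p = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if n >= 4 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    elif abs(r) == 1.0:
        lo = hi = r
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(imaging, histology, n, r, float(p),
                             float(lo), float(hi), bool(p < alpha))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonDesign:
    """Which comparison to run on a long-format table.

    kind "two_way": two-way ANOVA on ``value ~ factor_a * factor_b`` with
    Bonferroni-adjusted pairwise t-tests across ``factor_a`` levels.
    kind "one_way": one-way ANOVA across ``factor_a`` with Tukey HSD.
    kind "ttest": pooled-variance two-sided t-test between the two levels of
    ``factor_a``.
    """

    kind: Literal["two_way", "one_way", "ttest"]
    value: str
    factor_a: str
    factor_b: str | None = None


@dataclass
class PairwiseResult:
    level_a: str
    level_b: str
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonReport:
    design: ComparisonDesign
    anova: pd.DataFrame | None
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _check_cells(df: pd.DataFrame, value: str, factors: list[str],
                 min_per_cell: int = 2) -> None:
    counts = df.groupby(factors, observed=True)[value].count()
    full = pd.MultiIndex.from_product(
        [df[f].unique() for f in factors], names=factors) if len(factors) > 1 else None
    if full is not None:
        counts = counts.reindex(full, fill_value=0)
    bad = counts[counts < min_per_cell]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(f"cell {cell!r} has {int(bad.iloc[0])} observations "
                         f"(need >= {min_per_cell})")


def bonferroni_pairwise(df: pd.DataFrame, value: str, group: str,
                        alpha: float = ALPHA) -> list[PairwiseResult]:
    """All pairwise pooled-variance t-tests, Bonferroni-adjusted (capped at 1)."""
    levels = list(df[group].unique())
    pairs = list(itertools.combinations(levels, 2))
    out = []
    for a, b in pairs:
        xa = df.loc[df[group] == a, value].to_numpy()
        xb = df.loc[df[group] == b, value].to_numpy()
        t, p = sps.ttest_ind(xa, xb, equal_var=True)
        p_adj = min(1.0, float(p) * len(pairs))
        out.append(PairwiseResult(str(a), str(b), float(t), p_adj, p_adj < alpha))
    return out


def compare_groups(df: pd.DataFrame, design: ComparisonDesign,
                   alpha: float = ALPHA) -> ComparisonReport:
    """Run the requested comparison and mark significant pairs at ``alpha``."""
    df = df.copy()
    levels_a = df[design.factor_a].unique()
    if len(levels_a) < 2:
        raise ValueError(f"factor {design.factor_a!r} needs >= 2 levels")

    if design.kind == "two_way":
        if design.factor_b is None:
            raise ValueError("two_way design requires factor_b")
        _check_cells(df, design.value, [design.factor_a, design.factor_b])
        df = df.rename(columns={design.value: "_y", design.factor_a: "_a",
                                design.factor_b: "_b"})
        model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        pairwise = bonferroni_pairwise(
            df.rename(columns={"_y": design.value, "_a": design.factor_a}),
            design.value, design.factor_a, alpha)
        return ComparisonReport(design, anova, pairwise)

    if design.kind == "one_way":
        _check_cells(df, design.value, [design.factor_a])
        groups = [g[design.value].to_numpy() for _, g in df.groupby(design.factor_a)]
        f, p = sps.f_oneway(*groups)
        anova = pd.DataFrame({"F": [float(f)], "PR(>F)": [float(p)]},
                             index=[design.factor_a])
        tk = pairwise_tukeyhsd(df[design.value].to_numpy(),
                               df[design.factor_a].to_numpy(), alpha=alpha)
        idx_pairs = list(itertools.combinations(range(len(tk.groupsunique)), 2))
        pairwise = [PairwiseResult(str(tk.groupsunique[i]), str(tk.groupsunique[j]),
                                   float(md), float(padj), bool(rej))
                    for (i, j), md, padj, rej in zip(idx_pairs, tk.meandiffs,
                                                    tk.pvalues, tk.reject)]
        return ComparisonReport(design, anova, pairwise)

    if design.kind == "ttest":
        levels = list(levels_a)
        if len(levels) != 2:
            raise ValueError(f"t-test requires exactly 2 levels, got {len(levels)}")
        xa = df.loc[df[design.factor_a] == levels[0], design.value].to_numpy()
        xb = df.loc[df[design.factor_a] == levels[1], design.value].to_numpy()
        t, p = sps.ttest_ind(xa, xb, equal_var=True)
        pw = [PairwiseResult(str(levels[0]), str(levels[1]), float(t), float(p),
                             bool(p < alpha))]
        return ComparisonReport(design, None, pw)

    raise ValueError(f"unknown design kind {design.kind!r}")


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(imaging: pd.DataFrame, histology: pd.DataFrame,
                       on: str = "tumor_id", alpha: float = ALPHA,
                       adjust: Literal[None, "bh"] = None) -> list[CorrelationResult]:
    """Correlate every imaging parameter column with every histology variable.

    ``imaging`` is wide-format: one row per tumor, the join key plus one
    column per parameter-region combination.  Pairs with fewer than 3 joined
    observations or zero variance are skipped with a warning.  Results are
    sorted by p-value.
    """
    if on not in imaging.columns or on not in histology.columns:
        raise ValueError(f"join key {on!r} must be present on both tables")
    merged = imaging.merge(histology, on=on, suffixes=("", "_hist"))
    img_cols = [c for c in imaging.columns if c != on
                and pd.api.types.is_numeric_dtype(imaging[c])]
    hist_cols = [c for c in histology.columns if c != on
                 and pd.api.types.is_numeric_dtype(histology[c])]

    results = []
    for ic, hc in itertools.product(img_cols, hist_cols):
        sub = merged[[ic, hc]].dropna()
        if len(sub) < 3:
            warnings.warn(f"skipping {ic} vs {hc}: n = {len(sub)} < 3")
            continue
        if sub[ic].std() == 0 or sub[hc].std() == 0:
            warnings.warn(f"skipping {ic} vs {hc}: zero variance")
            continue
        results.append(pearson_with_ci(sub[ic], sub[hc], alpha,
                                       imaging=ic, histology=hc))
    results.sort(key=lambda r: r.p)
    if adjust == "bh":
        m = len(results)
        qs = [r.p * m / (i + 1) for i, r in enumerate(results)]
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            qs[i] = min(qs[i], qs[i + 1])
        for r, q in zip(results, qs):
            r.significant = bool(min(q, 1.0) < alpha)
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "imaging": r.imaging, "histology": r.histology, "n": r.n, "r": r.r,
        "p": r.p, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "significant": r.significant} for r in results])
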