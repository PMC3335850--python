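"""Case-control comparison battery with correlation-scale effect sizes.

Conventions follow common psychiatric-neuroscience reporting practice:
Pearson chi-square without continuity correction, equal-variance pooled t
tests, SPSS-style Mann-Whitney U (smaller-U convention, tie-corrected
normal approximation for larger samples), effect sizes on the r scale
(r = sqrt(t^2/(t^2+df)), r = |Z|/sqrt(N), r = sqrt(chi^2/N)), Spearman
correlation screens, and directional one-tailed p-values that halve the
two-tailed p only when the observed direction matches the prediction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "chi_square_2x2",
    "pooled_t_test",
    "mann_whitney_u",
    "effect_size_from_t",
    "effect_size_from_z",
    "effect_size_from_chi2",
    "correlation_screen",
    "two_way_anova",
    "one_sample_t",
]


class StatsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    df: float | tuple | None
    p_value: float
    tails: str = "two"  # "one" | "two"
    effect_size_r: float | None = None
    direction: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not np.isnan(self.p_value):
            assert 0.0 <= self.p_value <= 1.0


def _directional_p(p_two: float, observed_sign: float, predicted: str | None) -> float:
    """One-tailed p: p/2 if the observed direction matches the prediction,
    else the conservative 1 - p/2."""
    if predicted not in {"greater", "less"}:
        raise StatsError(f"predicted_direction must be 'greater' or 'less', got {predicted!r}")
    matches = (observed_sign > 0) if predicted == "greater" else (observed_sign < 0)
    return p_two / 2.0 if matches else 1.0 - p_two / 2.0


def chi_square_2x2(table: np.ndarray | list[list[float]]) -> ComparisonResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1.

    Rows are groups, columns the binary trait.  A zero row or column margin
    leaves the statistic undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise StatsError("counts must be non-negative")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined: a table margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    n = t.sum()
    return ComparisonResult(
        "chi_square_2x2", float(chi2), int(df), float(p), "two",
        effect_size_r=float(np.sqrt(chi2 / n)),
        note=f"N={int(n)}",
    )


def pooled_t_test(
    group1: np.ndarray | tuple[int, float, float],
    group2: np.ndarray | tuple[int, float, float],
    tails: str = "two",
    predicted_direction: str | None = None,
) -> ComparisonResult:
    """Equal-variance pooled t test, df = n1 + n2 - 2.

    Each group is either a raw vector or a printed-summary triple
    ``(n, mean, sd)``, so statistics can be recomputed straight from a
    published demographics table.  One-tailed p halves the two-tailed p when
    the observed direction matches ``predicted_direction`` ('greater' means
    group1 > group2 predicted).
    """
    def _summary(g):
        if isinstance(g, tuple) and len(g) == 3:
            return int(g[0]), float(g[1]), float(g[2])
        arr = np.asarray(g, dtype=float)
        return arr.size, float(arr.mean()), float(arr.std(ddof=1))

    n1, m1, s1 = _summary(group1)
    n2, m2, s2 = _summary(group2)
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if not (np.isfinite(s1) and np.isfinite(s2)):
        raise StatsError("group SDs must be finite")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        if m1 != m2:
            raise StatsError("zero pooled variance with unequal means: t is infinite")
        t_stat, p_two = 0.0, 1.0
    else:
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t_stat = (m1 - m2) / se
        p_two = 2.0 * stats.t.sf(abs(t_stat), df)
    p = p_two if tails == "two" else _directional_p(p_two, t_stat, predicted_direction)
    return ComparisonResult(
        "pooled_t", float(t_stat), df, float(p), tails,
        effect_size_r=effect_size_from_t(t_stat, df),
        direction=predicted_direction,
    )


def _tie_corrected_sigma(all_values: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    return np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))


def mann_whitney_u(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    tails: str = "two",
    predicted_direction: str | None = None,
    exact_threshold: int = 20,
) -> ComparisonResult:
    """Mann-Whitney U with SPSS reporting conventions.

    U is reported under the smaller-U convention min(U1, n1*n2 - U1).  The
    p-value uses exact enumeration for small tie-free samples
    (max group size <= ``exact_threshold``) and otherwise the tie-corrected
    normal approximation without continuity correction.  Effect size
    r = |Z| / sqrt(N).  ``predicted_direction='greater'`` predicts x
    stochastically greater than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1  # pairs where x < y, ties half
    u = min(u1, n1 * n2 - u1)
    sigma = _tie_corrected_sigma(pooled, n1, n2)
    if sigma == 0:
        return ComparisonResult(
            "mann_whitney_u", float(u), (n1, n2), float("nan"), tails,
            effect_size_r=0.0, note="all values tied across groups; Z undefined",
        )
    z = (u1 - n1 * n2 / 2.0) / sigma
    has_ties = np.unique(pooled).size < pooled.size
    if max(n1, n2) <= exact_threshold and not has_ties:
        p_two = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        p_two = 2.0 * stats.norm.sf(abs(z))
    p = p_two if tails == "two" else _directional_p(p_two, -z, predicted_direction)
    # u1 counts x<y pairs, so a negative z means x tends larger; flip for direction
    return ComparisonResult(
        "mann_whitney_u", float(u), (n1, n2), float(p), tails,
        effect_size_r=effect_size_from_z(z, n1 + n2),
        direction=predicted_direction, note=f"Z={z:.4f}",
    )


def effect_size_from_t(t: float, df: float) -> float:
    """r = sqrt(t^2 / (t^2 + df)); correlation-scale effect magnitude."""
    if df <= 0:
        raise StatsError("df must be > 0")
    return float(np.sqrt(t**2 / (t**2 + df)))


def effect_size_from_z(z: float, n: int) -> float:
    """r = |Z| / sqrt(N)."""
    if n <= 0:
        raise StatsError("n must be > 0")
    return float(abs(z) / np.sqrt(n))


def effect_size_from_chi2(chi2: float, n: int) -> float:
    """r = sqrt(chi^2 / N) (phi for a 2x2 table)."""
    if n <= 0:
        raise StatsError("n must be > 0")
    return float(np.sqrt(chi2 / n))


def correlation_screen(
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate each expression column with each covariate column.

    Spearman rank correlation (average ranks on ties) by default; Pearson
    available.  Pairs are handled pairwise-complete; cells with fewer than 3
    complete pairs or a constant member are reported as missing.  Returns a
    tidy frame (gene, covariate, n, r, p) with two-tailed p-values.
    """
    if method not in {"spearman", "pearson"}:
        raise StatsError(f"method must be 'spearman' or 'pearson', got {method!r}")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for gene in expression.columns:
        for cov in covariates.columns:
            pair = pd.concat(
                [expression[gene], covariates[cov]], axis=1, join="inner"
            ).dropna()
            gvals = pair.iloc[:, 0].to_numpy(float)
            cvals = pair.iloc[:, 1].to_numpy(float)
            n = len(pair)
            if n < 3 or np.ptp(gvals) == 0 or np.ptp(cvals) == 0:
                rows.append((gene, cov, n, np.nan, np.nan))
                continue
            res = corr(gvals, cvals)
            rows.append((gene, cov, n, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["gene", "covariate", "n", "r", "p"])


def two_way_anova(
    values: np.ndarray | list[float],
    factor_a: list,
    factor_b: list,
    posthoc: bool = False,
) -> dict:
    """Fixed-effects two-way ANOVA with interaction (Type II SS).

    Returns a dict with per-effect F, df and p for factor A, factor B and
    the interaction; with ``posthoc=True`` also Tukey HSD contrasts on each
    factor's level means.  Type II sums of squares keep main-effect tests
    meaningful in unbalanced designs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": np.asarray(values, float),
                       "a": list(factor_a), "b": list(factor_b)})
    for fac in ("a", "b"):
        if df[fac].nunique() < 2:
            raise StatsError(f"factor {fac!r} needs >= 2 levels")
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = {}
    for label, key in [("C(a)", "factor_a"), ("C(b)", "factor_b"),
                       ("C(a):C(b)", "interaction")]:
        out[key] = {
            "F": float(tab.loc[label, "F"]),
            "df": (float(tab.loc[label, "df"]), float(tab.loc["Residual", "df"])),
            "p": float(tab.loc[label, "PR(>F)"]),
        }
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        out["tukey"] = {
            fac: pairwise_tukeyhsd(df["value"], df[fac]).summary()
            for fac in ("a", "b") if df[fac].nunique() > 1
        }
    return out


def one_sample_t(values: np.ndarray | list[float], mu0: float = 0.0) -> ComparisonResult:
    """One-sample t test of the mean against mu0; df = n - 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("one_sample_t needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero standard deviation: t undefined")
    t_stat = (x.mean() - mu0) / (sd / np.sqrt(x.size))
    df = x.size - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return ComparisonResult(
        "one_sample_t", float(t_stat), df, float(p), "two",
        effect_size_r=effect_size_from_t(t_stat, df),
    )


def exact_mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Brute-force U and two-sided p by enumerating all rank assignments.

    Exponential-time reference oracle for tiny tie-free samples; exposed for
    validation, not for routine use.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.sort(np.concatenate([x, y]))
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u_obs = min(u1, n1 * n2 - u1)
    all_ranks = stats.rankdata(pooled)
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = all_ranks[list(combo)].sum()
        u = n1 * n2 + n1 * (n1 + 1) / 2.0 - r
        us.append(min(u, n1 * n2 - u))
    us = np.array(us)
    p = float((us <= u_obs + 1e-12).mean())
    return float(u_obs), min(1.0, p)
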