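"""Control-anchored high-expressor detection and the trimmed "normal core".

A sample is a *high expressor* when its relative quantity exceeds the
unaffected-control group's median plus 1.25 x IQR.  The flagged/unflagged
split is cross-tabulated against diagnosis (Pearson chi-square, no
continuity correction) and summarized as a risk ratio (and odds ratio).
The *normal core* of the distribution is estimated by reiteratively
removing the single highest value until a Lilliefors-corrected
Kolmogorov-Smirnov normality test stops rejecting at alpha; the flagged
subpopulation's elevation is then reported in core-SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .group_stats import chi_square_2x2, StatsError

__all__ = [
    "SubgroupResult",
    "CoreSummary",
    "high_expression_threshold",
    "classify_and_associate",
    "iterative_normal_core",
    "sd_distance",
]

IQR_MULTIPLIER = 1.25
QUANTILE_METHODS = {"linear", "weibull"}  # weibull ~ SPSS HAVERAGE hinge


class SubgroupError(ValueError):
    pass


@dataclass
class CoreSummary:
    """Mean/SD/n of the surviving normal core plus the final KS result."""

    mean: float
    sd: float
    n: int
    ks_D: float
    ks_p: float
    removed: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class SubgroupResult:
    threshold: float
    flags: Mapping[str, np.ndarray]  # group -> boolean flags
    counts: Mapping[str, tuple[int, int]]  # group -> (flagged, total)
    chi2: float | None
    p: float | None
    effect_size_r: float | None
    risk_ratio: float | None
    odds_ratio: float | None
    note: str = ""


def high_expression_threshold(
    control_values: np.ndarray | list[float],
    multiplier: float = IQR_MULTIPLIER,
    quantile_method: str = "linear",
) -> float:
    """T = median(controls) + 1.25 x IQR(controls).

    ``quantile_method`` selects the quartile convention: ``linear``
    (interpolation between order statistics, the common scientific-software
    default) or ``weibull`` (the (n+1)p weighted-average hinge SPSS uses).
    Requires at least 4 control values so the quartiles are data-supported.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 4:
        raise SubgroupError(f"need >= 4 control values, got {x.size}")
    if quantile_method not in QUANTILE_METHODS:
        raise SubgroupError(f"quantile_method must be one of {sorted(QUANTILE_METHODS)}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    return float(np.median(x) + multiplier * (q3 - q1))


def classify_and_associate(
    values_by_group: Mapping[str, np.ndarray],
    threshold: float,
    case_group: str,
    control_group: str,
) -> SubgroupResult:
    """Flag values above the threshold and test the 2x2 group association.

    The chi-square comes from the shared 2x2 routine (no continuity
    correction).  ``risk_ratio`` is case prevalence over control prevalence;
    the odds ratio is reported alongside because "times more likely" is
    ambiguous between the two.  Zero flagged controls give an infinite risk
    ratio with a warning; no flags at all give a degenerate result with the
    association left undefined.
    """
    for g in (case_group, control_group):
        if g not in values_by_group or len(values_by_group[g]) == 0:
            raise SubgroupError(f"group {g!r} is missing or empty")
    flags = {g: np.asarray(v, float) > threshold for g, v in values_by_group.items()}
    counts = {g: (int(f.sum()), int(f.size)) for g, f in flags.items()}

    fc, nc = counts[case_group]
    f0, n0 = counts[control_group]
    note = ""
    if fc + f0 == 0:
        warnings.warn("no sample exceeds the threshold; association undefined")
        return SubgroupResult(threshold, flags, counts, None, None, None, None, None,
                              note="no high expressors")
    table = [[fc, nc - fc], [f0, n0 - f0]]
    try:
        res = chi_square_2x2(table)
        chi2, p, r = res.statistic, res.p_value, res.effect_size_r
    except StatsError as exc:  # e.g. everything flagged
        chi2, p, r = None, None, None
        note = f"chi-square undefined: {exc}"

    if f0 == 0:
        warnings.warn("zero flagged controls: risk ratio infinite")
        risk_ratio = float("inf")
    else:
        risk_ratio = (fc / nc) / (f0 / n0)
    if f0 == 0 or fc == nc or f0 == n0 or fc == 0:
        odds_ratio = float("inf") if f0 == 0 and fc > 0 else (
            0.0 if fc == 0 else float("nan"))
    else:
        odds_ratio = (fc / (nc - fc)) / (f0 / (n0 - f0))
    return SubgroupResult(threshold, flags, counts, chi2, p, r, risk_ratio,
                          odds_ratio, note)


def iterative_normal_core(
    values: np.ndarray | list[float],
    alpha: float = 0.05,
    min_n: int = 5,
) -> CoreSummary:
    """Reiteratively trim the maximum until KS normality stops rejecting.

    Each pass runs a Kolmogorov-Smirnov test against a normal with the
    current sample's estimated mean/SD, using Lilliefors-corrected
    significance (a plain KS p with estimated parameters would be
    anti-conservative).  While p <= alpha the single largest value is
    removed (ties at the maximum: one occurrence per pass, the last index)
    and the test repeated; the loop stops when p > alpha or when a further
    removal would shrink the sample below ``min_n`` (reported as
    non-convergence).  Removed values are returned in removal order.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = list(np.asarray(values, dtype=float))
    if len(x) < min_n:
        raise SubgroupError(f"need >= {min_n} values, got {len(x)}")
    removed: list[float] = []
    while True:
        arr = np.asarray(x)
        if arr.std(ddof=1) == 0:
            raise SubgroupError("constant values: KS statistic undefined (zero SD)")
        d, p = lilliefors(arr, dist="norm", pvalmethod="table")
        if p > alpha:
            return CoreSummary(float(arr.mean()), float(arr.std(ddof=1)), arr.size,
                               float(d), float(p), removed, converged=True)
        if arr.size - 1 < min_n:
            return CoreSummary(float(arr.mean()), float(arr.std(ddof=1)), arr.size,
                               float(d), float(p), removed, converged=False)
        # last occurrence of the maximum, for deterministic tie handling
        i = int(np.where(arr == arr.max())[0][-1])
        removed.append(float(x.pop(i)))


def sd_distance(
    flagged_values: np.ndarray | list[float],
    core: CoreSummary | tuple[float, float],
) -> float:
    """Elevation of the flagged subpopulation in core-SD units.

    (mean of flagged values - core mean) / core SD.  Invariant under affine
    rescaling applied to both the flagged values and the core.
    """
    x = np.asarray(flagged_values, dtype=float)
    if x.size == 0:
        raise SubgroupError("need >= 1 flagged value")
    mean, sd = (core.mean, core.sd) if isinstance(core, CoreSummary) else core
    if sd <= 0:
        raise SubgroupError("core SD must be > 0")
    return float((x.mean() - mean) / sd)
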