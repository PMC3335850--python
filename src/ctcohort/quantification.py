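"""Delta-delta-Ct relative quantification with replicate cleaning.

Raw qRT-PCR Ct triplicates are cleaned (replicates deviating from the
triplicate median by more than ``max_dev`` Ct are dropped), each sample's
target-gene Ct is normalized against the geometric mean of its housekeeper
Cts (dCt), dCt values are re-centered on a calibrator group's mean (ddCt),
and relative quantities are reported as 2**(-ddCt).  A population-level
Grubbs screen flags extreme relative quantities for review; nothing is
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean

__all__ = [
    "clean_triplicates",
    "delta_ct",
    "relative_quantity",
    "grubbs_screen",
    "quantify",
    "CleaningLog",
]

DEFAULT_MAX_DEV = 0.5  # Ct units; deviation from the triplicate median


class QuantificationError(ValueError):
    pass


@dataclass
class CleaningLog:
    """Record of every replicate dropped and every Grubbs flag raised."""

    dropped_replicates: list[dict] = field(default_factory=list)
    grubbs_flags: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"event": "dropped_replicate", **d} for d in self.dropped_replicates]
        rows += [{"event": "grubbs_flag", **d} for d in self.grubbs_flags]
        return pd.DataFrame(
            rows, columns=["event", "sample_id", "gene", "replicate_index", "value"]
        )


def clean_triplicates(
    replicates: np.ndarray | list[float], max_dev: float = DEFAULT_MAX_DEV
) -> tuple[np.ndarray, float, np.ndarray]:
    """Drop replicates deviating from the triplicate median by > ``max_dev`` Ct.

    Returns ``(retained_values, mean_ct, retained_mask)``.  Pairs and
    singletons are never trimmed — with two values there is no majority to
    define the outlier — and at least one replicate always survives (the
    median itself has zero deviation, so with three replicates at least the
    middle one is retained).
    """
    values = np.asarray(replicates, dtype=float)
    if values.size == 0:
        raise QuantificationError("clean_triplicates needs at least one replicate")
    if values.size <= 2:
        return values, float(values.mean()), np.ones(values.size, dtype=bool)
    keep = np.abs(values - np.median(values)) <= max_dev
    retained = values[keep]
    return retained, float(retained.mean()), keep


def delta_ct(target_ct: float, housekeeper_cts: dict[str, float]) -> float:
    """dCt = target Ct minus the geometric mean of the housekeeper Cts.

    The geometric mean is taken of the Ct values themselves (cycle numbers),
    not of linearized 2**(-Ct) quantities.  Requires >= 3 housekeepers, all
    finite; a missing housekeeper raises an error naming the gene.
    """
    if len(housekeeper_cts) < 3:
        raise QuantificationError(
            f"need >= 3 housekeeper genes, got {sorted(housekeeper_cts)}"
        )
    for gene, ct in housekeeper_cts.items():
        if ct is None or not np.isfinite(ct):
            raise QuantificationError(f"housekeeper {gene!r} has missing/non-finite Ct")
    return float(target_ct - gmean(list(housekeeper_cts.values())))


def relative_quantity(
    delta_cts: pd.DataFrame, calibrator: str, group_col: str = "group"
) -> pd.DataFrame:
    """ddCt against the calibrator group's mean dCt; rq = 2**(-ddCt).

    ``delta_cts`` is long-format with columns ``sample_id``, ``gene``,
    ``delta_ct`` and a group column.  The calibrator mean is computed per
    gene, so each gene's calibrator-group ddCt values average to zero by
    construction.
    """
    if calibrator not in set(delta_cts[group_col]):
        raise QuantificationError(f"unknown calibrator group {calibrator!r}")
    out = delta_cts.copy()
    cal_mean = (
        delta_cts[delta_cts[group_col] == calibrator]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    missing = set(out["gene"]) - set(cal_mean.index)
    if missing:
        raise QuantificationError(
            f"calibrator group {calibrator!r} has no dCt values for genes {sorted(missing)}"
        )
    out["ddct"] = out["delta_ct"] - out["gene"].map(cal_mean)
    out["rq"] = np.exp2(-out["ddct"])
    return out


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(values: np.ndarray | list[float], alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs outlier test; returns a boolean flag array.

    The most extreme value (largest |x - mean| / SD) is tested against
    G_crit(n, alpha); while significant it is flagged, removed, and the test
    repeated.  Zero-SD (constant) data yields no flags.  Requires n >= 3.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise QuantificationError("grubbs_screen needs n >= 3")
    flags = np.zeros(x.size, dtype=bool)
    active = np.arange(x.size)
    while active.size >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= grubbs_critical(active.size, alpha):
            break
        flags[active[i]] = True
        active = np.delete(active, i)
    return flags


def quantify(
    ct_table: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    calibrator: str,
    max_dev: float = DEFAULT_MAX_DEV,
    grubbs_alpha: float | None = 0.05,
) -> tuple[pd.DataFrame, CleaningLog]:
    """Full chain: clean triplicates -> dCt -> ddCt -> rq, with a cleaning log.

    ``ct_table`` is long-format (``sample_id``, ``gene``, ``replicate_index``,
    ``ct``, ``is_housekeeper``); ``groups`` maps sample_id to diagnostic
    group.  Returns an expression table (``sample_id``, ``group``, ``gene``,
    ``delta_ct``, ``ddct``, ``rq``, ``grubbs_flag``) for target genes only,
    plus the log of dropped replicates and Grubbs flags.  Grubbs screening
    is applied per gene on rq values; flagged samples are annotated, never
    removed.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    log = CleaningLog()

    mean_ct: dict[tuple[str, str], float] = {}
    hk_by_sample: dict[str, dict[str, float]] = {}
    for (sid, gene), grp in ct_table.groupby(["sample_id", "gene"], sort=False):
        values = grp["ct"].to_numpy(float)
        retained, mean, keep = clean_triplicates(values, max_dev=max_dev)
        for idx, val in zip(grp["replicate_index"].to_numpy()[~keep], values[~keep]):
            log.dropped_replicates.append(
                {"sample_id": sid, "gene": gene, "replicate_index": int(idx),
                 "value": float(val)}
            )
        mean_ct[(sid, gene)] = mean
        if bool(grp["is_housekeeper"].iloc[0]):
            hk_by_sample.setdefault(sid, {})[gene] = mean

    target_genes = sorted(set(ct_table.loc[~ct_table["is_housekeeper"], "gene"]))
    rows = []
    for sid in ct_table["sample_id"].unique():
        hk = hk_by_sample.get(sid, {})
        for gene in target_genes:
            if (sid, gene) not in mean_ct:
                continue
            rows.append({
                "sample_id": sid,
                "group": groups.get(sid),
                "gene": gene,
                "delta_ct": delta_ct(mean_ct[(sid, gene)], hk),
            })
    expr = relative_quantity(pd.DataFrame(rows), calibrator)

    expr["grubbs_flag"] = False
    if grubbs_alpha is not None:
        for gene, grp in expr.groupby("gene"):
            if len(grp) >= 3:
                flags = grubbs_screen(grp["rq"].to_numpy(float), alpha=grubbs_alpha)
                expr.loc[grp.index[flags], "grubbs_flag"] = True
                for sid, val in zip(grp["sample_id"].to_numpy()[flags],
                                    grp["rq"].to_numpy(float)[flags]):
                    log.grubbs_flags.append(
                        {"sample_id": sid, "gene": gene, "replicate_index": None,
                         "value": float(val)}
                    )
    return expr, log
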