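"""Synthetic case-control qRT-PCR cohorts with a planted high-expressor subpopulation.

The generator emulates the statistical structure of a postmortem brain
case-control expression study: demographic covariates per diagnostic group,
log2-scale relative quantities drawn from a normal "core" with an optional
elevated subpopulation several core-SDs above it, expression coupled to
tissue pH, and raw Ct triplicates (target and housekeeper genes) with
occasional aberrant replicates.  Everything is deterministic given a seed,
so downstream modules can assert parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "GroupCovariates",
    "CohortSpec",
    "GeneSpec",
    "CtNoiseSpec",
    "generate_cohort",
    "generate_expression",
    "generate_ct_table",
]


class SpecError(ValueError):
    """A generator spec failed validation; the message names the field."""


@dataclass
class GroupCovariates:
    """Covariate distribution parameters for one diagnostic group.

    Continuous covariates (age in years, tissue pH, postmortem interval in
    hours) are normal; binary covariates are Bernoulli with the stated
    proportion.  Defaults are overridden per group in :func:`default_cohort_spec`.
    """

    age_mean: float = 47.6
    age_sd: float = 12.2
    ph_mean: float = 6.64
    ph_sd: float = 0.28
    pmi_mean: float = 27.04
    pmi_sd: float = 12.15
    male_prop: float = 0.77
    left_hemisphere_prop: float = 0.42
    smoking_prop: float = 0.46
    suicide_prop: float = 0.0

    def validate(self, group: str) -> None:
        for name in ("age_sd", "ph_sd", "pmi_sd"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{group}.{name} must be > 0, got {getattr(self, name)}")
        for name in ("male_prop", "left_hemisphere_prop", "smoking_prop", "suicide_prop"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{group}.{name} must be in [0, 1], got {p}")


@dataclass
class CohortSpec:
    """Sample sizes and per-group covariate distributions for a cohort."""

    n_per_group: Mapping[str, int]
    covariate_params: Mapping[str, GroupCovariates]
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group:
            raise SpecError("n_per_group must name at least one group")
        for group, n in self.n_per_group.items():
            if n < 2:
                raise SpecError(f"n_per_group[{group!r}] must be >= 2, got {n}")
            if group not in self.covariate_params:
                raise SpecError(f"covariate_params missing group {group!r}")
        for group, params in self.covariate_params.items():
            params.validate(group)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Two-group cohort shaped like a combined postmortem DLPFC collection.

    71 unaffected controls and 72 schizophrenia cases; ages ~48 +/- 12 y,
    tissue pH ~6.6 +/- 0.28, postmortem delay ~27-30 h, male-majority, with
    smoking and suicide strongly group-dependent.  Smoking proportions are
    among donors with recorded smoking status.
    """
    return CohortSpec(
        n_per_group={"control": 71, "schizophrenia": 72},
        covariate_params={
            "control": GroupCovariates(
                age_mean=47.6, age_sd=12.2, ph_mean=6.64, ph_sd=0.28,
                pmi_mean=27.04, pmi_sd=12.15, male_prop=55 / 71,
                left_hemisphere_prop=30 / 71, smoking_prop=18 / 39,
                suicide_prop=0 / 71,
            ),
            "schizophrenia": GroupCovariates(
                age_mean=47.1, age_sd=12.5, ph_mean=6.55, ph_sd=0.28,
                pmi_mean=29.89, pmi_sd=14.63, male_prop=50 / 72,
                left_hemisphere_prop=37 / 72, smoking_prop=46 / 57,
                suicide_prop=15 / 72,
            ),
        },
        seed=seed,
    )


@dataclass
class GeneSpec:
    """Generative parameters for one gene's relative-quantity distribution.

    ``core_mean``/``core_sd`` place the normal core on the log2
    relative-quantity scale.  A fraction ``subpop_prevalence`` of samples
    (scalar, or per-group mapping) is displaced upward by
    ``subpop_shift_sd`` x ``core_sd``.  ``ph_coupling`` is the target Pearson
    correlation between log2 expression and tissue pH within the core;
    ``group_effect`` adds a per-group shift to the core mean (log2 units).
    """

    name: str
    core_mean: float = 0.0
    core_sd: float = 0.5
    subpop_shift_sd: float = 5.0
    subpop_prevalence: float | Mapping[str, float] = 0.0
    ph_coupling: float = 0.0
    group_effect: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.core_sd <= 0:
            raise SpecError(f"{self.name}.core_sd must be > 0, got {self.core_sd}")
        if not abs(self.ph_coupling) < 1:
            raise SpecError(f"{self.name}.ph_coupling must satisfy |rho| < 1")
        prevs = (
            self.subpop_prevalence.values()
            if isinstance(self.subpop_prevalence, Mapping)
            else [self.subpop_prevalence]
        )
        for p in prevs:
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{self.name}.subpop_prevalence must be in [0, 1], got {p}")

    def prevalence_for(self, group: str) -> float:
        if isinstance(self.subpop_prevalence, Mapping):
            if group not in self.subpop_prevalence:
                raise SpecError(
                    f"{self.name}.subpop_prevalence has no entry for group {group!r}"
                )
            return self.subpop_prevalence[group]
        return self.subpop_prevalence


@dataclass
class CtNoiseSpec:
    """Measurement-noise model for raw Ct triplicates.

    Each sample x gene is measured in three technical replicates with
    N(0, replicate_sd) noise (Ct units); with probability ``aberrant_rate``
    a replicate is additionally displaced by +/- ``aberrant_shift`` Ct,
    emulating pipetting or amplification failures that triplicate cleaning
    should remove.  ``housekeeper_baseline`` gives the mean Ct of each
    housekeeper gene (at least three are required downstream).
    """

    replicate_sd: float = 0.15
    aberrant_rate: float = 0.02
    aberrant_shift: float = 3.0
    housekeeper_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"ACTB": 18.0, "TBP": 27.0, "UBC": 22.0}
    )
    n_replicates: int = 3

    def validate(self) -> None:
        if self.replicate_sd <= 0:
            raise SpecError(f"replicate_sd must be > 0, got {self.replicate_sd}")
        if not 0.0 <= self.aberrant_rate < 1.0:
            raise SpecError(f"aberrant_rate must be in [0, 1), got {self.aberrant_rate}")
        if self.aberrant_shift <= 3 * self.replicate_sd:
            raise SpecError(
                "aberrant_shift must exceed 3x replicate_sd "
                f"({self.aberrant_shift} <= {3 * self.replicate_sd})"
            )
        if len(self.housekeeper_baseline) < 3:
            raise SpecError(
                "housekeeper_baseline must name >= 3 housekeeper genes, "
                f"got {len(self.housekeeper_baseline)}"
            )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a sample manifest: one row per donor with group and covariates.

    Returns a DataFrame with columns ``sample_id``, ``group``, ``age``,
    ``sex`` (M/F), ``hemisphere`` (L/R), ``pmi``, ``ph``, ``smoking`` (0/1),
    ``suicide`` (0/1).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group in spec.n_per_group:  # insertion order: stable per spec
        n = spec.n_per_group[group]
        p = spec.covariate_params[group]
        frames.append(pd.DataFrame({
            "group": group,
            "age": rng.normal(p.age_mean, p.age_sd, n),
            "sex": np.where(rng.random(n) < p.male_prop, "M", "F"),
            "hemisphere": np.where(rng.random(n) < p.left_hemisphere_prop, "L", "R"),
            "pmi": rng.normal(p.pmi_mean, p.pmi_sd, n),
            "ph": rng.normal(p.ph_mean, p.ph_sd, n),
            "smoking": (rng.random(n) < p.smoking_prop).astype(int),
            "suicide": (rng.random(n) < p.suicide_prop).astype(int),
        }))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(cohort))])
    return cohort


def generate_expression(
    cohort: pd.DataFrame,
    genes: list[GeneSpec] | GeneSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw true relative quantities per sample x gene.

    For each gene the log2 value is

        core_mean + group_effect + slope * (pH - mean pH) + eps
        [+ subpop_shift_sd * core_sd  with prob. subpop_prevalence(group)]

    where ``slope`` and the SD of ``eps`` are calibrated so that within the
    core the marginal SD equals ``core_sd`` and the Pearson correlation with
    pH equals ``ph_coupling``.  Returned columns: ``sample_id``, ``gene``,
    ``log2_rq`` (true log2 value), ``rq`` (2**log2_rq, all > 0) and
    ``is_subpop`` (ground-truth subpopulation membership).
    """
    if isinstance(genes, GeneSpec):
        genes = [genes]
    if cohort["ph"].isna().any():
        raise SpecError("every sample needs a pH value to generate expression")
    rng = np.random.default_rng(seed)
    ph = cohort["ph"].to_numpy(float)
    ph_centered = ph - ph.mean()
    ph_sd = ph.std(ddof=1)
    n = len(cohort)
    frames = []
    for g in genes:
        g.validate()
        rho = g.ph_coupling
        slope = rho * g.core_sd / ph_sd if ph_sd > 0 else 0.0
        resid_sd = g.core_sd * np.sqrt(1.0 - rho**2)
        prev = np.array([g.prevalence_for(grp) for grp in cohort["group"]])
        shift_group = np.array([g.group_effect.get(grp, 0.0) for grp in cohort["group"]])
        is_subpop = rng.random(n) < prev
        log2 = (
            g.core_mean
            + shift_group
            + slope * ph_centered
            + rng.normal(0.0, resid_sd, n)
            + is_subpop * g.subpop_shift_sd * g.core_sd
        )
        frames.append(pd.DataFrame({
            "sample_id": cohort["sample_id"].to_numpy(),
            "gene": g.name,
            "log2_rq": log2,
            "rq": np.exp2(log2),
            "is_subpop": is_subpop,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_ct_table(
    expression: pd.DataFrame,
    noise: CtNoiseSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Back-transform true relative quantities into raw Ct triplicates.

    Housekeeper replicates are drawn around each housekeeper's baseline Ct.
    A target gene's noiseless Ct is the geometric mean of the housekeeper
    baselines minus log2(true rq), so with zero noise the quantification
    chain recovers ``rq`` exactly (2**(-delta Ct) == rq).  Aberrant
    replicates are displaced by +/- ``aberrant_shift`` at ``aberrant_rate``.

    Returns a long-format DataFrame with columns ``sample_id``, ``gene``,
    ``replicate_index``, ``ct``, ``is_housekeeper``.
    """
    noise = noise or CtNoiseSpec()
    noise.validate()
    rng = np.random.default_rng(seed)
    hk_genes = list(noise.housekeeper_baseline)
    hk_geomean = float(gmean(list(noise.housekeeper_baseline.values())))
    nrep = noise.n_replicates

    def _replicates(center: float) -> np.ndarray:
        cts = center + rng.normal(0.0, noise.replicate_sd, nrep)
        aberrant = rng.random(nrep) < noise.aberrant_rate
        signs = np.where(rng.random(nrep) < 0.5, -1.0, 1.0)
        return cts + aberrant * signs * noise.aberrant_shift

    rows = []
    targets_by_sample = {
        sid: list(zip(grp["gene"], hk_geomean - np.log2(grp["rq"].to_numpy(float))))
        for sid, grp in expression.groupby("sample_id", sort=False)
    }
    for sid in expression["sample_id"].unique():
        for hk in hk_genes:
            for j, ct in enumerate(_replicates(noise.housekeeper_baseline[hk])):
                rows.append((sid, hk, j, ct, True))
        for gene, center in targets_by_sample[sid]:
            for j, ct in enumerate(_replicates(center)):
                rows.append((sid, gene, j, ct, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "replicate_index", "ct", "is_housekeeper"]
    )
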