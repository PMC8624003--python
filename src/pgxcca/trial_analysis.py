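"""Trial-alongside cost-consequence analysis.

Arm summaries, provider-cluster bootstrap mean differences, nested
cost-category ladders, and scenario/sensitivity analyses over
patient-level records in the interchange format written by
:mod:`pgxcca.synthetic_trial`.

Inference is by percentile cluster bootstrap: providers are resampled
with replacement jointly across both arms (providers see patients of
both arms under pseudo-cluster randomization), all of a provider's
patients travel together, and the provider count is preserved in each
replicate.  Binary-outcome differences are reported in percentage
points, costs in USD; the sign convention is PGx+ minus PGx-.

A generalized-estimating-equation (GEE) cross-check hook is provided
(:func:`gee_difference`) for comparing point estimates against an
exchangeable-correlation GEE fit; it is a convenience wrapper, not the
implemented inferential method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ValidationError
from .synthetic_trial import ARMS

__all__ = [
    "ArmSummary",
    "DifferenceEstimate",
    "CostLadder",
    "summarize_arm",
    "summarize_arms",
    "cluster_bootstrap_diff",
    "cost_ladder",
    "scenario_analysis",
    "ladder_tiers",
    "gee_difference",
    "SUBGROUPS",
]

#: redraw cap for bootstrap replicates that land an empty arm
MAX_REDRAW_ROUNDS = 100

SUBGROUPS = ("statin_users", "carriers_TC_CC", "TT", "ACC_AHA_high_risk")


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    outcome: str
    n: int
    mean: float
    sd: float
    count: int | None = None  # binary outcomes only
    proportion: float | None = None

    @property
    def percent(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion


@dataclass(frozen=True)
class DifferenceEstimate:
    """Between-arm mean difference with percentile cluster-bootstrap CI.

    ``scale`` is ``"percentage_points"`` for binary outcomes and
    ``"usd"``/``"native"`` otherwise; ``delta`` is PGx+ minus PGx-.
    """

    outcome: str
    delta: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int | None
    scale: str = "native"
    n_redraws: int = 0
    #: percentile CIs need not contain the point estimate in pathological
    #: resamples; flagged rather than failed
    anomaly: bool = False


@dataclass(frozen=True)
class CostLadder:
    """Nested cost-tier differences (each tier a superset of the last)."""

    variant: str
    tiers: Mapping[str, tuple[tuple[str, ...], DifferenceEstimate]]

    def delta(self, tier: str) -> float:
        return self.tiers[tier][1].delta


def _outcome_values(df: pd.DataFrame, outcome: str) -> tuple[np.ndarray, bool]:
    if outcome not in df.columns:
        raise ValidationError(f"unknown outcome column {outcome!r}")
    col = df[outcome]
    binary = col.dtype == bool
    return col.to_numpy(dtype=float), binary


def summarize_arm(records: pd.DataFrame, outcome: str, arm: str) -> ArmSummary:
    """Per-arm n, mean and sample SD (plus count/proportion for binaries)."""
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}")
    sub = records[records["arm"] == arm]
    if len(sub) == 0:
        raise ValidationError(f"no records in arm {arm}")
    vals, binary = _outcome_values(sub, outcome)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if binary:
        return ArmSummary(
            arm=arm, outcome=outcome, n=len(vals), mean=mean, sd=sd,
            count=int(vals.sum()), proportion=mean,
        )
    return ArmSummary(arm=arm, outcome=outcome, n=len(vals), mean=mean, sd=sd)


def summarize_arms(records: pd.DataFrame, outcome: str) -> dict[str, ArmSummary]:
    return {arm: summarize_arm(records, outcome, arm) for arm in ARMS}


def _provider_aggregates(records: pd.DataFrame, outcome: str):
    """Per-provider sums and counts by arm, aligned on provider order."""
    vals, binary = _outcome_values(records, outcome)
    prov = records["provider_id"].to_numpy()
    providers, inv = np.unique(prov, return_inverse=True)
    pos = (records["arm"] == "PGx+").to_numpy()
    p = len(providers)
    sum_pos = np.bincount(inv, weights=vals * pos, minlength=p)
    n_pos = np.bincount(inv, weights=pos.astype(float), minlength=p)
    sum_neg = np.bincount(inv, weights=vals * ~pos, minlength=p)
    n_neg = np.bincount(inv, weights=(~pos).astype(float), minlength=p)
    return sum_pos, n_pos, sum_neg, n_neg, binary


def cluster_bootstrap_diff(
    records: pd.DataFrame,
    outcome: str,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> DifferenceEstimate:
    """Percentile cluster-bootstrap CI for the between-arm mean difference.

    Providers are resampled with replacement (preserving the provider
    count); the PGx+ minus PGx- difference of patient-level means is
    recomputed per replicate and the 2.5th/97.5th percentiles bound the
    interval.  Replicates in which one arm receives no patients are
    redrawn (counted; hard failure after ``MAX_REDRAW_ROUNDS`` rounds).
    """
    if n_bootstrap < 1:
        raise ValidationError(f"n_bootstrap must be >= 1, got {n_bootstrap}")
    for arm in ARMS:
        sub = records[records["arm"] == arm]
        if sub["provider_id"].nunique() < 2:
            raise ValidationError(f"need >= 2 providers with patients in arm {arm}")
    sum_pos, n_pos, sum_neg, n_neg, binary = _provider_aggregates(records, outcome)
    scale = 100.0 if binary else 1.0
    delta = scale * (sum_pos.sum() / n_pos.sum() - sum_neg.sum() / n_neg.sum())

    p = len(n_pos)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p, size=(n_bootstrap, p))
    tot_pos = n_pos[idx].sum(axis=1)
    tot_neg = n_neg[idx].sum(axis=1)
    n_redraws = 0
    rounds = 0
    bad = (tot_pos == 0) | (tot_neg == 0)
    while bad.any():
        rounds += 1
        if rounds > MAX_REDRAW_ROUNDS:
            raise ValidationError(
                f"bootstrap kept producing empty-arm replicates after {MAX_REDRAW_ROUNDS} rounds"
            )
        n_redraws += int(bad.sum())
        idx[bad] = rng.integers(0, p, size=(int(bad.sum()), p))
        tot_pos = n_pos[idx].sum(axis=1)
        tot_neg = n_neg[idx].sum(axis=1)
        bad = (tot_pos == 0) | (tot_neg == 0)
    deltas = scale * (
        sum_pos[idx].sum(axis=1) / tot_pos - sum_neg[idx].sum(axis=1) / tot_neg
    )
    lo, hi = (float(q) for q in np.percentile(deltas, [2.5, 97.5]))
    return DifferenceEstimate(
        outcome=outcome,
        delta=float(delta),
        ci_low=lo,
        ci_high=hi,
        n_bootstrap=n_bootstrap,
        seed=seed,
        scale="percentage_points" if binary else "usd" if outcome.startswith("cost_") else "native",
        n_redraws=n_redraws,
        anomaly=not (lo <= delta <= hi),
    )


def ladder_tiers(variant: str = "lipid_rx") -> dict[str, tuple[str, ...]]:
    """Nested cost tiers, innermost (intervention-immediate) first.

    ``variant`` picks the immediate lipid component: ``"statin"``
    (statin prescriptions only) or ``"lipid_rx"`` (all lipid therapy).
    """
    if variant not in ("statin", "lipid_rx"):
        raise ValidationError(f"unknown ladder variant {variant!r}")
    lipid = f"cost_{variant}"
    immediate = ("cost_pgx_test", lipid, "cost_sams_care")
    plus_cardio = immediate + ("cost_cardiology",)
    plus_pc = plus_cardio + ("cost_primary_care",)
    attributable = plus_pc + ("cost_laboratory", "cost_imaging")
    total = attributable + ("cost_other_outpatient", "cost_inpatient")
    return {
        "immediate": immediate,
        "plus_cardiology": plus_cardio,
        "plus_primary_care": plus_pc,
        "attributable": attributable,
        "total": total,
    }


def cost_ladder(
    records: pd.DataFrame,
    variant: str = "lipid_rx",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> CostLadder:
    """Cluster-bootstrap difference for each nested cost tier."""
    tiers = ladder_tiers(variant)
    out: dict[str, tuple[tuple[str, ...], DifferenceEstimate]] = {}
    work = records.copy()
    for i, (name, cats) in enumerate(tiers.items()):
        col = f"_tier_{name}"
        work[col] = work[list(cats)].sum(axis=1)
        est = cluster_bootstrap_diff(work, col, n_bootstrap=n_bootstrap, seed=None if seed is None else seed + i)
        out[name] = (cats, DifferenceEstimate(
            outcome=name, delta=est.delta, ci_low=est.ci_low, ci_high=est.ci_high,
            n_bootstrap=est.n_bootstrap, seed=est.seed, scale="usd",
            n_redraws=est.n_redraws, anomaly=est.anomaly,
        ))
    return CostLadder(variant=variant, tiers=out)


def apply_scenario(records: pd.DataFrame, scenario_spec: Mapping) -> pd.DataFrame:
    """Return a modified copy of the records per a scenario specification.

    Keys: ``pgx_cost_factor`` (scales the PGx test cost; 0 models fully
    preemptive, already-available results), ``statin_cost_factor``
    (scales statin prescription costs), ``subgroup`` (one of
    ``statin_users``, ``carriers_TC_CC``, ``TT``, ``ACC_AHA_high_risk``).
    Derived columns (lipid Rx, total) are recomputed after rescaling.
    """
    known = {"pgx_cost_factor", "statin_cost_factor", "subgroup"}
    unknown = set(scenario_spec) - known
    if unknown:
        raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
    df = records.copy()
    f = scenario_spec.get("pgx_cost_factor")
    if f is not None:
        if f < 0:
            raise ValidationError("pgx_cost_factor must be >= 0")
        df["cost_pgx_test"] = df["cost_pgx_test"] * f
    f = scenario_spec.get("statin_cost_factor")
    if f is not None:
        if f < 0:
            raise ValidationError("statin_cost_factor must be >= 0")
        df["cost_statin"] = df["cost_statin"] * f
    df["cost_lipid_rx"] = df["cost_statin"] + df["cost_other_lipid"]
    df["cost_total"] = df[
        [
            "cost_pgx_test",
            "cost_lipid_rx",
            "cost_sams_care",
            "cost_primary_care",
            "cost_cardiology",
            "cost_imaging",
            "cost_laboratory",
            "cost_other_outpatient",
            "cost_inpatient",
        ]
    ].sum(axis=1)
    sub = scenario_spec.get("subgroup")
    if sub is not None:
        if sub == "statin_users":
            mask = df["prescribed_statin"]
        elif sub == "carriers_TC_CC":
            mask = df["genotype"].isin(("TC", "CC"))
        elif sub == "TT":
            mask = df["genotype"] == "TT"
        elif sub == "ACC_AHA_high_risk":
            mask = df["high_risk"]
        else:
            raise ValidationError(f"unknown subgroup {sub!r}; expected one of {SUBGROUPS}")
        df = df[mask]
        if len(df) == 0:
            raise ValidationError(f"subgroup filter {sub!r} selected no records")
    return df


def scenario_analysis(
    records: pd.DataFrame,
    scenario_spec: Mapping,
    variant: str = "lipid_rx",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> CostLadder:
    """Recompute the cost ladder under a scenario (see :func:`apply_scenario`)."""
    return cost_ladder(
        apply_scenario(records, scenario_spec), variant=variant,
        n_bootstrap=n_bootstrap, seed=seed,
    )


def gee_difference(records: pd.DataFrame, outcome: str):
    """Cross-check hook: between-arm difference from an exchangeable GEE.

    Fits ``outcome ~ arm`` with provider clusters via statsmodels and
    returns the arm coefficient (PGx+ minus PGx-).  Intended only for
    comparing against :func:`cluster_bootstrap_diff` point estimates.
    """
    import statsmodels.api as sm  # deferred; optional cross-check only
    import statsmodels.formula.api as smf

    df = records.copy()
    df["_y"], binary = _outcome_values(df, outcome)
    df["_pgx"] = (df["arm"] == "PGx+").astype(int)
    model = smf.gee(
        "_y ~ _pgx", groups="provider_id", data=df,
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit()
    coef = float(res.params["_pgx"])
    return 100.0 * coef if binary else coef
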