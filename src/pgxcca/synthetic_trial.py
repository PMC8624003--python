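"""Synthetic patient-level trial data generator.

Emits datasets with the statistical structure of a pragmatic,
provider-clustered pharmacogenetic testing trial (two randomization
arms nested in primary-care provider clusters, genotype prevalence,
a statin offer -> prescription -> type cascade, muscle-symptom and
discontinuation flags, and right-skewed per-category annual costs), so
the trial-alongside analysis is testable without access-restricted
records.

Cost categories are drawn from zero-inflated gamma distributions
moment-matched on the marginal mean/SD: the configured zero mass plus
a gamma on the positive part whose two moments are solved so the
overall mean and SD equal the configured values.  Statin costs are
gated on an actual statin prescription rather than an independent zero
mass.  Categories are independent within patient given arm, which is a
known simplification (real cost categories are positively correlated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ValidationError

__all__ = [
    "CostModel",
    "TrialGenConfig",
    "default_trial_config",
    "generate_trial",
    "write_trial_csv",
    "read_trial_csv",
    "validate_records",
    "ARMS",
    "COST_CATEGORIES",
    "COLUMN_DICTIONARY",
]

ARMS = ("PGx+", "PGx-")

#: generated per-category cost columns (cost_lipid_rx = statin + other lipid
#: is derived, cost_pgx_test is structural)
COST_CATEGORIES = (
    "statin",
    "other_lipid",
    "sams_care",
    "primary_care",
    "cardiology",
    "imaging",
    "laboratory",
    "other_outpatient",
    "inpatient",
)

UTILIZATION = ("inpatient_stays", "outpatient_encounters", "primary_care_visits", "cardiology_visits")

COLUMN_DICTIONARY = {
    "patient_id": "integer, unique within dataset",
    "provider_id": "integer cluster id (randomization/bootstrap unit)",
    "arm": "PGx+ (results released immediately) or PGx- (usual care)",
    "genotype": "SLCO1B1 rs4149056: TT, TC or CC",
    "high_risk": "bool, 10-year ASCVD risk >= 7.5%",
    "offered_statin": "bool",
    "prescribed_statin": "bool (implies offered_statin)",
    "statin_type": "atorvastatin/simvastatin/rosuvastatin, empty if not prescribed",
    "sams": "bool, provider-documented muscle symptoms (implies prescribed)",
    "discontinued": "bool, stopped statin (implies prescribed)",
    "inpatient_stays": "count over 12 months",
    "outpatient_encounters": "count over 12 months",
    "primary_care_visits": "count over 12 months",
    "cardiology_visits": "count over 12 months",
    "cost_pgx_test": "USD, 99 iff arm PGx+ else 0",
    "cost_statin": "USD, 0 unless prescribed_statin",
    "cost_other_lipid": "USD, non-statin lipid therapy",
    "cost_lipid_rx": "USD, statin + other lipid (derived)",
    "cost_sams_care": "USD",
    "cost_primary_care": "USD",
    "cost_cardiology": "USD",
    "cost_imaging": "USD",
    "cost_laboratory": "USD",
    "cost_other_outpatient": "USD",
    "cost_inpatient": "USD, non-mental-health inpatient care",
    "cost_total": "USD, pgx_test + lipid_rx + sams_care + primary_care + cardiology + imaging + laboratory + other_outpatient + inpatient",
}


@dataclass(frozen=True)
class CostModel:
    """Marginal moments for one cost category in one arm.

    ``p_zero`` is the point mass at zero; the positive part is a gamma
    whose moments are solved so the overall mean/SD match.  Feasibility
    requires ``1 - p_zero > mean^2 / (sd^2 + mean^2)``.
    """

    mean: float
    sd: float
    p_zero: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValidationError(f"cost model needs mean, sd >= 0, got {self.mean}, {self.sd}")
        if not 0.0 <= self.p_zero < 1.0 and self.mean > 0:
            raise ValidationError(f"p_zero must be in [0, 1), got {self.p_zero}")

    def gamma_moments(self, p_nonzero: float | None = None) -> tuple[float, float]:
        """(shape, scale) of the positive part given the nonzero fraction."""
        p_nz = 1.0 - self.p_zero if p_nonzero is None else p_nonzero
        if p_nz <= self.mean**2 / (self.sd**2 + self.mean**2):
            raise ValidationError(
                f"cost model infeasible: nonzero fraction {p_nz:.4f} too small for "
                f"mean {self.mean}, sd {self.sd}"
            )
        mg = self.mean / p_nz
        vg = (self.sd**2 + self.mean**2) / p_nz - mg**2
        return mg**2 / vg, vg / mg

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` marginal values (zero mass + gamma positive part)."""
        if self.mean == 0:
            return np.zeros(size)
        if self.sd == 0:
            return np.full(size, self.mean)
        nonzero = rng.random(size) < (1.0 - self.p_zero)
        shape, scale = self.gamma_moments()
        out = np.zeros(size)
        k = int(nonzero.sum())
        if k:
            out[nonzero] = rng.gamma(shape, scale, size=k)
        return out


def _per_arm(pos: float, neg: float) -> dict[str, float]:
    return {"PGx+": pos, "PGx-": neg}


@dataclass(frozen=True)
class TrialGenConfig:
    """Generator configuration; defaults emulate the trial's marginals."""

    n_providers: int = 39
    # cluster sizes: 1 + NegBin(r, mean mu) truncated to [min, max]
    cluster_size_r: float = 0.7
    cluster_size_mean: float = 10.0
    cluster_size_min: int = 1
    cluster_size_max: int = 61
    arm_allocation: float = 193 / 408  # P(PGx+) per patient
    p_carrier: float = 0.294
    p_cc_given_carrier: float = 0.1  # CC vs TC among C-allele carriers
    p_high_risk: float = 0.90
    p_offer_statin: Mapping[str, float] = field(default_factory=lambda: _per_arm(0.337, 0.321))
    p_prescribe_statin: Mapping[str, float] = field(  # marginal, not conditional on offer
        default_factory=lambda: _per_arm(0.135, 0.112)
    )
    statin_type_mix: Mapping[str, tuple[float, float, float]] = field(
        # (atorvastatin, simvastatin, rosuvastatin); pooled observed mix
        default_factory=lambda: {"PGx+": (0.76, 0.18, 0.06), "PGx-": (0.76, 0.18, 0.06)}
    )
    p_sams_given_statin: Mapping[str, float] = field(default_factory=lambda: _per_arm(0.077, 0.125))
    p_disc_given_statin: Mapping[str, float] = field(default_factory=lambda: _per_arm(0.115, 0.167))
    pgx_test_cost: float = 99.0
    cost_models: Mapping[str, Mapping[str, CostModel]] = field(
        default_factory=lambda: {
            "statin": {"PGx+": CostModel(6, 23), "PGx-": CostModel(4, 19)},
            "other_lipid": {"PGx+": CostModel(11, 70, 0.927), "PGx-": CostModel(4, 25, 0.944)},
            "sams_care": {"PGx+": CostModel(3, 27, 0.985), "PGx-": CostModel(0, 0)},
            "primary_care": {
                "PGx+": CostModel(2955, 2802, 0.05),
                "PGx-": CostModel(3400, 8950, 0.05),
            },
            "cardiology": {"PGx+": CostModel(316, 901, 0.60), "PGx-": CostModel(640, 2571, 0.60)},
            "imaging": {"PGx+": CostModel(1243, 2998, 0.30), "PGx-": CostModel(1331, 3509, 0.30)},
            "laboratory": {
                "PGx+": CostModel(1015, 1574, 0.05),
                "PGx-": CostModel(1027, 1386, 0.05),
            },
            "other_outpatient": {
                "PGx+": CostModel(8748, 15263, 0.02),
                "PGx-": CostModel(9381, 12236, 0.02),
            },
            "inpatient": {
                "PGx+": CostModel(6107, 27836, 0.80),
                "PGx-": CostModel(4926, 18887, 0.80),
            },
        }
    )
    utilization_models: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "inpatient_stays": {"PGx+": (0.4, 1.3), "PGx-": (0.4, 1.4)},
            "outpatient_encounters": {"PGx+": (40.1, 31.0), "PGx-": (38.9, 27.2)},
            "primary_care_visits": {"PGx+": (3.9, 3.7), "PGx-": (4.7, 10.4)},
            "cardiology_visits": {"PGx+": (0.6, 1.3), "PGx-": (0.9, 1.9)},
        }
    )
    #: published per-arm total-cost mean/SD, kept for reference (generated
    #: totals are sums of independent categories, so the SD is smaller)
    total_cost_reference: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"PGx+": (20497, 38216), "PGx-": (20706, 30769)}
    )

    def __post_init__(self) -> None:
        if self.n_providers < 1:
            raise ValidationError("n_providers must be >= 1")
        if not 0.0 <= self.arm_allocation <= 1.0:
            raise ValidationError("arm_allocation must be in [0, 1]")
        for name in ("p_carrier", "p_cc_given_carrier", "p_high_risk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for arm in ARMS:
            mix = self.statin_type_mix[arm]
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValidationError(f"statin_type_mix for {arm} must sum to 1, got {mix}")
            for m in (self.p_offer_statin, self.p_prescribe_statin,
                      self.p_sams_given_statin, self.p_disc_given_statin):
                if not 0.0 <= m[arm] <= 1.0:
                    raise ValidationError(f"per-arm probability out of [0, 1]: {m[arm]}")
            if self.p_prescribe_statin[arm] > self.p_offer_statin[arm]:
                raise ValidationError(
                    f"marginal prescribe probability exceeds offer probability in {arm}"
                )

    def with_scale(self, scale: float) -> "TrialGenConfig":
        """Scaled-up copy (more providers) for large-sample checks."""
        return replace(self, n_providers=max(1, int(round(self.n_providers * scale))))


def default_trial_config() -> TrialGenConfig:
    """Defaults reproducing the trial's published marginals in expectation.

    39 providers; cluster sizes with median 7 on [1, 61]; 29.4% C-allele
    carriers; per-arm statin offer 33.7%/32.1% and prescription
    13.5%/11.2%; pooled statin mix 76/18/6 (atorva/simva/rosuva); SAMS
    among statin users 7.7%/12.5%; per-category cost means/SDs from the
    published arm summaries.
    """
    return TrialGenConfig()


def _nb_counts(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Moment-matched count draws: negative binomial, or Poisson if var <= mean."""
    var = sd**2
    if mean == 0:
        return np.zeros(size, dtype=int)
    if var <= mean:
        return rng.poisson(mean, size)
    r = mean**2 / (var - mean)
    return rng.negative_binomial(r, r / (r + mean), size)


def _cluster_sizes(rng: np.random.Generator, cfg: TrialGenConfig) -> np.ndarray:
    r, mu = cfg.cluster_size_r, cfg.cluster_size_mean
    sizes = 1 + rng.negative_binomial(r, r / (r + mu), size=cfg.n_providers)
    # truncate by redraw
    bad = (sizes < cfg.cluster_size_min) | (sizes > cfg.cluster_size_max)
    while bad.any():
        sizes[bad] = 1 + rng.negative_binomial(r, r / (r + mu), size=int(bad.sum()))
        bad = (sizes < cfg.cluster_size_min) | (sizes > cfg.cluster_size_max)
    return sizes


def generate_trial(config: TrialGenConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic trial dataset (one row per patient).

    Providers and cluster sizes are drawn first; patients are then
    randomized to arms individually within provider (simple stratified
    assignment), genotyped, passed through the prescription cascade,
    and costed.  Reproducible per seed.
    """
    cfg = config or default_trial_config()
    rng = np.random.default_rng(seed)
    sizes = _cluster_sizes(rng, cfg)
    n = int(sizes.sum())
    provider = np.repeat(np.arange(1, cfg.n_providers + 1), sizes)

    is_pos = rng.random(n) < cfg.arm_allocation
    arm = np.where(is_pos, "PGx+", "PGx-")
    carrier = rng.random(n) < cfg.p_carrier
    cc = carrier & (rng.random(n) < cfg.p_cc_given_carrier)
    genotype = np.where(cc, "CC", np.where(carrier, "TC", "TT"))
    high_risk = rng.random(n) < cfg.p_high_risk

    offered = np.zeros(n, dtype=bool)
    prescribed = np.zeros(n, dtype=bool)
    sams = np.zeros(n, dtype=bool)
    discontinued = np.zeros(n, dtype=bool)
    statin_type = np.full(n, "", dtype=object)
    util = {u: np.zeros(n, dtype=int) for u in UTILIZATION}
    costs = {c: np.zeros(n) for c in COST_CATEGORIES}

    statins = np.array(["atorvastatin", "simvastatin", "rosuvastatin"])
    for a in ARMS:
        mask = arm == a
        m = int(mask.sum())
        if m == 0:
            continue
        offered[mask] = rng.random(m) < cfg.p_offer_statin[a]
        p_cond = (
            cfg.p_prescribe_statin[a] / cfg.p_offer_statin[a] if cfg.p_offer_statin[a] else 0.0
        )
        prescribed[mask] = offered[mask] & (rng.random(m) < p_cond)
        rx = mask & prescribed
        k = int(rx.sum())
        if k:
            statin_type[rx] = rng.choice(statins, size=k, p=cfg.statin_type_mix[a])
            sams[rx] = rng.random(k) < cfg.p_sams_given_statin[a]
            discontinued[rx] = rng.random(k) < cfg.p_disc_given_statin[a]
        for u in UTILIZATION:
            mean, sd = cfg.utilization_models[u][a]
            util[u][mask] = _nb_counts(rng, mean, sd, m)
        for cat in COST_CATEGORIES:
            model = cfg.cost_models[cat][a]
            if cat == "statin":
                # statin costs attach only to actual prescriptions; the
                # configured marginal moments are rescaled to the
                # configured prescription probability
                if model.mean == 0 or cfg.p_prescribe_statin[a] == 0:
                    continue
                shape, scale = model.gamma_moments(p_nonzero=cfg.p_prescribe_statin[a])
                vals = np.zeros(m)
                idx = prescribed[mask]
                if idx.sum():
                    vals[idx] = rng.gamma(shape, scale, size=int(idx.sum()))
                costs[cat][mask] = vals
            else:
                costs[cat][mask] = model.draw(rng, m)

    cost_pgx = np.where(is_pos, cfg.pgx_test_cost, 0.0)
    lipid_rx = costs["statin"] + costs["other_lipid"]
    total = (
        cost_pgx
        + lipid_rx
        + costs["sams_care"]
        + costs["primary_care"]
        + costs["cardiology"]
        + costs["imaging"]
        + costs["laboratory"]
        + costs["other_outpatient"]
        + costs["inpatient"]
    )
    df = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "provider_id": provider,
            "arm": arm,
            "genotype": genotype,
            "high_risk": high_risk,
            "offered_statin": offered,
            "prescribed_statin": prescribed,
            "statin_type": statin_type,
            "sams": sams,
            "discontinued": discontinued,
            **{u: util[u] for u in UTILIZATION},
            "cost_pgx_test": cost_pgx,
            "cost_statin": costs["statin"],
            "cost_other_lipid": costs["other_lipid"],
            "cost_lipid_rx": lipid_rx,
            "cost_sams_care": costs["sams_care"],
            "cost_primary_care": costs["primary_care"],
            "cost_cardiology": costs["cardiology"],
            "cost_imaging": costs["imaging"],
            "cost_laboratory": costs["laboratory"],
            "cost_other_outpatient": costs["other_outpatient"],
            "cost_inpatient": costs["inpatient"],
            "cost_total": total,
        }
    )
    validate_records(df)
    return df


def validate_records(df: pd.DataFrame) -> None:
    """Check the cascade and cost invariants of a patient-record table."""
    missing = set(COLUMN_DICTIONARY) - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if not df["arm"].isin(ARMS).all():
        raise ValidationError("arm must be PGx+ or PGx-")
    if (df["prescribed_statin"] & ~df["offered_statin"]).any():
        raise ValidationError("prescribed_statin without offered_statin")
    if (df["sams"] & ~df["prescribed_statin"]).any():
        raise ValidationError("sams without prescribed_statin")
    if (df["discontinued"] & ~df["prescribed_statin"]).any():
        raise ValidationError("discontinued without prescribed_statin")
    if ((df["statin_type"] != "") != df["prescribed_statin"]).any():
        raise ValidationError("statin_type must be present iff prescribed_statin")
    cost_cols = [c for c in df.columns if c.startswith("cost_")]
    if (df[cost_cols] < 0).any().any():
        raise ValidationError("negative costs")


def write_trial_csv(df: pd.DataFrame, path) -> None:
    """Write the interchange CSV consumed by :mod:`pgxcca.trial_analysis`."""
    df.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    """Read and validate a patient-record CSV."""
    df = pd.read_csv(
        path,
        dtype={"arm": str, "genotype": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("high_risk", "offered_statin", "prescribed_statin", "sams", "discontinued"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    validate_records(df)
    return df
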