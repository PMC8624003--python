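"""Expected-value evaluation of the 1-month statin decision tree.

Two strategies over a closed cohort initiated on statin therapy:

* ``no_testing`` — every patient starts simvastatin.
* ``testing`` — SLCO1B1 C-allele carriers are switched before
  initiation to an alternative statin (atorvastatin/rosuvastatin split
  by ``switch_to_atorva``); non-carriers start simvastatin.

Genotype-attributable (genetic) myalgia/myopathy risk applies only to
carriers who remain on simvastatin; the background (non-genetic) risks
apply to everyone on a statin.  Myalgia and myopathy are independent
per-patient risks.  Discontinuation probabilities are conditional on
an event and applied to expected event counts.  All internal counts
are fractional expectations; :func:`integer_display` (floor) is
applied only at the reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .parameters import ModelParameters, ValidationError

__all__ = [
    "StrategyOutcome",
    "ComparisonResult",
    "run_strategy",
    "compare",
    "run_comparison",
    "integer_display",
    "STRATEGIES",
    "STATINS",
]

STRATEGIES = ("testing", "no_testing")
STATINS = ("simvastatin", "atorvastatin", "rosuvastatin")


@dataclass(frozen=True)
class StrategyOutcome:
    """Cohort expectations for one strategy arm."""

    strategy: str
    cohort_size: int
    n_assigned: Mapping[str, float]  # statin -> patients at initiation
    events: Mapping[str, float]  # myalgia/myopathy x genetic/nongenetic, expected
    discontinuations: float  # expected count
    costs: Mapping[str, float]  # testing / statin / events / total, USD
    per_patient_cost: float

    @property
    def total_events(self) -> float:
        return sum(self.events.values())

    @property
    def myalgia_total(self) -> float:
        return self.events["myalgia_genetic"] + self.events["myalgia_nongenetic"]

    @property
    def myopathy_total(self) -> float:
        return self.events["myopathy_genetic"] + self.events["myopathy_nongenetic"]


@dataclass(frozen=True)
class ComparisonResult:
    """Testing vs no-testing contrast (reported counts are floored)."""

    averted_myalgia: int
    averted_myopathy: int
    discontinuations_testing: int
    discontinuations_no_testing: int
    incremental_cost_per_patient: float
    cost_per_event_averted: float | None  # None when no events averted

    @property
    def averted_total(self) -> int:
        return self.averted_myalgia + self.averted_myopathy


def integer_display(x: float) -> int:
    """Reporting rule for expected counts: floor to a whole number.

    Flooring (rather than rounding half-up) is the convention used for
    every printed count; internal arithmetic stays fractional.
    """
    if x < 0:
        raise ValidationError(f"integer_display requires x >= 0, got {x}")
    return math.floor(x)


def _assignments(params: ModelParameters, strategy: str) -> dict[str, float]:
    n = params.cohort_size
    if strategy == "no_testing":
        return {"simvastatin": float(n), "atorvastatin": 0.0, "rosuvastatin": 0.0}
    carriers = params.p_carrier * n
    # cohort-level deterministic split; an odd expected carrier count puts
    # the extra patient on atorvastatin
    if params.switch_to_atorva == 0.5 and float(carriers).is_integer():
        to_atorva = math.ceil(carriers / 2.0)
        to_rosuva = carriers - to_atorva
    else:
        to_atorva = params.switch_to_atorva * carriers
        to_rosuva = carriers - to_atorva
    return {
        "simvastatin": n - carriers,
        "atorvastatin": float(to_atorva),
        "rosuvastatin": float(to_rosuva),
    }


def run_strategy(params: ModelParameters, strategy: str) -> StrategyOutcome:
    """Evaluate one strategy as cohort expected values."""
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    n = params.cohort_size
    carriers = params.p_carrier * n
    assigned = _assignments(params, strategy)

    # genetic risk only for carriers still on simvastatin
    carriers_on_simva = carriers if strategy == "no_testing" else 0.0
    events = {
        "myalgia_genetic": carriers_on_simva * params.p_myalgia_gen,
        "myalgia_nongenetic": n * params.p_myalgia_base,
        "myopathy_genetic": carriers_on_simva * params.p_myopathy_gen,
        "myopathy_nongenetic": n * params.p_myopathy_base,
    }
    myalgias = events["myalgia_genetic"] + events["myalgia_nongenetic"]
    myopathies = events["myopathy_genetic"] + events["myopathy_nongenetic"]
    disc = params.p_disc_myalgia * myalgias + params.p_disc_myopathy * myopathies

    statin_cost = (
        assigned["simvastatin"] * params.c_statin_simva
        + assigned["atorvastatin"] * params.c_statin_atorva
        + assigned["rosuvastatin"] * params.c_statin_rosuva
    )
    event_cost = myalgias * params.c_myalgia + myopathies * params.c_myopathy
    test_cost = params.c_test * n if strategy == "testing" else 0.0
    total = test_cost + statin_cost + event_cost
    costs = {"testing": test_cost, "statin": statin_cost, "events": event_cost, "total": total}
    return StrategyOutcome(
        strategy=strategy,
        cohort_size=n,
        n_assigned=assigned,
        events=events,
        discontinuations=disc,
        costs=costs,
        per_patient_cost=total / n if n else 0.0,
    )


def compare(testing: StrategyOutcome, no_testing: StrategyOutcome) -> ComparisonResult:
    """Contrast the two strategy outcomes.

    Averted counts are the genetic events of the no-testing arm minus
    those of the testing arm, floored for display.  The incremental
    cost is per patient; cost per event averted divides the cohort-level
    incremental cost by the (floored) total events averted.
    """
    if testing.cohort_size != no_testing.cohort_size:
        raise ValidationError(
            f"cohort sizes differ: {testing.cohort_size} vs {no_testing.cohort_size}"
        )
    n = testing.cohort_size
    averted_mya = integer_display(
        no_testing.events["myalgia_genetic"] - testing.events["myalgia_genetic"]
    )
    averted_myo = integer_display(
        no_testing.events["myopathy_genetic"] - testing.events["myopathy_genetic"]
    )
    inc = testing.per_patient_cost - no_testing.per_patient_cost
    averted_total = averted_mya + averted_myo
    cpea = inc * n / averted_total if averted_total > 0 else None
    return ComparisonResult(
        averted_myalgia=averted_mya,
        averted_myopathy=averted_myo,
        discontinuations_testing=integer_display(testing.discontinuations),
        discontinuations_no_testing=integer_display(no_testing.discontinuations),
        incremental_cost_per_patient=inc,
        cost_per_event_averted=cpea,
    )


def run_comparison(params: ModelParameters) -> tuple[StrategyOutcome, StrategyOutcome, ComparisonResult]:
    """Run both strategies and compare them (best-case point evaluation)."""
    testing = run_strategy(params, "testing")
    no_testing = run_strategy(params, "no_testing")
    return testing, no_testing, compare(testing, no_testing)
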