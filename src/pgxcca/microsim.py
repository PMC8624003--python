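"""Individual-level Bernoulli microsimulation of the decision tree.

Serves as the brute-force stochastic oracle for the expected-value
engine in :mod:`pgxcca.decision_model`: every patient's carrier status,
statin assignment, muscle events, and discontinuation are drawn as
Bernoulli indicators, so replicate-averaged counts must converge to the
tree's expectations.  Carrier counts are binomial (not fixed at the
expectation) and the 50/50 switch for carriers under testing is
stochastic per patient.

Genotype-attributable risk is additive: a carrier on simvastatin has
event probability ``p_base + p_gen``, and the cause of a realised event
is attributed to the genetic component with conditional probability
``p_gen / (p_base + p_gen)``, so the genetic/non-genetic cells match
the expected-value model's cells in expectation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ValidationError
from .decision_model import STRATEGIES, StrategyOutcome

__all__ = ["simulate_cohort", "simulate_patients"]


def _draw_events(
    rng: np.random.Generator, p_base: float, p_gen: float, genetic_risk: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Event indicator and genetic-cause indicator for one event type.

    ``genetic_risk`` marks patients (carriers on simvastatin) exposed to
    the additional genetic probability.  A single uniform per patient
    yields both the event and its cause attribution.
    """
    n = genetic_risk.shape[0]
    p_g = np.where(genetic_risk, p_gen, 0.0)
    u = rng.random(n)
    event = u < p_base + p_g
    genetic = u < p_g  # a sub-interval of the event region
    return event, genetic


def simulate_patients(
    params: ModelParameters, strategy: str, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one cohort realisation; one row per patient.

    Columns: carrier, statin, myalgia, myalgia_genetic, myopathy,
    myopathy_genetic, discontinued_myalgia, discontinued_myopathy,
    discontinued, cost.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.cohort_size
    carrier = rng.random(n) < params.p_carrier

    statin = np.full(n, "simvastatin", dtype=object)
    if strategy == "testing":
        switch_atorva = rng.random(n) < params.switch_to_atorva
        statin[carrier & switch_atorva] = "atorvastatin"
        statin[carrier & ~switch_atorva] = "rosuvastatin"

    genetic_risk = carrier & (statin == "simvastatin")
    myalgia, myalgia_gen = _draw_events(
        rng, params.p_myalgia_base, params.p_myalgia_gen, genetic_risk
    )
    myopathy, myopathy_gen = _draw_events(
        rng, params.p_myopathy_base, params.p_myopathy_gen, genetic_risk
    )

    # discontinuation is event-conditional; either cause suffices for the
    # patient-level flag, but cause indicators are kept separately because
    # the expected-value engine counts discontinuation *events* (a patient
    # with both events can contribute twice)
    disc_mya = myalgia & (rng.random(n) < params.p_disc_myalgia)
    disc_myo = myopathy & (rng.random(n) < params.p_disc_myopathy)
    discontinued = disc_mya | disc_myo

    statin_price = {
        "simvastatin": params.c_statin_simva,
        "atorvastatin": params.c_statin_atorva,
        "rosuvastatin": params.c_statin_rosuva,
    }
    cost = np.array([statin_price[s] for s in statin], dtype=float)
    cost += myalgia * params.c_myalgia + myopathy * params.c_myopathy
    if strategy == "testing":
        cost += params.c_test

    return pd.DataFrame(
        {
            "carrier": carrier,
            "statin": statin,
            "myalgia": myalgia,
            "myalgia_genetic": myalgia_gen,
            "myopathy": myopathy,
            "myopathy_genetic": myopathy_gen,
            "discontinued_myalgia": disc_mya,
            "discontinued_myopathy": disc_myo,
            "discontinued": discontinued,
            "cost": cost,
        }
    )


def simulate_cohort(
    params: ModelParameters, strategy: str, seed: int | np.random.Generator | None = None
) -> StrategyOutcome:
    """Simulate one cohort and aggregate to a :class:`StrategyOutcome`.

    Counts are realised integers, not expectations.  The discontinuation
    count sums cause indicators (a patient stopping with both events
    contributes twice), mirroring the expected-value engine's
    event-conditional arithmetic; the patient-level ``discontinued``
    flag in :func:`simulate_patients` stays a single boolean.
    """
    df = simulate_patients(params, strategy, seed)
    n = params.cohort_size
    events = {
        "myalgia_genetic": float(df["myalgia_genetic"].sum()),
        "myalgia_nongenetic": float((df["myalgia"] & ~df["myalgia_genetic"]).sum()),
        "myopathy_genetic": float(df["myopathy_genetic"].sum()),
        "myopathy_nongenetic": float((df["myopathy"] & ~df["myopathy_genetic"]).sum()),
    }
    assigned = {
        s: float((df["statin"] == s).sum())
        for s in ("simvastatin", "atorvastatin", "rosuvastatin")
    }
    test_cost = params.c_test * n if strategy == "testing" else 0.0
    statin_price = {
        "simvastatin": params.c_statin_simva,
        "atorvastatin": params.c_statin_atorva,
        "rosuvastatin": params.c_statin_rosuva,
    }
    statin_cost = sum(assigned[s] * statin_price[s] for s in assigned)
    event_cost = (
        float(df["myalgia"].sum()) * params.c_myalgia
        + float(df["myopathy"].sum()) * params.c_myopathy
    )
    total = test_cost + statin_cost + event_cost
    return StrategyOutcome(
        strategy=strategy,
        cohort_size=n,
        n_assigned=assigned,
        events=events,
        # event-count convention: sums cause indicators, matching the
        # expected-value engine's event-conditional arithmetic
        discontinuations=float(df["discontinued_myalgia"].sum() + df["discontinued_myopathy"].sum()),
        costs={"testing": test_cost, "statin": statin_cost, "events": event_cost, "total": total},
        per_patient_cost=total / n if n else 0.0,
    )
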