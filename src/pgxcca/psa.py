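"""Probabilistic sensitivity analysis for the decision tree.

Repeatedly draws a full parameter set from the attached distributions,
re-evaluates both strategies, and summarises the tracked outputs with
min/max, mean, and nearest-rank 2.5th/97.5th percentiles.  A single RNG
stream drives the whole run and parameter draws are consumed in a
fixed (sorted-name) order, so results are reproducible per seed and
adding a tracked output can never perturb the draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import ModelParameters, ValidationError, parameters_digest, sample_parameters
from .decision_model import ComparisonResult, run_comparison

__all__ = ["PSAResult", "run_psa", "summarize_range", "TRACKED_OUTPUTS"]

#: outputs recorded each iteration (event counts use the floor display rule;
#: costs stay fractional)
TRACKED_OUTPUTS = (
    "averted_myalgia",
    "averted_myopathy",
    "averted_total",
    "sams_total_no_testing",
    "sams_total_testing",
    "discontinuations_testing",
    "discontinuations_no_testing",
    "per_patient_cost_testing",
    "per_patient_cost_no_testing",
    "incremental_cost_per_patient",
    "cost_per_event_averted",
)


@dataclass(frozen=True)
class PSAIteration:
    digest: str  # short hash of the sampled parameter set
    params: ModelParameters
    comparison: ComparisonResult
    outputs: dict[str, float | None]


@dataclass(frozen=True)
class PSAResult:
    n_iterations: int
    seed: int | None
    per_iteration: Sequence[PSAIteration]
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    #: iterations with zero events averted, excluded from the
    #: cost-per-event-averted summary
    n_undefined_cpea: int = 0


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: value at rank ceil(q * n), 1-based."""
    n = len(sorted_vals)
    rank = max(1, math.ceil(q * n))
    return float(sorted_vals[rank - 1])


def _summarize(values: list[float]) -> dict[str, float]:
    arr = np.sort(np.asarray(values, dtype=float))
    return {
        "min": float(arr[0]),
        "max": float(arr[-1]),
        "mean": float(arr.mean()),
        "p2.5": _nearest_rank(arr, 0.025),
        "p97.5": _nearest_rank(arr, 0.975),
        "n": int(arr.size),
    }


def run_psa(params: ModelParameters, n_iterations: int = 1000, seed: int | None = None) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Each of ``n_iterations`` iterations draws one parameter set via
    :func:`pgxcca.parameters.sample_parameters`, runs both strategies,
    and records the comparison.  Iterations in which no events are
    averted record an undefined (``None``) cost per event averted;
    those iterations are excluded from that output's summary only, and
    the exclusion count is reported.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    if not params.dist:
        raise ValidationError("PSA requires at least one parameter with a distribution")
    rng = np.random.default_rng(seed)
    iterations: list[PSAIteration] = []
    for _ in range(n_iterations):
        sampled = sample_parameters(params, rng)
        testing, no_testing, cmp_ = run_comparison(sampled)
        outputs: dict[str, float | None] = {
            "averted_myalgia": cmp_.averted_myalgia,
            "averted_myopathy": cmp_.averted_myopathy,
            "averted_total": cmp_.averted_total,
            "sams_total_no_testing": math.floor(no_testing.total_events),
            "sams_total_testing": math.floor(testing.total_events),
            "discontinuations_testing": cmp_.discontinuations_testing,
            "discontinuations_no_testing": cmp_.discontinuations_no_testing,
            "per_patient_cost_testing": testing.per_patient_cost,
            "per_patient_cost_no_testing": no_testing.per_patient_cost,
            "incremental_cost_per_patient": cmp_.incremental_cost_per_patient,
            "cost_per_event_averted": cmp_.cost_per_event_averted,
        }
        iterations.append(
            PSAIteration(
                digest=parameters_digest(sampled),
                params=sampled,
                comparison=cmp_,
                outputs=outputs,
            )
        )
    summaries = {}
    n_undefined = 0
    for name in TRACKED_OUTPUTS:
        vals = [it.outputs[name] for it in iterations]
        defined = [v for v in vals if v is not None]
        if name == "cost_per_event_averted":
            n_undefined = len(vals) - len(defined)
        if defined:
            summaries[name] = _summarize(defined)
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        per_iteration=iterations,
        summaries=summaries,
        n_undefined_cpea=n_undefined,
    )


def summarize_range(result: PSAResult, output_name: str) -> tuple[float, float, float, float, float]:
    """(min, max, mean, p2.5, p97.5) for one tracked output."""
    if output_name not in TRACKED_OUTPUTS:
        raise ValidationError(f"unknown PSA output {output_name!r}")
    s = result.summaries.get(output_name)
    if s is None:
        raise ValidationError(f"output {output_name!r} has no defined iterations")
    return (s["min"], s["max"], s["mean"], s["p2.5"], s["p97.5"])
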