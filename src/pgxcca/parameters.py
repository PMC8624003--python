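"""Model inputs for the 1-month statin decision tree.

Holds every probability and unit cost used by the decision tree, the
sampling distributions attached for probabilistic sensitivity analysis
(PSA), configuration loading/serialization, and CPI-based currency
adjustment.

Calibration
-----------
The published model's appendix inputs are not reproduced in the main
text, so the defaults here are *calibrated reconstructions*: event
probabilities are back-calculated so that the best-case run reproduces
the printed cohort outputs (2560 carriers switched; 109 myalgias and
3 myopathies averted; 403 total muscle events without testing), and
unit costs are solved from the printed per-patient cost identities
(28 USD without testing, 124 USD with testing) under fixed price
ratios (simvastatin : atorvastatin : rosuvastatin = 1 : 3 : 8 and
myopathy = 5 x myalgia management cost).  Supply a config file to
override any of them with true values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ModelParameters",
    "default_parameters",
    "with_default_distributions",
    "load_parameters",
    "serialize_parameters",
    "resolved_parameters_json",
    "adjust_currency",
    "sample_parameters",
    "solve_unit_costs",
    "ConfigError",
    "ValidationError",
]

#: fields interpreted as probabilities (must lie in [0, 1])
_PROB_FIELDS = (
    "p_carrier",
    "p_myalgia_base",
    "p_myopathy_base",
    "p_myalgia_gen",
    "p_myopathy_gen",
    "p_disc_myalgia",
    "p_disc_myopathy",
    "switch_to_atorva",
)

#: fields interpreted as USD amounts (must be >= 0)
_COST_FIELDS = (
    "c_test",
    "c_statin_simva",
    "c_statin_atorva",
    "c_statin_rosuva",
    "c_myalgia",
    "c_myopathy",
)


class ConfigError(ValueError):
    """Raised when a configuration document cannot be parsed or has unknown keys."""


class ValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution attached to one model parameter.

    kind
        ``"fixed"`` (degenerate), ``"beta"`` (shape ``alpha``, ``beta``),
        or ``"triangular"`` (``min`` <= ``mode`` <= ``max``, parameter units).
    """

    kind: str
    value: float | None = None
    alpha: float | None = None
    beta: float | None = None
    min: float | None = None
    mode: float | None = None
    max: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None:
                raise ValidationError("fixed distribution requires 'value'")
        elif self.kind == "beta":
            if self.alpha is None or self.beta is None:
                raise ValidationError("beta distribution requires 'alpha' and 'beta'")
            if self.alpha <= 0 or self.beta <= 0:
                raise ValidationError(
                    f"beta shapes must be positive, got alpha={self.alpha}, beta={self.beta}"
                )
        elif self.kind == "triangular":
            if self.min is None or self.mode is None or self.max is None:
                raise ValidationError("triangular distribution requires 'min', 'mode', 'max'")
            if not (self.min <= self.mode <= self.max):
                raise ValidationError(
                    f"triangular requires min <= mode <= max, got ({self.min}, {self.mode}, {self.max})"
                )
        else:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")

    def support(self) -> tuple[float, float]:
        """Closed interval containing every possible draw."""
        if self.kind == "fixed":
            return (self.value, self.value)  # type: ignore[return-value]
        if self.kind == "beta":
            return (0.0, 1.0)
        return (self.min, self.max)  # type: ignore[return-value]

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)  # type: ignore[arg-type]
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta))
        if self.min == self.max:  # degenerate triangular
            return float(self.min)  # type: ignore[arg-type]
        return float(rng.triangular(self.min, self.mode, self.max))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for k in ("value", "alpha", "beta", "min", "mode", "max"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        known = {"kind", "value", "alpha", "beta", "min", "mode", "max"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown distribution keys: {sorted(unknown)}")
        return cls(**{k: d[k] for k in d})

    @classmethod
    def beta_from_moments(cls, mean: float, sd: float) -> "DistributionSpec":
        """Method-of-moments beta for a probability with given mean and SD."""
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta moment match needs mean in (0,1), got {mean}")
        if sd <= 0:
            raise ValidationError("beta moment match needs sd > 0")
        k = mean * (1.0 - mean) / sd**2 - 1.0
        if k <= 0:
            raise ValidationError(f"sd {sd} too large for mean {mean}")
        return cls(kind="beta", alpha=mean * k, beta=(1.0 - mean) * k)

    @classmethod
    def triangular_pm25(cls, point: float) -> "DistributionSpec":
        """Triangular spread of +/-25% around a point estimate."""
        return cls(kind="triangular", min=0.75 * point, mode=point, max=1.25 * point)


@dataclass(frozen=True)
class ModelParameters:
    """Complete input set for the decision tree.

    Probabilities are on the [0, 1] scale; percentages appear only in
    reports.  ``dist`` optionally maps field names to sampling
    distributions for PSA.
    """

    cohort_size: int = 10_000
    p_carrier: float = 0.256
    p_myalgia_base: float = 291 / 10_000
    p_myopathy_base: float = 0.0
    p_myalgia_gen: float = 109 / 2560
    p_myopathy_gen: float = 3 / 2560
    p_disc_myalgia: float = 0.27
    p_disc_myopathy: float = 0.40
    switch_to_atorva: float = 0.5
    c_test: float = 99.0
    c_statin_simva: float = 0.0
    c_statin_atorva: float = 0.0
    c_statin_rosuva: float = 0.0
    c_myalgia: float = 0.0
    c_myopathy: float = 0.0
    dist: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_size < 0:
            raise ValidationError(f"cohort_size must be >= 0, got {self.cohort_size}")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.p_myalgia_base + self.p_myalgia_gen > 1.0 + 1e-12:
            raise ValidationError("p_myalgia_base + p_myalgia_gen exceeds 1")
        if self.p_myopathy_base + self.p_myopathy_gen > 1.0 + 1e-12:
            raise ValidationError("p_myopathy_base + p_myopathy_gen exceeds 1")
        unknown = set(self.dist) - set(_PROB_FIELDS) - set(_COST_FIELDS)
        if unknown:
            raise ValidationError(f"distributions attached to unknown parameters: {sorted(unknown)}")

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {
            "cohort": {"size": self.cohort_size},
            "probabilities": {
                "carrier": self.p_carrier,
                "myalgia_base": self.p_myalgia_base,
                "myopathy_base": self.p_myopathy_base,
                "myalgia_genetic": self.p_myalgia_gen,
                "myopathy_genetic": self.p_myopathy_gen,
                "disc_myalgia": self.p_disc_myalgia,
                "disc_myopathy": self.p_disc_myopathy,
                "switch_to_atorva": self.switch_to_atorva,
            },
            "costs": {
                "test": self.c_test,
                "statin_simvastatin": self.c_statin_simva,
                "statin_atorvastatin": self.c_statin_atorva,
                "statin_rosuvastatin": self.c_statin_rosuva,
                "myalgia": self.c_myalgia,
                "myopathy": self.c_myopathy,
            },
        }
        if self.dist:
            d["distributions"] = {k: v.to_dict() for k, v in sorted(self.dist.items())}
        return d


# config key -> dataclass field
_KEYMAP = {
    ("cohort", "size"): "cohort_size",
    ("probabilities", "carrier"): "p_carrier",
    ("probabilities", "myalgia_base"): "p_myalgia_base",
    ("probabilities", "myopathy_base"): "p_myopathy_base",
    ("probabilities", "myalgia_genetic"): "p_myalgia_gen",
    ("probabilities", "myopathy_genetic"): "p_myopathy_gen",
    ("probabilities", "disc_myalgia"): "p_disc_myalgia",
    ("probabilities", "disc_myopathy"): "p_disc_myopathy",
    ("probabilities", "switch_to_atorva"): "switch_to_atorva",
    ("costs", "test"): "c_test",
    ("costs", "statin_simvastatin"): "c_statin_simva",
    ("costs", "statin_atorvastatin"): "c_statin_atorva",
    ("costs", "statin_rosuvastatin"): "c_statin_rosuva",
    ("costs", "myalgia"): "c_myalgia",
    ("costs", "myopathy"): "c_myopathy",
}


def solve_unit_costs(
    params: ModelParameters,
    per_patient_no_testing: float = 28.0,
    per_patient_testing: float = 124.0,
    statin_price_ratios: tuple[float, float, float] = (1.0, 3.0, 8.0),
    myopathy_to_myalgia: float = 5.0,
) -> ModelParameters:
    """Solve unit costs from the two per-patient cost identities.

    The two best-case per-patient totals (no-testing and testing) are
    a two-equation system.  With the statin price ratios
    (simva : atorva : rosuva) and the myopathy/myalgia cost ratio held
    fixed, the simvastatin monthly price ``s`` and the myalgia
    management cost ``c`` are the two unknowns:

        s + (E_mya_nt + r_myo * E_myo_nt) / N * c            = target_nt
        c_test + w * s + (E_mya_t + r_myo * E_myo_t) / N * c = target_t

    where ``w`` is the expected statin-price multiple per patient under
    the testing strategy and ``E`` are expected event counts.  Raises
    if the solved costs are not all non-negative.
    """
    p = params
    n = p.cohort_size
    if n == 0:
        raise ValidationError("cannot calibrate costs on an empty cohort")
    carriers = p.p_carrier * n
    r1, r2, r3 = statin_price_ratios
    # expected events, no testing (all on simvastatin)
    mya_nt = n * p.p_myalgia_base + carriers * p.p_myalgia_gen
    myo_nt = n * p.p_myopathy_base + carriers * p.p_myopathy_gen
    # testing: carriers switched off simvastatin -> no genetic events
    mya_t = n * p.p_myalgia_base
    myo_t = n * p.p_myopathy_base
    switch_price = p.switch_to_atorva * r2 + (1.0 - p.switch_to_atorva) * r3
    w = (1.0 - p.p_carrier) * r1 + p.p_carrier * switch_price
    a = np.array(
        [
            [r1, (mya_nt + myopathy_to_myalgia * myo_nt) / n],
            [w, (mya_t + myopathy_to_myalgia * myo_t) / n],
        ]
    )
    b = np.array([per_patient_no_testing, per_patient_testing - p.c_test])
    try:
        s, c = (float(x) for x in np.linalg.solve(a, b))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate calibration
        raise ValidationError(f"cost identities are singular: {exc}") from exc
    if s < 0 or c < 0:
        raise ValidationError(
            f"cost identities have no non-negative solution (simva={s:.2f}, myalgia={c:.2f})"
        )
    return p.replace(
        c_statin_simva=r1 * s,
        c_statin_atorva=r2 * s,
        c_statin_rosuva=r3 * s,
        c_myalgia=c,
        c_myopathy=myopathy_to_myalgia * c,
    )


def default_parameters() -> ModelParameters:
    """Calibrated default inputs for the hypothetical 10,000-veteran cohort.

    Event probabilities are back-calculated from the printed best-case
    outputs; unit costs are solved from the per-patient cost identities
    (see module docstring).  All defaults are reconstructions, not the
    original appendix inputs.
    """
    return solve_unit_costs(ModelParameters())


def with_default_distributions(params: ModelParameters) -> ModelParameters:
    """Attach the default PSA distributions.

    Beta (method-of-moments, SD = 25% of the point estimate) on the
    1-month myalgia/myopathy probabilities; triangular +/-25% on every
    other sampled input (carrier prevalence, discontinuation
    probabilities, test and unit costs).  Parameters whose point
    estimate is zero stay fixed.  The 50/50 switch split and cohort
    size are structural and never sampled.
    """
    dist: dict[str, DistributionSpec] = {}
    for name in ("p_myalgia_base", "p_myopathy_base", "p_myalgia_gen", "p_myopathy_gen"):
        point = getattr(params, name)
        if point > 0:
            dist[name] = DistributionSpec.beta_from_moments(point, 0.25 * point)
        else:
            dist[name] = DistributionSpec(kind="fixed", value=0.0)
    for name in (
        "p_carrier",
        "p_disc_myalgia",
        "p_disc_myopathy",
        "c_test",
        "c_statin_simva",
        "c_statin_atorva",
        "c_statin_rosuva",
        "c_myalgia",
        "c_myopathy",
    ):
        dist[name] = DistributionSpec.triangular_pm25(getattr(params, name))
    return params.replace(dist=dist)


def load_parameters(config_text: str) -> ModelParameters:
    """Parse a YAML/JSON parameter configuration.

    Top-level sections: ``cohort``, ``probabilities``, ``costs``,
    ``distributions``, ``scenario``.  Unspecified fields take the
    calibrated defaults; unknown keys are rejected.  An empty document
    is identical to :func:`default_parameters`.

    The optional ``scenario`` section applies multiplicative factors
    after everything else: ``test_cost_factor`` scales ``c_test`` and
    ``statin_cost_factor`` scales all three statin prices.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration parse failure: {exc}") from exc
    if doc is None:
        return default_parameters()
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration root must be a mapping, got {type(doc).__name__}")
    known_sections = {"cohort", "probabilities", "costs", "distributions", "scenario"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")

    changes: dict = {}
    for section in ("cohort", "probabilities", "costs"):
        sub = doc.get(section) or {}
        if not isinstance(sub, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in sub.items():
            fld = _KEYMAP.get((section, key))
            if fld is None:
                raise ConfigError(f"unknown key {section}.{key}")
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"{section}.{key} must be a number, got {value!r}")
            changes[fld] = value

    # costs absent from the config are solved from the identities, as in the defaults;
    # once any cost is given explicitly, remaining costs fall back to solved defaults.
    base = default_parameters()
    params = base.replace(**changes)

    dists = doc.get("distributions") or {}
    if not isinstance(dists, Mapping):
        raise ConfigError("section 'distributions' must be a mapping")
    field_names = {f.name for f in dataclasses.fields(ModelParameters)}
    spec_map = {}
    for key, spec in dists.items():
        if key not in field_names:
            raise ConfigError(f"distribution attached to unknown parameter {key!r}")
        if not isinstance(spec, Mapping):
            raise ConfigError(f"distributions.{key} must be a mapping")
        spec_map[key] = DistributionSpec.from_dict(spec)
    if spec_map:
        params = params.replace(dist=spec_map)

    scenario = doc.get("scenario") or {}
    if not isinstance(scenario, Mapping):
        raise ConfigError("section 'scenario' must be a mapping")
    unknown = set(scenario) - {"test_cost_factor", "statin_cost_factor"}
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    if "test_cost_factor" in scenario:
        params = params.replace(c_test=params.c_test * float(scenario["test_cost_factor"]))
    if "statin_cost_factor" in scenario:
        f = float(scenario["statin_cost_factor"])
        params = params.replace(
            c_statin_simva=params.c_statin_simva * f,
            c_statin_atorva=params.c_statin_atorva * f,
            c_statin_rosuva=params.c_statin_rosuva * f,
        )
    return params


def serialize_parameters(params: ModelParameters) -> str:
    """Emit a YAML document that :func:`load_parameters` round-trips."""
    return yaml.safe_dump(params.to_dict(), sort_keys=True)


def resolved_parameters_json(params: ModelParameters) -> str:
    """Fully resolved parameter set (defaults + overrides + solved costs) as JSON."""
    return json.dumps(params.to_dict(), indent=2, sort_keys=True)


def adjust_currency(amount_usd: float, cpi_from: float, cpi_to: float) -> float:
    """Re-express a USD amount between price years via CPI index values.

    Returns ``amount_usd * cpi_to / cpi_from``.  Index values are
    user-supplied (e.g. annual CPI-U); no CPI table is bundled.
    """
    if cpi_from <= 0 or cpi_to <= 0:
        raise ValidationError(f"CPI indices must be positive, got {cpi_from}, {cpi_to}")
    return amount_usd * (cpi_to / cpi_from)


_MAX_REJECTION = 1000


def sample_parameters(params: ModelParameters, rng: np.random.Generator | int) -> ModelParameters:
    """Draw one PSA parameter set.

    Each parameter carrying a :class:`DistributionSpec` is replaced by a
    single draw; others are untouched.  Draws are consumed in sorted
    field-name order so the stream layout never depends on dict
    insertion order.  Probability draws outside [0, 1] are resampled
    (rejection), never clamped.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    changes: dict[str, float] = {}
    for name in sorted(params.dist):
        spec = params.dist[name]
        value = spec.draw(rng)
        if name in _PROB_FIELDS:
            tries = 0
            while not 0.0 <= value <= 1.0:
                tries += 1
                if tries > _MAX_REJECTION:
                    raise ValidationError(
                        f"distribution for {name} keeps producing values outside [0, 1]"
                    )
                value = spec.draw(rng)
        changes[name] = value
    # joint constraint: base + genetic probability sums must stay valid
    out = dict(changes)
    for pair in (("p_myalgia_base", "p_myalgia_gen"), ("p_myopathy_base", "p_myopathy_gen")):
        a = out.get(pair[0], getattr(params, pair[0]))
        b = out.get(pair[1], getattr(params, pair[1]))
        tries = 0
        while a + b > 1.0:
            tries += 1
            if tries > _MAX_REJECTION:
                raise ValidationError(f"cannot satisfy {pair[0]} + {pair[1]} <= 1 by resampling")
            if pair[0] in params.dist:
                a = params.dist[pair[0]].draw(rng)
            if pair[1] in params.dist:
                b = params.dist[pair[1]].draw(rng)
            out[pair[0]], out[pair[1]] = a, b
    return params.replace(**out)


def parameters_digest(params: ModelParameters) -> str:
    """Short stable digest of a resolved parameter set (for manifests/PSA rows)."""
    import hashlib

    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
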