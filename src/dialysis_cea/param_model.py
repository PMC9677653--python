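"""Model parameters and probabilistic-sensitivity-analysis distributions.

The cost-utility model compares two strategies for incident end-stage
kidney disease: start on peritoneal dialysis (PD-first) or start on
hemodialysis (HD-first).  Every input — annual transition probabilities,
state costs (2021 USD at a fixed THB/USD rate) and EQ-5D utility weights
— is an :class:`Estimate`: a point value plus a 95% interval and a
distribution family used when sampling for PSA.

Interval-to-distribution inversion uses a symmetric normal approximation:
the implied standard deviation is ``(high - low) / (2 * 1.96)`` and the
beta/gamma parameters are then obtained by method of moments so that the
analytic mean of the sampled distribution equals the point estimate
exactly.  Exponential rows are a one-parameter family and are sampled
with the point estimate as their mean; their printed intervals are kept
for one-way sensitivity analysis only.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Iterator

import numpy as np

logger = logging.getLogger(__name__)

_Z95 = 2.0 * 1.959963984540054  # full width of a 95% normal interval in sd units


class ParameterError(ValueError):
    """Raised when a parameter value or structure violates its contract."""


class HealthState(str, Enum):
    """The five Markov states; DEATH is absorbing."""

    PD = "PD"
    PD_CC = "PD_CC"
    HD = "HD"
    HD_CC = "HD_CC"
    DEATH = "DEATH"


STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.PD,
    HealthState.PD_CC,
    HealthState.HD,
    HealthState.HD_CC,
    HealthState.DEATH,
)
LIVING_STATES: tuple[HealthState, ...] = STATE_ORDER[:4]
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}
DEATH_INDEX = STATE_INDEX[HealthState.DEATH]

#: dialysis modality of each living state
MODALITY: dict[HealthState, str] = {
    HealthState.PD: "PD",
    HealthState.PD_CC: "PD",
    HealthState.HD: "HD",
    HealthState.HD_CC: "HD",
}
#: whether a living state carries chronic complications
IS_CHRONIC: dict[HealthState, bool] = {
    HealthState.PD: False,
    HealthState.PD_CC: True,
    HealthState.HD: False,
    HealthState.HD_CC: True,
}
#: destination of a modality switch (chronic status is retained)
SWITCH_DESTINATION: dict[HealthState, HealthState] = {
    HealthState.PD: HealthState.HD,
    HealthState.PD_CC: HealthState.HD_CC,
    HealthState.HD: HealthState.PD,
    HealthState.HD_CC: HealthState.PD_CC,
}

DISTRIBUTIONS = ("beta", "gamma", "exponential", "uniform", "fixed")


def beta_from_interval(mean: float, low: float, high: float) -> tuple[float, float] | None:
    """Beta parameters (alpha, beta) matching ``mean`` and a 95% interval.

    The standard deviation is taken as ``(high - low) / 3.92``.  Returns
    ``None`` for a degenerate interval (point mass).  Raises
    :class:`ParameterError` when the implied variance is infeasible for a
    beta distribution, i.e. ``var >= mean * (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must be in (0,1), got {mean}")
    if not (0.0 <= low <= mean <= high <= 1.0):
        raise ParameterError(f"require 0 <= low <= mean <= high <= 1, got ({low}, {mean}, {high})")
    sd = (high - low) / _Z95
    if sd == 0.0:
        return None
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"interval ({low}, {high}) implies variance {var:.3g} >= mean(1-mean) "
            f"= {mean * (1 - mean):.3g}; beta distribution infeasible"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_interval(mean: float, low: float, high: float) -> tuple[float, float] | None:
    """Gamma parameters (shape, scale) matching ``mean`` and a 95% interval.

    Same sd convention as :func:`beta_from_interval`; returns ``None`` for a
    degenerate interval.
    """
    if mean <= 0.0:
        raise ParameterError(f"gamma mean must be positive, got {mean}")
    if low > high:
        raise ParameterError(f"low {low} exceeds high {high}")
    sd = (high - low) / _Z95
    if sd == 0.0:
        return None
    var = sd * sd
    return mean * mean / var, var / mean


@dataclass
class Estimate:
    """A point estimate with uncertainty interval and PSA distribution."""

    mean: float
    low: float | None = None
    high: float | None = None
    dist: str = "fixed"

    def __post_init__(self) -> None:
        if self.dist not in DISTRIBUTIONS:
            raise ParameterError(f"unknown distribution {self.dist!r}")
        if self.mean < 0 and self.dist != "fixed":
            raise ParameterError(f"negative mean {self.mean} for {self.dist} estimate")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.mean <= self.high):
                raise ParameterError(
                    f"interval violation: low {self.low} <= mean {self.mean} "
                    f"<= high {self.high} does not hold"
                )
        if self.dist == "beta" and not 0.0 < self.mean < 1.0:
            raise ParameterError(f"beta estimate requires mean in (0,1), got {self.mean}")
        self._cache_dist_params()

    def _cache_dist_params(self) -> None:
        self._params: tuple[float, float] | None = None
        if self.dist in ("beta", "gamma", "uniform") and self.low is not None:
            if self.low == self.high:
                self._params = None
            elif self.dist == "beta":
                self._params = beta_from_interval(self.mean, self.low, self.high)
            elif self.dist == "gamma":
                self._params = gamma_from_interval(self.mean, self.low, self.high)
            else:
                self._params = (self.low, self.high)

    @property
    def bounds(self) -> tuple[float, float]:
        """(low, high) for one-way sensitivity; collapses to the mean if absent."""
        lo = self.mean if self.low is None else self.low
        hi = self.mean if self.high is None else self.high
        return lo, hi

    def analytic_mean(self) -> float:
        """Mean of the sampling distribution (equals ``mean`` by construction)."""
        if self.dist == "fixed" or self._params is None and self.dist != "exponential":
            if self.dist == "uniform" and self._params is not None:
                lo, hi = self._params
                return 0.5 * (lo + hi)
            return self.mean
        if self.dist == "beta":
            a, b = self._params
            return a / (a + b)
        if self.dist == "gamma":
            shape, scale = self._params
            return shape * scale
        if self.dist == "uniform":
            lo, hi = self._params
            return 0.5 * (lo + hi)
        return self.mean  # exponential

    def sample(self, rng: np.random.Generator) -> float:
        """One random draw; degenerate or fixed estimates return the mean."""
        if self.dist == "fixed":
            return self.mean
        if self.dist == "exponential":
            return float(rng.exponential(self.mean))
        if self._params is None:
            return self.mean
        if self.dist == "beta":
            return float(rng.beta(*self._params))
        if self.dist == "gamma":
            shape, scale = self._params
            return float(rng.gamma(shape, scale))
        lo, hi = self._params
        return float(rng.uniform(lo, hi))


def _check_prob(est: Estimate, name: str) -> None:
    if not 0.0 <= est.mean <= 1.0:
        raise ParameterError(f"{name}: probability {est.mean} outside [0,1]")


def _check_nonneg(est: Estimate, name: str) -> None:
    if est.mean < 0:
        raise ParameterError(f"{name}: cost {est.mean} is negative")


@dataclass
class TransitionParameters:
    """Annual transition probabilities for one initial-modality stratum.

    The stratum is the modality the cohort *started* on; its parameters
    cover both current modalities (a switched patient keeps the initial
    stratum's parameters).  ``p_acute`` holds the annual probability of a
    transient acute complication (peritonitis, vascular-access infection)
    per current state; acute events price an add-on cost but cause no
    state change.
    """

    stratum: str
    p_switch: Estimate
    p_pd_to_pd_cc: Estimate
    p_hd_to_hd_cc: Estimate
    p_acute: dict[str, Estimate]

    def validate(self) -> None:
        if self.stratum not in ("PD", "HD"):
            raise ParameterError(f"stratum must be PD or HD, got {self.stratum!r}")
        _check_prob(self.p_switch, f"transitions.{self.stratum}.p_switch")
        _check_prob(self.p_pd_to_pd_cc, f"transitions.{self.stratum}.p_pd_to_pd_cc")
        _check_prob(self.p_hd_to_hd_cc, f"transitions.{self.stratum}.p_hd_to_hd_cc")
        for state in LIVING_STATES:
            if state.value not in self.p_acute:
                raise ParameterError(
                    f"transitions.{self.stratum}.p_acute missing state {state.value}"
                )
            _check_prob(self.p_acute[state.value], f"transitions.{self.stratum}.p_acute.{state.value}")


@dataclass
class CostParameters:
    """State costs in 2021 USD.

    ``setup`` is charged once on entering a modality (dialysis catheter /
    vascular access); annual costs accrue per cycle of state occupancy;
    acute add-ons are expected per-event costs weighted by the acute
    complication probability.
    """

    setup: dict[str, Estimate]
    annual_direct_medical: dict[str, Estimate]
    acute_addon: Estimate
    acute_chronic_addon: Estimate
    annual_direct_nonmedical: dict[str, Estimate]
    annual_indirect: dict[str, Estimate]

    def validate(self) -> None:
        for mod in ("PD", "HD"):
            if mod not in self.setup:
                raise ParameterError(f"costs.setup missing modality {mod}")
            _check_nonneg(self.setup[mod], f"costs.setup.{mod}")
        for group_name in ("annual_direct_medical", "annual_direct_nonmedical", "annual_indirect"):
            group = getattr(self, group_name)
            for state in LIVING_STATES:
                if state.value not in group:
                    raise ParameterError(f"costs.{group_name} missing state {state.value}")
                _check_nonneg(group[state.value], f"costs.{group_name}.{state.value}")
        _check_nonneg(self.acute_addon, "costs.acute_addon")
        _check_nonneg(self.acute_chronic_addon, "costs.acute_chronic_addon")


@dataclass
class UtilityParameters:
    """EQ-5D utility weight per living state (utility/year)."""

    utility: dict[str, Estimate]

    def validate(self, require_ordering: bool = True) -> None:
        for state in LIVING_STATES:
            if state.value not in self.utility:
                raise ParameterError(f"utilities missing state {state.value}")
            u = self.utility[state.value]
            if not 0.0 <= u.mean <= 1.0:
                raise ParameterError(f"utilities.{state.value}: {u.mean} outside [0,1]")
        if require_ordering:
            for mod in ("PD", "HD"):
                if self.utility[f"{mod}_CC"].mean > self.utility[mod].mean:
                    raise ParameterError(
                        f"utilities.{mod}_CC exceeds utilities.{mod}: chronic-state utility "
                        "must not exceed the complication-free utility of the same modality"
                    )


@dataclass
class ModelParameters:
    """Complete parameter payload of the Markov model."""

    transitions: dict[str, TransitionParameters]
    costs: CostParameters
    utilities: UtilityParameters

    def validate(self, require_ordering: bool = True) -> None:
        for stratum in ("PD", "HD"):
            if stratum not in self.transitions:
                raise ParameterError(f"transitions missing stratum {stratum}")
            self.transitions[stratum].validate()
        self.costs.validate()
        self.utilities.validate(require_ordering=require_ordering)

    def iter_estimates(self) -> Iterator[tuple[str, Estimate]]:
        """Yield (dotted-name, Estimate) pairs in a stable order."""
        for stratum in ("PD", "HD"):
            tp = self.transitions[stratum]
            yield f"transitions.{stratum}.p_switch", tp.p_switch
            yield f"transitions.{stratum}.p_pd_to_pd_cc", tp.p_pd_to_pd_cc
            yield f"transitions.{stratum}.p_hd_to_hd_cc", tp.p_hd_to_hd_cc
            for state in LIVING_STATES:
                yield f"transitions.{stratum}.p_acute.{state.value}", tp.p_acute[state.value]
        for mod in ("PD", "HD"):
            yield f"costs.setup.{mod}", self.costs.setup[mod]
        for group in ("annual_direct_medical", "annual_direct_nonmedical", "annual_indirect"):
            for state in LIVING_STATES:
                yield f"costs.{group}.{state.value}", getattr(self.costs, group)[state.value]
        yield "costs.acute_addon", self.costs.acute_addon
        yield "costs.acute_chronic_addon", self.costs.acute_chronic_addon
        for state in LIVING_STATES:
            yield f"utilities.{state.value}", self.utilities.utility[state.value]

    def get_estimate(self, name: str) -> Estimate:
        for n, est in self.iter_estimates():
            if n == name:
                return est
        raise KeyError(name)

    def with_mean(self, name: str, value: float) -> "ModelParameters":
        """A deep copy with one estimate's point value replaced (for tornado).

        The copied estimate collapses to a fixed value: the new point may
        lie outside the original interval, and one-way analysis evaluates
        the deterministic model only.
        """
        out = copy.deepcopy(self)
        for n, est in out.iter_estimates():
            if n == name:
                est.mean = value
                est.low = est.high = None
                est.dist = "fixed"
                est._cache_dist_params()
                return out
        raise KeyError(name)


@dataclass
class AnalysisConfig:
    """Analysis settings: discounting, perspective, horizon, PSA controls."""

    discount_rate: float = 0.03
    perspective: str = "societal"
    start_age: float = 55.7
    age_cap: float = 100.0
    wtp: float = 4766.0
    psa_iterations: int = 5000
    seed: int = 0
    fx_rate: float = 33.57
    half_cycle_correction: bool = False
    setup_cost_on_switch: bool = True
    living_mass_tol: float = 1e-8

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.perspective not in ("government", "societal"):
            raise ParameterError(f"perspective must be government or societal, got {self.perspective!r}")
        if not self.start_age < self.age_cap:
            raise ParameterError(f"start_age {self.start_age} must be below age_cap {self.age_cap}")
        if self.psa_iterations < 1:
            raise ParameterError("psa_iterations must be >= 1")
        if self.fx_rate <= 0:
            raise ParameterError("fx_rate must be positive")


def _sampled(est: Estimate, rng: np.random.Generator) -> Estimate:
    # drawn values may legitimately fall outside the printed interval
    return Estimate(mean=est.sample(rng), dist="fixed")


def sample_parameters(
    params: ModelParameters,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> ModelParameters:
    """One PSA draw: every estimate replaced by a random value, dist 'fixed'.

    Parameters are sampled mutually independently.  A draw that violates a
    structural invariant (currently: chronic-state utility above the
    complication-free utility of the same modality) is rejected and
    redrawn, with the rejection count logged.
    """
    for attempt in range(max_retries):
        draw = ModelParameters(
            transitions={
                stratum: TransitionParameters(
                    stratum=stratum,
                    p_switch=_sampled(tp.p_switch, rng),
                    p_pd_to_pd_cc=_sampled(tp.p_pd_to_pd_cc, rng),
                    p_hd_to_hd_cc=_sampled(tp.p_hd_to_hd_cc, rng),
                    p_acute={s: _sampled(e, rng) for s, e in tp.p_acute.items()},
                )
                for stratum, tp in params.transitions.items()
            },
            costs=CostParameters(
                setup={m: _sampled(e, rng) for m, e in params.costs.setup.items()},
                annual_direct_medical={
                    s: _sampled(e, rng) for s, e in params.costs.annual_direct_medical.items()
                },
                acute_addon=_sampled(params.costs.acute_addon, rng),
                acute_chronic_addon=_sampled(params.costs.acute_chronic_addon, rng),
                annual_direct_nonmedical={
                    s: _sampled(e, rng) for s, e in params.costs.annual_direct_nonmedical.items()
                },
                annual_indirect={
                    s: _sampled(e, rng) for s, e in params.costs.annual_indirect.items()
                },
            ),
            utilities=UtilityParameters(
                utility={s: _sampled(e, rng) for s, e in params.utilities.utility.items()}
            ),
        )
        try:
            draw.validate()
        except ParameterError as exc:
            if attempt == max_retries - 1:
                raise ParameterError(
                    f"could not draw a valid parameter set in {max_retries} attempts: {exc}"
                )
            logger.debug("rejected invalid PSA draw (attempt %d): %s", attempt + 1, exc)
            continue
        if attempt > 0:
            logger.info("PSA draw accepted after %d rejected attempts", attempt)
        return draw
    raise AssertionError("unreachable")
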