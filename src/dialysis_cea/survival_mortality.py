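"""Mortality: Weibull AFT fitting, Kaplan-Meier annual probabilities, and
calibration of a minimal mortality model to published life-year targets.

The per-cycle death probability fed to the Markov engine is the
conditional one-year event probability ``1 - S(t+1|x)/S(t|x)`` of a
Weibull accelerated-failure-time model

    S(t|x) = exp(-(t * exp(-x'beta) / scale)**shape)

so a positive coefficient prolongs survival.  Chronic-complication
states apply a proportional-hazards multiplier ``m >= 1`` to the
conditional probability: ``1 - (S(t+1)/S(t))**m``.

Because source cohorts rarely publish their fitted coefficients, the
module also offers :func:`calibrate_mortality`, which recovers (shape,
scale, age coefficient, chronic multiplier) per strategy stratum from a
table of discounted life expectancies by age at dialysis initiation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, WeibullAFTFitter
from scipy import optimize

logger = logging.getLogger(__name__)


@dataclass
class MortalityModel:
    """Weibull AFT survival model with optional chronic-state multiplier.

    ``coefficients`` are on the log-time-acceleration scale (AFT): the
    linear predictor ``x'beta`` multiplies the time scale by
    ``exp(x'beta)``.  ``age_center`` is subtracted from age before the
    age coefficient is applied, so ``scale`` is the Weibull scale for a
    patient at the reference age.
    """

    shape: float
    scale: float
    coefficients: dict[str, float] = field(default_factory=dict)
    chronic_hazard_multiplier: float = 1.0
    stratum: str | None = None
    age_center: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError(f"shape and scale must be positive, got {self.shape}, {self.scale}")
        if self.chronic_hazard_multiplier < 1.0:
            raise ValueError("chronic_hazard_multiplier must be >= 1")

    def linear_predictor(self, covariables: dict[str, float]) -> float:
        lp = 0.0
        for name, beta in self.coefficients.items():
            if name not in covariables:
                raise KeyError(f"covariable {name!r} required by the mortality model")
            lp += beta * covariables[name]
        return lp

    def survival(self, t: float, covariables: dict[str, float] | None = None) -> float:
        """S(t|x); t in years."""
        if t <= 0:
            return 1.0
        lp = self.linear_predictor(covariables or {})
        return math.exp(-((t * math.exp(-lp) / self.scale) ** self.shape))

    def annual_death_prob(
        self,
        covariables: dict[str, float] | None = None,
        t: int = 0,
        chronic: bool = False,
    ) -> float:
        """Conditional probability of death during cycle [t, t+1)."""
        if t < 0:
            raise ValueError(f"cycle must be >= 0, got {t}")
        s_t = self.survival(float(t), covariables)
        if s_t == 0.0:
            return 1.0
        ratio = self.survival(float(t) + 1.0, covariables) / s_t
        if chronic and self.chronic_hazard_multiplier != 1.0:
            ratio = ratio ** self.chronic_hazard_multiplier
        return min(1.0, max(0.0, 1.0 - ratio))

    def death_prob(self, age: float, t: int, chronic: bool = False) -> float:
        """Engine-facing helper: age enters via the 'age' (and optional
        'age2') coefficients, centred at ``age_center``."""
        covs = {name: 0.0 for name in self.coefficients}
        if "age" in self.coefficients:
            covs["age"] = age - self.age_center
        if "age2" in self.coefficients:
            covs["age2"] = (age - self.age_center) ** 2
        return self.annual_death_prob(covs, t, chronic)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "scale": self.scale,
            "coefficients": dict(self.coefficients),
            "chronic_hazard_multiplier": self.chronic_hazard_multiplier,
            "stratum": self.stratum,
            "age_center": self.age_center,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MortalityModel":
        return cls(**d)


def fit_weibull(
    records: pd.DataFrame,
    covariable_names: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> MortalityModel:
    """Maximum-likelihood Weibull AFT fit on patient-level survival records.

    ``records`` needs a positive ``time`` column, a 0/1 ``event`` column
    and the listed covariable columns.  Returns a
    :class:`MortalityModel` whose ``diagnostics`` carry the lifelines
    summary (coefficient table, standard errors, log-likelihood).
    """
    if records[event_col].sum() < 2:
        raise ValueError("need at least 2 observed events to fit a Weibull model")
    for name in covariable_names:
        if records[name].nunique() < 2:
            raise ValueError(f"covariable {name!r} is constant; drop it before fitting")
    df = records[[time_col, event_col] + list(covariable_names)].copy()
    aft = WeibullAFTFitter()
    aft.fit(df, duration_col=time_col, event_col=event_col)
    params = aft.params_
    scale = float(np.exp(params[("lambda_", "Intercept")]))
    shape = float(np.exp(params[("rho_", "Intercept")]))
    coefficients = {
        name: float(params[("lambda_", name)]) for name in covariable_names
    }
    se = aft.standard_errors_
    diagnostics = {
        "log_likelihood": float(aft.log_likelihood_),
        "n": int(len(df)),
        "n_events": int(df[event_col].sum()),
        "standard_errors": {
            "log_scale": float(se[("lambda_", "Intercept")]),
            "log_shape": float(se[("rho_", "Intercept")]),
            **{name: float(se[("lambda_", name)]) for name in covariable_names},
        },
    }
    return MortalityModel(
        shape=shape, scale=scale, coefficients=coefficients, diagnostics=diagnostics
    )


def km_annual_prob(
    times: np.ndarray,
    events: np.ndarray,
) -> pd.Series:
    """Annual event probabilities from the Kaplan-Meier product-limit curve.

    For each year interval ``[j, j+1)`` returns ``1 - S(j+1)/S(j)``.
    Intervals whose risk set is exhausted are NaN.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if events.sum() < 1:
        raise ValueError("need at least one event for a Kaplan-Meier estimate")
    km = KaplanMeierFitter()
    km.fit(times, events)
    max_year = int(np.ceil(times.max()))
    years = np.arange(max_year + 1, dtype=float)
    surv = km.survival_function_at_times(years).to_numpy()
    probs = {}
    last_risk_time = times.max()
    for j in range(max_year):
        if surv[j] <= 0.0 or j >= last_risk_time:
            probs[j] = np.nan
        else:
            probs[j] = 1.0 - surv[j + 1] / surv[j]
    return pd.Series(probs, name="annual_event_prob")


def _discounted_life_years(
    model: MortalityModel,
    params,
    config,
    strategy: str,
) -> float:
    from .markov_engine import evaluate_strategy  # deferred: avoid circular import

    _, outcome = evaluate_strategy(params, model, config, strategy)
    return outcome.life_years


def calibrate_mortality(
    params,
    targets: dict[float, float],
    strategy: str,
    config_base,
    discounted: bool = True,
    age_center: float = 50.0,
    quadratic_age: bool = True,
) -> MortalityModel:
    """Recover a minimal mortality model from life-expectancy targets.

    Finds (Weibull shape, scale at the reference age, AFT age
    coefficient — plus a quadratic age term by default — and a chronic
    hazard multiplier >= 1) minimising the squared error between the
    Markov model's discounted life-years and ``targets`` (start age ->
    life-years) with the transition parameters held at their point
    estimates.  Multiple starting points guard against local minima;
    residuals per age and the RMS error are stored in ``diagnostics``.
    """
    from dataclasses import replace as dc_replace

    ages = sorted(targets)
    y = np.array([targets[a] for a in ages])

    def model_from(x: np.ndarray) -> MortalityModel:
        coeffs = {"age": x[2]}
        if quadratic_age:
            coeffs["age2"] = x[4]
        return MortalityModel(
            shape=x[0],
            scale=x[1],
            coefficients=coeffs,
            chronic_hazard_multiplier=x[3],
            stratum=strategy,
            age_center=age_center,
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        model = model_from(x)
        out = np.empty(len(ages))
        for k, a in enumerate(ages):
            cfg = dc_replace(
                config_base,
                start_age=float(a),
                discount_rate=config_base.discount_rate if discounted else 0.0,
            )
            out[k] = _discounted_life_years(model, params, cfg, strategy) - y[k]
        return out

    starts = [
        [1.1, 6.0, -0.02, 1.5],
        [1.1, 15.0, -0.05, 3.0],
        [0.8, 4.0, -0.04, 1.2],
        [1.3, 25.0, -0.06, 6.0],
    ]
    lower = [0.2, 0.5, -0.2, 1.0]
    upper = [5.0, 80.0, 0.2, 10.0]
    if quadratic_age:
        starts = [s + [0.0] for s in starts]
        lower = lower + [-0.005]
        upper = upper + [0.005]
    result = None
    for x0 in starts:
        try:
            r = optimize.least_squares(
                residuals,
                np.asarray(x0),
                bounds=(np.asarray(lower), np.asarray(upper)),
                xtol=1e-12,
                ftol=1e-14,
            )
        except Exception as exc:  # keep the best start that worked
            logger.warning("calibration start %s failed: %s", x0, exc)
            continue
        if result is None or r.cost < result.cost:
            result = r
    if result is None:
        raise RuntimeError("mortality calibration failed from every starting point")
    if not result.success:
        logger.warning("mortality calibration did not fully converge: %s", result.message)
    model = model_from(result.x)
    res = residuals(result.x)
    model.diagnostics = {
        "targets": {float(a): float(targets[a]) for a in ages},
        "residuals": {float(a): float(r) for a, r in zip(ages, res)},
        "rms": float(np.sqrt(np.mean(res**2))),
        "converged": bool(result.success),
        "discounted_targets": discounted,
    }
    logger.info(
        "calibrated %s-first mortality: shape=%.4f scale=%.4f coeffs=%s mult=%.4f rms=%.4f",
        strategy,
        model.shape,
        model.scale,
        model.coefficients,
        model.chronic_hazard_multiplier,
        model.diagnostics["rms"],
    )
    return model


def save_mortality(models: dict[str, MortalityModel], path: str | Path) -> None:
    """Serialise calibrated mortality models (one per stratum) to JSON."""
    Path(path).write_text(
        json.dumps({k: m.to_dict() for k, m in models.items()}, indent=2)
    )


def load_mortality(path: str | Path) -> dict[str, MortalityModel]:
    raw = json.loads(Path(path).read_text())
    return {k: MortalityModel.from_dict(v) for k, v in raw.items()}
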