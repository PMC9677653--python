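"""Synthetic patient-level data with the structure the estimators assume.

Emulates a multi-hospital dialysis cohort: covariables with realistic
marginals, treatment assignment confounded with those covariables
through a logit model, Weibull event times with administrative
censoring, gamma-distributed 30-day billing costs, and EQ-5D ordinal
responses whose tariff-scored utilities have known means per
(treatment, complication) cell by construction.  Every quantity the
generator uses is recorded in :func:`truth_report` so recovery tests
can compare estimates against ground truth without re-deriving it.

The covariable marginals are illustrative package constants, loosely
matched to a Thai dialysis population; the purpose of the module is
statistical structure (confounding, censoring, skewed costs, ordinal
utilities), not demographic realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .estimation import EQ5D_DIMENSIONS, Tariff, toy_tariff

RAW_BILLING_LABELS = {
    # 12 representative raw labels -> the eight analysis groups
    "CBC panel": "lab",
    "Blood chemistry": "lab",
    "Dialyzer": "medical_supply",
    "PD solution bag": "medical_supply",
    "Erythropoietin": "medicine",
    "Phosphate binder": "medicine",
    "Catheter placement": "operation",
    "Ward bed-day": "room",
    "Nursing service": "service",
    "Dialysis session fee": "service",
    "Chest film": "xray",
    "Miscellaneous": "other",
}


@dataclass
class GeneratorSpec:
    """Ground-truth configuration of the synthetic cohort.

    Defaults follow the modelled study conditions: a cohort of ~10,000
    dialysis starters with ~18% PD, utility cell means equal to the
    model's utility table (PD 0.731 / HD 0.811 without chronic
    complications, 0.599 / 0.639 with), annual modality-switch
    probabilities 0.039 (PD-first) and 0.0073 (HD-first), and HD
    survival longer than PD.
    """

    n_patients: int = 10_252
    seed: int = 7

    # treatment assignment: logit P(PD) = intercept + age_coef*(age-55) + income_coef*income
    assignment_intercept: float = -1.9
    assignment_age_coef: float = -0.05
    assignment_income_coef: float = 0.25

    # Weibull survival per treatment (scale in years at age 50), AFT age effect
    survival_shape: dict = field(default_factory=lambda: {"PD": 1.15, "HD": 1.25})
    survival_scale: dict = field(default_factory=lambda: {"PD": 6.0, "HD": 8.5})
    survival_age_coef: float = -0.02
    survival_diabetes_coef: float = -0.25
    censoring_years: float = 9.0  # administrative follow-up window

    # annual probabilities of modality switch, by initial modality
    switch_prob: dict = field(default_factory=lambda: {"PD": 0.039, "HD": 0.0073})

    # 30-day direct-medical cost means in THB per (treatment, complication group)
    visit_cost_mean_thb: dict = field(
        default_factory=lambda: {
            ("PD", "none"): 22_000.0,
            ("PD", "chronic"): 26_000.0,
            ("PD", "acute"): 30_000.0,
            ("PD", "chronic_acute"): 36_000.0,
            ("HD", "none"): 25_000.0,
            ("HD", "chronic"): 34_000.0,
            ("HD", "acute"): 33_000.0,
            ("HD", "chronic_acute"): 47_000.0,
        }
    )
    visit_cost_cv: float = 0.5  # coefficient of variation of the gamma costs
    visit_months: int = 24  # billing horizon per patient (30-day windows)
    monthly_acute_prob: dict = field(default_factory=lambda: {"PD": 0.004, "HD": 0.013})

    # true potential-outcome utility means per (treatment, chronic status)
    utility_mean: dict = field(
        default_factory=lambda: {
            ("PD", "none"): 0.731,
            ("PD", "chronic"): 0.599,
            ("HD", "none"): 0.811,
            ("HD", "chronic"): 0.639,
        }
    )
    utility_age_coef: float = -0.006  # confounds utility with assignment via age
    chronic_prob: float = 0.35  # complication status in the utility survey
    chronic_prob_survival: dict = field(default_factory=lambda: {"PD": 0.30, "HD": 0.45})

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for d in (self.switch_prob, self.monthly_acute_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability {v} outside [0,1]")
        for v in self.visit_cost_mean_thb.values():
            if v <= 0:
                raise ValueError("visit cost means must be positive")


@dataclass
class SyntheticCohort:
    """The three patient-level tables the estimation stages consume."""

    survival: pd.DataFrame
    visits: pd.DataFrame
    eq5d: pd.DataFrame


def _draw_covariables(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    age = np.clip(rng.normal(55.0, 13.0, n), 25.0, 80.0)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "sex": rng.binomial(1, 0.45, n),  # 1 = female
            "education": rng.integers(0, 3, n),
            "income": rng.integers(0, 3, n),
            "region": rng.integers(0, 4, n),
            "reimbursement": rng.integers(0, 3, n),
            "fracture": rng.binomial(1, 0.05, n),
            "diabetes": rng.binomial(1, 0.40, n),
            "hypertension": rng.binomial(1, 0.70, n),
            "dyslipidaemia": rng.binomial(1, 0.35, n),
            "cardiovascular": rng.binomial(1, 0.20, n),
        }
    )


def _assign_treatment(
    cov: pd.DataFrame, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    lp = (
        spec.assignment_intercept
        + spec.assignment_age_coef * (cov["age"].to_numpy() - 55.0)
        + spec.assignment_income_coef * cov["income"].to_numpy()
    )
    p_pd = 1.0 / (1.0 + np.exp(-lp))
    return np.where(rng.random(len(cov)) < p_pd, "PD", "HD")


def _weibull_times(
    spec: GeneratorSpec,
    treatment: np.ndarray,
    cov: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(cov)
    shape = np.where(treatment == "PD", spec.survival_shape["PD"], spec.survival_shape["HD"])
    scale0 = np.where(treatment == "PD", spec.survival_scale["PD"], spec.survival_scale["HD"])
    lp = spec.survival_age_coef * (cov["age"].to_numpy() - 50.0)
    lp = lp + spec.survival_diabetes_coef * cov["diabetes"].to_numpy()
    scale = scale0 * np.exp(lp)
    u = rng.random(n)
    return scale * (-np.log(u)) ** (1.0 / shape)


def _eq5d_profiles(
    target_utility: np.ndarray, tariff: Tariff, rng: np.random.Generator
) -> pd.DataFrame:
    """Ordinal profiles whose tariff score equals the target in expectation.

    The total target deficit ``1 - u`` is split equally over the five
    dimensions; each dimension draws level 2 or level 3 with
    probabilities solved so the expected decrement matches its share
    (half of the share through each level's decrement).
    """
    levels = {dim: sorted(tariff.levels(dim)) for dim in EQ5D_DIMENSIONS}
    for dim, lv in levels.items():
        if lv[:1] != [1] or len(lv) < 3:
            raise ValueError("profile generation expects tariff levels 1..3 per dimension")
    lo = tariff.min_score()
    if np.any(target_utility < lo) or np.any(target_utility > tariff.constant):
        raise ValueError(
            f"target utilities outside the tariff's reachable range [{lo}, {tariff.constant}]"
        )
    n = len(target_utility)
    deficit_per_dim = (tariff.constant - target_utility) / len(EQ5D_DIMENSIONS)
    out = {}
    for dim in EQ5D_DIMENSIONS:
        d2 = tariff.decrements[(dim, 2)]
        d3 = tariff.decrements[(dim, 3)]
        p3 = 0.5 * deficit_per_dim / d3
        p2 = 0.5 * deficit_per_dim / d2
        if np.any(p2 + p3 > 1.0):
            raise ValueError("target utility too low for the equal-split level scheme")
        u = rng.random(n)
        level = np.ones(n, dtype=int)
        level[u < p3] = 3
        level[(u >= p3) & (u < p3 + p2)] = 2
        out[dim] = level
    return pd.DataFrame(out)


def generate_cohort(spec: GeneratorSpec, tariff: Tariff | None = None) -> SyntheticCohort:
    """Draw the full synthetic cohort (survival, billing, EQ-5D tables).

    Deterministic given ``spec`` (including its seed).
    """
    spec.validate()
    tariff = tariff or toy_tariff()
    rng = np.random.default_rng(spec.seed)
    if spec.n_patients == 0:
        empty = pd.DataFrame()
        return SyntheticCohort(empty, empty, empty)

    cov = _draw_covariables(spec, rng)
    treatment = _assign_treatment(cov, spec, rng)
    death_time = _weibull_times(spec, treatment, cov, rng)
    censor_time = rng.uniform(1.0, spec.censoring_years, spec.n_patients)
    time = np.minimum(death_time, censor_time)
    event = (death_time <= censor_time).astype(int)

    # modality-switch process: exponential with the annual-probability hazard
    switch_rate = np.where(
        treatment == "PD",
        -np.log1p(-spec.switch_prob["PD"]),
        -np.log1p(-spec.switch_prob["HD"]),
    )
    switch_latent = rng.exponential(1.0 / switch_rate)
    switch_event = (switch_latent <= time).astype(int)
    switch_time = np.minimum(switch_latent, time)

    chronic_surv = rng.random(spec.n_patients) < np.where(
        treatment == "PD",
        spec.chronic_prob_survival["PD"],
        spec.chronic_prob_survival["HD"],
    )

    survival = cov.copy()
    survival["initial_modality"] = treatment
    survival["chronic"] = chronic_surv.astype(int)
    survival["time"] = time
    survival["event"] = event
    survival["switch_time"] = switch_time
    survival["switch_event"] = switch_event

    # ------------------------------------------------ billing visits ----
    labels = np.array(list(RAW_BILLING_LABELS))
    months = np.minimum(spec.visit_months, np.ceil(time * 12.0).astype(int))
    rows = []
    start = pd.Timestamp("2015-01-01")
    cv2 = spec.visit_cost_cv**2
    for i in range(spec.n_patients):
        m = months[i]
        if m == 0:
            continue
        t = treatment[i]
        chronic = bool(chronic_surv[i])
        acute = rng.random(m) < spec.monthly_acute_prob[t]
        for j in range(m):
            group = ("chronic_" if chronic else "") + ("acute" if acute[j] else "")
            group = group or "none"
            group = {"chronic_": "chronic"}.get(group, group)
            mean = spec.visit_cost_mean_thb[(t, group)]
            amount = rng.gamma(1.0 / cv2, mean * cv2)
            rows.append(
                (
                    i,
                    start + pd.Timedelta(days=int(i % 28) + 30 * j),
                    labels[rng.integers(0, len(labels))],
                    amount,
                    t,
                    bool(acute[j]),
                    chronic,
                )
            )
    visits = pd.DataFrame(
        rows,
        columns=["patient_id", "date", "category", "amount_thb", "treatment", "acute", "chronic"],
    )

    # ------------------------------------------------ EQ-5D survey ----
    chronic_eq = rng.random(spec.n_patients) < spec.chronic_prob
    cell = np.array(
        [
            spec.utility_mean[(t, "chronic" if c else "none")]
            for t, c in zip(treatment, chronic_eq)
        ]
    )
    target = cell + spec.utility_age_coef * (cov["age"].to_numpy() - 55.0)
    profiles = _eq5d_profiles(target, tariff, rng)
    eq5d = pd.concat([cov.reset_index(drop=True), profiles], axis=1)
    eq5d["treatment"] = treatment
    eq5d["chronic"] = chronic_eq.astype(int)

    return SyntheticCohort(survival=survival, visits=visits, eq5d=eq5d)


def truth_report(spec: GeneratorSpec) -> dict:
    """Machine-readable ground truth for recovery tests.

    Includes the spec fields verbatim plus derived quantities: the
    implied annual death probabilities per treatment for the first
    cycles (Weibull closed form at the reference age) and the implied
    switch hazards.  Serialises losslessly to JSON.
    """
    spec.validate()

    def annual_probs(shape: float, scale: float, n_years: int = 5) -> list[float]:
        def S(t: float) -> float:
            return float(np.exp(-((t / scale) ** shape)))

        return [1.0 - S(t + 1.0) / S(t) for t in range(n_years)]

    report = {
        "spec": {
            k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in asdict(spec).items()
        },
        "implied": {
            "annual_death_prob": {
                t: annual_probs(spec.survival_shape[t], spec.survival_scale[t])
                for t in ("PD", "HD")
            },
            "switch_hazard": {
                t: -float(np.log1p(-p)) for t, p in spec.switch_prob.items()
            },
            "expected_pd_fraction_at_mean_covariables": float(
                1.0 / (1.0 + np.exp(-(spec.assignment_intercept + spec.assignment_income_coef * 1.0)))
            ),
        },
    }
    return report


def spec_from_report(report: dict) -> GeneratorSpec:
    """Rebuild a :class:`GeneratorSpec` from a serialised truth report."""
    import ast

    raw = dict(report["spec"])

    def tuplify(d: dict) -> dict:
        out = {}
        for k, v in d.items():
            key = ast.literal_eval(k) if k.startswith("(") else k  # keys serialised via str()
            out[key] = v
        return out

    for name in ("visit_cost_mean_thb", "utility_mean"):
        raw[name] = tuplify(raw[name])
    return GeneratorSpec(**raw)
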