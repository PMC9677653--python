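"""Parameter estimation from patient-level data.

Four procedures feed the Markov model's parameter table:

* :func:`aggregate_direct_medical` — six-step aggregation of hospital
  billing records into per-30-day direct-medical cost summaries by
  treatment and complication group, inflation-adjusted and converted to
  USD;
* :func:`unit_cost_nonmedical` — median/IQR unit costing of direct
  non-medical and indirect (productivity-loss) survey costs;
* :func:`score_eq5d` — additive tariff scoring of EQ-5D profiles;
* :func:`ipwra_utility` — inverse-probability-weighted regression
  adjustment (doubly robust) estimation of potential-outcome mean
  utilities by treatment and complication status, correcting for the
  non-random assignment of dialysis modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

COST_GROUPS_8 = (
    "lab",
    "medical_supply",
    "medicine",
    "operation",
    "room",
    "service",
    "xray",
    "other",
)


# ------------------------------------------------------------- costs ----


def aggregate_direct_medical(
    visits: pd.DataFrame,
    category_map: dict[str, str],
    inflation_series: dict[int, float],
    fx: float,
    base_year: int = 2021,
    window_days: int = 30,
) -> pd.DataFrame:
    """Six-step direct-medical cost aggregation.

    Steps: (1) re-categorise raw billing labels into the eight cost
    groups; (2) aggregate each patient's visits into non-overlapping
    30-day observations anchored at the patient's first visit; (3) pool
    patients into one cohort; (4) adjust each amount to ``base_year``
    THB by the inflation index ratio; (5) classify observations into the
    eight (treatment × {none, chronic, acute, chronic+acute}) outcome
    groups; (6) summarise per group (mean, sd, median, IQR per
    observation) and convert to USD at ``fx`` THB/USD.

    ``visits`` columns: patient_id, date, category, amount_thb,
    treatment, acute, chronic.  Unmapped categories and missing
    inflation years raise with the offending labels listed.
    """
    required = {"patient_id", "date", "category", "amount_thb", "treatment", "acute", "chronic"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visits frame missing columns: {sorted(missing)}")
    df = visits.copy()
    unmapped = sorted(set(df["category"]) - set(category_map))
    if unmapped:
        raise ValueError(f"unmapped billing categories: {unmapped}")
    df["cost_group"] = df["category"].map(category_map)
    bad_groups = sorted(set(df["cost_group"]) - set(COST_GROUPS_8))
    if bad_groups:
        raise ValueError(f"category map targets outside the eight groups: {bad_groups}")

    df["date"] = pd.to_datetime(df["date"])
    years = df["date"].dt.year
    missing_years = sorted(set(years) - set(inflation_series))
    if missing_years or base_year not in inflation_series:
        raise ValueError(
            f"inflation series missing years: {sorted(set(missing_years) | ({base_year} - set(inflation_series)))}"
        )
    # step 4 applied per visit before summation: index ratio to the base year
    factor = years.map(lambda y: inflation_series[base_year] / inflation_series[y])
    df["amount_adj"] = df["amount_thb"] * factor

    # step 2: non-overlapping windows anchored at each patient's first visit
    first = df.groupby("patient_id")["date"].transform("min")
    df["window"] = ((df["date"] - first).dt.days // window_days).astype(int)

    obs = (
        df.groupby(["patient_id", "window"])
        .agg(
            amount_thb=("amount_adj", "sum"),
            treatment=("treatment", "first"),
            acute=("acute", "any"),
            chronic=("chronic", "any"),
        )
        .reset_index()
    )
    obs["complication_group"] = np.select(
        [
            obs["chronic"] & obs["acute"],
            obs["chronic"] & ~obs["acute"],
            ~obs["chronic"] & obs["acute"],
        ],
        ["chronic_acute", "chronic", "acute"],
        default="none",
    )
    obs["amount_usd"] = obs["amount_thb"] / fx

    summary = (
        obs.groupby(["treatment", "complication_group"])["amount_usd"]
        .agg(
            n="count",
            mean="mean",
            sd="std",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            total="sum",
        )
        .reset_index()
    )
    summary.attrs["total_usd"] = float(obs["amount_usd"].sum())
    summary.attrs["total_thb_adjusted"] = float(obs["amount_thb"].sum())
    return summary


def unit_cost_nonmedical(costs_per_visit, n_visits: float) -> dict:
    """Median/IQR unit cost per visit and implied total.

    ``total = median * n_visits`` (use hospital days for admissions).
    """
    arr = np.asarray(list(costs_per_visit), dtype=float)
    if arr.size == 0:
        raise ValueError("no cost records supplied")
    median = float(np.median(arr))
    return {
        "median": median,
        "q1": float(np.quantile(arr, 0.25)),
        "q3": float(np.quantile(arr, 0.75)),
        "n_records": int(arr.size),
        "total": median * n_visits,
    }


# ----------------------------------------------------------- utility ----


@dataclass
class Tariff:
    """Additive EQ-5D value set: utility = constant − Σ decrements.

    ``decrements[(dimension, level)]`` gives the decrement for scoring a
    dimension at a level; level 1 ("no problems") must decrement 0 so a
    full-health profile scores ``constant`` (1.0 for standard tariffs).
    """

    constant: float
    decrements: dict[tuple[str, int], float]

    def levels(self, dimension: str) -> list[int]:
        return sorted(l for (d, l) in self.decrements if d == dimension)

    def score(self, profile: dict[str, int]) -> float:
        total = self.constant
        for dim in EQ5D_DIMENSIONS:
            if dim not in profile:
                raise ValueError(f"profile missing dimension {dim!r}")
            key = (dim, int(profile[dim]))
            if key not in self.decrements:
                raise ValueError(
                    f"level {profile[dim]} outside tariff range for dimension {dim!r}"
                )
            total -= self.decrements[key]
        return total

    @classmethod
    def from_csv(cls, path: str | Path) -> "Tariff":
        """Load a tariff CSV with columns dimension, level, decrement.

        A row with dimension ``constant`` supplies the additive constant.
        """
        df = pd.read_csv(path)
        const_rows = df[df["dimension"] == "constant"]
        constant = float(const_rows["decrement"].iloc[0]) if len(const_rows) else 1.0
        dec = {
            (str(r.dimension), int(r.level)): float(r.decrement)
            for r in df[df["dimension"] != "constant"].itertuples()
        }
        return cls(constant=constant, decrements=dec)

    def min_score(self) -> float:
        out = self.constant
        for dim in EQ5D_DIMENSIONS:
            out -= max(self.decrements[(dim, l)] for l in self.levels(dim))
        return out


def toy_tariff() -> Tariff:
    """Three-level additive test tariff: decrements 0 / 0.1 / 0.3."""
    dec = {}
    for dim in EQ5D_DIMENSIONS:
        dec[(dim, 1)] = 0.0
        dec[(dim, 2)] = 0.1
        dec[(dim, 3)] = 0.3
    return Tariff(constant=1.0, decrements=dec)


def score_eq5d(response: dict[str, int] | pd.Series, tariff: Tariff) -> float:
    """Utility score of one EQ-5D response under an additive tariff."""
    if isinstance(response, pd.Series):
        response = response.to_dict()
    return tariff.score(response)


def score_eq5d_frame(responses: pd.DataFrame, tariff: Tariff) -> pd.Series:
    """Vectorised scoring of a frame holding the five dimension columns."""
    score = pd.Series(np.full(len(responses), tariff.constant), index=responses.index)
    for dim in EQ5D_DIMENSIONS:
        levels = responses[dim].astype(int)
        valid = set(tariff.levels(dim))
        bad = set(levels.unique()) - valid
        if bad:
            raise ValueError(f"levels {sorted(bad)} outside tariff range for {dim!r}")
        dec_map = {l: tariff.decrements[(dim, l)] for l in valid}
        score -= levels.map(dec_map)
    return score.rename("utility")


# ------------------------------------------------------------- IPWRA ----

PROPENSITY_COVARIABLES = (
    "age",
    "education",
    "income",
    "region",
    "reimbursement",
    "fracture",
    "diabetes",
    "hypertension",
    "dyslipidaemia",
    "cardiovascular",
)
OUTCOME_COVARIABLES = ("age", "sex", "income", "region", "fracture", "chronic")


@dataclass
class UtilityEstimate:
    """Potential-outcome mean utilities by treatment and complication status."""

    means: dict[tuple[str, str], float]
    standard_errors: dict[tuple[str, str], float] = field(default_factory=dict)
    naive_means: dict[tuple[str, str], float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _fit_ipwra(
    df: pd.DataFrame,
    propensity_covariables: list[str],
    outcome_covariables: list[str],
    eps: float,
) -> tuple[dict[tuple[str, str], float], dict]:
    """One IPWRA pass; returns potential-outcome means and diagnostics."""
    t_pd = (df["treatment"] == "PD").astype(float).to_numpy()
    X_prop = sm.add_constant(df[list(propensity_covariables)].astype(float))
    logit = sm.Logit(t_pd, X_prop).fit(disp=0)
    p_pd = np.asarray(logit.predict(X_prop))
    n_trunc = int(((p_pd < eps) | (p_pd > 1 - eps)).sum())
    if n_trunc:
        logger.warning(
            "truncating %d propensity scores outside (%g, %g)", n_trunc, eps, 1 - eps
        )
    p_pd = np.clip(p_pd, eps, 1 - eps)

    X_out = sm.add_constant(df[list(outcome_covariables)].astype(float))
    y = df["utility"].to_numpy()
    means: dict[tuple[str, str], float] = {}
    for treatment in ("PD", "HD"):
        in_group = df["treatment"] == treatment
        w = np.where(t_pd == 1, 1.0 / p_pd, 1.0 / (1.0 - p_pd))[in_group]
        model = sm.WLS(y[in_group.to_numpy()], X_out[in_group.to_numpy()], weights=w).fit()
        pred = np.asarray(model.predict(X_out))  # predict counterfactual for everyone
        means[(treatment, "overall")] = float(pred.mean())
        chronic = df["chronic"].astype(bool).to_numpy()
        means[(treatment, "chronic")] = float(pred[chronic].mean())
        means[(treatment, "none")] = float(pred[~chronic].mean())
    diagnostics = {
        "propensity_range": (float(p_pd.min()), float(p_pd.max())),
        "n_truncated": n_trunc,
        "propensity_converged": bool(logit.mle_retvals.get("converged", True)),
    }
    return means, diagnostics


def ipwra_utility(
    responses: pd.DataFrame,
    tariff: Tariff,
    propensity_covariables: list[str] = PROPENSITY_COVARIABLES,
    outcome_covariables: list[str] = OUTCOME_COVARIABLES,
    eps: float = 0.01,
    n_boot: int = 100,
    seed: int = 0,
) -> UtilityEstimate:
    """Doubly robust utility estimation by treatment and complication status.

    Three steps: (i) logit propensity of PD assignment on the listed
    covariables; (ii) per-treatment linear outcome model weighted by
    inverse assignment probability (truncated to ``(eps, 1-eps)``);
    (iii) potential-outcome means as the average counterfactual
    prediction over the whole sample, overall and within chronic /
    complication-free subgroups.  Standard errors are nonparametric
    bootstrap over patients (``n_boot`` replicates).
    """
    for treatment in ("PD", "HD"):
        if (responses["treatment"] == treatment).sum() == 0:
            raise ValueError(f"no {treatment} patients in the sample")
    df = responses.copy()
    dim_cols = [d for d in EQ5D_DIMENSIONS if d in df.columns]
    n_missing = int(df[dim_cols].isna().any(axis=1).sum()) if dim_cols else 0
    if n_missing:
        logger.info("excluding %d responses with missing EQ-5D dimensions", n_missing)
        df = df.dropna(subset=dim_cols)
    if "utility" not in df.columns:
        df["utility"] = score_eq5d_frame(df[list(EQ5D_DIMENSIONS)], tariff)

    means, diagnostics = _fit_ipwra(df, propensity_covariables, outcome_covariables, eps)

    naive = {}
    for treatment in ("PD", "HD"):
        grp = df[df["treatment"] == treatment]
        naive[(treatment, "overall")] = float(grp["utility"].mean())
        naive[(treatment, "chronic")] = float(grp.loc[grp["chronic"].astype(bool), "utility"].mean())
        naive[(treatment, "none")] = float(grp.loc[~grp["chronic"].astype(bool), "utility"].mean())

    ses: dict[tuple[str, str], float] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        samples: dict[tuple[str, str], list[float]] = {k: [] for k in means}
        n = len(df)
        for _ in range(n_boot):
            boot = df.iloc[rng.integers(0, n, size=n)].reset_index(drop=True)
            try:
                m, _ = _fit_ipwra(boot, propensity_covariables, outcome_covariables, eps)
            except Exception:  # rare degenerate resample
                continue
            for k, v in m.items():
                samples[k].append(v)
        ses = {k: float(np.std(v, ddof=1)) for k, v in samples.items() if len(v) > 1}
        diagnostics["n_boot_effective"] = len(next(iter(samples.values())))

    return UtilityEstimate(
        means=means, standard_errors=ses, naive_means=naive, diagnostics=diagnostics
    )
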