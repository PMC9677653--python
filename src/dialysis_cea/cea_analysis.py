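"""Economic-evaluation layer: ICER, deterministic tables, tornado, PSA, CEAC.

All comparisons take PD-first as the reference strategy and HD-first as
the alternative, so a positive ICER is the extra cost per QALY gained by
starting patients on hemodialysis.  Probabilistic sensitivity analysis
draws every parameter independently from its distribution, re-runs both
strategies, and summarises the cloud of (Δcost, ΔQALY) pairs; the
cost-effectiveness acceptability curve reports, at each
willingness-to-pay λ, the fraction of draws in which each strategy has
the larger net monetary benefit λ·QALY − cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov_engine import evaluate_strategy
from .param_model import (
    AnalysisConfig,
    ModelParameters,
    ParameterError,
    sample_parameters,
)
from .survival_mortality import MortalityModel

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class ICERResult:
    """Incremental cost-effectiveness of the alternative vs the reference."""

    delta_cost: float
    delta_qaly: float
    value: float | None
    label: str  # "icer", "dominant", "dominated" or "undefined"

    def __float__(self) -> float:
        return float("nan") if self.value is None else self.value


def icer(cost_ref: float, qaly_ref: float, cost_alt: float, qaly_alt: float) -> ICERResult:
    """Δcost/ΔQALY of the alternative strategy against the reference.

    The alternative is *dominant* if strictly cheaper and strictly more
    effective, *dominated* if strictly dearer and strictly less
    effective.  ΔQALY of exactly zero yields an undefined ICER (Δcost is
    still reported).
    """
    for v in (cost_ref, qaly_ref, cost_alt, qaly_alt):
        if not np.isfinite(v):
            raise ParameterError("ICER inputs must be finite")
    d_cost = cost_alt - cost_ref
    d_qaly = qaly_alt - qaly_ref
    if d_qaly == 0.0:
        return ICERResult(d_cost, d_qaly, None, UNDEFINED)
    if d_cost < 0.0 and d_qaly > 0.0:
        return ICERResult(d_cost, d_qaly, d_cost / d_qaly, DOMINANT)
    if d_cost > 0.0 and d_qaly < 0.0:
        return ICERResult(d_cost, d_qaly, d_cost / d_qaly, DOMINATED)
    return ICERResult(d_cost, d_qaly, d_cost / d_qaly, "icer")


def _run_pair(
    params: ModelParameters,
    mortality: dict[str, MortalityModel],
    config: AnalysisConfig,
) -> dict[str, tuple[float, float, float]]:
    """(cost, ly, qaly) per strategy with its stratum-specific mortality."""
    out = {}
    for strategy in ("PD", "HD"):
        _, o = evaluate_strategy(params, mortality[strategy], config, strategy)
        out[strategy] = (o.lifetime_cost, o.life_years, o.qalys)
    return out


def deterministic_table(
    params: ModelParameters,
    mortality: dict[str, MortalityModel],
    config: AnalysisConfig,
    ages: list[float] = (20.0, 30.0, 40.0, 50.0, 60.0),
    perspectives: list[str] = ("government", "societal"),
) -> pd.DataFrame:
    """Deterministic results by age at initiation and perspective.

    One row per (perspective, age) with lifetime cost, LY, QALY and cost
    per life-year for each strategy, plus the HD-vs-PD ICER.
    """
    rows = []
    for perspective in perspectives:
        for age in ages:
            cfg = replace(config, perspective=perspective, start_age=float(age))
            res = _run_pair(params, mortality, cfg)
            (c_pd, ly_pd, q_pd), (c_hd, ly_hd, q_hd) = res["PD"], res["HD"]
            ic = icer(c_pd, q_pd, c_hd, q_hd)
            rows.append(
                {
                    "perspective": perspective,
                    "age": age,
                    "ly_pd": ly_pd,
                    "ly_hd": ly_hd,
                    "qaly_pd": q_pd,
                    "qaly_hd": q_hd,
                    "cost_pd": c_pd,
                    "cost_hd": c_hd,
                    "cost_per_ly_pd": c_pd / ly_pd,
                    "cost_per_ly_hd": c_hd / ly_hd,
                    "icer": ic.value if ic.value is not None else np.nan,
                    "icer_label": ic.label,
                }
            )
    return pd.DataFrame(rows)


def tornado(
    params: ModelParameters,
    mortality: dict[str, MortalityModel],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """One-way sensitivity analysis of the ICER.

    Each parameter in turn is set to its low then high bound (95%
    interval; ±10% for setup costs) with everything else at base; the
    two resulting ICERs and their span are recorded, sorted by
    descending span.  Bounds yielding an undefined ICER flag the entry
    and exclude it from the ranking.
    """
    base = _run_pair(params, mortality, config)
    base_icer = icer(*base["PD"][::2], *base["HD"][::2])
    rows = []
    for name, est in params.iter_estimates():
        lo, hi = est.bounds
        if lo == hi == est.mean:
            rows.append(
                {
                    "parameter": name,
                    "icer_at_low": base_icer.value,
                    "icer_at_high": base_icer.value,
                    "span": 0.0,
                    "defined": True,
                }
            )
            continue
        icers = []
        defined = True
        for bound in (lo, hi):
            res = _run_pair(params.with_mean(name, bound), mortality, config)
            ic = icer(*res["PD"][::2], *res["HD"][::2])
            if ic.value is None:
                defined = False
                icers.append(np.nan)
            else:
                icers.append(ic.value)
        span = abs(icers[1] - icers[0]) if defined else np.nan
        if defined and not (
            min(icers) <= base_icer.value <= max(icers)
        ):
            logger.info(
                "tornado: base ICER %.1f outside [%0.1f, %0.1f] for %s "
                "(non-monotone response)",
                base_icer.value,
                min(icers),
                max(icers),
                name,
            )
        rows.append(
            {
                "parameter": name,
                "icer_at_low": icers[0],
                "icer_at_high": icers[1],
                "span": span,
                "defined": defined,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["defined", "span"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["base_icer"] = base_icer.value
    return df


@dataclass
class PSAResult:
    """Per-iteration strategy outcomes of the probabilistic analysis."""

    costs: np.ndarray  # (n, 2): columns PD, HD
    qalys: np.ndarray  # (n, 2)
    seed: int
    perspective: str
    start_age: float
    n_resampled: int = 0

    @property
    def n(self) -> int:
        return self.costs.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[:, 1] - self.costs[:, 0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qalys[:, 1] - self.qalys[:, 0]

    def summary(self) -> dict:
        return {
            "iterations": self.n,
            "mean_cost_pd": float(self.costs[:, 0].mean()),
            "mean_cost_hd": float(self.costs[:, 1].mean()),
            "mean_cost_diff": float(self.delta_cost.mean()),
            "mean_qaly_pd": float(self.qalys[:, 0].mean()),
            "mean_qaly_hd": float(self.qalys[:, 1].mean()),
            "mean_qaly_diff": float(self.delta_qaly.mean()),
            "seed": self.seed,
            "perspective": self.perspective,
            "start_age": self.start_age,
            "n_resampled": self.n_resampled,
        }

    def bootstrap_se(self, n_boot: int = 500, seed: int = 0) -> dict:
        """Bootstrap Monte-Carlo standard errors of the summary means."""
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.n, size=(n_boot, self.n))
        return {
            "se_mean_cost_diff": float(self.delta_cost[idx].mean(axis=1).std(ddof=1)),
            "se_mean_qaly_diff": float(self.delta_qaly[idx].mean(axis=1).std(ddof=1)),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n),
                "cost_pd": self.costs[:, 0],
                "cost_hd": self.costs[:, 1],
                "qaly_pd": self.qalys[:, 0],
                "qaly_hd": self.qalys[:, 1],
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def run_psa(
    params: ModelParameters,
    mortality: dict[str, MortalityModel],
    config: AnalysisConfig,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per iteration: draw one parameter set (all estimates sampled
    independently from their distributions), run both strategies through
    the deterministic engine, store the (cost, QALY) pairs.  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.psa_iterations
    costs = np.empty((n, 2))
    qalys = np.empty((n, 2))
    for i in range(n):
        draw = sample_parameters(params, rng)
        res = _run_pair(draw, mortality, config)
        costs[i] = (res["PD"][0], res["HD"][0])
        qalys[i] = (res["PD"][2], res["HD"][2])
    return PSAResult(
        costs=costs,
        qalys=qalys,
        seed=config.seed,
        perspective=config.perspective,
        start_age=config.start_age,
    )


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective along a WTP grid."""

    wtp: np.ndarray
    prob_pd: np.ndarray
    prob_hd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp, "prob_pd": self.prob_pd, "prob_hd": self.prob_hd}
        )


def ceac(
    psa: PSAResult,
    wtp_grid: np.ndarray | None = None,
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from stored PSA draws.

    At each willingness-to-pay λ a strategy is preferred in a draw iff
    its net monetary benefit λ·QALY − cost is maximal; exact ties are
    split equally.
    """
    if psa.n == 0:
        raise ParameterError("PSA result holds no draws")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 60_000.0 + 100.0, 100.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    # NMB difference HD - PD per draw and λ
    nmb_diff = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    prob_hd = (nmb_diff > 0).mean(axis=1) + 0.5 * (nmb_diff == 0).mean(axis=1)
    return CEACCurve(wtp=wtp_grid, prob_pd=1.0 - prob_hd, prob_hd=prob_hd)


def crossover_wtp(curve: CEACCurve) -> float | None:
    """Willingness-to-pay where the preferred strategy flips (prob = 0.5).

    Linear interpolation between the bracketing grid points of the first
    sign change of ``prob_hd - 0.5``; ``None`` when the curves do not
    cross on the grid (extend the grid and re-evaluate).
    """
    diff = curve.prob_hd - 0.5
    sign = np.sign(diff)
    nonzero = sign != 0
    crossings = np.where(np.diff(sign[nonzero]) != 0)[0]
    if diff[0] == 0.0:
        return float(curve.wtp[0])
    if crossings.size == 0:
        exact = np.where(diff == 0.0)[0]
        if exact.size:
            return float(curve.wtp[exact[0]])
        logger.warning(
            "CEAC does not cross 0.5 on the WTP grid [%g, %g]; extend the grid",
            curve.wtp[0],
            curve.wtp[-1],
        )
        return None
    idx_nonzero = np.where(nonzero)[0]
    i = idx_nonzero[crossings[0]]
    j = idx_nonzero[crossings[0] + 1]
    x0, x1 = curve.wtp[i], curve.wtp[j]
    y0, y1 = diff[i], diff[j]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
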