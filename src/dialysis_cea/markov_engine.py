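"""Annual-cycle Markov cohort engine for the five dialysis states.

State order everywhere: (PD, PD_CC, HD, HD_CC, DEATH).  Within a cycle,
death is resolved first from the state- and age-specific mortality model;
modality switching and chronic-complication onset are then applied to the
surviving fraction; the remainder stays put.  Acute complications are
transient within-cycle events: they carry an expected add-on cost but no
state change and no utility decrement.

The engine tracks expected state occupancy (cohort fractions), which for
a Markov chain equals the large-sample limit of a per-individual
microsimulation; :func:`microsimulate` provides that stochastic
counterpart for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .param_model import (
    DEATH_INDEX,
    IS_CHRONIC,
    LIVING_STATES,
    MODALITY,
    STATE_INDEX,
    STATE_ORDER,
    SWITCH_DESTINATION,
    AnalysisConfig,
    HealthState,
    ModelParameters,
    ParameterError,
    TransitionParameters,
)
from .survival_mortality import MortalityModel

logger = logging.getLogger(__name__)

N_STATES = 5


def discount_factor(cycle: float, rate: float) -> float:
    """Discount factor ``1 / (1 + rate)**cycle``; cycle 0 is undiscounted."""
    if rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    if cycle < 0:
        raise ParameterError(f"cycle must be >= 0, got {cycle}")
    return (1.0 + rate) ** (-cycle)


def build_matrix(
    transitions: TransitionParameters,
    mortality: MortalityModel,
    start_age: float,
    cycle: int,
) -> np.ndarray:
    """One annual 5x5 transition matrix.

    For each living state the row is assembled death-first: the mortality
    model gives the annual death probability (age- and chronic-status
    specific); switch and chronic-complication probabilities then split
    the surviving fraction.  If the competing probabilities sum above 1
    they are renormalised proportionally and a warning is logged —
    a signal of implausible parameters, not an error.
    """
    if cycle < 0:
        raise ParameterError(f"cycle must be >= 0, got {cycle}")
    mat = np.zeros((N_STATES, N_STATES))
    mat[DEATH_INDEX, DEATH_INDEX] = 1.0
    for state in LIVING_STATES:
        i = STATE_INDEX[state]
        q = mortality.death_prob(start_age, cycle, chronic=IS_CHRONIC[state])
        p_switch = transitions.p_switch.mean
        if state is HealthState.PD:
            p_cc = transitions.p_pd_to_pd_cc.mean
        elif state is HealthState.HD:
            p_cc = transitions.p_hd_to_hd_cc.mean
        else:
            p_cc = 0.0
        total = p_switch + p_cc
        if total > 1.0:
            logger.warning(
                "state %s cycle %d: competing probabilities sum to %.4f > 1; "
                "renormalising proportionally",
                state.value,
                cycle,
                total,
            )
            p_switch /= total
            p_cc /= total
        survive = 1.0 - q
        mat[i, DEATH_INDEX] = q
        mat[i, STATE_INDEX[SWITCH_DESTINATION[state]]] += survive * p_switch
        if p_cc > 0.0:
            dest_cc = HealthState.PD_CC if state is HealthState.PD else HealthState.HD_CC
            mat[i, STATE_INDEX[dest_cc]] += survive * p_cc
        mat[i, i] += survive * max(0.0, 1.0 - p_switch - p_cc)
    return mat


@dataclass
class CohortTrace:
    """State occupancy per cycle for one strategy.

    ``occupancy`` has ``n_cycles + 1`` rows; row ``t`` is the distribution
    at the start of cycle ``t``.  ``switch_to_pd`` / ``switch_to_hd`` hold
    the expected cohort mass switching modality during cycle ``t`` (used
    to charge setup costs on switching).
    """

    occupancy: np.ndarray
    strategy: str
    start_age: float
    switch_to_pd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    switch_to_hd: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def living_mass(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEATH_INDEX]


@dataclass
class LifetimeOutcome:
    """Discounted (and undiscounted) lifetime cost, life-years and QALYs."""

    lifetime_cost: float
    life_years: float
    qalys: float
    lifetime_cost_undiscounted: float
    life_years_undiscounted: float
    qalys_undiscounted: float


def run_cohort(
    params: ModelParameters,
    mortality: MortalityModel,
    config: AnalysisConfig,
    strategy: str,
) -> CohortTrace:
    """Propagate a unit cohort from the strategy's starting state to death.

    The simulation stops when living mass falls below
    ``config.living_mass_tol`` or the cohort reaches ``config.age_cap``.
    """
    config.validate()
    if strategy not in ("PD", "HD"):
        raise ParameterError(f"strategy must be PD or HD, got {strategy!r}")
    transitions = params.transitions[strategy]
    max_cycles = int(np.ceil(config.age_cap - config.start_age))
    rows = [np.zeros(N_STATES)]
    rows[0][STATE_INDEX[HealthState[strategy]]] = 1.0
    sw_pd: list[float] = []
    sw_hd: list[float] = []
    occ = rows[0]
    for t in range(max_cycles):
        if 1.0 - occ[DEATH_INDEX] < config.living_mass_tol:
            break
        mat = build_matrix(transitions, mortality, config.start_age, t)
        # expected switch flows this cycle, by destination modality
        to_pd = to_hd = 0.0
        for state in LIVING_STATES:
            i = STATE_INDEX[state]
            flow = occ[i] * mat[i, STATE_INDEX[SWITCH_DESTINATION[state]]]
            if MODALITY[SWITCH_DESTINATION[state]] == "PD":
                to_pd += flow
            else:
                to_hd += flow
        sw_pd.append(to_pd)
        sw_hd.append(to_hd)
        occ = occ @ mat
        rows.append(occ)
    return CohortTrace(
        occupancy=np.vstack(rows),
        strategy=strategy,
        start_age=config.start_age,
        switch_to_pd=np.asarray(sw_pd),
        switch_to_hd=np.asarray(sw_hd),
    )


def _state_cost_vector(params: ModelParameters, strategy: str, perspective: str) -> np.ndarray:
    """Annual expected cost per living state, perspective-filtered."""
    if perspective not in ("government", "societal"):
        raise ParameterError(f"unknown perspective {perspective!r}")
    costs = params.costs
    transitions = params.transitions[strategy]
    vec = np.zeros(N_STATES)
    for state in LIVING_STATES:
        i = STATE_INDEX[state]
        addon = costs.acute_chronic_addon if IS_CHRONIC[state] else costs.acute_addon
        c = (
            costs.annual_direct_medical[state.value].mean
            + transitions.p_acute[state.value].mean * addon.mean
        )
        if perspective == "societal":
            c += costs.annual_direct_nonmedical[state.value].mean
            c += costs.annual_indirect[state.value].mean
        vec[i] = c
    return vec


def accrue(
    trace: CohortTrace,
    costs_params: ModelParameters,
    config: AnalysisConfig,
) -> LifetimeOutcome:
    """Accrue discounted lifetime cost, life-years and QALYs over a trace.

    Cycle ``t`` contributes occupancy at the start of cycle ``t`` times the
    annual amounts, discounted by ``1/(1+r)**t``.  Setup cost is charged
    once at entry and (optionally) on each expected modality switch.
    """
    config.validate()
    params = costs_params
    strategy = trace.strategy
    n = trace.n_cycles
    occ = trace.occupancy[:n]  # state at the start of each completed cycle
    t_idx = np.arange(n, dtype=float)
    if config.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:n] + trace.occupancy[1 : n + 1])
    disc = (1.0 + config.discount_rate) ** (-t_idx)

    cost_vec = _state_cost_vector(params, strategy, config.perspective)
    util_vec = np.zeros(N_STATES)
    for state in LIVING_STATES:
        util_vec[STATE_INDEX[state]] = params.utilities.utility[state.value].mean

    living = occ[:, :DEATH_INDEX].sum(axis=1)
    per_cycle_cost = occ @ cost_vec
    per_cycle_qaly = occ @ util_vec

    setup_disc = params.costs.setup[strategy].mean  # entry, cycle 0, d(0)=1
    setup_undisc = params.costs.setup[strategy].mean
    if config.setup_cost_on_switch and n > 0:
        sw_cost = (
            trace.switch_to_pd[:n] * params.costs.setup["PD"].mean
            + trace.switch_to_hd[:n] * params.costs.setup["HD"].mean
        )
        setup_disc += float(sw_cost @ disc)
        setup_undisc += float(sw_cost.sum())

    return LifetimeOutcome(
        lifetime_cost=float(per_cycle_cost @ disc) + setup_disc,
        life_years=float(living @ disc),
        qalys=float(per_cycle_qaly @ disc),
        lifetime_cost_undiscounted=float(per_cycle_cost.sum()) + setup_undisc,
        life_years_undiscounted=float(living.sum()),
        qalys_undiscounted=float(per_cycle_qaly.sum()),
    )


def evaluate_strategy(
    params: ModelParameters,
    mortality: MortalityModel,
    config: AnalysisConfig,
    strategy: str,
) -> tuple[CohortTrace, LifetimeOutcome]:
    """Run the cohort and accrue outcomes for one strategy."""
    trace = run_cohort(params, mortality, config, strategy)
    return trace, accrue(trace, params, config)


def microsimulate(
    params: ModelParameters,
    mortality: MortalityModel,
    config: AnalysisConfig,
    strategy: str,
    n_patients: int,
    rng: np.random.Generator,
    n_batches: int = 20,
) -> list[LifetimeOutcome]:
    """Individual-level Monte-Carlo counterpart of the cohort engine.

    Simulates ``n_patients`` split into ``n_batches`` independent batches
    (state counts propagated by multinomial draws through the same annual
    matrices) and returns one mean :class:`LifetimeOutcome` per batch, so
    callers can form Monte-Carlo standard errors.  Serves as a validation
    oracle for :func:`run_cohort` / :func:`accrue`.
    """
    config.validate()
    transitions = params.transitions[strategy]
    max_cycles = int(np.ceil(config.age_cap - config.start_age))
    matrices = [
        build_matrix(transitions, mortality, config.start_age, t) for t in range(max_cycles)
    ]
    per_batch = n_patients // n_batches
    outcomes = []
    for _ in range(n_batches):
        counts = np.zeros(N_STATES, dtype=np.int64)
        counts[STATE_INDEX[HealthState[strategy]]] = per_batch
        rows = [counts.astype(float) / per_batch]
        sw_pd: list[float] = []
        sw_hd: list[float] = []
        for t in range(max_cycles):
            if counts[:DEATH_INDEX].sum() == 0:
                break
            new = np.zeros(N_STATES, dtype=np.int64)
            new[DEATH_INDEX] = counts[DEATH_INDEX]
            to_pd = to_hd = 0
            for state in LIVING_STATES:
                i = STATE_INDEX[state]
                if counts[i] == 0:
                    continue
                flows = rng.multinomial(counts[i], matrices[t][i])
                new += flows
                j = STATE_INDEX[SWITCH_DESTINATION[state]]
                if MODALITY[SWITCH_DESTINATION[state]] == "PD":
                    to_pd += flows[j]
                else:
                    to_hd += flows[j]
            sw_pd.append(to_pd / per_batch)
            sw_hd.append(to_hd / per_batch)
            counts = new
            rows.append(counts.astype(float) / per_batch)
        trace = CohortTrace(
            occupancy=np.vstack(rows),
            strategy=strategy,
            start_age=config.start_age,
            switch_to_pd=np.asarray(sw_pd),
            switch_to_hd=np.asarray(sw_hd),
        )
        outcomes.append(accrue(trace, params, config))
    return outcomes
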