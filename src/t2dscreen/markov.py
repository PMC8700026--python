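"""Five-state cohort engine with HbA1c-scaled risks.

States: disease-free (NGT), undiagnosed disease, diagnosed disease,
complication, dead.  Background mortality comes from a life table; the
diseased states multiply the background risk on the rate scale by relative
risks anchored at the diagnosed glycaemic level.  Screening, when active in
a cycle, adds a detection route from undiagnosed to diagnosed combined with
clinical detection as independent events.

Accumulation applies a composite Simpson 1/3 within-cycle correction to the
continuous flows (treatment cost, life years, quality-adjusted life years)
and discounts each cycle at the annual rate; screening costs are discrete
events discounted with the cycle they occur in but not Simpson-weighted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .params import ParameterSet
from .screening import CascadeResult, ScreeningStrategy, misclassification_outcomes
from .synthetic_data import LifeTable

log = logging.getLogger(__name__)


class HealthState(IntEnum):
    NGT = 0
    UNDX = 1
    DX = 2
    COMP = 3
    DEAD = 4


N_STATES = len(HealthState)
ALIVE = np.array([1.0, 1.0, 1.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# risk arithmetic
# ---------------------------------------------------------------------------

def adjust_probability(p: float, rr: float) -> float:
    """Scale an annual probability by a relative risk on the rate scale.

    ``p' = 1 - (1 - p)^rr``, i.e. the annual rate ``-ln(1-p)`` is multiplied
    by ``rr`` and converted back.  Identity at ``rr = 1``; undefined at
    ``p = 1``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must lie in [0,1), got {p}")
    if rr <= 0.0:
        raise ValueError(f"rr must be > 0, got {rr}")
    return 1.0 - (1.0 - p) ** rr


def hba1c_multiplier(rr_per_pct: float, hba1c: float, ref_hba1c: float) -> float:
    """Relative risk accumulated over the glycaemic gap: ``rr^(h - ref)``."""
    if rr_per_pct <= 0.0:
        raise ValueError("rr_per_pct must be > 0")
    return rr_per_pct ** (hba1c - ref_hba1c)


def mortality_rr(state: HealthState, params: ParameterSet) -> float:
    """All-cause mortality multiplier vs background, by health state.

    Diagnosed disease carries the bare disease relative risk; the other
    diseased states scale it further by the per-1% mortality multiplier
    over their glycaemic gap to the diagnosed level (the anchor).
    """
    if state in (HealthState.NGT, HealthState.DEAD):
        return 1.0
    if state == HealthState.DX:
        return params.rr_death_t2dm
    ref = params.hba1c_dx
    h = params.hba1c_undx if state == HealthState.UNDX else params.hba1c_comp
    return params.rr_death_t2dm * hba1c_multiplier(params.rr_death_per_hba1c, h, ref)


def state_mortality(qx: float, state: HealthState, params: ParameterSet) -> float:
    """Annual death probability in ``state`` given background ``qx``."""
    if qx >= 1.0:
        return 1.0
    if not 0.0 < qx:
        raise ValueError(f"qx must lie in (0,1), got {qx}")
    rr = mortality_rr(state, params)
    return qx if rr == 1.0 else adjust_probability(qx, rr)


def undx_comp_probability(params: ParameterSet) -> float:
    """Annual undiagnosed->complication probability, derived at run time.

    The diagnosed->complication probability is rate-scaled by the per-1%
    complication risk ratio over the undiagnosed/diagnosed glycaemic gap.
    At the shipped point estimates this reproduces the tabulated 0.0231.
    """
    rr = hba1c_multiplier(params.rr_comp_per_hba1c, params.hba1c_undx, params.hba1c_dx)
    return adjust_probability(params.p_dx_comp, rr)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _exit_probabilities(state: HealthState, screened: bool,
                        cascade: Optional[CascadeResult],
                        params: ParameterSet) -> Dict[HealthState, float]:
    """Conditional-on-survival destination probabilities out of ``state``."""
    if state == HealthState.NGT:
        return {HealthState.UNDX: params.p_ngt_undx,
                HealthState.DX: params.p_ngt_dx}
    if state == HealthState.UNDX:
        p_detect = params.p_undx_dx
        if screened and cascade is not None:
            # screening and clinical detection as independent events (union)
            p_detect = 1.0 - (1.0 - p_detect) * (1.0 - cascade.p_detect_given_diseased)
        return {HealthState.DX: p_detect,
                HealthState.COMP: undx_comp_probability(params)}
    if state == HealthState.DX:
        return {HealthState.COMP: params.p_dx_comp}
    return {}


def build_transition_row(state: HealthState, age: int, screened: bool,
                         cascade: Optional[CascadeResult],
                         params: ParameterSet,
                         life_table: LifeTable) -> np.ndarray:
    """One row of the annual transition matrix.

    Death competes first at the state-specific mortality; surviving mass is
    allocated to destinations, with any residual staying in place.  Exits
    exceeding the survivor mass are rescaled proportionally (logged).
    """
    row = np.zeros(N_STATES)
    if state == HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
        return row
    d = state_mortality(life_table.q(age), state, params)
    s = 1.0 - d
    row[HealthState.DEAD] = d
    exits = _exit_probabilities(state, screened, cascade, params)
    total = sum(exits.values())
    if total > 1.0:
        log.warning("competing exits from %s sum to %.4f > 1; rescaling",
                    state.name, total)
        exits = {k: v / total for k, v in exits.items()}
        total = 1.0
    for dest, p in exits.items():
        row[dest] = s * p
    row[state] = s * (1.0 - total)
    if row[state] < -1e-12:
        raise ValueError(f"negative residual in state {state.name}")
    return row


def transition_matrix(age: int, screened: bool,
                      cascade: Optional[CascadeResult],
                      params: ParameterSet,
                      life_table: LifeTable) -> np.ndarray:
    return np.stack([
        build_transition_row(s, age, screened, cascade, params, life_table)
        for s in HealthState
    ])


# ---------------------------------------------------------------------------
# cohort run
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Scenario description for one cohort run."""

    start_age: int = 40
    max_age: int = 100
    discount_rate: float = 0.03
    perspective: str = "societal"
    strategy: Optional[ScreeningStrategy] = None
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        if self.cycle_length != 1.0:
            raise ValueError("cycle length is fixed at one year")
        if self.perspective not in ("societal", "provider"):
            raise ValueError(f"unknown perspective {self.perspective!r}")


@dataclass
class CohortTrace:
    """State occupancy over cycles plus per-cycle screening cost flows."""

    start_age: int
    occupancy: np.ndarray                   # (n_cycles + 1, 5), rows sum to 1
    screening_cost: Dict[str, np.ndarray]   # perspective -> per-cycle US$
    strategy: Optional[ScreeningStrategy] = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(self.n_cycles + 1)
        df = pd.DataFrame(self.occupancy,
                          columns=[s.name.lower() for s in HealthState])
        df.insert(0, "cycle", cycles)
        df.insert(1, "age", self.start_age + cycles)
        for persp, flow in self.screening_cost.items():
            df[f"screening_cost_{persp}"] = flow
        return df


def run_cohort(config: ModelConfig, params: ParameterSet,
               life_table: LifeTable) -> CohortTrace:
    """Propagate the cohort from start age to the horizon.

    The cohort starts free of diagnosed disease: the starting-age prevalence
    sits undiagnosed, the remainder disease-free.  Screening rounds modify
    the cycle's transition row and charge the cascade's expected cost to the
    alive screened states (disease-free and undiagnosed) at cycle start.
    """
    n = config.max_age - config.start_age
    if life_table.max_age < config.max_age - 1:
        raise ValueError("life table does not cover the model horizon")
    strategy = config.strategy
    cascade = misclassification_outcomes(strategy, params) if strategy else None
    screen_cycles = strategy.screening_cycles(n) if strategy else frozenset()

    prev = params.prevalence_for(config.start_age)
    occ = np.zeros((n + 1, N_STATES))
    occ[0, HealthState.NGT] = 1.0 - prev
    occ[0, HealthState.UNDX] = prev
    flows = {"societal": np.zeros(n + 1), "provider": np.zeros(n + 1)}

    # survival-conditional exits that do not change over cycles
    base_exits = {
        s: _exit_probabilities(s, False, None, params)
        for s in (HealthState.NGT, HealthState.UNDX, HealthState.DX)
    }
    screened_exits = {
        s: _exit_probabilities(s, True, cascade, params)
        for s in (HealthState.NGT, HealthState.UNDX, HealthState.DX)
    }
    rrs = np.array([mortality_rr(s, params)
                    for s in (HealthState.NGT, HealthState.UNDX,
                              HealthState.DX, HealthState.COMP)])

    for t in range(n):
        age = config.start_age + t
        screened = t in screen_cycles
        if screened and cascade is not None:
            for persp in flows:
                flows[persp][t] = (
                    occ[t, HealthState.NGT] * cascade.expected_cost_healthy[persp]
                    + occ[t, HealthState.UNDX] * cascade.expected_cost_diseased[persp]
                )
        qx = life_table.q(age)
        death = np.ones(4) if qx >= 1.0 else 1.0 - (1.0 - qx) ** rrs
        surv = 1.0 - death
        p_mat = np.zeros((N_STATES, N_STATES))
        p_mat[:, HealthState.DEAD] = np.append(death, 1.0)
        exits = screened_exits if screened else base_exits
        for s in (HealthState.NGT, HealthState.UNDX, HealthState.DX):
            ex = exits[s]
            total = sum(ex.values())
            scale = 1.0 / total if total > 1.0 else 1.0
            for dest, p in ex.items():
                p_mat[s, dest] = surv[s] * p * scale
            p_mat[s, s] = surv[s] * max(1.0 - total * scale, 0.0)
        p_mat[HealthState.COMP, HealthState.COMP] = surv[HealthState.COMP]
        occ[t + 1] = occ[t] @ p_mat

    return CohortTrace(start_age=config.start_age, occupancy=occ,
                       screening_cost=flows, strategy=strategy)


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def simpson_weights(n_cycles: int) -> np.ndarray:
    """Composite Simpson 1/3 weights over ``n_cycles`` unit intervals.

    Even interval counts use the pure 1/3 rule; odd counts finish with the
    3/8 rule on the last three intervals (n = 3 is pure 3/8).  Weights sum
    to the interval count, so they reduce to plain time integration for a
    constant flow.
    """
    if n_cycles < 2:
        raise ValueError("need at least two intervals")
    w = np.zeros(n_cycles + 1)

    def add_third(lo: int, hi: int) -> None:
        w[lo] += 1.0 / 3.0
        w[hi] += 1.0 / 3.0
        w[lo + 1:hi:2] += 4.0 / 3.0
        w[lo + 2:hi:2] += 2.0 / 3.0

    if n_cycles % 2 == 0:
        add_third(0, n_cycles)
    elif n_cycles == 3:
        w += np.array([3.0, 9.0, 9.0, 3.0]) / 8.0
    else:
        add_third(0, n_cycles - 3)
        w[n_cycles - 3:] += np.array([3.0, 9.0, 9.0, 3.0]) / 8.0
    return w


@dataclass(frozen=True)
class EconOutcome:
    """Discounted totals for one strategy under one perspective."""

    perspective: str
    screening_cost: float
    treatment_cost: float
    total_cost: float
    total_ly: float
    total_qaly: float

    def __post_init__(self) -> None:
        if abs(self.total_cost - self.screening_cost - self.treatment_cost) > 1e-9:
            raise ValueError("cost components must sum to total")
        if self.total_qaly > self.total_ly + 1e-9:
            raise ValueError("QALYs cannot exceed life years")


def state_cost_vector(params: ParameterSet, perspective: str) -> np.ndarray:
    """Annual treatment cost by state for the given perspective."""
    med = np.array([0.0, params.cost_tx_undx_med, params.cost_tx_dx_med,
                    params.cost_tx_comp_med, 0.0])
    if perspective == "provider":
        return med
    if perspective == "societal":
        return med + np.array([0.0, params.cost_tx_undx_nonmed,
                               params.cost_tx_dx_nonmed,
                               params.cost_tx_comp_nonmed, 0.0])
    raise ValueError(f"unknown perspective {perspective!r}")


def utility_vector(params: ParameterSet) -> np.ndarray:
    return np.array([params.u_ngt, params.u_undx, params.u_dx, params.u_comp, 0.0])


def accumulate(trace: CohortTrace, params: ParameterSet,
               config: ModelConfig) -> EconOutcome:
    """Discounted lifetime totals from a cohort trace.

    Treatment cost, life-year and QALY flows are Simpson-weighted across the
    cycle grid; screening costs are event costs (discounted, unit weight).
    Discounting uses the end-of-cycle convention with cycle 0 undiscounted.
    """
    n = trace.n_cycles
    w = simpson_weights(n)
    t = np.arange(n + 1)
    disc = (1.0 + config.discount_rate) ** (-t.astype(float))
    occ = trace.occupancy

    cost_flow = occ @ state_cost_vector(params, config.perspective)
    qaly_flow = occ @ utility_vector(params)
    ly_flow = occ @ ALIVE

    treatment = float(np.sum(w * disc * cost_flow))
    qaly = float(np.sum(w * disc * qaly_flow))
    ly = float(np.sum(w * disc * ly_flow))
    screening = float(np.sum(disc * trace.screening_cost[config.perspective]))
    return EconOutcome(
        perspective=config.perspective,
        screening_cost=screening,
        treatment_cost=treatment,
        total_cost=screening + treatment,
        total_ly=ly,
        total_qaly=qaly,
    )


def evaluate_strategy(strategy: Optional[ScreeningStrategy], start_age: int,
                      params: ParameterSet, life_table: LifeTable, *,
                      discount_rate: float = 0.03,
                      max_age: int = 100) -> Dict[str, EconOutcome]:
    """Run one scenario and accumulate it under both perspectives."""
    config = ModelConfig(start_age=start_age, max_age=max_age,
                         discount_rate=discount_rate, strategy=strategy)
    trace = run_cohort(config, params, life_table)
    out = {}
    for persp in ("societal", "provider"):
        cfg = ModelConfig(start_age=start_age, max_age=max_age,
                          discount_rate=discount_rate, perspective=persp,
                          strategy=strategy)
        out[persp] = accumulate(trace, params, cfg)
    return out
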