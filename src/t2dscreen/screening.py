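"""Screening cascades at the two primary-care tiers.

The commune-tier cascade is risk questionnaire -> capillary glucose ->
referral -> plasma glucose confirmation; the district-tier cascade is risk
questionnaire -> plasma glucose -> repeat plasma glucose.  Repeated tests
are treated as conditionally independent given true disease status.
Subjects whose full cascade is falsely positive incur the cascade's cost
but return to the disease-free state untreated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional

from .params import ParameterSet

SETTINGS = ("CHS", "DHC")
INTERVALS = ("one-off", "annual", "3-yearly")
PERSPECTIVES = ("societal", "provider")


@dataclass(frozen=True)
class ScreeningStrategy:
    """A screening programme: where, how often, from what age."""

    setting: str
    interval: str
    start_age: int = 40
    adherence_referral: Optional[float] = None  # None -> take from params

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if self.interval not in INTERVALS:
            raise ValueError(f"interval must be one of {INTERVALS}, got {self.interval!r}")
        if self.adherence_referral is not None and not 0.0 <= self.adherence_referral <= 1.0:
            raise ValueError("adherence_referral must lie in [0,1]")

    @property
    def label(self) -> str:
        return f"{self.interval} {self.setting}"

    def screening_cycles(self, n_cycles: int) -> FrozenSet[int]:
        """Cycle indices (0-based, before each transition) with screening."""
        if self.interval == "one-off":
            return frozenset({0} if n_cycles > 0 else set())
        if self.interval == "annual":
            return frozenset(range(n_cycles))
        return frozenset(range(0, n_cycles, 3))


@dataclass(frozen=True)
class CascadeResult:
    """Per-round cascade outcomes by true state, plus costs per perspective."""

    p_detect_given_diseased: float
    p_full_false_cascade_given_healthy: float
    expected_cost_diseased: Dict[str, float]
    expected_cost_healthy: Dict[str, float]

    def __post_init__(self) -> None:
        for p in (self.p_detect_given_diseased,
                  self.p_full_false_cascade_given_healthy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("cascade probabilities must lie in [0,1]")
        for costs in (self.expected_cost_diseased, self.expected_cost_healthy):
            if costs["provider"] > costs["societal"] + 1e-12:
                raise ValueError("provider cost cannot exceed societal cost")


def _adherence(strategy: ScreeningStrategy, params: ParameterSet) -> float:
    if strategy.setting != "CHS":
        return 1.0  # both tests happen in one district visit, no referral leg
    if strategy.adherence_referral is not None:
        return strategy.adherence_referral
    return params.adherence_referral


def detection_probability(strategy: ScreeningStrategy, params: ParameterSet) -> float:
    """Probability a truly diseased participant completes a positive cascade."""
    if strategy.setting == "CHS":
        return (params.sens_findrisc * params.sens_fcg
                * _adherence(strategy, params) * params.sens_fpg)
    return params.sens_findrisc * params.sens_fpg ** 2


def false_cascade_probability(strategy: ScreeningStrategy, params: ParameterSet) -> float:
    """Probability a healthy participant is positive at every cascade step."""
    if strategy.setting == "CHS":
        return ((1.0 - params.spec_findrisc) * (1.0 - params.spec_fcg)
                * _adherence(strategy, params) * (1.0 - params.spec_fpg))
    return (1.0 - params.spec_findrisc) * (1.0 - params.spec_fpg) ** 2


def expected_screening_cost(strategy: ScreeningStrategy, true_state: str,
                            perspective: str, params: ParameterSet) -> float:
    """Expected per-round cascade cost for one participant of ``true_state``.

    Societal costing adds the tier's per-visit non-medical cost once per
    visit (the commune visit at entry, the district visit on referral or at
    entry); the provider perspective counts test costs only.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if true_state not in ("healthy", "diseased"):
        raise ValueError(f"true_state must be healthy|diseased, got {true_state!r}")
    diseased = true_state == "diseased"
    p1 = params.sens_findrisc if diseased else 1.0 - params.spec_findrisc
    societal = perspective == "societal"
    adh = _adherence(strategy, params)
    if strategy.setting == "CHS":
        p2 = params.sens_fcg if diseased else 1.0 - params.spec_fcg
        cost = params.cost_test_findrisc + p1 * params.cost_test_fcg
        cost += p1 * p2 * adh * params.cost_test_fpg
        if societal:
            cost += params.cost_visit_chs
            cost += p1 * p2 * adh * params.cost_visit_dhc
        return cost
    pf = params.sens_fpg if diseased else 1.0 - params.spec_fpg
    cost = params.cost_test_findrisc + p1 * params.cost_test_fpg
    cost += p1 * pf * params.cost_test_fpg
    if societal:
        cost += params.cost_visit_dhc
    return cost


def misclassification_outcomes(strategy: ScreeningStrategy,
                               params: ParameterSet) -> CascadeResult:
    """Full per-round cascade summary for one screening round.

    Diseased participants split into detected (enter the diagnosed state)
    and missed (stay undiagnosed); healthy participants always return to
    the disease-free state, double false positives included.
    """
    return CascadeResult(
        p_detect_given_diseased=detection_probability(strategy, params),
        p_full_false_cascade_given_healthy=false_cascade_probability(strategy, params),
        expected_cost_diseased={
            p: expected_screening_cost(strategy, "diseased", p, params)
            for p in PERSPECTIVES
        },
        expected_cost_healthy={
            p: expected_screening_cost(strategy, "healthy", p, params)
            for p in PERSPECTIVES
        },
    )
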