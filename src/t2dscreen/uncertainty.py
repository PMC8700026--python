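"""Deterministic and probabilistic sensitivity analysis.

One-way DSA reruns the full model at each parameter's low/high bound (all
else at base) and reports incremental net monetary benefit spans for the
tornado diagram.  The PSA draws full parameter sets (common random draws
shared by every strategy within an iteration), reruns the model per draw,
and summarizes the cloud as cost-effectiveness planes and acceptability
curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .econ_eval import DEFAULT_WTP, nmb
from .markov import evaluate_strategy
from .params import (ParameterSet, ParameterSpec, dsa_bounds,
                     sample_parameter_set)
from .screening import ScreeningStrategy
from .synthetic_data import LifeTable

log = logging.getLogger(__name__)

NO_SCREENING = "no screening"


def _inc_nmb(values: Dict[str, float], strategy: ScreeningStrategy,
             start_age: int, life_table: LifeTable, wtp: float,
             perspective: str, discount_rate: float, max_age: int) -> float:
    params = ParameterSet.from_values(values)
    alt = evaluate_strategy(strategy, start_age, params, life_table,
                            discount_rate=discount_rate, max_age=max_age)
    base = evaluate_strategy(None, start_age, params, life_table,
                             discount_rate=discount_rate, max_age=max_age)
    return nmb(alt[perspective], wtp) - nmb(base[perspective], wtp)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    nmb_low: float
    nmb_high: float

    @property
    def span(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def one_way_dsa(specs: Mapping[str, ParameterSpec],
                strategy: ScreeningStrategy, life_table: LifeTable, *,
                vary: Optional[Sequence[str]] = None,
                start_age: int = 40, wtp: float = DEFAULT_WTP,
                perspective: str = "societal", discount_rate: float = 0.03,
                max_age: int = 100) -> List[TornadoEntry]:
    """Tornado entries for incremental NMB vs no screening, sorted by span.

    ``vary`` restricts the analysis to a subset of parameter names (default:
    every parameter with a DSA rule).  Parameters without a rule are skipped
    (logged).  Both arms of the comparison are rerun at each bound, so a
    parameter that also moves the comparator is handled consistently.
    """
    base_values = {name: s.mean for name, s in specs.items()}
    names = sorted(specs) if vary is None else list(vary)
    entries = []
    for name in names:
        spec = specs[name]
        if spec.dsa_rule == "none":
            log.info("DSA: skipping %s (no rule)", name)
            continue
        lo, hi = dsa_bounds(spec)
        results = []
        for bound in (lo, hi):
            values = dict(base_values)
            values[name] = bound
            results.append(_inc_nmb(values, strategy, start_age, life_table,
                                    wtp, perspective, discount_rate, max_age))
        entries.append(TornadoEntry(parameter=name, nmb_low=results[0],
                                    nmb_high=results[1]))
    entries.sort(key=lambda e: -e.span)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parameter, e.nmb_low, e.nmb_high, e.span) for e in entries],
        columns=["parameter", "nmb_low", "nmb_high", "span"],
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

@dataclass
class PsaDraws:
    """Monte Carlo cost/effect table: one row per draw, strategy, perspective."""

    table: pd.DataFrame
    n_draws: int
    seed: int
    strategies: List[str]

    def pivot(self, column: str, perspective: str) -> pd.DataFrame:
        sub = self.table[self.table["perspective"] == perspective]
        return sub.pivot(index="draw", columns="strategy", values=column)


def run_psa(specs: Mapping[str, ParameterSpec],
            strategies: Sequence[Optional[ScreeningStrategy]],
            life_table: LifeTable, *, start_age: int = 40,
            n_draws: int = 1000, seed: int = 0,
            discount_rate: float = 0.03, max_age: int = 100,
            max_retries: int = 100) -> PsaDraws:
    """Seeded PSA: one parameter draw per iteration shared by all strategies.

    ``None`` in ``strategies`` denotes the no-screening comparator.  A draw
    that fails validation is resampled (logged), capped at ``max_retries``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [s.label if s is not None else NO_SCREENING for s in strategies]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")
    records = []
    for d in range(n_draws):
        params = None
        for attempt in range(max_retries):
            try:
                params = sample_parameter_set(specs, rng)
                break
            except ValueError as exc:  # infeasible joint draw
                log.warning("draw %d attempt %d rejected: %s", d, attempt, exc)
        if params is None:
            raise RuntimeError(f"draw {d}: no feasible sample in {max_retries} tries")
        for strat, label in zip(strategies, labels):
            outs = evaluate_strategy(strat, start_age, params, life_table,
                                     discount_rate=discount_rate, max_age=max_age)
            for persp, o in outs.items():
                records.append((d, label, persp, o.total_cost, o.total_qaly,
                                o.total_ly))
    table = pd.DataFrame(records, columns=["draw", "strategy", "perspective",
                                           "cost", "qaly", "ly"])
    return PsaDraws(table=table, n_draws=n_draws, seed=seed, strategies=labels)


@dataclass
class CeacCurve:
    """Probability each strategy is optimal across a willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: pd.DataFrame  # index lambda, one column per strategy


def default_lambda_grid(wtp: float = DEFAULT_WTP, n: int = 100) -> np.ndarray:
    return np.linspace(0.0, 3.0 * wtp, n + 1)


def ceac(draws: PsaDraws, lambda_grid: Optional[np.ndarray] = None, *,
         perspective: str = "societal", rule: str = "max_nmb",
         base_strategy: str = NO_SCREENING) -> CeacCurve:
    """Acceptability curves over the strategy set.

    ``max_nmb`` (default): at each threshold, the probability a strategy
    attains the strictly maximal NMB among all strategies, ties split
    equally, so probabilities sum to one.  ``pairwise``: probability each
    strategy beats ``base_strategy`` (columns then need not sum to one).
    """
    if draws.table.empty:
        raise ValueError("empty PSA draw table")
    if rule not in ("max_nmb", "pairwise"):
        raise ValueError(f"unknown CEAC rule {rule!r}")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    cost = draws.pivot("cost", perspective)
    qaly = draws.pivot("qaly", perspective)
    strategies = list(cost.columns)
    n = len(cost)
    probs = np.zeros((len(lambda_grid), len(strategies)))
    c = cost.to_numpy()
    q = qaly.to_numpy()
    for i, lam in enumerate(lambda_grid):
        net = lam * q - c
        if rule == "max_nmb":
            best = net.max(axis=1, keepdims=True)
            winners = net >= best - 1e-12
            probs[i] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n
        else:
            j = strategies.index(base_strategy)
            probs[i] = (net > net[:, [j]]).mean(axis=0)
            probs[i, j] = np.nan
    frame = pd.DataFrame(probs, index=lambda_grid, columns=strategies)
    frame.index.name = "lambda"
    return CeacCurve(lambdas=np.asarray(lambda_grid), probabilities=frame)


def ce_plane(draws: PsaDraws, base_strategy: str = NO_SCREENING, *,
             perspective: str = "societal") -> pd.DataFrame:
    """Per-draw incremental (QALY, cost) pairs against the comparator."""
    cost = draws.pivot("cost", perspective)
    qaly = draws.pivot("qaly", perspective)
    if base_strategy not in cost.columns:
        raise ValueError(f"base strategy {base_strategy!r} not in draws")
    records = []
    for sid in cost.columns:
        if sid == base_strategy:
            continue
        dq = qaly[sid] - qaly[base_strategy]
        dc = cost[sid] - cost[base_strategy]
        for d in cost.index:
            records.append((sid, d, dq.loc[d], dc.loc[d]))
    return pd.DataFrame(records,
                        columns=["strategy", "draw", "delta_qaly", "delta_cost"])


def quadrant_counts(plane: pd.DataFrame) -> pd.DataFrame:
    """Draw counts per CE-plane quadrant for each strategy.

    Quadrants: NE (more effective, dearer), SE (more effective, cheaper),
    NW, SW; boundary points (a zero difference) count toward the effective /
    dearer side by >= / > conventions stated here: dq >= 0 is 'E', dc >= 0
    is 'N'.
    """
    rows = []
    for sid, grp in plane.groupby("strategy"):
        east = grp["delta_qaly"] >= 0
        north = grp["delta_cost"] >= 0
        rows.append({
            "strategy": sid,
            "ne": int((east & north).sum()),
            "se": int((east & ~north).sum()),
            "nw": int((~east & north).sum()),
            "sw": int((~east & ~north).sum()),
        })
    return pd.DataFrame(rows).set_index("strategy")


# ---------------------------------------------------------------------------
# plotting (numeric CSVs are the contract; figures are a convenience)
# ---------------------------------------------------------------------------

def plot_ceac(curve: CeacCurve, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in curve.probabilities.columns:
        ax.plot(curve.lambdas, curve.probabilities[sid], label=sid)
    ax.set_xlabel("willingness to pay (US$/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(plane: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    for sid, grp in plane.groupby("strategy"):
        ax.scatter(grp["delta_qaly"], grp["delta_cost"], s=6, alpha=0.4, label=sid)
    ax.axhline(0.0, color="k", lw=0.6)
    ax.axvline(0.0, color="k", lw=0.6)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (US$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: Sequence[TornadoEntry], base_nmb: float,
                 path: str, top: int = 15) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    shown = list(entries[:top])[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.nmb_low, e.nmb_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    ax.axvline(base_nmb, color="k", lw=0.8)
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("incremental NMB (US$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
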