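"""Synthetic stand-ins for inputs that are not publicly deposited.

Three generators live here:

* a Gompertz-Makeham period life table calibrated to a life-expectancy
  target, replacing the national table the analysis would normally use;
* gamma-distributed patient-level annual treatment costs;
* five-dimension, five-level health-profile questionnaires valued by a
  configurable additive-decrement stub.

Alongside the generators sit the estimators that collapse microdata back
into (mean, SE) rows of the parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Single-age period life table: annual death probability by age."""

    ages: np.ndarray   # integer years 0..max_age
    qx: np.ndarray     # annual death probability, closed with qx[-1] == 1

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape or ages.ndim != 1:
            raise ValueError("ages and qx must be equal-length vectors")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ValueError("ages must be consecutive integers")
        if np.any(qx <= 0.0) or np.any(qx > 1.0):
            raise ValueError("every qx must lie in (0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("table must close with qx = 1 at the final age")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Death probability at integer ``age`` (1.0 beyond the table)."""
        if age > self.max_age:
            return 1.0
        i = age - int(self.ages[0])
        if i < 0:
            raise ValueError(f"age {age} below table start {self.ages[0]}")
        return float(self.qx[i])

    def survivorship(self) -> np.ndarray:
        """l(x): probability of surviving from the first age to each age."""
        lx = np.ones(len(self.ages) + 1)
        lx[1:] = np.cumprod(1.0 - self.qx)
        return lx[:-1]

    def life_expectancy(self, age: Optional[int] = None) -> float:
        """Period life expectancy at ``age`` (default: first tabulated age).

        Uses the trapezoid person-years approximation
        ``Lx = (l(x) + l(x+1)) / 2``.
        """
        start = int(self.ages[0]) if age is None else age
        i = start - int(self.ages[0])
        lx = np.ones(len(self.ages) + 1)
        lx[1:] = np.cumprod(1.0 - self.qx)
        big_l = 0.5 * (lx[:-1] + lx[1:])
        return float(big_l[i:].sum() / lx[i])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"}.issubset(df.columns):
            raise ValueError("life table CSV needs 'age' and 'qx' columns")
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def make_life_table(makeham_a: float, gompertz_b: float, makeham_c: float,
                    max_age: int = 100) -> LifeTable:
    """Life table from the Gompertz-Makeham hazard ``c + a e^{bx}``.

    ``qx = 1 - exp(-(c + a e^{bx}))`` at each integer age, with the closing
    row forced to 1.
    """
    if makeham_a <= 0.0 or gompertz_b <= 0.0 or makeham_c < 0.0:
        raise ValueError("require a > 0, b > 0, c >= 0")
    ages = np.arange(max_age + 1)
    hazard = makeham_c + makeham_a * np.exp(gompertz_b * ages)
    qx = 1.0 - np.exp(-hazard)
    if np.any(qx[:60] >= 1.0):
        raise ValueError("parameters give certain death before age 60")
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def calibrate_life_table(target_e0: float, gompertz_b: float = 0.095,
                         makeham_c: float = 5e-4, max_age: int = 100,
                         tol: float = 0.1) -> LifeTable:
    """Solve for ``makeham_a`` so life expectancy at birth hits ``target_e0``.

    Deterministic one-dimensional root find over log10(a); raises if the
    target cannot be bracketed with the given ``b`` and ``c``.
    """
    if not 40.0 < target_e0 < 95.0:
        raise ValueError("target_e0 must lie in (40, 95)")

    def gap(log_a: float) -> float:
        table = make_life_table(10.0 ** log_a, gompertz_b, makeham_c, max_age)
        return table.life_expectancy(0) - target_e0

    lo, hi = -9.0, -2.0
    if gap(lo) < 0.0 or gap(hi) > 0.0:
        raise ValueError(f"target e0={target_e0} not bracketable")
    log_a = brentq(gap, lo, hi, xtol=1e-10)
    table = make_life_table(10.0 ** log_a, gompertz_b, makeham_c, max_age)
    if abs(table.life_expectancy(0) - target_e0) > tol:
        raise ValueError("calibration failed to reach target within tolerance")
    return table


# ---------------------------------------------------------------------------
# cost microdata
# ---------------------------------------------------------------------------

def synth_cost_records(n: int, mean_cost: float, cv: float,
                       state_label: str = "diagnosed",
                       perspective_component: str = "medical",
                       seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Patient-level annual costs, gamma with given mean and CV.

    Returns a DataFrame with columns ``patient_id``, ``state_label``,
    ``perspective_component`` and ``annual_cost``.  ``cv = 0`` degenerates
    to every record equalling the mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_cost <= 0.0:
        raise ValueError("mean_cost must be > 0")
    if cv < 0.0:
        raise ValueError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cv == 0.0:
        costs = np.full(n, mean_cost)
    else:
        shape = 1.0 / (cv * cv)
        costs = rng.gamma(shape, mean_cost * cv * cv, size=n)
    return pd.DataFrame({
        "patient_id": np.arange(n),
        "state_label": state_label,
        "perspective_component": perspective_component,
        "annual_cost": costs,
    })


def estimate_mean_se(records, column: Optional[str] = None):
    """Arithmetic mean and standard error of the mean (sd / sqrt(n))."""
    if isinstance(records, pd.DataFrame):
        if column is None:
            for cand in ("annual_cost", "utility"):
                if cand in records.columns:
                    column = cand
                    break
            else:
                raise ValueError("no annual_cost or utility column found")
        x = records[column].to_numpy(dtype=float)
    else:
        x = np.asarray(records, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two records")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


# ---------------------------------------------------------------------------
# EQ-5D-style microdata
# ---------------------------------------------------------------------------

#: per-dimension decrement per level step; utility = 1 - sum coef * (level-1).
#: Placeholder coefficients only -- no fidelity to any national value set.
DEFAULT_VALUE_SET = (0.05, 0.05, 0.05, 0.07, 0.08)

_DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain", "anxiety")


def stub_utility(levels: Sequence[int],
                 value_set: Sequence[float] = DEFAULT_VALUE_SET) -> float:
    """Additive-decrement valuation: all-ones profile maps to exactly 1.0."""
    levels = np.asarray(levels)
    if levels.shape[-1] != len(value_set):
        raise ValueError("profile length must match value set")
    if np.any(levels < 1) or np.any(levels > 5):
        raise ValueError("levels must be integers in 1..5")
    return float(1.0 - np.dot(levels - 1, value_set))


def severity_for_mean_utility(target_utility: float,
                              value_set: Sequence[float] = DEFAULT_VALUE_SET) -> float:
    """Severity giving the requested expected utility under the level model."""
    total = 4.0 * float(np.sum(value_set))
    sev = (1.0 - target_utility) / total
    if not 0.0 <= sev <= 1.0:
        raise ValueError("target utility unreachable under this value set")
    return sev


def synth_eq5d(n: int, state_label: str, severity: float,
               value_set: Sequence[float] = DEFAULT_VALUE_SET,
               seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Synthetic five-level questionnaire responses with derived utilities.

    Each dimension's level is ``1 + Binomial(4, severity)``, so severity 0
    yields the all-ones profile (utility exactly 1) and the expected utility
    declines linearly in severity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = 1 + rng.binomial(4, severity, size=(n, len(value_set)))
    utility = 1.0 - (levels - 1) @ np.asarray(value_set, dtype=float)
    df = pd.DataFrame(levels, columns=list(_DIMENSIONS))
    df.insert(0, "patient_id", np.arange(n))
    df.insert(1, "state_label", state_label)
    df["utility"] = utility
    return df
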