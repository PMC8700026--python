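"""Model parameters: point estimates, PSA distributions, and DSA ranges.

Every quantity the model reads is declared as a :class:`ParameterSpec`
(mean, standard error, distribution family, one-way sensitivity rule).
Distributions are parameterized from the two published moments by the
method of moments; specs are sampled jointly and independently into a
:class:`ParameterSet`, the flat value object consumed by the cascade and
cohort engines.

A transcription of the published input table ships with the package
(``data/parameters.csv``) and is loaded by :func:`load_specs`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

DIST_KINDS = frozenset({"beta", "gamma", "normal", "lognormal", "fixed"})
DSA_RULES = frozenset({"pct20", "ci95", "none"})
DOMAINS = frozenset({"probability", "utility", "hba1c", "positive", "ratio", "real"})

#: draws of glycated-haemoglobin levels below this are clipped (nonphysical)
HBA1C_FLOOR = 4.0


class VarianceInfeasibleError(ValueError):
    """Requested (mean, se) cannot be matched by the requested family."""


# ---------------------------------------------------------------------------
# moment matching
# ---------------------------------------------------------------------------

def beta_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Return beta shapes ``(alpha, beta)`` matching an exact mean and SE.

    Uses ``k = mean (1 - mean) / se^2 - 1`` with ``alpha = mean k`` and
    ``beta = (1 - mean) k``.  ``se`` must be strictly positive and below the
    Bernoulli bound ``sqrt(mean (1 - mean))``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie strictly in (0,1), got {mean}")
    if se <= 0.0:
        raise ValueError("se must be > 0 for a proper beta; se = 0 is a point mass")
    if se * se >= mean * (1.0 - mean):
        raise VarianceInfeasibleError(
            f"se={se} too large for a beta with mean {mean}"
        )
    k = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * k, (1.0 - mean) * k


def gamma_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Return gamma ``(shape, scale)`` matching an exact mean and SE."""
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if se <= 0.0:
        raise ValueError("se must be > 0 for a proper gamma; se = 0 is a point mass")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_from_moments(mean: float, se: float) -> Tuple[float, float]:
    """Return log-scale ``(mu, sigma)`` whose arithmetic moments match.

    ``sigma^2 = ln(1 + (se/mean)^2)`` and ``mu = ln(mean) - sigma^2 / 2``.
    """
    if mean <= 0.0:
        raise ValueError(f"lognormal mean must be > 0, got {mean}")
    if se <= 0.0:
        raise ValueError("se must be > 0 for a proper lognormal; se = 0 is a point mass")
    sigma2 = math.log(1.0 + (se / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """One model input: point estimate plus uncertainty description."""

    name: str
    mean: float
    se: float = 0.0
    dist: str = "fixed"
    dsa_rule: str = "none"
    domain: str = "real"
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.dist not in DIST_KINDS:
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dsa_rule not in DSA_RULES:
            raise ValueError(f"{self.name}: unknown dsa rule {self.dsa_rule!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"{self.name}: unknown domain {self.domain!r}")
        if self.se < 0.0:
            raise ValueError(f"{self.name}: se must be >= 0")
        if self.se > 0.0:
            if self.dist == "beta":
                beta_from_moments(self.mean, self.se)  # validates feasibility
            elif self.dist == "gamma":
                gamma_from_moments(self.mean, self.se)
            elif self.dist == "lognormal":
                lognormal_from_moments(self.mean, self.se)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the fitted distribution (point mass when ``se == 0``)."""
        if self.se == 0.0 or self.dist == "fixed":
            return np.full(size, self.mean) if size is not None else self.mean
        if self.dist == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return rng.beta(a, b, size)
        if self.dist == "gamma":
            shape, scale = gamma_from_moments(self.mean, self.se)
            return rng.gamma(shape, scale, size)
        if self.dist == "normal":
            return rng.normal(self.mean, self.se, size)
        if self.dist == "lognormal":
            mu, sigma = lognormal_from_moments(self.mean, self.se)
            return rng.lognormal(mu, sigma, size)
        raise AssertionError("unreachable")


def _domain_limits(domain: str) -> Tuple[float, float]:
    if domain in ("probability", "utility"):
        return 0.0, 1.0
    if domain == "hba1c":
        return HBA1C_FLOOR, math.inf
    if domain in ("positive", "ratio"):
        return 0.0, math.inf
    return -math.inf, math.inf


def clip_to_domain(value: float, domain: str) -> float:
    lo, hi = _domain_limits(domain)
    return min(max(value, lo), hi)


def dsa_bounds(spec: ParameterSpec) -> Tuple[float, float]:
    """Low/high values for one-way sensitivity analysis.

    ``pct20`` gives mean +/- 20%; ``ci95`` gives mean -/+ 1.96 SE.  Both are
    clipped to the parameter's domain, so the bounds always bracket the mean.
    """
    if spec.dsa_rule == "none":
        raise ValueError(f"{spec.name}: no DSA rule defined")
    if spec.dsa_rule == "pct20":
        lo, hi = 0.8 * spec.mean, 1.2 * spec.mean
    else:  # ci95
        lo, hi = spec.mean - 1.96 * spec.se, spec.mean + 1.96 * spec.se
    lo = clip_to_domain(min(lo, spec.mean), spec.domain)
    hi = clip_to_domain(max(hi, spec.mean), spec.domain)
    return lo, hi


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

_PREV_PREFIX = "prev_t2dm_"

_SCALAR_FIELDS = (
    "sens_findrisc", "spec_findrisc",
    "sens_fcg", "spec_fcg",
    "sens_fpg", "spec_fpg",
    "hba1c_undx", "hba1c_dx", "hba1c_comp",
    "rr_death_t2dm", "rr_death_per_hba1c", "rr_comp_per_hba1c",
    "p_ngt_undx", "p_ngt_dx", "p_undx_dx", "p_undx_comp", "p_dx_comp",
    "cost_test_findrisc", "cost_test_fcg", "cost_test_fpg",
    "cost_visit_chs", "cost_visit_dhc",
    "cost_tx_dx_med", "cost_tx_undx_med", "cost_tx_comp_med",
    "cost_tx_dx_nonmed", "cost_tx_undx_nonmed", "cost_tx_comp_nonmed",
    "u_ngt", "u_undx", "u_dx", "u_comp",
    "adherence_referral",
)


@dataclass
class ParameterSet:
    """Flat bundle of every value the screening and cohort engines read."""

    prevalence: Dict[int, float]
    sens_findrisc: float
    spec_findrisc: float
    sens_fcg: float
    spec_fcg: float
    sens_fpg: float
    spec_fpg: float
    hba1c_undx: float
    hba1c_dx: float
    hba1c_comp: float
    rr_death_t2dm: float
    rr_death_per_hba1c: float
    rr_comp_per_hba1c: float
    p_ngt_undx: float
    p_ngt_dx: float
    p_undx_dx: float
    p_undx_comp: float
    p_dx_comp: float
    cost_test_findrisc: float
    cost_test_fcg: float
    cost_test_fpg: float
    cost_visit_chs: float
    cost_visit_dhc: float
    cost_tx_dx_med: float
    cost_tx_undx_med: float
    cost_tx_comp_med: float
    cost_tx_dx_nonmed: float
    cost_tx_undx_nonmed: float
    cost_tx_comp_nonmed: float
    u_ngt: float
    u_undx: float
    u_dx: float
    u_comp: float
    adherence_referral: float = 1.0

    @classmethod
    def from_values(cls, values: Mapping[str, float]) -> "ParameterSet":
        prevalence = {
            int(name[len(_PREV_PREFIX):]): float(v)
            for name, v in values.items()
            if name.startswith(_PREV_PREFIX)
        }
        if not prevalence:
            raise ValueError("no prevalence entries (prev_t2dm_<age>) supplied")
        kwargs = {}
        for fname in _SCALAR_FIELDS:
            if fname in values:
                kwargs[fname] = float(values[fname])
            elif fname == "adherence_referral":
                kwargs[fname] = 1.0
            else:
                raise ValueError(f"missing parameter {fname!r}")
        return cls(prevalence=prevalence, **kwargs)

    def to_values(self) -> Dict[str, float]:
        out = {f"{_PREV_PREFIX}{age}": p for age, p in sorted(self.prevalence.items())}
        for fname in _SCALAR_FIELDS:
            out[fname] = getattr(self, fname)
        return out

    def prevalence_for(self, age: int) -> float:
        """Prevalence at the nearest tabulated starting age <= ``age``."""
        if age in self.prevalence:
            return self.prevalence[age]
        below = [a for a in self.prevalence if a <= age]
        key = max(below) if below else min(self.prevalence)
        return self.prevalence[key]

    def validate(self) -> None:
        for name in ("sens_findrisc", "spec_findrisc", "sens_fcg", "spec_fcg",
                     "sens_fpg", "spec_fpg", "p_ngt_undx", "p_ngt_dx",
                     "p_undx_dx", "p_undx_comp", "p_dx_comp",
                     "u_ngt", "u_undx", "u_dx", "u_comp", "adherence_referral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for v in self.prevalence.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("prevalence outside [0,1]")
        for name in ("cost_test_findrisc", "cost_test_fcg", "cost_test_fpg",
                     "cost_visit_chs", "cost_visit_dhc",
                     "cost_tx_dx_med", "cost_tx_undx_med", "cost_tx_comp_med",
                     "cost_tx_dx_nonmed", "cost_tx_undx_nonmed",
                     "cost_tx_comp_nonmed"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Constants:
    """Run-level constants shared by every scenario."""

    discount_rate: float = 0.03
    wtp_threshold: float = 2715.3      # one GDP per capita, US$/QALY
    fx_rate: float = 23143.0           # VND per US$
    cycle_length: float = 1.0
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.discount_rate < 0.0:
            raise ValueError("discount_rate must be >= 0")
        if self.wtp_threshold <= 0.0:
            raise ValueError("wtp_threshold must be > 0")


# ---------------------------------------------------------------------------
# loading and sampling
# ---------------------------------------------------------------------------

def load_specs(path: Optional[str | Path] = None,
               cost_se_mode: str = "patient_variance") -> Dict[str, ParameterSpec]:
    """Load parameter specs from CSV (packaged table by default).

    ``cost_se_mode`` controls how the dispersion column of primary-data cost
    rows is read: ``"patient_variance"`` (default) treats it as the
    patient-level variance in US$^2 and converts to an SE of the mean using
    the row's sample size; ``"raw_se"`` takes it at face value.
    """
    if cost_se_mode not in ("patient_variance", "raw_se"):
        raise ValueError(f"unknown cost_se_mode {cost_se_mode!r}")
    if path is None:
        ref = resources.files("t2dscreen.data").joinpath("parameters.csv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    specs: Dict[str, ParameterSpec] = {}
    for row in csv.DictReader(text.splitlines()):
        se = float(row["se"])
        if row.get("se_kind") == "patient_variance" and cost_se_mode == "patient_variance":
            n = float(row["n_obs"])
            se = math.sqrt(se / n)
        spec = ParameterSpec(
            name=row["name"],
            mean=float(row["mean"]),
            se=se,
            dist=row["dist"],
            dsa_rule=row["dsa_rule"],
            domain=row["domain"],
            units=row.get("units", ""),
            source=row.get("source", ""),
        )
        if spec.name in specs:
            raise ValueError(f"duplicate parameter {spec.name!r}")
        specs[spec.name] = spec
    return specs


def base_parameter_set(specs: Mapping[str, ParameterSpec]) -> ParameterSet:
    """Point-estimate ParameterSet (every value at its mean)."""
    ps = ParameterSet.from_values({name: s.mean for name, s in specs.items()})
    ps.validate()
    return ps


def sample_parameter_set(specs: Mapping[str, ParameterSpec],
                         seed: int | np.random.Generator) -> ParameterSet:
    """One joint independent draw of all parameters.

    Reproducible under a fixed integer seed.  Draws that leave a parameter's
    physical domain (a normal HbA1c below the floor, a probability outside
    the unit interval) are clipped and the event logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: Dict[str, float] = {}
    for name in sorted(specs):
        spec = specs[name]
        x = float(spec.sample(rng))
        clipped = clip_to_domain(x, spec.domain)
        if clipped != x:
            log.info("draw for %s clipped from %g to %g", name, x, clipped)
        values[name] = clipped
    ps = ParameterSet.from_values(values)
    ps.validate()
    return ps
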