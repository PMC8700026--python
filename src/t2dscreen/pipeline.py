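"""Scenario-grid orchestration: config validation, fan-out, reporting."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import econ_eval
from .econ_eval import DEFAULT_WTP, icer, nmb
from .markov import EconOutcome, evaluate_strategy
from .params import base_parameter_set, load_specs
from .screening import INTERVALS, PERSPECTIVES, SETTINGS, ScreeningStrategy
from .synthetic_data import LifeTable, calibrate_life_table
from .uncertainty import NO_SCREENING

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "params_path", "cost_se_mode", "life_table_path", "life_table_e0",
    "ages", "intervals", "settings", "perspectives", "wtp",
    "adherence_referral", "discount_rate", "max_age",
    "psa_n", "seed", "out_dir",
}

RESULT_COLUMNS = [
    "strategy", "setting", "interval", "start_age", "perspective",
    "screening_cost", "treatment_cost", "total_cost", "ly", "qaly",
    "delta_cost", "delta_ly", "delta_qaly", "icer", "flag",
    "nmb", "incremental_nmb",
]


@dataclass
class RunConfig:
    """Validated, normalized run configuration."""

    params_path: Optional[str] = None
    cost_se_mode: str = "patient_variance"
    life_table_path: Optional[str] = None
    life_table_e0: float = 73.6
    ages: List[int] = field(default_factory=lambda: [40])
    intervals: List[str] = field(default_factory=lambda: list(INTERVALS))
    settings: List[str] = field(default_factory=lambda: list(SETTINGS))
    perspectives: List[str] = field(default_factory=lambda: list(PERSPECTIVES))
    wtp: float = DEFAULT_WTP
    adherence_referral: Optional[float] = None
    discount_rate: float = 0.03
    max_age: int = 100
    psa_n: int = 1000
    seed: int = 12345
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(raw: Optional[dict]) -> RunConfig:
    """Normalize a raw config mapping, applying defaults and checking values."""
    raw = dict(raw or {})
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for name in ("ages", "intervals", "settings", "perspectives"):
        if not getattr(cfg, name):
            raise ValueError(f"config field {name!r} must be a non-empty list")
    cfg.ages = [int(a) for a in cfg.ages]
    for iv in cfg.intervals:
        if iv not in INTERVALS:
            raise ValueError(f"unknown interval {iv!r}")
    for st in cfg.settings:
        if st not in SETTINGS:
            raise ValueError(f"unknown setting {st!r}")
    for p in cfg.perspectives:
        if p not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {p!r}")
    for path_attr in ("params_path", "life_table_path"):
        path = getattr(cfg, path_attr)
        if path is not None and not Path(path).exists():
            raise ValueError(f"{path_attr} does not exist: {path}")
    if not isinstance(cfg.seed, int):
        raise ValueError("seed must be an integer")
    if cfg.psa_n < 1:
        raise ValueError("psa_n must be >= 1")
    if any(a >= cfg.max_age for a in cfg.ages):
        raise ValueError("every starting age must be below max_age")
    return cfg


def load_config_file(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def resolve_life_table(config: RunConfig) -> LifeTable:
    if config.life_table_path is not None:
        return LifeTable.from_csv(config.life_table_path)
    return calibrate_life_table(config.life_table_e0, max_age=config.max_age)


def grid_strategies(config: RunConfig, start_age: int) -> List[ScreeningStrategy]:
    return [
        ScreeningStrategy(setting=st, interval=iv, start_age=start_age,
                          adherence_referral=config.adherence_referral)
        for iv in config.intervals for st in config.settings
    ]


def run_grid(config: RunConfig) -> pd.DataFrame:
    """Evaluate every (age, interval, setting, perspective) cell plus the
    no-screening comparator per (age, perspective); write outputs if
    ``out_dir`` is set."""
    specs = load_specs(config.params_path, cost_se_mode=config.cost_se_mode)
    params = base_parameter_set(specs)
    life_table = resolve_life_table(config)

    rows = []
    for age in config.ages:
        base = evaluate_strategy(None, age, params, life_table,
                                 discount_rate=config.discount_rate,
                                 max_age=config.max_age)
        cells: Dict[str, Dict[str, EconOutcome]] = {}
        for strat in grid_strategies(config, age):
            cells[strat.label] = evaluate_strategy(
                strat, age, params, life_table,
                discount_rate=config.discount_rate, max_age=config.max_age)
        for persp in config.perspectives:
            o = base[persp]
            base_nmb = nmb(o, config.wtp)
            rows.append({
                "strategy": NO_SCREENING, "setting": "", "interval": "",
                "start_age": age, "perspective": persp,
                "screening_cost": o.screening_cost,
                "treatment_cost": o.treatment_cost,
                "total_cost": o.total_cost, "ly": o.total_ly,
                "qaly": o.total_qaly, "delta_cost": 0.0, "delta_ly": 0.0,
                "delta_qaly": 0.0, "icer": None, "flag": "comparator",
                "nmb": base_nmb, "incremental_nmb": 0.0,
            })
            for strat in grid_strategies(config, age):
                o = cells[strat.label][persp]
                cmp = icer(base[persp], o)
                strat_nmb = nmb(o, config.wtp)
                rows.append({
                    "strategy": strat.label, "setting": strat.setting,
                    "interval": strat.interval, "start_age": age,
                    "perspective": persp,
                    "screening_cost": o.screening_cost,
                    "treatment_cost": o.treatment_cost,
                    "total_cost": o.total_cost, "ly": o.total_ly,
                    "qaly": o.total_qaly, "delta_cost": cmp.delta_cost,
                    "delta_ly": cmp.delta_ly, "delta_qaly": cmp.delta_qaly,
                    "icer": cmp.icer, "flag": cmp.flag,
                    "nmb": strat_nmb,
                    "incremental_nmb": strat_nmb - base_nmb,
                })
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        summary = {
            "config": config.to_dict(),
            "n_rows": len(table),
            "best_by_nmb": {},
        }
        for (age, persp), grp in table.groupby(["start_age", "perspective"]):
            best = grp.loc[grp["nmb"].idxmax()]
            summary["best_by_nmb"][f"age{age}_{persp}"] = str(best["strategy"])
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("grid results written to %s (%d rows)", out, len(table))
    return table
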