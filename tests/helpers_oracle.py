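"""Independent oracles kept deliberately separate from the package code.

* ``enumerate_cascade``: explicit leaf-by-leaf enumeration of the screening
  decision trees (probabilities and costs per path).
* ``microsimulate``: individual-level Monte Carlo of the cohort model using
  only per-row transition sampling.
"""

from __future__ import annotations

import numpy as np

from t2dscreen.markov import transition_matrix
from t2dscreen.screening import misclassification_outcomes


def enumerate_cascade(setting, true_state, params, adherence=1.0):
    """All leaf paths of one screening round: (probability, cost dict) pairs."""
    diseased = true_state == "diseased"
    p_fr = params.sens_findrisc if diseased else 1.0 - params.spec_findrisc
    leaves = []

    if setting == "CHS":
        base = {"societal": params.cost_test_findrisc + params.cost_visit_chs,
                "provider": params.cost_test_findrisc}
        # FINDRISC negative
        leaves.append((1.0 - p_fr, base, False))
        p_fcg = params.sens_fcg if diseased else 1.0 - params.spec_fcg
        after_fcg = {k: v + params.cost_test_fcg for k, v in base.items()}
        # FINDRISC positive, FCG negative
        leaves.append((p_fr * (1.0 - p_fcg), after_fcg, False))
        # FCG positive, referral not followed
        leaves.append((p_fr * p_fcg * (1.0 - adherence), after_fcg, False))
        p_fpg = params.sens_fpg if diseased else 1.0 - params.spec_fpg
        confirmed = {
            "societal": after_fcg["societal"] + params.cost_test_fpg + params.cost_visit_dhc,
            "provider": after_fcg["provider"] + params.cost_test_fpg,
        }
        # referred, FPG negative / positive
        leaves.append((p_fr * p_fcg * adherence * (1.0 - p_fpg), confirmed, False))
        leaves.append((p_fr * p_fcg * adherence * p_fpg, confirmed, True))
    else:
        base = {"societal": params.cost_test_findrisc + params.cost_visit_dhc,
                "provider": params.cost_test_findrisc}
        leaves.append((1.0 - p_fr, base, False))
        p_fpg = params.sens_fpg if diseased else 1.0 - params.spec_fpg
        one_fpg = {k: v + params.cost_test_fpg for k, v in base.items()}
        leaves.append((p_fr * (1.0 - p_fpg), one_fpg, False))
        two_fpg = {k: v + params.cost_test_fpg for k, v in one_fpg.items()}
        leaves.append((p_fr * p_fpg * (1.0 - p_fpg), two_fpg, False))
        leaves.append((p_fr * p_fpg * p_fpg, two_fpg, True))
    return leaves


def cascade_summary(setting, true_state, params, adherence=1.0):
    """Total probability, expected costs, and full-cascade-positive rate."""
    leaves = enumerate_cascade(setting, true_state, params, adherence)
    total_p = sum(p for p, _, _ in leaves)
    expected = {
        persp: sum(p * cost[persp] for p, cost, _ in leaves)
        for persp in ("societal", "provider")
    }
    p_positive = sum(p for p, _, positive in leaves if positive)
    return total_p, expected, p_positive


def microsimulate(n_persons, config, params, life_table, seed):
    """Individual-level cohort simulation; returns occupancy proportions."""
    rng = np.random.default_rng(seed)
    n = config.max_age - config.start_age
    strategy = config.strategy
    cascade = misclassification_outcomes(strategy, params) if strategy else None
    screen_cycles = strategy.screening_cycles(n) if strategy else frozenset()
    prev = params.prevalence_for(config.start_age)
    states = np.where(rng.random(n_persons) < prev, 1, 0).astype(np.int64)
    occ = np.zeros((n + 1, 5))
    for t in range(n + 1):
        occ[t] = np.bincount(states, minlength=5) / n_persons
        if t == n:
            break
        p_mat = transition_matrix(config.start_age + t, t in screen_cycles,
                                  cascade, params, life_table)
        cum = p_mat.cumsum(axis=1)
        u = rng.random(n_persons)
        states = (u[:, None] > cum[states]).sum(axis=1)
    return occ
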