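"""Decision metrics: ICER with dominance flags, NMB ranking, frontier."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

from .markov import EconOutcome

DEFAULT_WTP = 2715.3  # US$/QALY, one GDP per capita


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of an alternative against a comparator."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: Optional[float]
    flag: str

    @property
    def is_dominant(self) -> bool:
        return self.flag == "dominant"


def icer(base: EconOutcome, alt: EconOutcome) -> ComparisonResult:
    """Classify the incremental comparison ``alt`` vs ``base``.

    Quadrants: more effective and cheaper -> ``dominant``; less effective
    and dearer -> ``dominated``; otherwise a ratio, tagged ``icer`` in the
    north-east and ``icer_sw`` in the south-west.  A zero QALY difference
    never divides: it yields an order flag instead.
    """
    if base.perspective != alt.perspective:
        raise ValueError("comparison requires a common perspective")
    dc = alt.total_cost - base.total_cost
    dq = alt.total_qaly - base.total_qaly
    dly = alt.total_ly - base.total_ly
    if dq == 0.0:
        if dc > 0.0:
            flag = "dominated-or-equal"
        elif dc < 0.0:
            flag = "dominant-or-equal"
        else:
            flag = "equal"
        return ComparisonResult(dc, dq, dly, None, flag)
    if dq > 0.0:
        if dc < 0.0:
            return ComparisonResult(dc, dq, dly, None, "dominant")
        return ComparisonResult(dc, dq, dly, dc / dq, "icer")
    if dc > 0.0:
        return ComparisonResult(dc, dq, dly, None, "dominated")
    return ComparisonResult(dc, dq, dly, dc / dq, "icer_sw")


def nmb(outcome: EconOutcome, wtp: float = DEFAULT_WTP) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``."""
    if wtp < 0.0:
        raise ValueError("wtp must be >= 0")
    return wtp * outcome.total_qaly - outcome.total_cost


@dataclass(frozen=True)
class NMBRow:
    strategy: str
    nmb: float
    rank: int
    tied: bool = False


def rank_strategies(outcomes: Mapping[str, EconOutcome],
                    wtp: float = DEFAULT_WTP) -> List[NMBRow]:
    """Strategies ordered by descending NMB.

    Ties are broken by lower total cost, then lexical strategy id, and are
    flagged on every member of the tie.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to rank")
    scored = [(nmb(o, wtp), o.total_cost, sid) for sid, o in outcomes.items()]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    nmbs = [s[0] for s in scored]
    rows = []
    for i, (value, _, sid) in enumerate(scored):
        tied = (i > 0 and nmbs[i - 1] == value) or \
               (i + 1 < len(nmbs) and nmbs[i + 1] == value)
        rows.append(NMBRow(strategy=sid, nmb=value, rank=i + 1, tied=tied))
    return rows


@dataclass(frozen=True)
class FrontierEntry:
    strategy: str
    cost: float
    qaly: float
    icer_vs_previous: Optional[float]  # None for the cheapest survivor


def incremental_frontier(outcomes: Mapping[str, EconOutcome]) -> List[FrontierEntry]:
    """Efficient frontier with stepwise ICERs between adjacent survivors.

    Strategies are ordered by cost; strictly dominated options (dearer, not
    more effective) are dropped, then extended dominance removes any option
    whose incoming stepwise ICER is not below the outgoing one.  Resulting
    ICERs are strictly increasing along the frontier.
    """
    if not outcomes:
        raise ValueError("no strategies supplied")
    items = sorted(
        ((o.total_cost, -o.total_qaly, sid) for sid, o in outcomes.items())
    )
    pts: List[tuple] = []
    best_q = -float("inf")
    for cost, negq, sid in items:
        q = -negq
        if q > best_q:
            pts.append((sid, cost, q))
            best_q = q
    # extended dominance: incoming ICER must be below outgoing ICER
    changed = True
    while changed and len(pts) > 2:
        changed = False
        for i in range(1, len(pts) - 1):
            icer_in = (pts[i][1] - pts[i - 1][1]) / (pts[i][2] - pts[i - 1][2])
            icer_out = (pts[i + 1][1] - pts[i][1]) / (pts[i + 1][2] - pts[i][2])
            if icer_in >= icer_out:
                del pts[i]
                changed = True
                break
    entries = []
    for i, (sid, cost, q) in enumerate(pts):
        step = None
        if i > 0:
            step = (cost - pts[i - 1][1]) / (q - pts[i - 1][2])
        entries.append(FrontierEntry(strategy=sid, cost=cost, qaly=q,
                                     icer_vs_previous=step))
    return entries
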