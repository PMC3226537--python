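"""Incremental cost-effectiveness analysis.

ICERs, strong/extended dominance classification, the cost-effectiveness
frontier, and a net-monetary-benefit sweep over a willingness-to-pay grid
(EUR per asthma case avoided).  Net-benefit ties are broken in favour of the
cheaper strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from asthmacea.tree_engine import StrategyExpectation

STRONGLY_DOMINATED = "strongly_dominated"
DOMINANT = "dominant"
EXTENDEDLY_DOMINATED = "extendedly_dominated"
EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of a comparator strategy against a reference.

    Exactly one of ``icer`` and ``dominance`` is set: the ICER exists only
    when the effect difference is non-zero and neither strategy dominates.
    """

    comparator: str
    reference: str
    delta_cost: float
    delta_effect: float
    icer: Optional[float] = None
    dominance: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.icer is None) == (self.dominance is None):
            raise ValueError("exactly one of icer and dominance must be set")

    @property
    def icer_rounded_thousand(self) -> Optional[float]:
        """ICER rounded to the nearest 1,000 EUR (headline figure)."""
        if self.icer is None:
            return None
        return round(self.icer / 1000.0) * 1000.0


def _compare(comp: StrategyExpectation, ref: StrategyExpectation) -> IncrementalResult:
    d_cost = comp.expected_cost - ref.expected_cost
    d_eff = comp.p_asthma_avoided - ref.p_asthma_avoided
    kwargs = dict(
        comparator=comp.strategy,
        reference=ref.strategy,
        delta_cost=d_cost,
        delta_effect=d_eff,
    )
    if d_cost == 0.0 and d_eff == 0.0:
        return IncrementalResult(dominance=EQUIVALENT, **kwargs)
    if d_cost <= 0.0 and d_eff >= 0.0:
        return IncrementalResult(dominance=DOMINANT, **kwargs)
    if d_cost >= 0.0 and d_eff <= 0.0:
        return IncrementalResult(dominance=STRONGLY_DOMINATED, **kwargs)
    # remaining quadrants: both differences non-zero with the same sign
    return IncrementalResult(icer=d_cost / d_eff, **kwargs)


def incremental_analysis(
    expectations: Sequence[StrategyExpectation], reference: str
) -> list[IncrementalResult]:
    """Compare every non-reference strategy against the reference.

    Dominance labels follow the payer convention: a comparator that is
    costlier and no more effective is strongly dominated; one that is
    cheaper and at least as effective is dominant.
    """
    labels = [e.strategy for e in expectations]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strategy labels: {sorted(labels)}")
    if reference not in labels:
        raise ValueError(f"reference strategy {reference!r} not among {sorted(labels)}")
    if len(expectations) < 2:
        raise ValueError("incremental analysis requires at least two strategies")
    ref = next(e for e in expectations if e.strategy == reference)
    return [_compare(e, ref) for e in expectations if e.strategy != reference]


@dataclass(frozen=True)
class FrontierEntry:
    expectation: StrategyExpectation
    icer_vs_previous: Optional[float]  # None for the cheapest frontier member


@dataclass(frozen=True)
class FrontierResult:
    frontier: tuple[FrontierEntry, ...]
    excluded: dict[str, str]  # strategy label -> dominance reason


def efficient_frontier(
    expectations: Sequence[StrategyExpectation],
) -> FrontierResult:
    """Cost-effectiveness frontier with dominance classification.

    Strategies are sorted by cost; strongly dominated ones are removed,
    then extendedly dominated ones (ICER strictly higher than the next more
    effective option) are removed iteratively.  The surviving frontier has
    non-decreasing cost and effect and strictly increasing ICERs.
    """
    if not expectations:
        raise ValueError("efficient_frontier requires at least one strategy")
    labels = [e.strategy for e in expectations]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strategy labels: {sorted(labels)}")

    excluded: dict[str, str] = {}
    candidates = sorted(
        expectations, key=lambda e: (e.expected_cost, -e.p_asthma_avoided)
    )

    def dominates(a: StrategyExpectation, b: StrategyExpectation) -> bool:
        return (
            a.expected_cost <= b.expected_cost
            and a.p_asthma_avoided >= b.p_asthma_avoided
            and (
                a.expected_cost < b.expected_cost
                or a.p_asthma_avoided > b.p_asthma_avoided
            )
        )

    surviving = []
    for e in candidates:
        if any(dominates(other, e) for other in expectations if other is not e):
            excluded[e.strategy] = STRONGLY_DOMINATED
        else:
            surviving.append(e)

    # exact-tie duplicates: keep the first, label the rest equivalent
    deduped: list[StrategyExpectation] = []
    for e in surviving:
        if deduped and (
            e.expected_cost == deduped[-1].expected_cost
            and e.p_asthma_avoided == deduped[-1].p_asthma_avoided
        ):
            excluded[e.strategy] = EQUIVALENT
        else:
            deduped.append(e)

    def icer(a: StrategyExpectation, b: StrategyExpectation) -> float:
        return (b.expected_cost - a.expected_cost) / (
            b.p_asthma_avoided - a.p_asthma_avoided
        )

    changed = True
    while changed and len(deduped) > 2:
        changed = False
        for i in range(1, len(deduped) - 1):
            if icer(deduped[i - 1], deduped[i]) > icer(deduped[i], deduped[i + 1]):
                excluded[deduped[i].strategy] = EXTENDEDLY_DOMINATED
                del deduped[i]
                changed = True
                break

    entries = [
        FrontierEntry(
            expectation=e,
            icer_vs_previous=None if i == 0 else icer(deduped[i - 1], e),
        )
        for i, e in enumerate(deduped)
    ]
    return FrontierResult(frontier=tuple(entries), excluded=excluded)


def net_benefit(expectation: StrategyExpectation, wtp: float) -> float:
    """Net monetary benefit ``wtp * p_asthma_avoided - expected_cost``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * expectation.p_asthma_avoided - expectation.expected_cost


@dataclass(frozen=True)
class ThresholdCurve:
    """Net monetary benefit per strategy over a willingness-to-pay grid."""

    lambdas: tuple[float, ...]
    nmb: dict[str, tuple[float, ...]]  # strategy -> NMB per grid point
    optimal: tuple[str, ...]  # argmax strategy per grid point

    def to_dict(self) -> dict:
        return {
            "lambdas": list(self.lambdas),
            "nmb": {k: list(v) for k, v in self.nmb.items()},
            "optimal": list(self.optimal),
        }


def threshold_sweep(
    expectations: Sequence[StrategyExpectation],
    lambda_min: float = 0.0,
    lambda_max: float = 70_000.0,
    step: float = 1_000.0,
) -> ThresholdCurve:
    """Evaluate net benefit for every strategy on an inclusive grid.

    The optimum at each grid point maximises net benefit; exact ties go to
    the cheaper strategy.
    """
    if not expectations:
        raise ValueError("threshold_sweep requires at least one strategy")
    if lambda_min < 0 or lambda_min > lambda_max or step <= 0:
        raise ValueError(
            f"invalid grid: lambda_min={lambda_min}, lambda_max={lambda_max}, step={step}"
        )
    labels = [e.strategy for e in expectations]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strategy labels: {sorted(labels)}")

    grid: list[float] = []
    k = 0
    while True:
        lam = lambda_min + k * step
        if lam > lambda_max * (1 + 1e-12) + 1e-9:
            break
        grid.append(min(lam, lambda_max))
        k += 1

    nmb = {e.strategy: tuple(net_benefit(e, lam) for lam in grid) for e in expectations}
    optimal = []
    for i in range(len(grid)):
        best = max(
            expectations,
            key=lambda e: (nmb[e.strategy][i], -e.expected_cost, e.p_asthma_avoided),
        )
        optimal.append(best.strategy)
    return ThresholdCurve(lambdas=tuple(grid), nmb=nmb, optimal=tuple(optimal))
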