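"""Decision-tree construction, branch-probability estimation and fold-back.

The canonical chance structure per care strategy is::

    symptoms? --symptomatic--> pharmacotherapy? --treated----> diagnosis
              |                                 --untreated--> diagnosis
              --asymptomatic------------------------------->   diagnosis

Branch probabilities are empirical ratios of one situation over its sum
with the complement; terminal payoffs are the mean observed per-child cost
on the path and the binary diagnosis outcome.  Empty cells (a chance node
reached by no record) are handled by a configurable policy: error out,
additive pseudo-count smoothing, or branch collapse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, TYPE_CHECKING

from asthmacea.costing import UnitPriceTable, child_cost
from asthmacea.diagnosis import (
    AsthmaStatus,
    DiagnosisConfig,
    DiagnosticProfile,
    classify_asthma,
    is_evaluable,
)

if TYPE_CHECKING:  # pragma: no cover
    from asthmacea.cohort_prep import ChildRecord

logger = logging.getLogger(__name__)

PROB_SUM_TOL = 1e-12

EMPTY_CELL_POLICIES = ("strict", "additive", "collapse")


class TreeError(ValueError):
    pass


class EmptyCellError(TreeError):
    def __init__(self, branch: str):
        self.branch = branch
        super().__init__(f"empty cell: no records reach branch point {branch!r}")


@dataclass
class Branch:
    label: str
    probability: Optional[float]  # None under a decision node
    node: "TreeNode"


@dataclass
class TreeNode:
    """A decision, chance or terminal node.

    Terminal nodes carry a payoff ``(cost, asthma)``; chance nodes carry
    probability-weighted branches summing to one; decision nodes carry
    unweighted branches and cannot be folded back directly.
    """

    kind: str  # decision | chance | terminal
    label: str
    branches: list[Branch] = field(default_factory=list)
    payoff: Optional[tuple[float, bool]] = None

    def validate(self) -> None:
        if self.kind not in ("decision", "chance", "terminal"):
            raise TreeError(f"unknown node kind {self.kind!r} at {self.label!r}")
        if self.kind == "terminal":
            if self.branches:
                raise TreeError(f"terminal node {self.label!r} has children")
            if self.payoff is None:
                raise TreeError(f"terminal node {self.label!r} has no payoff")
            cost, asthma = self.payoff
            if not isinstance(asthma, bool):
                raise TreeError(f"terminal node {self.label!r}: asthma payoff must be boolean")
            return
        if not self.branches:
            raise TreeError(f"{self.kind} node {self.label!r} has no branches")
        if self.kind == "chance":
            total = 0.0
            for br in self.branches:
                if br.probability is None or not (0.0 <= br.probability <= 1.0):
                    raise TreeError(
                        f"chance node {self.label!r}, branch {br.label!r}: "
                        f"probability {br.probability!r} outside [0, 1]"
                    )
                total += br.probability
            if abs(total - 1.0) > PROB_SUM_TOL:
                raise TreeError(
                    f"chance node {self.label!r}: branch probabilities sum to "
                    f"{total!r}, not 1"
                )
        else:  # decision
            for br in self.branches:
                if br.probability is not None:
                    raise TreeError(
                        f"decision node {self.label!r} carries a probability on "
                        f"branch {br.label!r}"
                    )
        for br in self.branches:
            br.node.validate()

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "label": self.label}
        if self.kind == "terminal":
            cost, asthma = self.payoff  # type: ignore[misc]
            d["payoff"] = {"cost": cost, "asthma": asthma}
        else:
            d["branches"] = [
                {
                    "label": br.label,
                    "probability": br.probability,
                    "node": br.node.to_dict(),
                }
                for br in self.branches
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if d["kind"] == "terminal":
            payoff = (float(d["payoff"]["cost"]), bool(d["payoff"]["asthma"]))
            return cls(kind="terminal", label=d["label"], payoff=payoff)
        branches = [
            Branch(
                label=bd["label"],
                probability=bd["probability"],
                node=cls.from_dict(bd["node"]),
            )
            for bd in d["branches"]
        ]
        return cls(kind=d["kind"], label=d["label"], branches=branches)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class StrategyExpectation:
    """Folded-back expected cost and probability of asthma avoidance."""

    strategy: str
    expected_cost: float
    p_asthma_avoided: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_asthma_avoided <= 1.0):
            raise ValueError(
                f"p_asthma_avoided must be in [0, 1], got {self.p_asthma_avoided}"
            )
        if self.expected_cost < 0:
            raise ValueError(f"expected_cost must be >= 0, got {self.expected_cost}")


def estimate_branch_probability(
    n_event: int,
    n_complement: int,
    smoothing: str = "additive",
    pseudo_count: float = 0.5,
) -> float:
    """Empirical branch probability ``n_event / (n_event + n_complement)``.

    With a positive denominator the raw ratio is returned unchanged.  When
    both counts are zero the configured empty-cell policy applies:
    ``strict`` raises :class:`EmptyCellError`, ``additive`` returns the
    symmetric smoothed estimate (0.5 for the default pseudo-count), and
    ``collapse`` raises because collapsing is structural — the caller must
    prune the branch instead of estimating it.
    """
    if smoothing not in EMPTY_CELL_POLICIES:
        raise ValueError(f"unknown empty-cell policy {smoothing!r}")
    if n_event < 0 or n_complement < 0:
        raise ValueError("counts must be >= 0")
    total = n_event + n_complement
    if total > 0:
        return n_event / total
    if smoothing == "additive":
        return (n_event + pseudo_count) / (total + 2 * pseudo_count)
    raise EmptyCellError("(0, 0) counts")


def _tree_symptomatic(record: "ChildRecord") -> bool:
    """Placement of a record on the symptoms chance node.

    Children treated with ICS whose symptom field is missing are placed on
    the symptomatic/treated path (pharmacotherapy is given as required,
    i.e. to symptomatic children).
    """
    s = record.profile.symptomatic
    if s is not None:
        return bool(s)
    if record.profile.ics_use:
        return True
    raise TreeError(
        f"record {record.id!r}: symptomatic missing on an ICS-negative profile"
    )


def build_strategy_tree(
    records: Sequence["ChildRecord"],
    price_table: UnitPriceTable,
    diagnosis_config: Optional[DiagnosisConfig] = None,
    include_intervention: bool = False,
    empty_cell_policy: str = "additive",
    strategy_label: str = "strategy",
    empty_cell_log: Optional[list[str]] = None,
) -> TreeNode:
    """Build the canonical chance tree for one strategy group.

    All records must belong to a single group and be evaluable.  Branch
    probabilities are empirical ratios; terminal costs are mean per-child
    costs among records reaching the leaf (falling back to the nearest
    non-empty ancestor's mean when a leaf is empty under the additive
    policy).
    """
    if empty_cell_policy not in EMPTY_CELL_POLICIES:
        raise ValueError(f"unknown empty-cell policy {empty_cell_policy!r}")
    if not records:
        raise TreeError(f"no records for strategy {strategy_label!r}")
    if diagnosis_config is None:
        diagnosis_config = DiagnosisConfig()
    for rec in records:
        if not is_evaluable(rec.profile):
            raise TreeError(
                f"record {rec.id!r} is not evaluable; filter the cohort first"
            )

    costs = {
        rec.id: float(child_cost(rec, price_table, include_intervention))
        for rec in records
    }
    events = empty_cell_log if empty_cell_log is not None else []

    def mean_cost(recs, fallback: float) -> float:
        if not recs:
            return fallback
        return sum(costs[r.id] for r in recs) / len(recs)

    def split_prob(n_event: int, n_complement: int, where: str) -> float:
        if n_event + n_complement == 0:
            events.append(where)
            logger.warning("empty cell at %s (%s policy)", where, empty_cell_policy)
            if empty_cell_policy == "strict":
                raise EmptyCellError(where)
        return estimate_branch_probability(
            n_event, n_complement, smoothing="additive"
            if empty_cell_policy != "strict"
            else "strict",
        )

    def diagnosis_node(recs, fallback: float, where: str) -> TreeNode:
        pos: list = []
        neg: list = []
        for r in recs:
            status = classify_asthma(r.profile, diagnosis_config)
            (pos if status is AsthmaStatus.POSITIVE else neg).append(r)
        fb = mean_cost(recs, fallback)
        p_pos = split_prob(len(pos), len(neg), f"{where}/diagnosis")
        branches = [
            Branch(
                "asthma",
                p_pos,
                TreeNode("terminal", f"{where}/asthma", payoff=(mean_cost(pos, fb), True)),
            ),
            Branch(
                "asthma_avoided",
                1.0 - p_pos,
                TreeNode(
                    "terminal",
                    f"{where}/asthma_avoided",
                    payoff=(mean_cost(neg, fb), False),
                ),
            ),
        ]
        if empty_cell_policy == "collapse" and recs:
            kept = [b for b, r in zip(branches, (pos, neg)) if r]
            total_p = sum(b.probability for b in kept)
            for b in kept:
                b.probability = b.probability / total_p
            branches = kept
        return TreeNode("chance", f"{where}/diagnosis", branches=branches)

    all_mean = mean_cost(list(records), 0.0)

    symptomatic = [r for r in records if _tree_symptomatic(r)]
    asymptomatic = [r for r in records if not _tree_symptomatic(r)]
    p_sym = split_prob(len(symptomatic), len(asymptomatic), f"{strategy_label}/symptoms")

    sym_mean = mean_cost(symptomatic, all_mean)
    treated = [r for r in symptomatic if r.profile.ics_use]
    untreated = [r for r in symptomatic if not r.profile.ics_use]
    p_treated = split_prob(
        len(treated), len(untreated), f"{strategy_label}/symptomatic/pharmacotherapy"
    )

    pharm_branches = [
        Branch(
            "treated",
            p_treated,
            diagnosis_node(treated, sym_mean, f"{strategy_label}/symptomatic/treated"),
        ),
        Branch(
            "untreated",
            1.0 - p_treated,
            diagnosis_node(untreated, sym_mean, f"{strategy_label}/symptomatic/untreated"),
        ),
    ]
    if empty_cell_policy == "collapse":
        kept = []
        for br, recs in zip(pharm_branches, (treated, untreated)):
            if recs:
                kept.append(br)
        if kept:
            pharm_branches = kept
            total_p = sum(b.probability for b in pharm_branches)
            if total_p > 0:
                for b in pharm_branches:
                    b.probability = b.probability / total_p

    pharm_node = TreeNode(
        "chance", f"{strategy_label}/symptomatic/pharmacotherapy", branches=pharm_branches
    )

    root_branches = [
        Branch("symptomatic", p_sym, pharm_node),
        Branch(
            "asymptomatic",
            1.0 - p_sym,
            diagnosis_node(asymptomatic, all_mean, f"{strategy_label}/asymptomatic"),
        ),
    ]
    if empty_cell_policy == "collapse":
        kept = []
        for br, recs in zip(root_branches, (symptomatic, asymptomatic)):
            if recs:
                kept.append(br)
        root_branches = kept
        total_p = sum(b.probability for b in root_branches)
        for b in root_branches:
            b.probability = b.probability / total_p

    tree = TreeNode("chance", f"{strategy_label}/symptoms", branches=root_branches)
    tree.validate()
    return tree


def fold_back(tree: TreeNode) -> tuple[float, float]:
    """Leaf-to-root probability-weighted aggregation.

    Returns ``(expected_cost, p_asthma_avoided)``.  The tree must contain no
    unresolved decision nodes; strategies are folded separately.
    """
    tree.validate()

    def rec(node: TreeNode) -> tuple[float, float]:
        if node.kind == "terminal":
            cost, asthma = node.payoff  # type: ignore[misc]
            return float(cost), 0.0 if asthma else 1.0
        if node.kind == "decision":
            raise TreeError(
                f"cannot fold back through unresolved decision node {node.label!r}"
            )
        cost = 0.0
        p_avoided = 0.0
        for br in node.branches:
            c, p = rec(br.node)
            cost += br.probability * c  # type: ignore[operator]
            p_avoided += br.probability * p  # type: ignore[operator]
        return cost, p_avoided

    return rec(tree)


def enumerate_paths(tree: TreeNode) -> list[tuple[float, float, bool]]:
    """Brute-force root-to-leaf path enumeration.

    Returns one ``(path probability, cost, asthma)`` entry per leaf; path
    probabilities multiply along the way and sum to one.  Serves as the
    independent oracle for :func:`fold_back`.
    """
    tree.validate()
    out: list[tuple[float, float, bool]] = []

    def rec(node: TreeNode, prob: float) -> None:
        if node.kind == "terminal":
            cost, asthma = node.payoff  # type: ignore[misc]
            out.append((prob, float(cost), asthma))
            return
        if node.kind == "decision":
            raise TreeError(
                f"cannot enumerate through unresolved decision node {node.label!r}"
            )
        for br in node.branches:
            rec(br.node, prob * br.probability)  # type: ignore[operator]

    rec(tree, 1.0)
    return out


def strategy_expectation_from_tree(
    tree: TreeNode, strategy: str, n: Optional[int] = None
) -> StrategyExpectation:
    cost, p = fold_back(tree)
    return StrategyExpectation(
        strategy=strategy, expected_cost=cost, p_asthma_avoided=p, n=n
    )
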