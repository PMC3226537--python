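"""Cohort preparation: evaluability filter, per-protocol grouping, mixture.

Children enter the analysis stratified by first-degree familial asthma
history (PFH positive / NFH negative).  PFH intervention and control
participants are reclassified per protocol by their actual compliance with
the two prevention measures (airborne-allergen avoidance and dietary
food-allergen avoidance): both measures → multifaceted prevention, exactly
one → unifaceted, neither → control.  The usual-care comparator ("current
situation") is a fixed-weight mixture of the PFH-control and NFH strata
(default 20% / 80%, the population ratio of the risk strata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from asthmacea.diagnosis import DiagnosticProfile, is_evaluable
from asthmacea.tree_engine import StrategyExpectation

logger = logging.getLogger(__name__)


class StrategyGroup(str, Enum):
    """Per-protocol strategy groups (exhaustive and mutually exclusive)."""

    MULTIFACETED = "multifaceted"
    UNIFACETED = "unifaceted"
    PFH_CONTROL = "pfh_control"
    NFH = "nfh"


FAMILY_HISTORIES = ("PFH", "NFH")
TRIAL_ARMS = ("intervention", "control", "natural_history")


@dataclass
class ChildRecord:
    """One child: stratum, trial arm, compliance, diagnostics, resource use.

    Compliance flags are defined only for PFH intervention/control records;
    NFH records carry ``None`` and always sit in the natural-history arm.
    """

    id: str
    family_history: str
    trial_arm: str
    airborne_compliant: Optional[bool]
    food_compliant: Optional[bool]
    profile: DiagnosticProfile
    resource_use: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family_history not in FAMILY_HISTORIES:
            raise ValueError(f"family_history must be PFH or NFH, got {self.family_history!r}")
        if self.trial_arm not in TRIAL_ARMS:
            raise ValueError(f"unknown trial_arm {self.trial_arm!r}")
        if self.family_history == "NFH":
            if self.trial_arm != "natural_history":
                raise ValueError("NFH records must have trial_arm 'natural_history'")
            if self.airborne_compliant is not None or self.food_compliant is not None:
                raise ValueError("compliance flags are undefined for NFH records")
        for item, qty in self.resource_use.items():
            if qty < 0:
                raise ValueError(f"negative resource use for {item!r}: {qty}")


@dataclass(frozen=True)
class MixtureWeights:
    """Population weights of the PFH-control and NFH strata in usual care."""

    w_pfh: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_pfh <= 1.0):
            raise ValueError(f"w_pfh must be in [0, 1], got {self.w_pfh}")

    @property
    def w_nfh(self) -> float:
        return 1.0 - self.w_pfh


def filter_evaluable(
    records: Sequence[ChildRecord],
) -> tuple[list[ChildRecord], int]:
    """Keep records whose diagnostic profile is evaluable.

    Returns ``(kept, excluded_count)``; exclusions are logged.
    """
    kept = [r for r in records if is_evaluable(r.profile)]
    excluded = len(records) - len(kept)
    if excluded:
        logger.info(
            "excluded %d of %d records lacking required diagnostic data",
            excluded,
            len(records),
        )
    return kept, excluded


def assign_group(record: ChildRecord) -> StrategyGroup:
    """Per-protocol strategy group of one record (immutable assignment)."""
    if record.family_history == "NFH":
        return StrategyGroup.NFH
    if record.airborne_compliant is None or record.food_compliant is None:
        raise ValueError(
            f"record {record.id!r}: PFH record with undefined compliance flags"
        )
    n_measures = int(record.airborne_compliant) + int(record.food_compliant)
    if n_measures == 2:
        return StrategyGroup.MULTIFACETED
    if n_measures == 1:
        return StrategyGroup.UNIFACETED
    return StrategyGroup.PFH_CONTROL


def group_counts(records: Sequence[ChildRecord]) -> dict[StrategyGroup, int]:
    """Record count per strategy group (all four keys always present)."""
    counts = {g: 0 for g in StrategyGroup}
    for rec in records:
        counts[assign_group(rec)] += 1
    return counts


def split_by_group(
    records: Sequence[ChildRecord],
) -> dict[StrategyGroup, list[ChildRecord]]:
    """Partition records into their strategy groups."""
    out: dict[StrategyGroup, list[ChildRecord]] = {g: [] for g in StrategyGroup}
    for rec in records:
        out[assign_group(rec)].append(rec)
    return out


def current_mixture(
    exp_pfh_control: StrategyExpectation,
    exp_nfh: StrategyExpectation,
    weights: MixtureWeights = MixtureWeights(),
    strategy: str = "current",
) -> StrategyExpectation:
    """Usual-care expectation as the weighted PFH-control / NFH mixture.

    Both the cost and the avoidance probability are componentwise weighted
    means, equivalent to record-level pooling by linearity of expectation.
    """
    w = weights.w_pfh
    n: Optional[int] = None
    if exp_pfh_control.n is not None and exp_nfh.n is not None:
        n = exp_pfh_control.n + exp_nfh.n
    return StrategyExpectation(
        strategy=strategy,
        expected_cost=w * exp_pfh_control.expected_cost + (1.0 - w) * exp_nfh.expected_cost,
        p_asthma_avoided=w * exp_pfh_control.p_asthma_avoided
        + (1.0 - w) * exp_nfh.p_asthma_avoided,
        n=n,
    )
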