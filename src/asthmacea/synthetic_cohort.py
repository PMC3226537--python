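"""Synthetic two-risk-stratum cohort generator with a closed-form oracle.

The generator emulates the statistical structure the downstream analysis
assumes: four strategy groups (multifaceted, unifaceted, PFH control, NFH),
per-group probabilities of symptoms, of pharmacotherapy given symptoms and
of positive reversibility / hyperreactivity tests (optionally conditioned on
symptomatic status), independent Poisson-type resource-use counts per cost
item, and independent per-field missingness for the diagnostic fields.

``analytic_strategy_expectation`` computes the exact expected cost and
probability of a negative diagnosis implied by these distributions by
summing over the finite outcome space — no sampling — and serves as the
independent oracle for the tree fold-back.

Reproducibility: a single master seed is expanded into one substream per
group via ``numpy.random.SeedSequence(seed).spawn(4)`` in the fixed group
order multifaceted, unifaceted, pfh_control, nfh; regenerating any prefix of
groups therefore yields identical records.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from asthmacea.cohort_prep import ChildRecord, StrategyGroup
from asthmacea.costing import ItemCategory, UnitPriceTable, indexed_unit_price
from asthmacea.diagnosis import (
    AsthmaStatus,
    DiagnosisConfig,
    DiagnosticProfile,
    classify_asthma,
    is_evaluable,
)
from asthmacea.tree_engine import StrategyExpectation

GROUP_ORDER = (
    StrategyGroup.MULTIFACETED,
    StrategyGroup.UNIFACETED,
    StrategyGroup.PFH_CONTROL,
    StrategyGroup.NFH,
)

_GROUP_META = {
    StrategyGroup.MULTIFACETED: ("PFH", "intervention"),
    StrategyGroup.UNIFACETED: ("PFH", "intervention"),
    StrategyGroup.PFH_CONTROL: ("PFH", "control"),
    StrategyGroup.NFH: ("NFH", "natural_history"),
}

_ID_PREFIX = {
    StrategyGroup.MULTIFACETED: "mf",
    StrategyGroup.UNIFACETED: "uf",
    StrategyGroup.PFH_CONTROL: "pc",
    StrategyGroup.NFH: "nf",
}


class GroupParams(BaseModel):
    """Distributional parameters for one strategy group.

    ``p_reversibility_pos`` / ``p_hyperreactivity_pos`` apply to all
    children; the optional ``*_symptomatic`` variants override them on the
    symptomatic stratum (default: independence of symptom status).
    ``resource_distribution`` selects Poisson counts (default) or
    deterministic counts equal to the (integer) rate — the latter makes
    costs exactly reproducible for degenerate-parameter checks.
    """

    n: int = Field(ge=0)
    p_symptomatic: float = Field(ge=0.0, le=1.0)
    p_ics_given_symptomatic: float = Field(ge=0.0, le=1.0)
    p_reversibility_pos: float = Field(ge=0.0, le=1.0)
    p_hyperreactivity_pos: float = Field(ge=0.0, le=1.0)
    p_reversibility_pos_symptomatic: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    p_hyperreactivity_pos_symptomatic: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    resource_rates: dict[str, float] = Field(default_factory=dict)
    resource_distribution: Literal["poisson", "fixed"] = "poisson"
    missing_symptomatic: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_reversibility: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_hyperreactivity: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_rates(self) -> "GroupParams":
        for item, rate in self.resource_rates.items():
            if rate < 0:
                raise ValueError(f"resource rate for {item!r} must be >= 0, got {rate}")
            if self.resource_distribution == "fixed" and rate != int(rate):
                raise ValueError(
                    f"fixed resource counts require integer rates; {item!r} has {rate}"
                )
        return self

    def p_rev(self, symptomatic: bool) -> float:
        if symptomatic and self.p_reversibility_pos_symptomatic is not None:
            return self.p_reversibility_pos_symptomatic
        return self.p_reversibility_pos

    def p_hyper(self, symptomatic: bool) -> float:
        if symptomatic and self.p_hyperreactivity_pos_symptomatic is not None:
            return self.p_hyperreactivity_pos_symptomatic
        return self.p_hyperreactivity_pos


class GeneratorParams(BaseModel):
    """Full generator configuration: one block per strategy group plus a seed."""

    groups: dict[StrategyGroup, GroupParams]
    seed: int = 0

    @model_validator(mode="after")
    def _check_groups(self) -> "GeneratorParams":
        missing = [g.value for g in GROUP_ORDER if g not in self.groups]
        if missing:
            raise ValueError(f"missing generator groups: {missing}")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        return cls.model_validate(data)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_generator_params(seed: int = 0) -> GeneratorParams:
    """Runnable placeholder parameters (not estimates of any trial).

    Rates reference the items of :func:`asthmacea.costing.default_price_table`.
    """
    base_resources = {
        "gp_visit": 1.2,
        "specialist_visit": 0.3,
        "hospital_admission": 0.05,
        "chest_xray": 0.4,
        "allergen_assay": 0.6,
        "medication": 0.8,
    }
    intervention_resources = {
        "nurse_visit": 3.0,
        "mite_cover": 2.0,
        "formula_feeding": 1.5,
        "brochure": 2.0,
    }

    def group(n, p_sym, p_ics, p_rev, p_hyper, extra=None):
        rates = dict(base_resources)
        if extra:
            rates.update(extra)
        return GroupParams(
            n=n,
            p_symptomatic=p_sym,
            p_ics_given_symptomatic=p_ics,
            p_reversibility_pos=p_rev,
            p_hyperreactivity_pos=p_hyper,
            resource_rates=rates,
            missing_symptomatic=0.02,
            missing_reversibility=0.05,
            missing_hyperreactivity=0.05,
        )

    return GeneratorParams(
        groups={
            StrategyGroup.MULTIFACETED: group(
                259, 0.18, 0.5, 0.08, 0.10, intervention_resources
            ),
            StrategyGroup.UNIFACETED: group(
                53, 0.20, 0.5, 0.09, 0.11, intervention_resources
            ),
            StrategyGroup.PFH_CONTROL: group(12, 0.25, 0.5, 0.10, 0.12),
            StrategyGroup.NFH: group(100, 0.10, 0.4, 0.04, 0.05),
        },
        seed=seed,
    )


def _compliance_flags(
    group: StrategyGroup, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray] | tuple[None, None]:
    if group is StrategyGroup.MULTIFACETED:
        return np.ones(n, dtype=bool), np.ones(n, dtype=bool)
    if group is StrategyGroup.UNIFACETED:
        airborne = rng.integers(0, 2, size=n).astype(bool)
        return airborne, ~airborne
    if group is StrategyGroup.PFH_CONTROL:
        return np.zeros(n, dtype=bool), np.zeros(n, dtype=bool)
    return None, None


def generate_cohort(params: GeneratorParams) -> list[ChildRecord]:
    """Draw a full cohort; the same parameters reproduce it byte-for-byte."""
    streams = np.random.SeedSequence(params.seed).spawn(len(GROUP_ORDER))
    records: list[ChildRecord] = []
    for group, seq in zip(GROUP_ORDER, streams):
        gp = params.groups[group]
        rng = np.random.default_rng(seq)
        n = gp.n
        family_history, trial_arm = _GROUP_META[group]

        symptomatic = rng.random(n) < gp.p_symptomatic
        ics = symptomatic & (rng.random(n) < gp.p_ics_given_symptomatic)
        p_rev = np.where(symptomatic, gp.p_rev(True), gp.p_rev(False))
        p_hyper = np.where(symptomatic, gp.p_hyper(True), gp.p_hyper(False))
        reversibility = rng.random(n) < p_rev
        hyperreactivity = rng.random(n) < p_hyper
        miss_sym = rng.random(n) < gp.missing_symptomatic
        miss_rev = rng.random(n) < gp.missing_reversibility
        miss_hyper = rng.random(n) < gp.missing_hyperreactivity

        items = sorted(gp.resource_rates)
        if gp.resource_distribution == "poisson":
            counts = {
                item: rng.poisson(gp.resource_rates[item], size=n) for item in items
            }
        else:
            counts = {
                item: np.full(n, int(gp.resource_rates[item])) for item in items
            }

        airborne, food = _compliance_flags(group, n, rng)
        prefix = _ID_PREFIX[group]
        for i in range(n):
            profile = DiagnosticProfile(
                ics_use=bool(ics[i]),
                symptomatic=None if miss_sym[i] else bool(symptomatic[i]),
                reversibility=None if miss_rev[i] else bool(reversibility[i]),
                hyperreactivity=None if miss_hyper[i] else bool(hyperreactivity[i]),
            )
            records.append(
                ChildRecord(
                    id=f"{prefix}-{i:05d}",
                    family_history=family_history,
                    trial_arm=trial_arm,
                    airborne_compliant=None if airborne is None else bool(airborne[i]),
                    food_compliant=None if food is None else bool(food[i]),
                    profile=profile,
                    # zero counts omitted so CSV round-trips are exact
                    resource_use={
                        item: int(counts[item][i])
                        for item in items
                        if counts[item][i] > 0
                    },
                )
            )
    return records


def _iter_outcomes(gp: GroupParams):
    """Yield ``(probability, profile)`` over the finite diagnostic space.

    Enumerates latent symptomatic status, pharmacotherapy (only symptomatic
    children are treated), both test results conditioned on symptom status,
    and the three independent missingness indicators.
    """
    for sym in (True, False):
        p_sym = gp.p_symptomatic if sym else 1.0 - gp.p_symptomatic
        if p_sym == 0.0:
            continue
        ics_options = (
            ((True, gp.p_ics_given_symptomatic), (False, 1.0 - gp.p_ics_given_symptomatic))
            if sym
            else ((False, 1.0),)
        )
        for ics, p_ics in ics_options:
            if p_ics == 0.0:
                continue
            for rev in (True, False):
                p_rev = gp.p_rev(sym) if rev else 1.0 - gp.p_rev(sym)
                if p_rev == 0.0:
                    continue
                for hyper in (True, False):
                    p_hyper = gp.p_hyper(sym) if hyper else 1.0 - gp.p_hyper(sym)
                    if p_hyper == 0.0:
                        continue
                    for m_sym in (True, False):
                        p_ms = (
                            gp.missing_symptomatic
                            if m_sym
                            else 1.0 - gp.missing_symptomatic
                        )
                        if p_ms == 0.0:
                            continue
                        for m_rev in (True, False):
                            p_mr = (
                                gp.missing_reversibility
                                if m_rev
                                else 1.0 - gp.missing_reversibility
                            )
                            if p_mr == 0.0:
                                continue
                            for m_hyper in (True, False):
                                p_mh = (
                                    gp.missing_hyperreactivity
                                    if m_hyper
                                    else 1.0 - gp.missing_hyperreactivity
                                )
                                if p_mh == 0.0:
                                    continue
                                prob = p_sym * p_ics * p_rev * p_hyper * p_ms * p_mr * p_mh
                                profile = DiagnosticProfile(
                                    ics_use=ics,
                                    symptomatic=None if m_sym else sym,
                                    reversibility=None if m_rev else rev,
                                    hyperreactivity=None if m_hyper else hyper,
                                )
                                yield prob, profile


def analytic_expected_cost(
    gp: GroupParams, group: StrategyGroup, price_table: UnitPriceTable
) -> float:
    """Exact expected per-child cost under the generator's rate parameters."""
    include_intervention = group in (StrategyGroup.MULTIFACETED, StrategyGroup.UNIFACETED)
    total = 0.0
    for item, rate in gp.resource_rates.items():
        entry = price_table.entries.get(item)
        if entry is None:
            raise KeyError(f"unknown cost item {item!r} in generator rates")
        if entry.category is ItemCategory.INTERVENTION and not include_intervention:
            continue
        total += rate * float(indexed_unit_price(item, price_table))
    return total


def analytic_strategy_expectation(
    params: GeneratorParams,
    group: StrategyGroup | str,
    price_table: UnitPriceTable,
    diagnosis_config: Optional[DiagnosisConfig] = None,
) -> StrategyExpectation:
    """Exact strategy expectation implied by the generator distributions.

    Sums the full finite outcome space; the avoidance probability is
    conditional on the profile being evaluable (mirroring the pipeline's
    evaluability filter), and the expected cost follows from the rate
    parameters since resource use is independent of the diagnostic path.
    """
    group = StrategyGroup(group)
    if group not in params.groups:
        raise KeyError(f"unknown generator group {group!r}")
    if diagnosis_config is None:
        diagnosis_config = DiagnosisConfig()
    gp = params.groups[group]

    p_evaluable = 0.0
    p_negative = 0.0
    for prob, profile in _iter_outcomes(gp):
        if not is_evaluable(profile):
            continue
        p_evaluable += prob
        if classify_asthma(profile, diagnosis_config) is AsthmaStatus.NEGATIVE:
            p_negative += prob
    if p_evaluable == 0.0:
        raise ValueError(
            f"group {group.value!r}: no evaluable outcome has positive probability"
        )
    return StrategyExpectation(
        strategy=group.value,
        expected_cost=analytic_expected_cost(gp, group, price_table),
        p_asthma_avoided=p_negative / p_evaluable,
        n=gp.n,
    )
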