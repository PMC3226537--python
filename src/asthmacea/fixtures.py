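"""Frozen reference values from the original trial-based demonstration.

The three strategy expectations, the group sizes and the threshold range are
verbatim constants used as regression fixtures and CEA-stage inputs.  They
are *not* recomputable from raw data (the underlying trial records are not
deposited) and must never be mistaken for synthetic-run outputs; golden
tests pin them.
"""

from __future__ import annotations

import json
from importlib import resources

from asthmacea.cohort_prep import ChildRecord, StrategyGroup
from asthmacea.diagnosis import DiagnosticProfile
from asthmacea.synthetic_cohort import (
    GeneratorParams,
    default_generator_params,
    generate_cohort,
)
from asthmacea.tree_engine import StrategyExpectation


def _load() -> dict:
    text = resources.files("asthmacea").joinpath("data/reference_values.json").read_text()
    return json.loads(text)


_VALUES = _load()


def reference_values() -> dict:
    """The raw frozen reference dictionary (a fresh copy)."""
    return json.loads(json.dumps(_VALUES))


def reference_expectations() -> list[StrategyExpectation]:
    """The three printed strategy expectations (multifaceted, unifaceted, current)."""
    out = []
    for strategy, vals in _VALUES["expectations"].items():
        out.append(
            StrategyExpectation(
                strategy=strategy,
                expected_cost=vals["expected_cost"],
                p_asthma_avoided=vals["p_asthma_avoided"],
                n=vals["n"],
            )
        )
    return out


def reference_group_sizes() -> dict[str, int]:
    return dict(_VALUES["group_sizes"])


def reference_mixture_weights() -> dict[str, float]:
    return dict(_VALUES["mixture_weights"])


def reference_threshold_range() -> tuple[float, float]:
    tr = _VALUES["threshold_range"]
    return float(tr["lambda_min"]), float(tr["lambda_max"])


def reference_cohort_params(seed: int = 20_090) -> GeneratorParams:
    """Generator parameters sized like the reference per-protocol groups."""
    sizes = reference_group_sizes()
    params = default_generator_params(seed=seed)
    groups = dict(params.groups)
    groups[StrategyGroup.MULTIFACETED] = groups[StrategyGroup.MULTIFACETED].model_copy(
        update={
            "n": sizes["multifaceted"],
            "missing_symptomatic": 0.0,
            "missing_reversibility": 0.0,
            "missing_hyperreactivity": 0.0,
        }
    )
    groups[StrategyGroup.UNIFACETED] = groups[StrategyGroup.UNIFACETED].model_copy(
        update={
            "n": sizes["unifaceted"],
            "missing_symptomatic": 0.0,
            "missing_reversibility": 0.0,
            "missing_hyperreactivity": 0.0,
        }
    )
    groups[StrategyGroup.PFH_CONTROL] = groups[StrategyGroup.PFH_CONTROL].model_copy(
        update={
            "n": sizes["pfh_control"],
            "missing_symptomatic": 0.0,
            "missing_reversibility": 0.0,
            "missing_hyperreactivity": 0.0,
        }
    )
    return GeneratorParams(groups=groups, seed=seed)


def reference_cohort(seed: int = 20_090) -> list[ChildRecord]:
    """A deterministic cohort echoing the reference filtering arithmetic.

    Contains 259 + 53 + 12 evaluable PFH records (zero missingness ensures
    evaluability), an NFH stratum, plus exactly
    ``candidate_pfh - evaluable_pfh`` non-evaluable PFH records (ICS
    negative, symptomatic, reversibility missing) so that the evaluability
    filter removes them and the candidate total is reproduced.
    """
    sizes = reference_group_sizes()
    records = generate_cohort(reference_cohort_params(seed))
    n_excluded = sizes["candidate_pfh"] - sizes["evaluable_pfh"]
    compliance_cycle = [(True, True), (True, False), (False, False)]
    for i in range(n_excluded):
        airborne, food = compliance_cycle[i % len(compliance_cycle)]
        records.append(
            ChildRecord(
                id=f"xx-{i:05d}",
                family_history="PFH",
                trial_arm="intervention" if airborne or food else "control",
                airborne_compliant=airborne,
                food_compliant=food,
                profile=DiagnosticProfile(
                    ics_use=False, symptomatic=True, reversibility=None
                ),
                resource_use={},
            )
        )
    return records
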