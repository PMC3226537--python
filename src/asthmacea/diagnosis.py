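"""Rule-based objective asthma diagnosis.

The classifier combines four observations made around age six: inhaled
corticosteroid (ICS) use in the three months before lung-function testing,
wheeze in the three months before testing, a bronchodilator reversibility
test, and a bronchial hyperreactivity test.  The rule set is a fixed lookup
table of ten rows; some cells are "not needed" and the corresponding field
may be missing without making the profile non-evaluable.

For children treated with ICS the symptom field is never consulted (treatment
may mask symptoms); a positive result on either objective test implies
asthma, and the doubly-negative cell is ambiguous — its resolution is a
configurable sensitivity-analysis rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class AsthmaStatus(str, Enum):
    """Outcome of the objective diagnosis."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class DiagnosticProfile:
    """One child's diagnostic observations.

    ``ics_use`` is always known; the other three fields are ``True``,
    ``False`` or ``None`` (missing).
    """

    ics_use: bool
    symptomatic: Optional[bool] = None
    reversibility: Optional[bool] = None
    hyperreactivity: Optional[bool] = None


@dataclass(frozen=True)
class DiagnosisConfig:
    """Resolution of the ambiguous (ICS+, reversibility−, hyperreactivity−) cell.

    ``ics_pos_rev_neg_hyper_neg_rule`` must be ``"positive"`` or
    ``"negative"``.  The negative (conservative) resolution is the default;
    the positive variant is run as a sensitivity scenario.
    """

    ics_pos_rev_neg_hyper_neg_rule: str = "negative"

    def __post_init__(self) -> None:
        if self.ics_pos_rev_neg_hyper_neg_rule not in ("positive", "negative"):
            raise ValueError(
                "ics_pos_rev_neg_hyper_neg_rule must be 'positive' or "
                f"'negative', got {self.ics_pos_rev_neg_hyper_neg_rule!r}"
            )

    @property
    def ambiguous_status(self) -> AsthmaStatus:
        return AsthmaStatus(self.ics_pos_rev_neg_hyper_neg_rule)


class NonEvaluableProfileError(ValueError):
    """A field required along the lookup path is missing."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"profile is not evaluable: required field {field!r} is missing")


def _walk(profile: DiagnosticProfile, config: Optional[DiagnosisConfig]):
    """Shared lookup-path walker.

    Reads exactly the fields the matched row requires, in path order, and
    returns the row outcome.  Raises :class:`NonEvaluableProfileError` on the
    first missing required field.  ``config`` may be None only when the walk
    is used for evaluability (the ambiguous cell then resolves arbitrarily).
    """
    ambiguous = config.ambiguous_status if config is not None else AsthmaStatus.NEGATIVE

    if profile.ics_use:
        # Symptom cell is "not needed" on every ICS+ row and must not be read.
        rev = profile.reversibility
        if rev is None:
            raise NonEvaluableProfileError("reversibility")
        hyper = profile.hyperreactivity
        if hyper is None:
            raise NonEvaluableProfileError("hyperreactivity")
        if rev or hyper:
            return AsthmaStatus.POSITIVE
        return ambiguous

    symptomatic = profile.symptomatic
    if symptomatic is None:
        raise NonEvaluableProfileError("symptomatic")
    rev = profile.reversibility
    if rev is None:
        raise NonEvaluableProfileError("reversibility")

    if symptomatic:
        if rev:
            # hyperreactivity not needed
            return AsthmaStatus.POSITIVE
        hyper = profile.hyperreactivity
        if hyper is None:
            raise NonEvaluableProfileError("hyperreactivity")
        return AsthmaStatus.POSITIVE if hyper else AsthmaStatus.NEGATIVE

    if rev:
        hyper = profile.hyperreactivity
        if hyper is None:
            raise NonEvaluableProfileError("hyperreactivity")
        return AsthmaStatus.POSITIVE if hyper else AsthmaStatus.NEGATIVE
    # asymptomatic, reversibility negative: hyperreactivity not needed
    return AsthmaStatus.NEGATIVE


def classify_asthma(
    profile: DiagnosticProfile, config: Optional[DiagnosisConfig] = None
) -> AsthmaStatus:
    """Classify a child's asthma status from an evaluable diagnostic profile.

    Parameters
    ----------
    profile
        The diagnostic observations.  Fields whose cell is "not needed" for
        the matched row may be missing; any other missing field raises
        :class:`NonEvaluableProfileError`.
    config
        Resolution of the ambiguous doubly-negative ICS+ cell.  Defaults to
        the conservative (negative) rule.

    Returns
    -------
    AsthmaStatus
    """
    if config is None:
        config = DiagnosisConfig()
    return _walk(profile, config)


def is_evaluable(profile: DiagnosticProfile) -> bool:
    """Whether every field required along the profile's lookup path is present."""
    try:
        _walk(profile, None)
    except NonEvaluableProfileError:
        return False
    return True
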