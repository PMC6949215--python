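"""CNA-profile risk classification and reclassification counting.

The classifier maps the copy-number states of eight genes (IKZF1,
CDKN2A/B, PAX5, EBF1, ETV6, BTG1, RB1) and the PAR1 region to a risk
group: good (GR), intermediate (IR) or poor (PR) risk.  The rule content
is configuration, not code — it ships as an ordered JSON rule list, and
reporting defaults to the two-level GR vs pooled IR/PR granularity used
when validating such profiles (good-risk patients are the clinically
decisive stratum).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .array_calls import CNAState

REGION_NAMES = (
    "IKZF1",
    "CDKN2A",
    "CDKN2B",
    "PAX5",
    "EBF1",
    "ETV6",
    "BTG1",
    "RB1",
    "PAR1",
)


class RiskGroup(enum.Enum):
    GR = "GR"
    IR = "IR"
    PR = "PR"

    @property
    def pooled(self) -> str:
        """Two-level reporting granularity: GR vs pooled IR/PR."""
        return "GR" if self is RiskGroup.GR else "IR/PR"


@dataclass(frozen=True)
class CNAProfile:
    """The 9-region copy-number state vector for one patient."""

    sample_id: str
    states: Mapping[str, CNAState]

    def __post_init__(self) -> None:
        missing = set(REGION_NAMES) - set(self.states)
        if missing:
            raise ValueError(f"profile {self.sample_id} missing regions: {sorted(missing)}")


_STATE_ALIASES = {
    "normal": CNAState.NORMAL,
    "loss_deletion": CNAState.LOSS_DELETION,
    "loss": CNAState.LOSS_DELETION,
    "deletion": CNAState.LOSS_DELETION,
    "gain_amplification": CNAState.GAIN_AMPLIFICATION,
    "gain": CNAState.GAIN_AMPLIFICATION,
    "amplification": CNAState.GAIN_AMPLIFICATION,
    "abnormal": "abnormal",  # matches any non-normal state
}


@dataclass(frozen=True)
class Rule:
    condition: Mapping[str, object]  # region -> CNAState or "abnormal"
    group: RiskGroup

    def matches(self, profile: CNAProfile) -> bool:
        for region, wanted in self.condition.items():
            state = profile.states[region]
            if wanted == "abnormal":
                if not state.abnormal:
                    return False
            elif state is not wanted:
                return False
        return True


@dataclass(frozen=True)
class RuleSet:
    """Ordered first-match-wins rules with a default group.

    The default makes the rule set total: every profile classifies.
    """

    rules: tuple[Rule, ...]
    default: RiskGroup

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RuleSet":
        try:
            default = RiskGroup(doc["default"])
            rules = []
            for raw in doc.get("rules", []):
                cond = {}
                for region, state_name in raw["if"].items():
                    if region not in REGION_NAMES:
                        raise ValueError(f"unknown region {region!r}")
                    key = str(state_name).lower()
                    if key not in _STATE_ALIASES:
                        raise ValueError(f"unknown state {state_name!r}")
                    cond[region] = _STATE_ALIASES[key]
                rules.append(Rule(cond, RiskGroup(raw["then"])))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed risk rule configuration: {exc}") from exc
        return cls(tuple(rules), default)


def classify(profile: CNAProfile, rules: RuleSet) -> RiskGroup:
    """First matching rule wins; the default group catches everything else."""
    for rule in rules.rules:
        if rule.matches(profile):
            return rule.group
    return rules.default


def count_reclassified(
    records: Iterable[Mapping[str, str]],
    mode_a: str,
    mode_b: str,
) -> int:
    """Number of distinct patients whose risk label differs between modes.

    ``records`` are row mappings carrying a ``patient_id`` plus one risk
    label column per mode (e.g. the per-gene rows of a discordant-call
    table: a patient appearing on several rows counts once).
    """
    changed = set()
    for row in records:
        if row[mode_a] != row[mode_b]:
            changed.add(row["patient_id"])
    return len(changed)
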