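"""Clinician-inspired rule-based fusion of the three head outputs.

The evaluation head proposes per-level probabilities; the diagnosis and
balance heads adjust the per-level decision thresholds (all initially 0.5)
and may forbid levels outright:

* **Rule 1** — diagnosis says *healthy*: level 2 is forbidden and the
  level-1 threshold is raised from 0.5 to 0.7;
* **Rule 2** — diagnosis says *Parkinson's positive*: the level-0 threshold
  is raised from 0.5 to 0.7;
* **Rule 3** — balance head finds *no severe impairment*: the level-2
  threshold is raised from 0.5 to 0.7;
* **Rule 4** — balance head finds *severe impairment*: level 0 is forbidden
  and the level-1 threshold is raised from 0.5 to 0.7.

Verdicts use strict inequalities (p > threshold), so Rules 1/2 are mutually
exclusive, as are Rules 3/4.  The final rating must be exactly one of
{0, 1, 2}: among non-forbidden levels the one with the largest margin
``p_level[k] − threshold[k]`` wins, ties going to the lower level.  With all
rules off this reduces to plain argmax of the evaluation-head output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core import SchemaError
from .heads import HeadProbabilities


@dataclass(frozen=True)
class FusionRuleConfig:
    rule1_on: bool = True
    rule2_on: bool = True
    rule3_on: bool = True
    rule4_on: bool = True
    base_threshold: float = 0.5
    raised_threshold: float = 0.7
    diag_threshold: float = 0.5
    balance_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.base_threshold <= self.raised_threshold < 1:
            raise SchemaError("need 0 < base_threshold <= raised_threshold < 1")

    @classmethod
    def from_mask(cls, mask: str | Sequence[int], **kw) -> "FusionRuleConfig":
        """Build from a 4-character on/off mask like ``"1011"`` (rules 1–4)."""
        bits = [bool(int(b)) for b in mask]
        if len(bits) != 4:
            raise SchemaError("rule mask must have exactly 4 entries")
        return cls(rule1_on=bits[0], rule2_on=bits[1],
                   rule3_on=bits[2], rule4_on=bits[3], **kw)


@dataclass(frozen=True)
class FusionDecision:
    level: int
    adjusted_thresholds: Tuple[float, float, float]
    forbidden_levels: Tuple[int, ...]
    rule_trace: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2) or self.level in self.forbidden_levels:
            raise SchemaError("decision level invalid or forbidden")


def fuse(probs: HeadProbabilities,
         rules: FusionRuleConfig | None = None) -> FusionDecision:
    """Combine head outputs into exactly one UPDRS gait level."""
    r = rules or FusionRuleConfig()
    pd_positive = probs.p_pd > r.diag_threshold
    impaired = probs.p_balance_impaired > r.balance_threshold

    theta = [r.base_threshold] * 3
    forbidden: List[int] = []
    trace: List[int] = []
    if r.rule1_on and not pd_positive:
        forbidden.append(2)
        theta[1] = r.raised_threshold
        trace.append(1)
    if r.rule2_on and pd_positive:
        theta[0] = r.raised_threshold
        trace.append(2)
    if r.rule3_on and not impaired:
        theta[2] = r.raised_threshold
        trace.append(3)
    if r.rule4_on and impaired:
        forbidden.append(0)
        theta[1] = r.raised_threshold
        trace.append(4)
    # rules 1/2 and 3/4 fire on complementary verdicts
    assert not ({1, 2} <= set(trace)) and not ({3, 4} <= set(trace))

    allowed = [k for k in range(3) if k not in forbidden]
    assert allowed, "all levels forbidden — impossible under the rule set"
    margins = [float(probs.p_level[k]) - theta[k] for k in allowed]
    level = allowed[int(np.argmax(margins))]  # argmax ties → first (lower level)
    return FusionDecision(
        level=level,
        adjusted_thresholds=tuple(theta),
        forbidden_levels=tuple(sorted(forbidden)),
        rule_trace=tuple(trace),
    )


RULE_MASKS_ROWS = ("00", "01", "10", "11")  # (rule1, rule2) states
RULE_MASKS_COLS = ("00", "01", "10", "11")  # (rule3, rule4) states


def ablate(
    cohort_predictions: Sequence[HeadProbabilities],
    labels: Sequence[int],
    base: FusionRuleConfig | None = None,
) -> Tuple[np.ndarray, List[dict]]:
    """Overall accuracy for all 16 on/off combinations of the four rules.

    Rows are the (rule1, rule2) state 00/01/10/11, columns the
    (rule3, rule4) state, matching the ablation heat-map layout.  Also
    returns a per-configuration record list.
    """
    if len(cohort_predictions) == 0:
        raise SchemaError("no predictions to ablate")
    if len(cohort_predictions) != len(labels):
        raise SchemaError("predictions/labels length mismatch")
    kw = {}
    if base is not None:
        kw = dict(base_threshold=base.base_threshold,
                  raised_threshold=base.raised_threshold,
                  diag_threshold=base.diag_threshold,
                  balance_threshold=base.balance_threshold)
    matrix = np.zeros((4, 4))
    table: List[dict] = []
    for i, row in enumerate(RULE_MASKS_ROWS):
        for j, col in enumerate(RULE_MASKS_COLS):
            mask = row + col
            cfg = FusionRuleConfig.from_mask(mask, **kw)
            preds = [fuse(p, cfg).level for p in cohort_predictions]
            acc = float(np.mean([p == t for p, t in zip(preds, labels)]))
            matrix[i, j] = acc
            table.append(dict(mask=mask, accuracy=acc))
    return matrix, table
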