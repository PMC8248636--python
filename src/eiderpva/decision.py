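"""Loss functions and the listing decision.

The recovery plan frames delisting as a statistical decision problem.  The
state of nature is the true mean population growth rate ``r``; the two
actions analyzed are to delist or to maintain threatened status.  The
underprotection loss — the cost of delisting a declining population — equals
the 50-year quasi-extinction probability at that growth rate for ``r < 0``
and is zero for ``r >= 0`` (delisting a stable or growing population is the
correct call).  The overprotection loss is its mirror image around ``r = 0``.
The risk of each misclassification error is the corresponding loss function
integrated against the posterior distribution of mean growth rate, evaluated
here by Monte-Carlo averaging over posterior draws with linear interpolation
on the loss grid (draws beyond the grid are clamped to its endpoints).

Delisting also requires the abundance criterion: the lower bound of the 95%
credible interval for current abundance must be at least 12,000 breeding
birds (6,000 pairs).  An alternative criteria set based solely on abundance
(10,000 pairs in three or more surveys, or 25,000 pairs in any survey) is
evaluated by :func:`alternative_criterion`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .projection import ExtinctionCurve
from .ssm import ParameterSummary

__all__ = [
    "Action",
    "LossCurve",
    "DecisionResult",
    "build_loss_curves",
    "expected_loss",
    "classification_decision",
    "alternative_criterion",
]

#: Abundance criterion: lower 95% CRI bound, in breeding birds (6,000 pairs).
ABUNDANCE_THRESHOLD = 12_000.0
#: One breeding pair counts as two breeding birds.
BIRDS_PER_PAIR = 2.0


class Action(enum.Enum):
    """Listing actions.  Reclassification to endangered is a recognized third
    alternative but carries no loss function in this analysis."""

    DELIST = "delist"
    MAINTAIN_THREATENED = "maintain_threatened"
    RECLASSIFY_ENDANGERED = "reclassify_endangered"


@dataclasses.dataclass(frozen=True)
class LossCurve:
    """Under- and over-protection loss on a symmetric growth-rate grid."""

    r_values: tuple[float, ...]
    under_loss: tuple[float, ...]
    over_loss: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values)
        under = np.asarray(self.under_loss)
        over = np.asarray(self.over_loss)
        if not (len(r) == len(under) == len(over)):
            raise ValueError("grid and losses must have equal length")
        if np.any((under < 0) | (under > 1) | (over < 0) | (over > 1)):
            raise ValueError("losses must lie in [0, 1]")
        if np.any(under[r >= 0] != 0.0):
            raise ValueError("underprotection loss must vanish for r >= 0")
        if np.any(over[r <= 0] != 0.0):
            raise ValueError("overprotection loss must vanish for r <= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r_values, "under_loss": self.under_loss,
                             "over_loss": self.over_loss})

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def build_loss_curves(ext_curve: ExtinctionCurve) -> LossCurve:
    """Turn an extinction-probability curve into the two loss functions.

    Requires a grid symmetric about 0 (as the default projection grid is) so
    that the overprotection loss is the exact mirror image of the
    underprotection loss: ``over(r) = under(-r)``.
    """
    r = np.asarray(ext_curve.rs_values, dtype=float)
    prob = np.asarray(ext_curve.probabilities, dtype=float)
    if not np.allclose(r + r[::-1], 0.0, atol=1e-9):
        raise ValueError("extinction-curve grid must be symmetric about 0")
    under = np.where(r < 0, prob, 0.0)
    over = under[::-1].copy()  # over(r) = under(-r); zero wherever r <= 0
    return LossCurve(r_values=tuple(float(v) for v in r),
                     under_loss=tuple(float(v) for v in under),
                     over_loss=tuple(float(v) for v in over))


def expected_loss(loss: LossCurve, rbar_draws: np.ndarray, action: Action) -> float:
    """Monte-Carlo posterior expected loss (misclassification risk) for one
    action: the mean over posterior growth-rate draws of the linearly
    interpolated loss curve."""
    draws = np.asarray(rbar_draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("need at least one posterior draw")
    if action == Action.DELIST:
        curve = loss.under_loss
    elif action == Action.MAINTAIN_THREATENED:
        curve = loss.over_loss
    else:
        raise ValueError(f"no loss function defined for action {action}")
    # np.interp clamps draws outside the grid to the endpoint losses
    return float(np.mean(np.interp(draws, loss.r_values, curve)))


@dataclasses.dataclass(frozen=True)
class DecisionResult:
    under_risk: float
    over_risk: float
    abundance_cri_low: float
    abundance_criterion_met: bool
    loss_criterion_met: bool
    alt_criterion_met: bool | None
    recommendation: Action

    def __post_init__(self) -> None:
        for risk in (self.under_risk, self.over_risk):
            if not (0.0 <= risk <= 1.0):
                raise ValueError("risks must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recommendation"] = self.recommendation.value
        return d

    def write_json(self, path: Union[str, Path], **provenance) -> None:
        payload = {**self.to_dict(), **provenance}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def classification_decision(under_risk: float, over_risk: float,
                            abundance_summary: ParameterSummary,
                            threshold: float = ABUNDANCE_THRESHOLD,
                            alt_criterion_met: bool | None = None) -> DecisionResult:
    """Apply the recovery criteria: delist only when the lower 95% CRI of
    current abundance meets the threshold AND overprotection risk strictly
    exceeds underprotection risk (ties fail the loss criterion)."""
    if not (0.0 <= under_risk <= 1.0 and 0.0 <= over_risk <= 1.0):
        raise ValueError("risks must lie in [0, 1]")
    abundance_ok = abundance_summary.cri_low >= threshold
    loss_ok = over_risk > under_risk
    recommendation = Action.DELIST if (abundance_ok and loss_ok) \
        else Action.MAINTAIN_THREATENED
    return DecisionResult(
        under_risk=under_risk,
        over_risk=over_risk,
        abundance_cri_low=abundance_summary.cri_low,
        abundance_criterion_met=abundance_ok,
        loss_criterion_met=loss_ok,
        alt_criterion_met=alt_criterion_met,
        recommendation=recommendation,
    )


def alternative_criterion(summaries: Mapping[int, ParameterSummary] |
                          Sequence[ParameterSummary],
                          pairs_three_surveys: float = 10_000.0,
                          pairs_any_survey: float = 25_000.0) -> bool:
    """Second criteria set, on abundance alone: lower 95% CRI of at least
    10,000 pairs (20,000 birds) in three or more surveys, or at least
    25,000 pairs (50,000 birds) in any survey.  Thresholds are inclusive."""
    values = summaries.values() if isinstance(summaries, Mapping) else summaries
    lows = [s.cri_low for s in values]
    n_high = sum(low >= pairs_three_surveys * BIRDS_PER_PAIR for low in lows)
    any_very_high = any(low >= pairs_any_survey * BIRDS_PER_PAIR for low in lows)
    return n_high >= 3 or any_very_high
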