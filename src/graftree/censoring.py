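"""Censoring handling for horizon classification.

Recasting graft survival as "failure by N years" classification has to decide
what to do with subjects whose follow-up ends, without an event, before the
horizon. This module implements the three published rules:

* Use One FALSE — short-follow-up subjects are excluded from training even
  when they failed;
* Use One TRUE — a subject who failed during a short follow-up still enters
  as a positive example;
* Zupan weighting — a subject censored at ``t_c`` before the horizon ``h``
  enters twice, as a negative with weight ``S(h)/S(t_c)`` and a positive with
  weight ``1 - S(h)/S(t_c)``, where ``S`` is the Kaplan-Meier survivor curve
  of the training partition (conditional probability of surviving to the
  horizon given survival to ``t_c``).

It also implements the first-year acute-rejection coding conditions. The
published conditions 1-2 and 2-2 assign opposite codes to a rejection inside
the first year (0 under 1-2, 1 under 2-2); the default ``"verbatim"`` map
reproduces them as printed, and an alternate ``"within1yr-positive"`` map
codes any rejection within 12 months as 1, matching how the fitted trees
treat first-year rejection as the risk-positive state. Code 2 marks "not
treated" rows, which are dropped from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

logger = logging.getLogger("graftree")

__all__ = [
    "HorizonLabel",
    "HorizonConfig",
    "WeightedInstance",
    "label_at_horizon",
    "zupan_weights",
    "horizon_instances",
    "encode_rejection",
]

MONTHS_PER_YEAR = 12.0


class HorizonLabel(Enum):
    POSITIVE = 1
    NEGATIVE = 0
    EXCLUDED = "excluded"
    CENSORED_SHORT = "censored-short"


@dataclass(frozen=True)
class HorizonConfig:
    """Prediction horizon in years plus the censoring-handling switches."""

    horizon: int = 10
    use_one: bool = True
    weighting: str = "nothing"  # "zupan" | "nothing"

    def __post_init__(self):
        if not 1 <= self.horizon <= 10:
            raise ValueError("horizon must be in 1..10 years")
        if self.weighting not in ("zupan", "nothing"):
            raise ValueError("weighting must be 'zupan' or 'nothing'")

    @property
    def horizon_months(self) -> float:
        return self.horizon * MONTHS_PER_YEAR


@dataclass(frozen=True)
class WeightedInstance:
    """A (row, horizon label, weight) training instance."""

    index: int
    label: int
    weight: float


def label_at_horizon(time: float, event: int, cfg: HorizonConfig) -> HorizonLabel:
    """Horizon label for one subject.

    An observed event by the horizon is positive; follow-up past the horizon
    without an earlier event is negative; censoring short of the horizon
    without an event is ``CENSORED_SHORT`` (excluded unless Zupan-weighted);
    an event during short follow-up is positive under Use One TRUE and
    excluded under FALSE.
    """
    if not time > 0:
        raise ValueError("time must be positive")
    h = cfg.horizon_months
    if event and time <= h:
        return HorizonLabel.POSITIVE if (cfg.use_one or time >= h) else HorizonLabel.EXCLUDED
    if time >= h:
        return HorizonLabel.NEGATIVE
    return HorizonLabel.CENSORED_SHORT


def zupan_weights(times, events, cfg: HorizonConfig, km) -> list[WeightedInstance]:
    """Kaplan-Meier conditional-probability instance weighting.

    ``km`` is a survivor step function estimated on the same training
    partition (``km(0) == 1``). Determinate rows get weight 1; each subject
    censored short of the horizon contributes a negative and a positive copy
    whose weights sum to 1.
    """
    h = cfg.horizon_months
    s_h = float(km(h))
    out: list[WeightedInstance] = []
    for i, (t, e) in enumerate(zip(np.asarray(times, float), np.asarray(events, int))):
        lab = label_at_horizon(t, e, cfg)
        if lab is HorizonLabel.POSITIVE:
            out.append(WeightedInstance(i, 1, 1.0))
        elif lab is HorizonLabel.NEGATIVE:
            out.append(WeightedInstance(i, 0, 1.0))
        elif lab is HorizonLabel.CENSORED_SHORT:
            s_t = float(km(t))
            if s_t <= 0.0:
                logger.warning(
                    "KM survivor is 0 at censoring time %.3f; assigning weight pair (0, 1)", t
                )
                w_neg = 0.0
            else:
                w_neg = min(s_h / s_t, 1.0)
            out.append(WeightedInstance(i, 0, w_neg))
            out.append(WeightedInstance(i, 1, 1.0 - w_neg))
    return out


def horizon_instances(times, events, cfg: HorizonConfig, km=None):
    """Training instance arrays ``(row_indices, labels, weights)``.

    With ``weighting='nothing'`` this is plain horizon labelling (excluded
    and censored-short rows dropped); with ``'zupan'`` censored-short rows
    are weighted via ``km`` (required).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if cfg.weighting == "zupan":
        if km is None:
            raise ValueError("zupan weighting requires a fitted KM survivor function")
        inst = zupan_weights(times, events, cfg, km)
    else:
        inst = []
        for i, (t, e) in enumerate(zip(times, events)):
            lab = label_at_horizon(t, e, cfg)
            if lab is HorizonLabel.POSITIVE:
                inst.append(WeightedInstance(i, 1, 1.0))
            elif lab is HorizonLabel.NEGATIVE:
                inst.append(WeightedInstance(i, 0, 1.0))
    idx = np.array([w.index for w in inst], dtype=int)
    lab = np.array([w.label for w in inst], dtype=int)
    wts = np.array([w.weight for w in inst], dtype=float)
    return idx, lab, wts


_REJECTION_MAPS = ("verbatim", "within1yr-positive")


def encode_rejection(
    followup: float,
    rejection_time: float | None,
    event: int,
    use_one: bool,
    coding: str = "verbatim",
) -> int:
    """First-year acute-rejection code in {0, 1, 2}.

    ``"verbatim"`` reproduces the published conditions: with adequate
    follow-up (Use One FALSE path) no rejection over >1 year codes 0, an
    observed rejection codes 0 within the first year and 1 after it; for a
    graft failure under short follow-up (Use One TRUE path) a rejection
    before 1 year codes 1 and a later one 0. ``"within1yr-positive"`` instead
    codes any rejection within 12 months as 1 and later/no rejection as 0.
    Code 2 ("not treated") marks rows the rules leave undetermined; they are
    dropped from training.
    """
    if coding not in _REJECTION_MAPS:
        raise ValueError(f"coding must be one of {_REJECTION_MAPS}")
    if not followup > 0:
        raise ValueError("followup must be positive")
    if rejection_time is not None:
        if not rejection_time > 0:
            raise ValueError("rejection_time must be positive when present")
        if rejection_time > followup:
            raise ValueError("rejection_time cannot exceed followup")

    if coding == "within1yr-positive":
        if rejection_time is not None:
            return 1 if rejection_time <= 12.0 else 0
        return 0 if followup > 12.0 else 2

    if use_one and event == 1:
        # conditions 2-1 / 2-2: graft failure despite short follow-up
        if rejection_time is None:
            return 2
        return 1 if rejection_time < 12.0 else 0
    # conditions 1-1 / 1-2
    if rejection_time is None:
        return 0 if followup > 12.0 else 2
    return 0 if rejection_time <= 12.0 else 1
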