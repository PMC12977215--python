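"""ROPE-based decision engine: posterior probabilities and classifications.

Converts posterior draws of the treatment effect into the protocol's
probabilistic conclusions: equal-tailed credible intervals, probabilities
of benefit and severe harm, the posterior mass inside the region of
practical equivalence (ROPE), and a four-way classification.

Conventions fixed here:

* Benefit direction is outcome-specific: OR > 1 for VFD, OR < 1 for
  28-day mortality, MD < 0 for ventilation duration.
* The ROPE is (-0.1, +0.1) on the log-OR scale by default, the protocol's
  literal statement (the exact bounds ln 0.9 / ln 1.1 are a switch).
* Superiority fires at posterior probability >= 0.975 (inclusive); a
  secondary report at the 0.95 threshold is always included.
* Practical equivalence requires the *entire* 95% CrI inside the ROPE —
  the strictest common reading; the fraction of the CrI width inside the
  ROPE is also reported so laxer rules can be applied post hoc.
* No ROPE or severe-harm threshold exists for ventilation duration; asking
  for one raises rather than inventing a bound.
* Quantiles use linear interpolation between order statistics (numpy's
  default rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .inference import PosteriorDraws


class DecisionError(ValueError):
    pass


@dataclass(frozen=True)
class DecisionThresholds:
    rope_or_lo: float = 0.9
    rope_or_hi: float = 1.1
    superiority_prob: float = 0.975
    severe_harm_or_vfd: float = 0.75
    severe_harm_or_mort: float = 1.25
    report_also_at: float = 0.95
    literal_log_rope: bool = True  # (-0.1, 0.1) literal vs (ln 0.9, ln 1.1)

    def __post_init__(self) -> None:
        if not self.rope_or_lo < 1.0 < self.rope_or_hi:
            raise DecisionError("ROPE must bracket OR = 1")
        if not 0.5 < self.superiority_prob < 1.0:
            raise DecisionError("superiority_prob must be in (0.5, 1)")

    @property
    def log_rope(self) -> tuple[float, float]:
        if self.literal_log_rope:
            return (-0.1, 0.1)
        return (math.log(self.rope_or_lo), math.log(self.rope_or_hi))


#: benefit direction per outcome, on the model's effect scale
BENEFIT_DIRECTION = {"vfd": "greater", "mortality_28d": "less", "duration": "less"}


@dataclass
class DecisionSummary:
    outcome: str
    prior_label: str
    effect_scale: str
    posterior_median: float
    cri_95: tuple[float, float]
    p_benefit: float
    classification: str
    p_rope: Optional[float] = None
    p_severe_harm: Optional[float] = None
    cri_inside_rope_fraction: Optional[float] = None
    superior_at_95: Optional[bool] = None
    posterior_median_natural: Optional[float] = None  # OR scale for log-OR outcomes
    cri_95_natural: Optional[tuple[float, float]] = None
    diagnostics: dict = field(default_factory=dict)


def _theta(draws: PosteriorDraws | np.ndarray) -> np.ndarray:
    arr = draws.theta if isinstance(draws, PosteriorDraws) else np.asarray(draws, float)
    if arr.size == 0:
        raise DecisionError("empty draw vector")
    return arr


def tail_probability(
    draws: PosteriorDraws | np.ndarray, direction: str, threshold: float
) -> float:
    """Fraction of effect draws strictly beyond ``threshold`` in ``direction``."""
    th = _theta(draws)
    if direction == "greater":
        return float(np.mean(th > threshold))
    if direction == "less":
        return float(np.mean(th < threshold))
    raise DecisionError(f"direction must be 'greater' or 'less', got {direction!r}")


def rope_probability(
    draws: PosteriorDraws | np.ndarray,
    thresholds: DecisionThresholds | None = None,
    outcome: Optional[str] = None,
) -> float:
    """Posterior mass inside the ROPE on the log-OR scale.

    Not defined for the duration outcome; the protocol specifies no ROPE
    for a mean difference in days.
    """
    thresholds = thresholds or DecisionThresholds()
    if outcome is None and isinstance(draws, PosteriorDraws):
        outcome = draws.outcome
    if outcome == "duration":
        raise DecisionError("no ROPE is defined for the duration outcome")
    lo, hi = thresholds.log_rope
    th = _theta(draws)
    return float(np.mean((th > lo) & (th < hi)))


def credible_interval(
    draws: PosteriorDraws | np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed quantile interval (linear-interpolation quantiles)."""
    if not 0.0 < level < 1.0:
        raise DecisionError("level must be in (0, 1)")
    th = _theta(draws)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(th, [a, 1.0 - a])
    return float(lo), float(hi)


def _severe_harm_spec(outcome: str, thresholds: DecisionThresholds):
    if outcome == "vfd":
        return "less", math.log(thresholds.severe_harm_or_vfd)
    if outcome == "mortality_28d":
        return "greater", math.log(thresholds.severe_harm_or_mort)
    raise DecisionError("no severe-harm threshold is defined for the duration outcome")


def classify_effect(
    *,
    outcome: str,
    p_benefit: float,
    cri_95: tuple[float, float],
    p_severe_harm: Optional[float] = None,
    thresholds: DecisionThresholds | None = None,
) -> str:
    """Four-way classification, evaluated in a fixed order.

    superior (p_benefit >= gate, inclusive) -> practically_equivalent (full
    95% CrI inside the ROPE) -> severe_harm_signal (severe-harm tail mass
    >= gate) -> indeterminate.  The first two regions are disjoint from the
    third for any sane gate, but the evaluation order is fixed regardless.
    For the duration outcome only superiority applies.
    """
    thresholds = thresholds or DecisionThresholds()
    if p_benefit >= thresholds.superiority_prob:
        return "superior"
    if outcome != "duration":
        lo, hi = thresholds.log_rope
        if lo < cri_95[0] and cri_95[1] < hi:
            return "practically_equivalent"
        if p_severe_harm is not None and p_severe_harm >= thresholds.superiority_prob:
            return "severe_harm_signal"
    return "indeterminate"


def _rope_overlap_fraction(cri: tuple[float, float], rope: tuple[float, float]) -> float:
    lo, hi = cri
    if hi == lo:
        return 1.0 if rope[0] < lo < rope[1] else 0.0
    overlap = max(0.0, min(hi, rope[1]) - max(lo, rope[0]))
    return overlap / (hi - lo)


def summarize_outcome(
    draws: PosteriorDraws,
    thresholds: DecisionThresholds | None = None,
    prior_label: str = "",
) -> DecisionSummary:
    """Assemble the full decision summary for one fitted outcome."""
    thresholds = thresholds or DecisionThresholds()
    outcome = draws.outcome
    if outcome not in BENEFIT_DIRECTION:
        raise DecisionError(f"unknown outcome {outcome!r}")
    th = _theta(draws)
    median = float(np.quantile(th, 0.5))
    cri = credible_interval(draws, 0.95)
    p_ben = tail_probability(draws, BENEFIT_DIRECTION[outcome], 0.0)

    p_rope = p_harm = frac = None
    nat_median = nat_cri = None
    if outcome != "duration":
        p_rope = rope_probability(draws, thresholds, outcome)
        direction, cut = _severe_harm_spec(outcome, thresholds)
        p_harm = tail_probability(draws, direction, cut)
        frac = _rope_overlap_fraction(cri, thresholds.log_rope)
        nat_median = math.exp(median)
        nat_cri = (math.exp(cri[0]), math.exp(cri[1]))

    return DecisionSummary(
        outcome=outcome,
        prior_label=prior_label,
        effect_scale=draws.effect_scale,
        posterior_median=median,
        cri_95=cri,
        p_benefit=p_ben,
        p_rope=p_rope,
        p_severe_harm=p_harm,
        cri_inside_rope_fraction=frac,
        classification=classify_effect(
            outcome=outcome,
            p_benefit=p_ben,
            cri_95=cri,
            p_severe_harm=p_harm,
            thresholds=thresholds,
        ),
        superior_at_95=bool(p_ben >= thresholds.report_also_at),
        posterior_median_natural=nat_median,
        cri_95_natural=nat_cri,
        diagnostics=dict(draws.diagnostics),
    )
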