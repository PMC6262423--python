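"""Greedy integer weight learning for the injury score.

Starting from the equal-weight baseline table, the point value of one
injury feature at a time is raised by a single point per iteration. A raise
is kept only while sensitivity strictly increases and specificity does not
decrease (both read at the current operating threshold); the first rejected
raise ends that feature and the search moves to the next one. Sensitivity
and specificity are carried as exact rationals so acceptance decisions are
never confounded by floating-point ties.

The result is order-dependent: features earlier in ``feature_order`` get
first claim on the available sensitivity gains. The default order walks the
seven weighted levels in descending clinical severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .cohort import Cohort
from .scoring import (
    DOMAIN_SEVERE_SIBLING,
    WEIGHT_FEATURES,
    InjuryProfile,
    WeightTable,
    baseline_weights,
    score_injury,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the greedy weight search.

    threshold_rule is either ``"youden"`` (re-pick the Youden-optimal
    integer threshold at every trial) or ``"fixed:K"`` (hold the operating
    threshold at the integer K throughout).
    """

    feature_order: tuple[str, ...] = WEIGHT_FEATURES
    max_weight: int = 10
    threshold_rule: str = "youden"
    start: Optional[WeightTable] = None

    def __post_init__(self) -> None:
        if sorted(self.feature_order) != sorted(WEIGHT_FEATURES):
            raise ValueError("feature_order must cover every weighted level exactly once")
        if self.max_weight < 1:
            raise ValueError("max_weight must be at least 1")
        if self.threshold_rule != "youden":
            kind, _, value = self.threshold_rule.partition(":")
            if kind != "fixed" or not value.lstrip("-").isdigit() or int(value) < 0:
                raise ValueError(
                    f"threshold_rule must be 'youden' or 'fixed:K', got {self.threshold_rule!r}"
                )


@dataclass(frozen=True)
class TraceEntry:
    feature: str
    trial_weight: int
    threshold: int
    sensitivity: Fraction
    specificity: Fraction
    accepted: bool
    note: str = ""


@dataclass
class SearchTrace:
    """Per-iteration record of the search, including the starting state."""

    entries: list[TraceEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def accepted(self) -> list[TraceEntry]:
        return [e for e in self.entries if e.accepted]

    def to_json_lines(self) -> str:
        import json

        lines = []
        for e in self.entries:
            lines.append(
                json.dumps(
                    {
                        "feature": e.feature,
                        "trial_weight": e.trial_weight,
                        "threshold": e.threshold,
                        "sensitivity": [e.sensitivity.numerator, e.sensitivity.denominator],
                        "specificity": [e.specificity.numerator, e.specificity.denominator],
                        "accepted": e.accepted,
                        "note": e.note,
                    }
                )
            )
        return "\n".join(lines) + "\n"


def sens_spec(
    scores: Sequence[int], labels: Sequence[bool], threshold: int
) -> tuple[Fraction, Fraction]:
    """Exact sensitivity and specificity at a strict ``score > threshold`` rule."""
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    n_pos = sum(bool(l) for l in labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    tp = sum(1 for s, l in zip(scores, labels) if l and s > threshold)
    tn = sum(1 for s, l in zip(scores, labels) if not l and s <= threshold)
    return Fraction(tp, n_pos), Fraction(tn, n_neg)


def best_threshold(
    scores: Sequence[int], labels: Sequence[bool], rule: str = "youden"
) -> int:
    """Operating threshold for the given rule.

    Under ``youden`` returns the integer threshold maximizing
    sensitivity + specificity - 1 over 0..max(score); ties break toward the
    lowest threshold. ``fixed:K`` returns K.
    """
    if rule != "youden":
        kind, _, value = rule.partition(":")
        if kind == "fixed":
            return int(value)
        raise ValueError(f"unknown threshold rule {rule!r}")
    best_t, best_j = 0, None
    for t in range(0, max(scores) + 1):
        se, sp = sens_spec(scores, labels, t)
        j = se + sp - 1
        if best_j is None or j > best_j:
            best_t, best_j = t, j
    return best_t


def _extract(cohort: Cohort) -> tuple[list[InjuryProfile], list[bool]]:
    labeled = cohort.labeled()
    profiles = [r.injury for r in labeled]
    labels = [bool(r.severe) for r in labeled]
    return profiles, labels


def learn_weights(
    cohort: "Cohort | tuple[Sequence[InjuryProfile], Sequence[bool]]",
    config: Optional[SearchConfig] = None,
) -> tuple[WeightTable, SearchTrace]:
    """Run the greedy one-feature-at-a-time weight escalation.

    Accepts a labeled :class:`~neoscore.cohort.Cohort`, or a
    ``(profiles, labels)`` pair for direct use in experiments. Returns the
    learned :class:`WeightTable` and the full :class:`SearchTrace`.
    """
    config = config or SearchConfig()
    if isinstance(cohort, Cohort):
        profiles, labels = _extract(cohort)
    else:
        profiles, labels = list(cohort[0]), [bool(l) for l in cohort[1]]
    if not any(labels) or all(labels):
        raise ValueError("cohort must contain both outcome classes")

    weights = config.start or baseline_weights()
    indicator_rows = [p.feature_indicators() for p in profiles]
    seen_levels = {name for row in indicator_rows for name, flag in row.items() if flag}
    missing = [name for name in WEIGHT_FEATURES if name not in seen_levels]
    if missing:
        logger.warning("no subjects carry injury level(s) %s; their weights cannot move", missing)

    def scores_for(w: WeightTable) -> list[int]:
        table = w.as_dict()
        return [sum(table[name] * flag for name, flag in row.items()) for row in indicator_rows]

    trace = SearchTrace()
    current_scores = scores_for(weights)
    threshold = best_threshold(current_scores, labels, config.threshold_rule)
    sens, spec = sens_spec(current_scores, labels, threshold)
    trace.entries.append(
        TraceEntry("<start>", 0, threshold, sens, spec, accepted=True, note="starting state")
    )

    for feature in config.feature_order:
        while True:
            trial_value = getattr(weights, feature) + 1
            if trial_value > config.max_weight:
                break
            sibling = DOMAIN_SEVERE_SIBLING.get(feature)
            if sibling is not None and trial_value > getattr(weights, sibling):
                # a milder level may never outweigh its domain's severe level
                logger.info(
                    "stopping %s at %d: raising it would exceed %s",
                    feature,
                    trial_value - 1,
                    sibling,
                )
                break
            trial = weights.replace(**{feature: trial_value})
            trial_scores = scores_for(trial)
            trial_threshold = best_threshold(trial_scores, labels, config.threshold_rule)
            trial_sens, trial_spec = sens_spec(trial_scores, labels, trial_threshold)
            accepted = trial_sens > sens and trial_spec >= spec
            trace.entries.append(
                TraceEntry(feature, trial_value, trial_threshold, trial_sens, trial_spec, accepted)
            )
            if not accepted:
                break
            weights, sens, spec, threshold = trial, trial_sens, trial_spec, trial_threshold

    return weights, trace
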