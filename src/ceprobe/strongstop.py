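"""Detection and exclusion of reverse-transcriptase strong-stops.

RT strong-stops are premature primer-extension terminations not caused by a
probe adduct (pre-existing cleavage or modification of the RNA); their
positions carry unreliable reactivity and must not enter normalization.

The automated classifier flags a position when the first of three criteria
fires, all ratios being taken against the experiment-wide average background
peak area ``mean_bg``:

1. the absolute reactivity is negative;
2. the background peak area is at least five times ``mean_bg``;
3. the reaction-minus-background difference is below 35% of ``mean_bg``
   while the background peak area is at or above ``mean_bg``.

A manual mode lets the user pick strong-stop positions from the peak-area
histogram and choose among three treatments of sub-threshold negative
reactivities (keep / set to zero / mark as no data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, FrozenSet, Optional, Tuple

from .core import Experiment, ExclusionReason, ProbingRecord, StrongStopMask
from .errors import InsufficientDataError, ValidationError

HIGH_BG_FACTOR = 5.0
LOW_DIFF_FACTOR = 0.35


class NegativeTreatment(Enum):
    """What to do with reactivities below the negative threshold (manual mode)."""

    KEEP = "KEEP"
    ZERO = "ZERO"
    NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class ManualPolicy:
    """User-driven exclusion policy for the manual/interactive mode."""

    negative_threshold: float = 0.0
    negative_treatment: NegativeTreatment = NegativeTreatment.KEEP
    user_selected_positions: FrozenSet[int] = frozenset()


def _mean_background(exp: Experiment) -> float:
    bgs = [r.bg_area for r in exp.records if not r.missing]
    if not bgs:
        raise InsufficientDataError("no background data: every record is missing")
    return sum(bgs) / len(bgs)


def detect_strong_stops_auto(exp: Experiment) -> StrongStopMask:
    """Classify every position as reliable or excluded by the three criteria.

    ``mean_bg`` is computed once, over all non-missing records, before any
    exclusion; the criteria are then evaluated per position in the fixed
    order 1 -> 2 -> 3 and the first match is recorded as the reason.
    Missing-input records are excluded with reason ``MISSING_INPUT``.
    """
    mean_bg = _mean_background(exp)
    reasons: Dict[int, ExclusionReason] = {}
    for r in exp.records:
        if r.missing:
            reasons[r.position] = ExclusionReason.MISSING_INPUT
        elif r.reactivity < 0:
            reasons[r.position] = ExclusionReason.NEGATIVE_REACTIVITY
        elif r.bg_area >= HIGH_BG_FACTOR * mean_bg:
            reasons[r.position] = ExclusionReason.HIGH_BACKGROUND
        elif (r.rx_area - r.bg_area) < LOW_DIFF_FACTOR * mean_bg and r.bg_area >= mean_bg:
            reasons[r.position] = ExclusionReason.LOW_DIFFERENCE
    return StrongStopMask(exp.positions, reasons, mean_bg)


def apply_manual_policy(
    exp: Experiment, policy: ManualPolicy
) -> Tuple[StrongStopMask, Experiment]:
    """Apply a user-defined exclusion policy; returns the mask and the
    experiment with reactivities adjusted per the negative-value treatment.

    User-selected positions are excluded with reason ``MANUAL``.  For the
    remaining positions, reactivities below ``negative_threshold`` are kept
    unchanged (``KEEP``), set to zero (``ZERO``) or excluded as no-data
    (``NO_DATA``).
    """
    absent = sorted(set(policy.user_selected_positions) - set(exp.positions))
    if absent:
        raise ValidationError(f"selected positions not in experiment: {absent}")

    try:
        mean_bg = _mean_background(exp)
    except InsufficientDataError:
        mean_bg = math.nan

    reasons: Dict[int, ExclusionReason] = {}
    new_records = []
    for r in exp.records:
        if r.position in policy.user_selected_positions:
            reasons[r.position] = ExclusionReason.MANUAL
            new_records.append(r)
            continue
        if r.missing:
            reasons[r.position] = ExclusionReason.MISSING_INPUT
            new_records.append(r)
            continue
        if r.reactivity < policy.negative_threshold:
            if policy.negative_treatment is NegativeTreatment.ZERO:
                r = replace(r, reactivity=0.0)
            elif policy.negative_treatment is NegativeTreatment.NO_DATA:
                reasons[r.position] = ExclusionReason.NEGATIVE_REACTIVITY
        new_records.append(r)

    mask = StrongStopMask(exp.positions, reasons, mean_bg)
    return mask, replace(exp, records=tuple(new_records))


def histogram_data(
    exp: Experiment,
) -> Tuple[Tuple[int, ...], Tuple[Optional[float], ...], Tuple[Optional[float], ...]]:
    """Aligned (positions, bg_area, rx_area) series for the manual-selection
    histogram view; missing records yield ``None`` gaps, never zeros."""
    positions = exp.positions
    bg = tuple(None if r.missing else r.bg_area for r in exp.records)
    rx = tuple(None if r.missing else r.rx_area for r in exp.records)
    return positions, bg, rx


def exclusion_table(exp: Experiment, mask: StrongStopMask) -> str:
    """TSV log of excluded positions: position, reason, triggering values."""
    lines = ["position\treason\treactivity\tbg_area\trx_area\tmean_bg"]
    by_pos = {r.position: r for r in exp.records}
    for pos in mask.excluded_positions:
        r = by_pos[pos]
        lines.append(
            "\t".join(
                str(x)
                for x in (pos, mask.reasons[pos].name, r.reactivity, r.bg_area,
                          r.rx_area, mask.mean_bg)
            )
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ClassificationMetrics:
    """Binary-classification quality of the strong-stop detector against an
    expert reference: reliable positions are the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")
        if self.total == 0:
            raise ValidationError("at least one count must be positive")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def tpr(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def tnr(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def rounded(self, ndigits: int = 2) -> Dict[str, Optional[float]]:
        """Rates rounded for display; undefined rates stay ``None``."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in
            {"acc": self.acc, "ppv": self.ppv, "tpr": self.tpr, "tnr": self.tnr}.items()
        }


def classification_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassificationMetrics:
    """Accuracy, precision, sensitivity and specificity from the four counts.

    Rates with a zero denominator are reported as not-applicable (``None``),
    never as 0.
    """
    return ClassificationMetrics(tp, tn, fp, fn)


def compare_masks(predicted: StrongStopMask, truth: StrongStopMask) -> ClassificationMetrics:
    """Score a predicted mask against a reference mask over the shared
    positions (reliable = positive class)."""
    if predicted.positions != truth.positions:
        raise ValidationError("masks cover different position sets")
    tp = tn = fp = fn = 0
    for pos in predicted.positions:
        p_rel = predicted.is_reliable(pos)
        t_rel = truth.is_reliable(pos)
        if p_rel and t_rel:
            tp += 1
        elif not p_rel and not t_rel:
            tn += 1
        elif p_rel and not t_rel:
            fp += 1
        else:
            fn += 1
    return ClassificationMetrics(tp, tn, fp, fn)
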