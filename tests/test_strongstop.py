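"""Strong-stop classification: criteria, manual policy, quality metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_experiment, reactivity_experiment

from ceprobe.core import Experiment, ExclusionReason, ProbingRecord
from ceprobe.errors import InsufficientDataError, ValidationError
from ceprobe.strongstop import (
    ManualPolicy,
    NegativeTreatment,
    apply_manual_policy,
    classification_metrics,
    detect_strong_stops_auto,
    histogram_data,
)


def oracle_exclusions(exp: Experiment) -> dict:
    """Independent literal transcription of the three exclusion criteria:
    negative reactivity; background at least five times the average
    background; reaction-minus-background difference below 35% of the
    average background while the background is at or above that average."""
    present = [r for r in exp.records if not r.missing]
    avg_bg = sum(r.bg_area for r in present) / len(present)
    out = {}
    for r in exp.records:
        if r.missing:
            out[r.position] = ExclusionReason.MISSING_INPUT
        elif r.reactivity < 0:
            out[r.position] = ExclusionReason.NEGATIVE_REACTIVITY
        elif r.bg_area >= 5 * avg_bg:
            out[r.position] = ExclusionReason.HIGH_BACKGROUND
        elif (r.rx_area - r.bg_area) < 0.35 * avg_bg and r.bg_area >= avg_bg:
            out[r.position] = ExclusionReason.LOW_DIFFERENCE
    return out


def random_experiment(rng: np.random.Generator) -> Experiment:
    n = int(rng.integers(1, 51))
    bg = rng.uniform(0, 10, n)
    rx = rng.uniform(0, 10, n)
    records = []
    for i in range(n):
        if rng.random() < 0.05:
            records.append(ProbingRecord(i + 1, "A", None, None, None))
        else:
            records.append(
                ProbingRecord(i + 1, "A", float(rx[i]), float(bg[i]),
                              float(rx[i] - bg[i]))
            )
    if all(r.missing for r in records):
        records[0] = ProbingRecord(1, "A", 1.0, 1.0, 0.0)
    return Experiment(tuple(records))


class TestAutoDetection:
    def test_clean_experiment_is_all_reliable(self):
        exp = build_experiment(bg=[1.0] * 10, rx=[2.0] * 10)
        mask = detect_strong_stops_auto(exp)
        assert mask.excluded_positions == ()
        assert mask.mean_bg == pytest.approx(1.0)

    def test_negative_reactivity_is_excluded(self):
        rx = [2.0] * 10
        rx[3] = 0.9  # reactivity -0.1 at position 4
        exp = build_experiment(bg=[1.0] * 10, rx=rx)
        mask = detect_strong_stops_auto(exp)
        assert mask.excluded_positions == (4,)
        assert mask.reasons[4] is ExclusionReason.NEGATIVE_REACTIVITY

    def test_high_background_boundary_is_inclusive(self):
        # bg (1x9, 9): mean 1.8, five times the mean is exactly 9.0
        bg = [1.0] * 9 + [9.0]
        rx = [3.0] * 9 + [10.0]
        exp = build_experiment(bg=bg, rx=rx)
        mask = detect_strong_stops_auto(exp)
        assert mask.mean_bg == pytest.approx(1.8)
        assert mask.excluded_positions == (10,)
        assert mask.reasons[10] is ExclusionReason.HIGH_BACKGROUND

    def test_low_difference_criterion(self):
        # bg all 2.0 -> mean 2.0; diff 0.5 < 0.7 with bg >= mean fires,
        # diff 1.0 does not
        bg = [2.0] * 10
        rx = [3.0] * 10
        rx[4] = 2.5
        exp = build_experiment(bg=bg, rx=rx)
        mask = detect_strong_stops_auto(exp)
        assert mask.excluded_positions == (5,)
        assert mask.reasons[5] is ExclusionReason.LOW_DIFFERENCE

    def test_missing_records_are_excluded_not_dropped(self):
        exp = build_experiment(bg=[1.0, None, 1.0], rx=[2.0, None, 2.0])
        mask = detect_strong_stops_auto(exp)
        assert mask.reasons[2] is ExclusionReason.MISSING_INPUT
        assert len(mask.positions) == 3

    def test_all_missing_is_an_error(self):
        exp = build_experiment(bg=[None, None], rx=[None, None])
        with pytest.raises(InsufficientDataError, match="no background data"):
            detect_strong_stops_auto(exp)

    def test_agrees_with_literal_oracle_on_random_experiments(self):
        rng = np.random.default_rng(20260921)
        for _ in range(300):
            exp = random_experiment(rng)
            mask = detect_strong_stops_auto(exp)
            assert dict(mask.reasons) == oracle_exclusions(exp)

    @given(data=st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_hypothesis_oracle_equivalence(self, data):
        n = data.draw(st.integers(1, 30))
        records = []
        for i in range(n):
            if data.draw(st.integers(0, 9)) == 0:
                records.append(ProbingRecord(i + 1, "A", None, None, None))
            else:
                rx = data.draw(st.floats(0, 100, allow_nan=False, allow_infinity=False))
                bg = data.draw(st.floats(0, 100, allow_nan=False, allow_infinity=False))
                records.append(ProbingRecord(i + 1, "A", rx, bg, rx - bg))
        if all(r.missing for r in records):
            records[0] = ProbingRecord(1, "A", 1.0, 1.0, 0.0)
        exp = Experiment(tuple(records))
        assert dict(detect_strong_stops_auto(exp).reasons) == oracle_exclusions(exp)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        for c in (1e-3, 0.5, 3.0, 1e4):
            exp = random_experiment(rng)
            scaled = Experiment(
                tuple(
                    ProbingRecord(
                        r.position, r.base,
                        None if r.rx_area is None else r.rx_area * c,
                        None if r.bg_area is None else r.bg_area * c,
                        None if r.reactivity is None else r.reactivity * c,
                    )
                    for r in exp.records
                )
            )
            assert dict(detect_strong_stops_auto(exp).reasons) == dict(
                detect_strong_stops_auto(scaled).reasons
            )

    def test_raising_background_never_rescues_a_position(self):
        # raise bg at one position while lowering another to hold the mean
        # fixed: the raised position may only go reliable -> excluded
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = 20
            bg = rng.uniform(1, 4, n)
            rx = bg + rng.uniform(0.0, 5.0, n)
            exp = build_experiment(bg=list(bg), rx=list(rx))
            before = detect_strong_stops_auto(exp)
            i = int(rng.integers(0, n - 1))
            delta = float(rng.uniform(0.1, 2.0))
            if bg[-1] - delta <= 0:
                continue
            bg2 = bg.copy()
            bg2[i] += delta
            bg2[-1] -= delta  # compensate so mean_bg is unchanged
            exp2 = build_experiment(bg=list(bg2), rx=list(rx))
            after = detect_strong_stops_auto(exp2)
            pos = i + 1
            if not before.is_reliable(pos):
                assert not after.is_reliable(pos)


class TestManualPolicy:
    def test_no_data_treatment_excludes_negatives(self):
        exp = reactivity_experiment([0.5, -0.2, 1.0])
        policy = ManualPolicy(0.0, NegativeTreatment.NO_DATA, frozenset())
        mask, adjusted = apply_manual_policy(exp, policy)
        assert mask.excluded_positions == (2,)
        assert mask.reasons[2] is ExclusionReason.NEGATIVE_REACTIVITY
        assert adjusted.records[1].reactivity == -0.2  # value untouched

    def test_zero_treatment_rewrites_values(self):
        exp = reactivity_experiment([0.5, -0.2, 1.0])
        policy = ManualPolicy(0.0, NegativeTreatment.ZERO, frozenset())
        mask, adjusted = apply_manual_policy(exp, policy)
        assert mask.excluded_positions == ()
        assert [r.reactivity for r in adjusted.records] == [0.5, 0.0, 1.0]

    def test_keep_with_user_selection(self):
        exp = reactivity_experiment([0.5, -0.2, 1.0])
        policy = ManualPolicy(0.0, NegativeTreatment.KEEP, frozenset({3}))
        mask, adjusted = apply_manual_policy(exp, policy)
        assert mask.reasons[3] is ExclusionReason.MANUAL
        assert adjusted.records[1].reactivity == -0.2

    def test_selection_outside_experiment_is_an_error(self):
        exp = reactivity_experiment([0.5, -0.2, 1.0])
        with pytest.raises(ValidationError, match="99"):
            apply_manual_policy(exp, ManualPolicy(0.0, NegativeTreatment.KEEP,
                                                  frozenset({99})))

    def test_custom_negative_threshold(self):
        exp = reactivity_experiment([0.5, 0.05, 1.0])
        policy = ManualPolicy(0.1, NegativeTreatment.NO_DATA, frozenset())
        mask, _ = apply_manual_policy(exp, policy)
        assert mask.excluded_positions == (2,)


class TestHistogramData:
    def test_aligned_series_with_gaps(self):
        exp = build_experiment(bg=[1.0, None, 2.0], rx=[2.0, None, 3.0])
        positions, bg, rx = histogram_data(exp)
        assert positions == (1, 2, 3)
        assert bg == (1.0, None, 2.0)
        assert rx == (2.0, None, 3.0)


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts",
        [(2462, 38, 0, 32), (2431, 35, 0, 25), (4893, 73, 0, 57)],
        ids=["shape", "dms", "all"],
    )
    def test_expert_comparison_rows(self, counts):
        m = classification_metrics(*counts)
        r = m.rounded(2)
        assert r == {"acc": 0.99, "ppv": 1.0, "tpr": 0.99, "tnr": 1.0}

    def test_zero_denominator_is_not_applicable(self):
        m = classification_metrics(1, 0, 0, 0)
        assert m.acc == 1.0 and m.ppv == 1.0 and m.tpr == 1.0
        assert m.tnr is None
        assert m.rounded()["tnr"] is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(-1, 1, 0, 0)
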