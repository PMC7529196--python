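"""Shared builders for the test suite."""

from __future__ import annotations

from typing import Optional, Sequence

import pytest

from ceprobe.core import Dialect, Experiment, ProbingRecord, Reagent, StrongStopMask


def build_experiment(
    bg: Sequence[Optional[float]],
    rx: Sequence[Optional[float]],
    reactivity: Optional[Sequence[Optional[float]]] = None,
    bases: Optional[str] = None,
    reagent: Reagent = Reagent.SHAPE,
    label: str = "test",
) -> Experiment:
    """Experiment from parallel area lists; reactivity defaults to rx - bg."""
    n = len(bg)
    assert len(rx) == n
    records = []
    for i in range(n):
        b = bases[i] if bases else "A"
        if reactivity is not None:
            react = reactivity[i]
        elif rx[i] is not None and bg[i] is not None:
            react = rx[i] - bg[i]
        else:
            react = None
        records.append(ProbingRecord(i + 1, b, rx[i], bg[i], react))
    return Experiment(tuple(records), reagent=reagent, dialect=Dialect.QUSHAPE, label=label)


def reactivity_experiment(values: Sequence[Optional[float]], label: str = "test") -> Experiment:
    """Experiment whose reactivities are given directly (areas are benign)."""
    records = tuple(
        ProbingRecord(i + 1, "A",
                      rx_area=None if v is None else 10.0,
                      bg_area=None if v is None else 1.0,
                      reactivity=v)
        for i, v in enumerate(values)
    )
    return Experiment(records, label=label)


def all_reliable_mask(exp: Experiment) -> StrongStopMask:
    return StrongStopMask(exp.positions, {}, mean_bg=1.0)


@pytest.fixture
def make_exp():
    return build_experiment


@pytest.fixture
def make_reactivity_exp():
    return reactivity_experiment
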