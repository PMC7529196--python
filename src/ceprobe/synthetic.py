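"""Deterministic synthetic peak-table generator with planted strong-stops.

The generator emulates the data regime of a CE probing experiment at the
peak-area-table level (the pipeline's input boundary — no electropherogram
traces are simulated): per-nucleotide background peak areas drawn from a
gamma distribution, reaction peak areas equal to background plus a signal
proportional to an intended normalized reactivity, and a chosen set of
positions planted as RT strong-stops of three kinds:

* ``NEGATIVE`` — reaction below background (negative absolute reactivity);
* ``HIGH_BG`` — background far above the experiment average;
* ``LOW_DIFF`` — weak signal over an above-average background.

Every planted stop satisfies its detection criterion with at least a 10%
margin and every clean position violates all criteria with at least a 10%
margin, so classifier-recovery tests are exact rather than probabilistic.
The construction is verified against a literal re-evaluation of the
criteria before the experiment is returned; an impossible configuration
(e.g. too many high-background stops for the requested length) raises
instead of silently degrading the guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    Dialect,
    Experiment,
    ExclusionReason,
    ProbingRecord,
    Reagent,
    StrongStopMask,
)
from .errors import ValidationError

MARGIN = 1.10  # every criterion satisfied/violated with >= 10% headroom

# planted-stop geometry, in units of the realized mean background
_HIGH_BG_FACTOR = 6.5       # > 5 * MARGIN, with slack for replicate noise
_LOW_DIFF_BG_FACTOR = 1.3   # >= mean * MARGIN
_LOW_DIFF_DIFF_FACTOR = 0.2  # < 0.35 * mean / MARGIN
_NEGATIVE_RX_FACTOR = 0.7   # rx = 0.7 * bg  ->  reactivity = -0.3 * bg

# clean-position safety redraw thresholds (pre-noise, stricter than MARGIN)
_CLEAN_BG_REDRAW_AT = 0.80
_CLEAN_DIFF_SAFE = 0.43
_CLEAN_BG_REDRAW_RANGE = (0.35, 0.78)

_CLEAN_DIFF_EPS = 0.05   # baseline signal (x bg_mean) keeping reactivity positive
_CLEAN_SIGNAL_SCALE = 2.0  # signal per unit intended reactivity (x bg_mean)

_NOISE_CLIP = 0.08  # replicate noise multipliers stay within 1 +/- this


class StopMode(Enum):
    NEGATIVE = "NEGATIVE"
    HIGH_BG = "HIGH_BG"
    LOW_DIFF = "LOW_DIFF"


_MODE_REASON = {
    StopMode.NEGATIVE: ExclusionReason.NEGATIVE_REACTIVITY,
    StopMode.HIGH_BG: ExclusionReason.HIGH_BACKGROUND,
    StopMode.LOW_DIFF: ExclusionReason.LOW_DIFFERENCE,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic experiment.

    ``bg_mean``/``bg_cv`` set the gamma background distribution (arbitrary
    fluorescence units; the pipeline is scale-invariant so only the shape
    matters).  ``reactivity_profile`` is the intended normalized reactivity
    per position in [0, 1.5]; when omitted, a right-skewed profile typical
    of structured RNAs (many unreactive positions, few highly reactive) is
    drawn from the seed.  ``replicate_noise_sd`` is the relative SD of the
    multiplicative between-replicate noise on peak areas.
    """

    length: int
    seed: int
    bg_mean: float = 100.0
    bg_cv: float = 0.2
    reactivity_profile: Optional[Tuple[float, ...]] = None
    planted_stops: Mapping[int, StopMode] = field(default_factory=dict)
    replicate_noise_sd: float = 0.03
    reagent: Reagent = Reagent.SHAPE

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValidationError("synthetic experiments need length >= 20")
        bad = [p for p in self.planted_stops if not 1 <= p <= self.length]
        if bad:
            raise ValidationError(f"planted stops outside 1..{self.length}: {sorted(bad)}")
        if self.reactivity_profile is not None and len(self.reactivity_profile) != self.length:
            raise ValidationError("reactivity_profile must have one value per position")
        if self.replicate_noise_sd < 0:
            raise ValidationError("replicate_noise_sd must be non-negative")


def _solve_mean(bg: np.ndarray, high: np.ndarray, low: np.ndarray) -> float:
    """Mean background after planting, solved exactly.

    Planted HIGH_BG/LOW_DIFF backgrounds are fixed multiples of the final
    mean M, so M satisfies a linear equation in the untouched backgrounds.
    """
    n = bg.size
    n_h, n_l = int(high.sum()), int(low.sum())
    denom = n - _HIGH_BG_FACTOR * n_h - _LOW_DIFF_BG_FACTOR * n_l
    if denom <= 0:
        raise ValidationError(
            f"margins unachievable: {n_h} high-background stops overwhelm "
            f"a length-{n} experiment"
        )
    s_other = float(bg[~(high | low)].sum())
    return s_other / denom


def generate_experiment(
    spec: SyntheticSpec, replicate: int = 0
) -> Tuple[Experiment, StrongStopMask]:
    """Build one replicate and its ground-truth strong-stop mask.

    Deterministic for a fixed (seed, replicate); replicates share the same
    underlying signal and planted stops and differ only by the
    multiplicative noise, so ``replicate_noise_sd = 0`` yields identical
    replicates.
    """
    rng = np.random.default_rng([spec.seed])
    n = spec.length
    B = spec.bg_mean

    bases = rng.choice(list("ACGU"), size=n)
    if spec.reactivity_profile is not None:
        r = np.asarray(spec.reactivity_profile, dtype=float)
    else:
        r = rng.beta(0.7, 2.0, size=n) * 1.5

    shape = 1.0 / spec.bg_cv**2
    bg = np.clip(rng.gamma(shape, B / shape, size=n), 0.2 * B, 2.5 * B)
    diff = (_CLEAN_DIFF_EPS + _CLEAN_SIGNAL_SCALE * r) * B

    modes = np.zeros(n, dtype=int)  # 0 clean, 1 neg, 2 high, 3 low
    for pos, mode in spec.planted_stops.items():
        modes[pos - 1] = {StopMode.NEGATIVE: 1, StopMode.HIGH_BG: 2, StopMode.LOW_DIFF: 3}[mode]
    high = modes == 2
    low = modes == 3
    clean = modes == 0

    # iterate: solve the final mean, then move any clean background that sits
    # too close to the low-signal criterion into a safe band below the mean
    M = _solve_mean(bg, high, low)
    for _ in range(100):
        unsafe = clean & (bg >= _CLEAN_BG_REDRAW_AT * M) & (diff < _CLEAN_DIFF_SAFE * M)
        if not unsafe.any():
            break
        bg[unsafe] = rng.uniform(*_CLEAN_BG_REDRAW_RANGE, size=int(unsafe.sum())) * M
        M = _solve_mean(bg, high, low)
    else:
        raise ValidationError("margins unachievable: clean-background redraw did not converge")

    bg[high] = _HIGH_BG_FACTOR * M
    bg[low] = _LOW_DIFF_BG_FACTOR * M
    diff[low] = _LOW_DIFF_DIFF_FACTOR * M
    diff[high] = 0.5 * M

    # replicate noise: truncated multiplicative jitter on areas
    noise_rng = np.random.default_rng([spec.seed, replicate, 7])
    sd = spec.replicate_noise_sd
    clip = min(3 * sd, _NOISE_CLIP) if sd > 0 else 0.0
    m_bg = 1 + np.clip(noise_rng.normal(0, sd, size=n) if sd > 0 else np.zeros(n), -clip, clip)
    m_df = 1 + np.clip(noise_rng.normal(0, sd, size=n) if sd > 0 else np.zeros(n), -clip, clip)

    bg_out = bg * m_bg
    diff_out = diff * m_df
    neg = modes == 1
    rx_out = bg_out + diff_out
    rx_out[neg] = bg_out[neg] * (1 - (1 - _NEGATIVE_RX_FACTOR) * m_df[neg])

    records = tuple(
        ProbingRecord(
            position=i + 1,
            base=str(bases[i]),
            rx_area=float(rx_out[i]),
            bg_area=float(bg_out[i]),
            reactivity=float(rx_out[i] - bg_out[i]),
        )
        for i in range(n)
    )
    exp = Experiment(
        records=records,
        reagent=spec.reagent,
        dialect=Dialect.QUSHAPE,
        label=f"synthetic_seed{spec.seed}_rep{replicate}",
    )

    mean_bg = float(bg_out.mean())
    reasons = {pos: _MODE_REASON[mode] for pos, mode in spec.planted_stops.items()}
    mask = StrongStopMask(exp.positions, reasons, mean_bg)
    _verify_margins(exp, spec, mean_bg)
    return exp, mask


def _verify_margins(exp: Experiment, spec: SyntheticSpec, mean_bg: float) -> None:
    """Literal margin audit of the construction against the realized mean."""
    M = mean_bg
    for rec in exp.records:
        mode = spec.planted_stops.get(rec.position)
        d = rec.rx_area - rec.bg_area
        if mode is None:
            ok = (
                rec.reactivity >= 0.005 * M
                and rec.bg_area <= 5 * M / MARGIN
                and (rec.bg_area <= M / MARGIN or d >= 0.35 * M * MARGIN)
            )
        elif mode is StopMode.NEGATIVE:
            ok = rec.reactivity <= -0.01 * M
        elif mode is StopMode.HIGH_BG:
            ok = rec.bg_area >= 5 * M * MARGIN and rec.reactivity >= 0.005 * M
        else:  # LOW_DIFF
            ok = (
                rec.bg_area >= M * MARGIN
                and rec.bg_area <= 5 * M / MARGIN
                and 0.005 * M <= d <= 0.35 * M / MARGIN
            )
        if not ok:
            raise ValidationError(
                f"margins unachievable at position {rec.position} "
                f"(mode {mode.name if mode else 'clean'})"
            )


def generate_replicates(
    spec: SyntheticSpec, count: int
) -> Tuple[List[Experiment], StrongStopMask]:
    """Generate ``count`` replicates sharing one planted ground truth.

    The returned mask carries the first replicate's realized mean
    background; the excluded set is identical across replicates.
    """
    if count < 1:
        raise ValidationError("count must be >= 1")
    pairs = [generate_experiment(spec, replicate=i) for i in range(count)]
    return [exp for exp, _ in pairs], pairs[0][1]


def make_boundary_experiment() -> Tuple[Experiment, StrongStopMask]:
    """Adversarial fixture pinning the inclusive high-background boundary.

    Nine positions with background 1.0 and one with 9.0 give a mean of 1.8,
    so the 9.0 position sits exactly at five times the mean and must be
    excluded ("at least five times" is inclusive); the others, with a
    comfortable reaction signal, are reliable.
    """
    records = []
    for i in range(1, 10):
        records.append(ProbingRecord(i, "A", rx_area=3.0, bg_area=1.0, reactivity=2.0))
    records.append(ProbingRecord(10, "A", rx_area=10.0, bg_area=9.0, reactivity=1.0))
    exp = Experiment(tuple(records), label="boundary_high_bg")
    mask = StrongStopMask(
        exp.positions, {10: ExclusionReason.HIGH_BACKGROUND}, mean_bg=1.8
    )
    return exp, mask


def write_fixture(exp: Experiment, dialect: Dialect, path: Union[str, Path]) -> Path:
    """Write an experiment as a dialect-correct peak table.

    Numbers are rendered with ``repr`` so a parse of the written file
    round-trips every field exactly; missing fields become empty cells.
    """
    path = Path(path)

    def cell(v: Optional[float]) -> str:
        return "" if v is None else repr(v)

    lines = []
    if dialect is Dialect.QUSHAPE:
        lines.append("seqNum\tseqRNA\tareaRX\tareaBG\tareaDiff")
        for r in exp.records:
            lines.append(
                f"{r.position}\t{r.base}\t{cell(r.rx_area)}\t{cell(r.bg_area)}\t{cell(r.reactivity)}"
            )
    else:
        for r in exp.records:
            lines.append(
                f"{r.position}\t{r.base}\t{cell(r.rx_area)}\t{cell(r.bg_area)}\t{cell(r.reactivity)}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
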