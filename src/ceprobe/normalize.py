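"""Box-plot normalization of absolute reactivities onto the uniform scale.

The scheme is the standard box-plot normalization for CE probing data:

* ``Q1``/``Q3`` are the quartiles of the included (reliable) reactivities,
  estimated by linear interpolation between order statistics (the common
  "type 7" convention);
* values above the upper extreme ``UP = Q3 + 1.5 * IQR`` are outliers,
  capped at 10% of the data when more than 100 values are included and at
  5% otherwise (when the cap binds, the largest values win);
* the *effective maximum reactivity* is the mean of the top 8% of
  non-outlier values;
* every included reactivity — outliers too — is divided by the effective
  maximum.  Outliers are flagged in the diagnostics, not dropped.

Values near 0 then mark unreactive (constrained) nucleotides and values
above ~0.85 highly reactive (flexible) ones.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np

from .core import (
    ColorBin,
    DEFAULT_BIN_THRESHOLDS,
    Experiment,
    NormalizationDiagnostics,
    NormalizedProfile,
    StrongStopMask,
)
from .errors import InsufficientDataError, NonPositiveScaleError, ValidationError

MIN_RELIABLE = 10
TOP_FRACTION = 0.08
LONG_RNA_CUTOFF = 100  # included-data count above which the 10% cap applies
CAP_LONG = 0.10
CAP_SHORT = 0.05


def outlier_cap(n_included: int) -> Tuple[float, int]:
    """(cap fraction, max outlier count) for ``n_included`` data points."""
    frac = CAP_LONG if n_included > LONG_RNA_CUTOFF else CAP_SHORT
    return frac, math.floor(frac * n_included)


def normalize_profile(exp: Experiment, mask: StrongStopMask) -> NormalizedProfile:
    """Normalize the reliable reactivities of one experiment.

    Positions excluded by the mask (or with missing input) become missing in
    the output; everything else is divided by the effective maximum.
    Requires at least 10 reliable values and a positive effective maximum.
    """
    if exp.positions != mask.positions:
        raise ValidationError("mask does not cover the experiment's positions")

    by_pos = {r.position: r for r in exp.records}
    included = [
        (pos, by_pos[pos].reactivity)
        for pos in mask.reliable_positions
        if not by_pos[pos].missing
    ]
    n = len(included)
    if n < MIN_RELIABLE:
        raise InsufficientDataError(
            f"insufficient data for normalization: {n} reliable values (< {MIN_RELIABLE})"
        )

    values = np.array([v for _, v in included], dtype=float)
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation (type 7)
    up = q3 + 1.5 * (q3 - q1)

    cap_fraction, max_outliers = outlier_cap(n)
    candidates = [(pos, v) for (pos, v) in included if v > up]
    if len(candidates) > max_outliers:
        # keep the most extreme values; ties broken by value then lower position
        candidates.sort(key=lambda pv: (-pv[1], pv[0]))
        candidates = candidates[:max_outliers]
    outlier_positions = frozenset(pos for pos, _ in candidates)

    non_outlier = np.array(
        [v for (pos, v) in included if pos not in outlier_positions], dtype=float
    )
    k = max(1, math.ceil(TOP_FRACTION * non_outlier.size))
    effective_max = float(np.mean(np.sort(non_outlier)[-k:]))
    if effective_max <= 0:
        raise NonPositiveScaleError(
            f"non-positive scale: effective maximum {effective_max}"
        )

    included_pos = {pos for pos, _ in included}
    out_values = tuple(
        (by_pos[pos].reactivity / effective_max) if pos in included_pos else None
        for pos in exp.positions
    )
    diagnostics = NormalizationDiagnostics(
        q1=float(q1),
        q3=float(q3),
        upper_extreme=float(up),
        outlier_positions=outlier_positions,
        effective_max=effective_max,
        cap_fraction=cap_fraction,
        n_included=n,
    )
    profile = NormalizedProfile(
        positions=exp.positions, values=out_values, label=exp.label,
        diagnostics=diagnostics,
    )
    return assign_color_bins(profile)


def assign_color_bins(
    profile: NormalizedProfile,
    thresholds: Tuple[float, float] = DEFAULT_BIN_THRESHOLDS,
) -> NormalizedProfile:
    """Attach the three-way color bin to every non-missing value.

    Bins are half-open: low ``(-inf, t1)``, mid ``[t1, t2)``, high
    ``[t2, inf)`` with defaults (0.4, 0.85); negative values (possible under
    a manual keep policy) fall in the low bin; missing stays missing.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValidationError(f"bin thresholds must satisfy t1 < t2, got {thresholds}")
    bins = tuple(
        None if v is None
        else ColorBin.LOW if v < t1
        else ColorBin.MID if v < t2
        else ColorBin.HIGH
        for v in profile.values
    )
    return replace(profile, bins=bins)


def dms_position_filter(exp: Experiment, enabled: bool = True) -> Experiment:
    """Optionally restrict a DMS experiment to A/C positions.

    DMS methylates the Watson-Crick edge of unpaired adenosines and
    cytosines only, so G/U positions carry no structural signal; when
    enabled they are marked missing before normalization so the quartiles
    and effective maximum are computed over A/C alone.  Disabled is the
    identity (the default: the pipeline normalizes whatever survives
    exclusion).
    """
    if not enabled:
        return exp
    new_records = tuple(
        replace(r, rx_area=None, bg_area=None, reactivity=None)
        if r.base not in ("A", "C")
        else r
        for r in exp.records
    )
    return replace(exp, records=new_records)
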