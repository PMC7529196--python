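"""Averaging of normalized replicate profiles.

Per nucleotide, the mean and sample (n-1) standard deviation are taken over
the replicates where a value is present; missing values are skipped, never
imputed.  The per-position support ``n_obs`` is reported so downstream users
can filter by replicate coverage.
"""

from __future__ import annotations

import statistics
from typing import List, Optional, Sequence, Tuple

from .core import AveragedProfile, NormalizedProfile
from .errors import ValidationError

MAX_REPLICATES = 15


def average_profiles(
    profiles: Sequence[NormalizedProfile], label: str = "averaged"
) -> AveragedProfile:
    """Combine 1-15 normalized replicates into a mean +/- SD profile.

    All profiles must share one position range.  A position's mean is
    missing iff no replicate observes it; its SD is missing unless at least
    two replicates do.
    """
    if not 1 <= len(profiles) <= MAX_REPLICATES:
        raise ValidationError(
            f"expected 1-{MAX_REPLICATES} replicate profiles, got {len(profiles)}"
        )
    positions = profiles[0].positions
    for p in profiles[1:]:
        if p.positions != positions:
            raise ValidationError(
                f"replicate {p.label or '?'} covers a different position range"
            )

    means: List[Optional[float]] = []
    sds: List[Optional[float]] = []
    n_obs: List[int] = []
    for i in range(len(positions)):
        obs = [p.values[i] for p in profiles if p.values[i] is not None]
        n_obs.append(len(obs))
        means.append(statistics.fmean(obs) if obs else None)
        sds.append(statistics.stdev(obs) if len(obs) >= 2 else None)

    return AveragedProfile(positions, tuple(means), tuple(sds), tuple(n_obs), label=label)
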