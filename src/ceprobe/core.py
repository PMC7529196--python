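"""Core domain types for capillary-electrophoresis RNA probing data.

The objects here mirror the stages of the analysis: raw per-nucleotide peak
measurements (:class:`ProbingRecord` grouped into an :class:`Experiment`),
the reliability classification of each position (:class:`StrongStopMask`),
and the normalized per-position reactivity profile
(:class:`NormalizedProfile`) with its normalization diagnostics.

All coordinates are 1-based nucleotide positions, matching the convention of
the upstream capillary-electrophoresis analysis tools; no re-indexing happens
anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping, Optional, Tuple

from .errors import ValidationError

MISSING_CODE = -999
"""Sentinel written for no-data positions in .shape restraint files."""


class Reagent(Enum):
    """Chemical probe used in the experiment."""

    SHAPE = "SHAPE"
    DMS = "DMS"
    OTHER = "OTHER"


class Dialect(Enum):
    """Peak-table dialect of the upstream electropherogram-analysis tool."""

    SHAPEFINDER = "SHAPEFINDER"
    QUSHAPE = "QUSHAPE"


class ExclusionReason(Enum):
    """Why a position was excluded from normalization."""

    NEGATIVE_REACTIVITY = "NEGATIVE_REACTIVITY"
    HIGH_BACKGROUND = "HIGH_BACKGROUND"
    LOW_DIFFERENCE = "LOW_DIFFERENCE"
    MANUAL = "MANUAL"
    MISSING_INPUT = "MISSING_INPUT"


class ColorBin(Enum):
    """Reactivity color bin: low [0, t1), mid [t1, t2), high [t2, inf)."""

    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"


DEFAULT_BIN_THRESHOLDS: Tuple[float, float] = (0.4, 0.85)
DEFAULT_BIN_COLORS: Mapping[ColorBin, str] = MappingProxyType(
    {ColorBin.LOW: "black", ColorBin.MID: "orange", ColorBin.HIGH: "red"}
)

_VALID_BASES = frozenset("ACGUN")


@dataclass(frozen=True)
class ProbingRecord:
    """One nucleotide's raw measurement from a CE probing experiment.

    ``rx_area`` is the reaction-channel (probe-treated) peak area,
    ``bg_area`` the background-channel (untreated control) peak area, both in
    arbitrary fluorescence units.  ``reactivity`` is the absolute,
    pre-normalization reactivity; when the input file carries no reactivity
    column it is the background-subtracted difference ``rx_area - bg_area``.
    Any of the three may be ``None``, in which case the record is *missing*
    and is carried through (never silently dropped) but excluded downstream.
    """

    position: int
    base: str
    rx_area: Optional[float]
    bg_area: Optional[float]
    reactivity: Optional[float]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.base not in _VALID_BASES:
            raise ValidationError(
                f"base must be one of A/C/G/U/N, got {self.base!r} at position {self.position}"
            )
        for name in ("rx_area", "bg_area"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"{name} must be non-negative, got {v} at position {self.position}"
                )

    @property
    def missing(self) -> bool:
        return self.rx_area is None or self.bg_area is None or self.reactivity is None


@dataclass(frozen=True)
class Experiment:
    """An ordered series of :class:`ProbingRecord` from one replicate."""

    records: Tuple[ProbingRecord, ...]
    reagent: Reagent = Reagent.SHAPE
    dialect: Dialect = Dialect.QUSHAPE
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError("an experiment needs at least one record")
        positions = [r.position for r in self.records]
        for a, b in zip(positions, positions[1:]):
            if b <= a:
                raise ValidationError(
                    f"positions must be strictly increasing; {b} follows {a}"
                )

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(r.position for r in self.records)

    @property
    def max_position(self) -> int:
        return self.records[-1].position

    def record_at(self, position: int) -> ProbingRecord:
        for r in self.records:
            if r.position == position:
                return r
        raise KeyError(position)


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the strict alphabet {A, C, G, U}."""

    residues: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - set("ACGU"))
        if bad:
            raise ValidationError(f"not RNA: invalid residues {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StrongStopMask:
    """Per-position reliability classification for one experiment.

    ``reasons`` maps each excluded position to the single criterion that
    fired first; positions absent from it are reliable.  ``mean_bg`` is the
    average background peak area the ratio criteria were evaluated against
    (computed once per experiment, before any exclusion).
    """

    positions: Tuple[int, ...]
    reasons: Mapping[int, ExclusionReason]
    mean_bg: float

    def __post_init__(self) -> None:
        extra = set(self.reasons) - set(self.positions)
        if extra:
            raise ValidationError(f"excluded positions not in mask domain: {sorted(extra)}")
        object.__setattr__(self, "reasons", MappingProxyType(dict(self.reasons)))

    def is_reliable(self, position: int) -> bool:
        return position not in self.reasons

    @property
    def reliable_positions(self) -> Tuple[int, ...]:
        return tuple(p for p in self.positions if p not in self.reasons)

    @property
    def excluded_positions(self) -> Tuple[int, ...]:
        return tuple(p for p in self.positions if p in self.reasons)


@dataclass(frozen=True)
class NormalizationDiagnostics:
    """Intermediate quantities of the box-plot normalization."""

    q1: float
    q3: float
    upper_extreme: float
    outlier_positions: frozenset
    effective_max: float
    cap_fraction: float
    n_included: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class NormalizedProfile:
    """Per-position normalized reactivities; ``None`` marks missing data."""

    positions: Tuple[int, ...]
    values: Tuple[Optional[float], ...]
    label: str = ""
    diagnostics: Optional[NormalizationDiagnostics] = None
    bins: Optional[Tuple[Optional[ColorBin], ...]] = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValidationError("positions and values must be aligned")
        if self.bins is not None and len(self.bins) != len(self.positions):
            raise ValidationError("bins must be aligned with positions")
        for a, b in zip(self.positions, self.positions[1:]):
            if b <= a:
                raise ValidationError("profile positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def is_contiguous_from_one(self) -> bool:
        return self.positions == tuple(range(1, len(self.positions) + 1))

    def value_at(self, position: int) -> Optional[float]:
        return dict(zip(self.positions, self.values))[position]

    def non_missing_values(self) -> Tuple[float, ...]:
        return tuple(v for v in self.values if v is not None)

    @property
    def missing_positions(self) -> Tuple[int, ...]:
        return tuple(p for p, v in zip(self.positions, self.values) if v is None)


@dataclass(frozen=True)
class AveragedProfile:
    """Per-position mean and sample SD across 1-15 normalized replicates."""

    positions: Tuple[int, ...]
    means: Tuple[Optional[float], ...]
    sds: Tuple[Optional[float], ...]
    n_obs: Tuple[int, ...]
    label: str = "averaged"

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.means) == len(self.sds) == len(self.n_obs) == n):
            raise ValidationError("averaged profile fields must be aligned")

    def __len__(self) -> int:
        return len(self.positions)

    def as_profile(self) -> NormalizedProfile:
        """View of the per-position means as a plain profile (for export/plots)."""
        return NormalizedProfile(self.positions, self.means, label=self.label)
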