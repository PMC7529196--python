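"""Plotting of reactivity profiles and experiment comparisons.

Single-experiment views: a color-binned bar plot (one bar per nucleotide,
black/orange/red by reactivity bin by default) and a piecewise-constant step
plot; averaged profiles may draw per-position SD whiskers.  Comparison
views for 2-5 experiments: overlaid comparative step plot, box-and-whisker
plot (whiskers at min/max) and violin plot.  Missing positions always render
as gaps, never as zeros.  Output formats: PNG and EPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import (
    AveragedProfile,
    ColorBin,
    DEFAULT_BIN_COLORS,
    DEFAULT_BIN_THRESHOLDS,
    NormalizedProfile,
)
from .errors import ValidationError
from .normalize import assign_color_bins
from .stats_compare import MAX_EXPERIMENTS, MIN_EXPERIMENTS


class PlotKind(Enum):
    STEP = "STEP"
    BAR = "BAR"
    COMPARATIVE_STEP = "COMPARATIVE_STEP"
    BOX = "BOX"
    VIOLIN = "VIOLIN"


class ImageFormat(Enum):
    PNG = "png"
    EPS = "eps"


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options shared by all plot kinds.

    Figure geometry and fonts are fixed defaults (overridable here) so that
    identical inputs produce identical images.
    """

    kind: PlotKind
    bin_colors: Dict[ColorBin, str] = field(
        default_factory=lambda: dict(DEFAULT_BIN_COLORS)
    )
    bin_thresholds: Tuple[float, float] = DEFAULT_BIN_THRESHOLDS
    output_format: ImageFormat = ImageFormat.PNG
    title: str = ""
    xlabel: str = "nucleotide position"
    ylabel: str = "normalized reactivity"
    figsize: Tuple[float, float] = (10.0, 3.0)
    dpi: int = 100

    def __post_init__(self) -> None:
        if set(self.bin_colors) != set(ColorBin):
            raise ValidationError("bin_colors must cover the LOW/MID/HIGH bins")


def _save(fig, path: Union[str, Path], spec: PlotSpec) -> Path:
    path = Path(path)
    # pinned metadata so identical inputs give byte-stable files
    if spec.output_format is ImageFormat.PNG:
        metadata = {"Software": "ceprobe"}
    else:
        metadata = {"Creator": "ceprobe", "CreationDate": None}
    fig.savefig(path, format=spec.output_format.value, dpi=spec.dpi, metadata=metadata)
    plt.close(fig)
    return path


def _axes(spec: PlotSpec):
    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.set_xlabel(spec.xlabel)
    ax.set_ylabel(spec.ylabel)
    if spec.title:
        ax.set_title(spec.title)
    return fig, ax


def _as_arrays(profile: Union[NormalizedProfile, AveragedProfile]):
    if isinstance(profile, AveragedProfile):
        pos = np.array(profile.positions)
        val = np.array([np.nan if v is None else v for v in profile.means])
        sd = np.array([np.nan if s is None else s for s in profile.sds])
        return pos, val, sd
    pos = np.array(profile.positions)
    val = np.array([np.nan if v is None else v for v in profile.values])
    return pos, val, None


def plot_profile(
    profile: Union[NormalizedProfile, AveragedProfile],
    spec: PlotSpec,
    path: Union[str, Path],
) -> Path:
    """Render one profile as a bar or step plot.

    Bars are colored by the same bin assignment used everywhere else in the
    pipeline; missing positions leave gaps.  For an averaged profile the
    per-position SD is drawn as error whiskers.
    """
    if len(profile) == 0:
        raise ValidationError("cannot plot an empty profile")
    if spec.kind not in (PlotKind.BAR, PlotKind.STEP):
        raise ValidationError(f"plot_profile cannot render {spec.kind}")

    pos, val, sd = _as_arrays(profile)
    fig, ax = _axes(spec)
    if spec.kind is PlotKind.BAR:
        base = profile.as_profile() if isinstance(profile, AveragedProfile) else profile
        binned = assign_color_bins(base, spec.bin_thresholds)
        colors = [
            spec.bin_colors[b] if b is not None else "none" for b in binned.bins
        ]
        ax.bar(pos, np.nan_to_num(val, nan=0.0), width=1.0, color=colors,
               edgecolor="none")
        if sd is not None and np.isfinite(sd).any():
            ax.errorbar(pos, val, yerr=sd, fmt="none", ecolor="gray",
                        elinewidth=0.8, capsize=1.5)
    else:
        ax.step(pos, val, where="mid", color="black", linewidth=1.0)
        if sd is not None and np.isfinite(sd).any():
            ax.errorbar(pos, val, yerr=sd, fmt="none", ecolor="gray",
                        elinewidth=0.8, capsize=1.5)
    return _save(fig, path, spec)


def plot_comparison(
    profiles: Sequence[NormalizedProfile],
    spec: PlotSpec,
    path: Union[str, Path],
) -> Path:
    """Render a comparative step, box-and-whisker or violin plot of 2-5
    experiments.  Box whiskers span the full min/max range; the violin shows
    a density per experiment."""
    if not MIN_EXPERIMENTS <= len(profiles) <= MAX_EXPERIMENTS:
        raise ValidationError(
            f"comparison plots need {MIN_EXPERIMENTS}-{MAX_EXPERIMENTS} profiles, "
            f"got {len(profiles)}"
        )
    labels = [p.label or f"experiment_{i+1}" for i, p in enumerate(profiles)]
    fig, ax = _axes(spec)

    if spec.kind is PlotKind.COMPARATIVE_STEP:
        for p, lbl in zip(profiles, labels):
            pos, val, _ = _as_arrays(p)
            ax.step(pos, val, where="mid", linewidth=1.0, label=lbl)
        ax.legend()
    elif spec.kind in (PlotKind.BOX, PlotKind.VIOLIN):
        samples = [np.array(p.non_missing_values(), dtype=float) for p in profiles]
        for lbl, s in zip(labels, samples):
            if s.size == 0:
                raise ValidationError(f"{lbl}: no values to plot")
        ax.set_xlabel("experiment")
        if spec.kind is PlotKind.BOX:
            ax.boxplot(samples, tick_labels=labels, whis=(0, 100))
        else:
            ax.violinplot(samples, showmedians=True)
            ax.set_xticks(range(1, len(labels) + 1), labels)
    else:
        raise ValidationError(f"plot_comparison cannot render {spec.kind}")
    return _save(fig, path, spec)
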