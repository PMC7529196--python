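"""Statistical comparison of 2-5 normalized probing experiments.

The cascade runs a Shapiro-Wilk normality test per experiment and a Bartlett
test of variance homogeneity across experiments, then — only if the data
depart from normality (any sample with Shapiro-Wilk p below alpha) — the
appropriate nonparametric location test: two-sided Mann-Whitney for two
experiments, Kruskal-Wallis rank-sum for three to five.  When every sample
looks normal no location test runs and the report says so; Bartlett's result
is informational and never gates the branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import NormalizedProfile
from .errors import InsufficientDataError, ValidationError

MIN_EXPERIMENTS = 2
MAX_EXPERIMENTS = 5
MIN_SAMPLE = 3
EXACT_MW_MAX_N = 20  # exact Mann-Whitney up to this per-sample size


class SelectedTest(Enum):
    MANN_WHITNEY = "Mann-Whitney U test (two-sided)"
    KRUSKAL_WALLIS = "Kruskal-Wallis rank-sum test"
    NONE = "none"


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of the normality / variance / location-test cascade."""

    labels: Tuple[str, ...]
    shapiro_p: Tuple[float, ...]
    normality_verdict: Tuple[bool, ...]
    bartlett_p: float
    equal_variance: bool
    selected_test: SelectedTest
    test_p: Optional[float]
    alpha: float
    note: str = ""

    @property
    def n_experiments(self) -> int:
        return len(self.labels)


def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value: exact for small tie-free samples,
    continuity-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if max(a.size, b.size) <= EXACT_MW_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_experiments(
    profiles: Sequence[NormalizedProfile], alpha: float = 0.05
) -> ComparisonReport:
    """Run the test cascade over the non-missing values of each profile.

    Each profile contributes its non-missing normalized reactivities as one
    sample (missing positions are ignored, so padding a profile with missing
    data never changes the report).  Every sample needs at least 3 values.
    """
    if not MIN_EXPERIMENTS <= len(profiles) <= MAX_EXPERIMENTS:
        raise ValidationError(
            f"comparison needs {MIN_EXPERIMENTS}-{MAX_EXPERIMENTS} experiments, "
            f"got {len(profiles)}"
        )
    labels = tuple(p.label or f"experiment_{i+1}" for i, p in enumerate(profiles))
    samples = [np.array(p.non_missing_values(), dtype=float) for p in profiles]
    for lbl, s in zip(labels, samples):
        if s.size < MIN_SAMPLE:
            raise InsufficientDataError(
                f"{lbl}: only {s.size} non-missing values (< {MIN_SAMPLE})"
            )

    shapiro_p = tuple(float(stats.shapiro(s).pvalue) for s in samples)
    normality = tuple(p >= alpha for p in shapiro_p)
    bartlett_p = float(stats.bartlett(*samples).pvalue)

    if all(normality):
        return ComparisonReport(
            labels, shapiro_p, normality, bartlett_p, bartlett_p >= alpha,
            SelectedTest.NONE, None, alpha,
            note=(
                "all samples are consistent with a normal distribution "
                f"(Shapiro-Wilk p >= {alpha}); no nonparametric location test was run"
            ),
        )

    if len(samples) == 2:
        test = SelectedTest.MANN_WHITNEY
        p = mann_whitney_p(samples[0], samples[1])
    else:
        test = SelectedTest.KRUSKAL_WALLIS
        p = float(stats.kruskal(*samples).pvalue)
    return ComparisonReport(
        labels, shapiro_p, normality, bartlett_p, bartlett_p >= alpha,
        test, p, alpha,
    )


def report_text(report: ComparisonReport) -> str:
    """Deterministic plain-text summary of a comparison.

    States per-experiment normality verdicts, the variance-homogeneity
    verdict, which location test ran and its p-value (or why none did).
    """
    lines = [
        f"Statistical comparison of {report.n_experiments} experiments "
        f"(alpha = {report.alpha!r})",
        "",
        "Normality (Shapiro-Wilk):",
    ]
    for lbl, p, ok in zip(report.labels, report.shapiro_p, report.normality_verdict):
        verdict = "consistent with normal" if ok else "departs from normal"
        lines.append(f"  {lbl}: p = {p!r} -> {verdict}")
    var_verdict = "equal variances" if report.equal_variance else "unequal variances"
    lines += [
        "",
        f"Variance homogeneity (Bartlett): p = {report.bartlett_p!r} -> {var_verdict}",
        "",
    ]
    if report.selected_test is SelectedTest.NONE:
        lines.append(f"Location test: none performed ({report.note})")
    else:
        lines.append(
            f"Location test: {report.selected_test.value}, p = {report.test_p!r}"
        )
    return "\n".join(lines) + "\n"
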