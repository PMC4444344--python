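"""Group-comparison statistics and library-level summaries.

The context-variability procedure applied to promoter activities measured
under several conditions: one-way ANOVA across conditions; if significant,
all pairwise homoscedastic t-tests with Bonferroni correction; conditions
are merged into statistically indistinguishable sub-groups; the final CV is
computed over the sub-group means (or over all condition means when no
sub-groups emerge) and corrected for small samples as CV * (1 + 1/(4N)).

Library summaries report the fold activity range (max/min) and the mean
relative spacing between strength-sorted adjacent members.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

DEFAULT_ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class MeasurementGroup:
    """Replicate measurements (e.g. RPU) for one condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise StatsError(f"group {self.label!r}: need >= 2 replicate values")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class GroupComparison:
    anova_p: float
    subgroups: tuple[tuple[str, ...], ...]
    cv_corrected: Optional[float]
    n_used: Optional[int]
    notes: str = ""


@dataclass(frozen=True)
class LibrarySummary:
    fold_range: float
    mean_spacing: float
    n_members: int
    spacing_definition: str = "adjacent-relative"


def anova(groups: Sequence[MeasurementGroup]) -> float:
    """One-way fixed-effects ANOVA p-value across the groups."""
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    if all(np.ptp(g.values) == 0 for g in groups):
        raise StatsError("zero within-group variance in all groups")
    return float(sps.f_oneway(*[g.values for g in groups]).pvalue)


def bonferroni_threshold(n_groups: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Per-test significance threshold: alpha / C(n_groups, 2)."""
    n_pairs = n_groups * (n_groups - 1) // 2
    return alpha / n_pairs


def posthoc_subgroups(
    groups: Sequence[MeasurementGroup], alpha: float = DEFAULT_ALPHA
) -> tuple[tuple[str, ...], ...]:
    """Partition conditions into statistically indistinguishable sub-groups.

    All pairwise equal-variance (homoscedastic) t-tests are run at the
    Bonferroni-corrected threshold alpha / (number of pairs).  Conditions are
    then sorted by mean and adjacent non-significant pairs are chain-merged;
    an adjacent significant pair starts a new block.  When no pair is
    significant the trivial one-block partition is returned.
    """
    if len(groups) < 2:
        return (tuple(g.label for g in groups),)
    thr = bonferroni_threshold(len(groups), alpha)
    order = sorted(range(len(groups)), key=lambda i: groups[i].mean)
    blocks: list[list[str]] = [[groups[order[0]].label]]
    prev = order[0]
    for idx in order[1:]:
        p = float(
            sps.ttest_ind(groups[prev].values, groups[idx].values, equal_var=True).pvalue
        )
        if p < thr:
            blocks.append([groups[idx].label])
        else:
            blocks[-1].append(groups[idx].label)
        prev = idx
    return tuple(tuple(b) for b in blocks)


def corrected_cv(values: Sequence[float]) -> float:
    """Small-sample-corrected coefficient of variation:
    (sd/|mean|) * (1 + 1/(4N)), sample sd (ddof=1)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise StatsError("corrected_cv needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0:
        raise StatsError("corrected_cv undefined for zero mean")
    cv = float(np.std(v, ddof=1)) / abs(mean)
    return cv * (1.0 + 1.0 / (4.0 * n))


def group_cv_procedure(
    groups: Sequence[MeasurementGroup], alpha: float = DEFAULT_ALPHA
) -> GroupComparison:
    """Full context-variability procedure for one promoter across conditions.

    ANOVA first; when non-significant no CV is reported.  When significant,
    sub-groups are formed by Bonferroni-corrected pairwise t-tests; the CV is
    computed over the sub-group means (members of a sub-group averaged
    first), corrected for small samples with N = number of values entering
    the CV.  When the post-hoc step finds no separation (a single block),
    the CV is computed over all condition means instead.
    """
    p = anova(groups)
    by_label = {g.label: g for g in groups}
    if p >= alpha:
        return GroupComparison(
            anova_p=p, subgroups=(tuple(g.label for g in groups),),
            cv_corrected=None, n_used=None,
            notes="no significant difference (ANOVA)",
        )
    subgroups = posthoc_subgroups(groups, alpha)
    if len(subgroups) > 1:
        means = [float(np.mean([by_label[l].mean for l in block])) for block in subgroups]
        notes = "CV over sub-group means"
    else:
        means = [g.mean for g in groups]
        notes = "significant ANOVA but no sub-groups; CV over all condition means"
    return GroupComparison(
        anova_p=p, subgroups=subgroups,
        cv_corrected=corrected_cv(means), n_used=len(means), notes=notes,
    )


def mean_spacing(activities: np.ndarray, definition: str = "adjacent-relative") -> float:
    a = np.sort(np.asarray(activities, dtype=float))
    if definition == "adjacent-relative":
        return float(np.mean((a[1:] - a[:-1]) / a[1:]))
    if definition == "geometric":
        return float((a[-1] / a[0]) ** (1.0 / (len(a) - 1)) - 1.0)
    raise StatsError(f"unknown spacing definition {definition!r}")


def library_summary(
    activities: Sequence[float], spacing_definition: str = "adjacent-relative"
) -> LibrarySummary:
    """Fold activity range and mean spacing of a strength-graded library.

    ``activities`` are the member activities (RPU) above detection; callers
    exclude members at or below the detection limit.  fold_range = max/min;
    mean spacing = mean over strength-sorted adjacent pairs of
    (a[i+1] - a[i]) / a[i+1] (a geometric alternative is available).
    """
    a = np.asarray(activities, dtype=float)
    if len(a) < 2:
        raise StatsError("library summary needs at least 2 members")
    if np.any(a <= 0):
        raise StatsError("all member activities must be > 0")
    return LibrarySummary(
        fold_range=float(np.max(a) / np.min(a)),
        mean_spacing=mean_spacing(a, spacing_definition),
        n_members=len(a),
        spacing_definition=spacing_definition,
    )
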