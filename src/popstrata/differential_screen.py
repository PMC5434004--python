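"""Group-difference IBD-sharing screen with percentile flags and Grubbs outlier stars.

Each focal population's IBD sharing with a fixed panel of comparison
populations forms a vector; vectors are averaged within population groups and
group pairs are subtracted. Entries of a difference vector strictly exceeding
its own empirical 0.10/0.90 percentile bounds are flagged (positive excess to
the first group, negative to the second), and each flagged entry is assessed
with the two-sided single-outlier Grubbs test, starred at p < 0.05 (*),
p < 0.01 (**) and p < 0.001 (***).

The screen is a pure function of the sharing matrix and the group
definitions: every report is exactly antisymmetric under swapping the two
groups (differences negate, excess flags exchange, p-values are unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ibd_sharing import TOTAL_CLASS, SharingMatrix

LOWER_PCT = 0.10
UPPER_PCT = 0.90
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

FLAG_GRP1 = "grp1_excess"
FLAG_GRP2 = "grp2_excess"
FLAG_NONE = "none"


class ScreenError(ValueError):
    pass


@dataclass
class SharingVector:
    """One focal population's W values against an ordered comparison panel."""

    focal: str
    comparisons: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.comparisons):
            raise ScreenError("vector length does not match comparison panel")


@dataclass
class DifferenceReport:
    """Grp1-minus-grp2 averaged sharing differences with flags and outlier tests."""

    grp1: str
    grp2: str
    comparisons: list[str]
    difference: np.ndarray
    flags: list[str] = field(default_factory=list)
    p_values: np.ndarray | None = None
    stars: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "comparison": self.comparisons,
                "difference": self.difference,
                "flag": self.flags if self.flags else [FLAG_NONE] * len(self.comparisons),
            }
        )
        df["grp1"] = self.grp1
        df["grp2"] = self.grp2
        if self.p_values is not None:
            df["p_value"] = self.p_values
            df["stars"] = self.stars
        return df


def sharing_vectors(
    matrix: SharingMatrix,
    focal_populations: list[str],
    comparison_populations: list[str],
    length_class: str = TOTAL_CLASS,
) -> list[SharingVector]:
    """Extract aligned sharing vectors, one per focal population."""
    for f in focal_populations:
        if f in comparison_populations:
            raise ScreenError(f"focal population {f!r} appears in the comparison panel")
    out = []
    for f in focal_populations:
        try:
            vals = [matrix.value(f, c, length_class) for c in comparison_populations]
        except KeyError as exc:
            raise ScreenError(f"missing sharing cell for focal {f!r}: {exc}") from exc
        out.append(SharingVector(f, list(comparison_populations), np.array(vals)))
    return out


def group_difference(
    vectors: list[SharingVector],
    group_assignment: dict[str, str],
    grp1: str,
    grp2: str,
) -> DifferenceReport:
    """Mean vector of grp1 minus mean vector of grp2, per comparison."""
    by_focal = {v.focal: v for v in vectors}
    members1 = [f for f, g in group_assignment.items() if g == grp1 and f in by_focal]
    members2 = [f for f, g in group_assignment.items() if g == grp2 and f in by_focal]
    if not members1 or not members2:
        raise ScreenError(f"empty group among ({grp1!r}, {grp2!r})")
    comps = vectors[0].comparisons
    for v in vectors:
        if v.comparisons != comps:
            raise ScreenError("comparison panels differ across vectors")
    mean1 = np.mean([by_focal[f].values for f in members1], axis=0)
    mean2 = np.mean([by_focal[f].values for f in members2], axis=0)
    return DifferenceReport(grp1, grp2, list(comps), mean1 - mean2)


def flag_outliers(
    report: DifferenceReport,
    lower_pct: float = LOWER_PCT,
    upper_pct: float = UPPER_PCT,
) -> DifferenceReport:
    """Flag entries strictly outside the vector's own percentile bounds.

    The empirical quantiles (linear interpolation between order statistics) of
    the difference vector itself define the bounds; values strictly above the
    upper bound are grp1 excess, strictly below the lower bound grp2 excess.
    """
    d = report.difference
    if len(d) < 5:
        raise ScreenError("need >= 5 comparisons to set percentile bounds")
    if np.allclose(d, d[0]):
        import warnings

        warnings.warn("constant difference vector: no outliers flagged", stacklevel=2)
        flags = [FLAG_NONE] * len(d)
    else:
        lo = np.quantile(d, lower_pct)
        hi = np.quantile(d, upper_pct)
        flags = [
            FLAG_GRP1 if x > hi else FLAG_GRP2 if x < lo else FLAG_NONE for x in d
        ]
    return DifferenceReport(
        report.grp1, report.grp2, report.comparisons, d.copy(), flags
    )


def grubbs_outlier_test(values: np.ndarray, candidate_index: int) -> tuple[float, float, str]:
    """Two-sided single-outlier Grubbs test for one candidate entry.

    G = |x_c - mean| / sd; the p-value inverts the critical-value relation
    G_crit(alpha) = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}, i.e. p = 2n * SF_t(t(G), n-2) clipped to [0, 1].
    Returns (G, p, stars).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ScreenError("Grubbs test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ScreenError("zero variance: Grubbs statistic undefined")
    G = abs(x[candidate_index] - x.mean()) / sd
    gmax = (n - 1) / np.sqrt(n)
    if G >= gmax:
        p = 0.0
    else:
        t_sq = (n - 2) * G**2 / (gmax**2 - G**2)
        p = float(min(1.0, 2 * n * stats.t.sf(np.sqrt(t_sq), n - 2)))
    stars = ""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            stars = s
            break
    return float(G), p, stars


def apply_grubbs(report: DifferenceReport) -> DifferenceReport:
    """Grubbs-test each flagged entry of a report (one-outlier test per cell)."""
    d = report.difference
    p_values = np.full(len(d), np.nan)
    stars = [""] * len(d)
    for i, flag in enumerate(report.flags):
        if flag == FLAG_NONE:
            continue
        _, p, s = grubbs_outlier_test(d, i)
        p_values[i] = p
        stars[i] = s
    return DifferenceReport(
        report.grp1, report.grp2, report.comparisons, d.copy(), list(report.flags),
        p_values, stars,
    )


def run_screen(
    matrix: SharingMatrix,
    group_defs: dict[str, list[str]],
    comparison_populations: list[str],
    length_class: str = TOTAL_CLASS,
    lower_pct: float = LOWER_PCT,
    upper_pct: float = UPPER_PCT,
) -> list[DifferenceReport]:
    """Difference -> percentile flag -> Grubbs test for every unordered group pair."""
    if len(group_defs) < 2:
        raise ScreenError("need at least 2 groups")
    focal = [p for members in group_defs.values() for p in members]
    if len(set(focal)) != len(focal):
        raise ScreenError("a population appears in more than one group")
    vectors = sharing_vectors(matrix, focal, comparison_populations, length_class)
    assignment = {p: g for g, members in group_defs.items() for p in members}
    reports = []
    for g1, g2 in combinations(sorted(group_defs), 2):
        rep = group_difference(vectors, assignment, g1, g2)
        rep = flag_outliers(rep, lower_pct, upper_pct)
        reports.append(apply_grubbs(rep))
    return reports


def screen_to_frame(reports: list[DifferenceReport]) -> pd.DataFrame:
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
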