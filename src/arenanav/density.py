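"""Point-pattern density over arena partitions, with exact binomial tests.

For a set of points (pooled encoding-path samples or recall responses) and a
partition of the arena, reports per-region counts, area-normalized densities
(points per square vm), the density ratio between the two regions of
interest, and an exact two-sided binomial test of the observed split against
the area-based null proportion:

* radial partition — inner disk vs outer annulus, null 25% / 75% by area;
* quadrant pair — landmark quadrant vs the diametrically opposite quadrant
  (equal areas), null 0.5, with points outside those two quadrants excluded.

The two-sided p-value uses the minimum-likelihood rule (sum the null
probabilities of all outcomes no more likely than the observed count).
Group contrasts are summarised as the difference and the ratio of the two
groups' density ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ArenaConfig, quadrant_region, radial_region, region_area
from .session import ParticipantSession

__all__ = [
    "DensityReport",
    "GroupDensityComparison",
    "binomial_exact_test",
    "radial_density_report",
    "quadrant_density_report",
    "compare_group_densities",
    "density_report_from_counts",
    "pooled_points",
]


@dataclass(frozen=True)
class DensityReport:
    """Counts, densities, and the binomial test for one partition."""

    scheme: str  # "radial" | "quadrant_pair"
    counts: Mapping[str, int]
    areas: Mapping[str, float]
    densities: Mapping[str, float]
    proportions: Mapping[str, float]
    density_ratio: float  # inner/outer or upper_left/lower_right
    n_used: int
    n_excluded: int
    binomial_p: float

    @property
    def ratio_labels(self) -> tuple[str, str]:
        return ("inner", "outer") if self.scheme == "radial" else (
            "upper_left",
            "lower_right",
        )


@dataclass(frozen=True)
class GroupDensityComparison:
    """Contrast of two groups' density ratios on the same partition."""

    scheme: str
    ratio_a: float
    ratio_b: float
    difference: float  # a − b
    ratio_of_ratios: float  # a / b


def binomial_exact_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood two-sidedness)."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binomtest(int(k), int(n), p0).pvalue)


def density_report_from_counts(
    scheme: str, counts: Mapping[str, int], arena: ArenaConfig, n_excluded: int = 0
) -> DensityReport:
    """Build a report from already-tallied counts (e.g. published tables)."""
    if scheme == "radial":
        labels, p0_label, p0 = ("inner", "outer"), "inner", None
        areas = {lab: region_area(lab, arena) for lab in labels}
        p0 = areas["inner"] / (areas["inner"] + areas["outer"])
    elif scheme == "quadrant_pair":
        labels, p0_label, p0 = ("upper_left", "lower_right"), "upper_left", 0.5
        areas = {lab: region_area(lab, arena) for lab in labels}
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")
    counts = {lab: int(counts.get(lab, 0)) for lab in labels}
    n_used = sum(counts.values())
    if n_used == 0:
        raise ValueError(f"no points in the {scheme} partition regions")
    densities = {lab: counts[lab] / areas[lab] for lab in labels}
    proportions = {lab: counts[lab] / n_used for lab in labels}
    num, den = labels
    ratio = densities[num] / densities[den] if densities[den] > 0 else float("inf")
    p = binomial_exact_test(counts[p0_label], n_used, p0)
    return DensityReport(
        scheme=scheme,
        counts=counts,
        areas=areas,
        densities=densities,
        proportions=proportions,
        density_ratio=ratio,
        n_used=n_used,
        n_excluded=n_excluded,
        binomial_p=p,
    )


def radial_density_report(points: Sequence, arena: ArenaConfig) -> DensityReport:
    """Inner-disk vs outer-annulus density report for a point set.

    Out-of-arena points are excluded from n and reported in ``n_excluded``.
    """
    counts = {"inner": 0, "outer": 0}
    excluded = 0
    for p in points:
        lab = radial_region(p, arena)
        if lab == "outside":
            excluded += 1
        else:
            counts[lab] += 1
    return density_report_from_counts("radial", counts, arena, n_excluded=excluded)


def quadrant_density_report(points: Sequence, arena: ArenaConfig) -> DensityReport:
    """Landmark-quadrant vs opposite-quadrant density report.

    Points on the axes, in the other two quadrants, or outside the arena are
    excluded from n and reported in ``n_excluded``.
    """
    counts = {"upper_left": 0, "lower_right": 0}
    excluded = 0
    for p in points:
        if radial_region(p, arena) == "outside":
            excluded += 1
            continue
        lab = quadrant_region(p, arena)
        if lab in counts:
            counts[lab] += 1
        else:
            excluded += 1
    return density_report_from_counts(
        "quadrant_pair", counts, arena, n_excluded=excluded
    )


def compare_group_densities(
    report_a: DensityReport, report_b: DensityReport
) -> GroupDensityComparison:
    """Difference (a − b) and ratio (a / b) of two groups' density ratios."""
    if report_a.scheme != report_b.scheme:
        raise ValueError(
            f"partition scheme mismatch: {report_a.scheme!r} vs {report_b.scheme!r}"
        )
    ra, rb = report_a.density_ratio, report_b.density_ratio
    return GroupDensityComparison(
        scheme=report_a.scheme,
        ratio_a=ra,
        ratio_b=rb,
        difference=ra - rb,
        ratio_of_ratios=ra / rb if rb != 0 else float("inf"),
    )


def pooled_points(
    sessions: Sequence[ParticipantSession],
    source: str = "encoding",
    cue: str | None = None,
    group: str | None = None,
) -> np.ndarray:
    """Pool points across participants (the group-level analysis unit).

    ``source`` is ``"encoding"`` (all path samples) or ``"recall"``
    (response coordinates, optionally restricted to one cue condition).
    """
    pts: list[np.ndarray] = []
    for s in sessions:
        if group is not None and s.group != group:
            continue
        if source == "encoding":
            if s.encoding_path is not None:
                pts.append(s.encoding_path.points)
        elif source == "recall":
            for t in s.recall_trials:
                if cue is None or t.cue == cue:
                    pts.append(np.array([[t.response.x, t.response.y]]))
        else:
            raise ValueError(f"unknown source {source!r}")
    if not pts:
        return np.empty((0, 2))
    return np.concatenate(pts, axis=0)
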