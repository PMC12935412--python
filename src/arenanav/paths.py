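"""Path-level metrics and their two-sample comparison.

Quantifies movement from position samples: per-step distances, total path
length, mean step distance, and the mean distance of path points from the
landmark and the arena center. Metrics are defined per sample (the task
samples at 1 Hz); irregular timestamps are accepted with a warning since
every metric here is a function of the sample sequence, not of time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .geometry import ArenaConfig
from .session import EncodingPath, ParticipantSession

__all__ = ["PathSummary", "WelchResult", "step_distances", "path_summary",
           "welch_t", "summarize_paths"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathSummary:
    participant_id: str
    phase: str
    mean_step: float
    total_distance: float
    mean_dist_landmark: float
    mean_dist_center: float
    n_samples: int


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t test (unequal variances)."""

    t: float
    df: float
    p: float


def step_distances(path: EncodingPath) -> np.ndarray:
    """Euclidean distance between consecutive position samples."""
    if path.n_samples < 2:
        raise InsufficientDataError(
            f"need >=2 samples to form steps, got {path.n_samples}"
        )
    if len(path.times) > 1:
        dt = np.diff(path.times)
        if not np.allclose(dt, dt[0]):
            log.warning(
                "path %s has irregular sample spacing; metrics are per-sample",
                path.participant_id,
            )
    return np.hypot(*np.diff(path.points, axis=0).T)


def path_summary(path: EncodingPath, arena: ArenaConfig) -> PathSummary:
    """Per-path movement summary.

    ``mean_step`` = total distance / (n − 1); the landmark/center mean
    distances average over *all* samples, the start point included.
    """
    steps = step_distances(path)
    total = float(steps.sum())
    d_lm = np.hypot(
        path.points[:, 0] - arena.landmark.x, path.points[:, 1] - arena.landmark.y
    )
    d_c = np.hypot(
        path.points[:, 0] - arena.center.x, path.points[:, 1] - arena.center.y
    )
    return PathSummary(
        participant_id=path.participant_id,
        phase=path.phase,
        mean_step=total / (path.n_samples - 1),
        total_distance=total,
        mean_dist_landmark=float(d_lm.mean()),
        mean_dist_center=float(d_c.mean()),
        n_samples=path.n_samples,
    )


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> WelchResult:
    """Independent-samples t test with Welch's unequal-variance correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("welch_t needs >=2 values per sample")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise InsufficientDataError("welch_t undefined for two zero-variance samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def summarize_paths(
    sessions: Sequence[ParticipantSession], arena: ArenaConfig
) -> pd.DataFrame:
    """Per-participant path summaries as a tidy table.

    Sessions without a stored path are skipped; the caller can compare
    ``len(result)`` to ``len(sessions)`` for the n actually used.
    """
    rows = []
    for s in sessions:
        if s.encoding_path is None:
            continue
        ps = path_summary(s.encoding_path, arena)
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "phase": ps.phase,
                "mean_step": ps.mean_step,
                "total_distance": ps.total_distance,
                "mean_dist_landmark": ps.mean_dist_landmark,
                "mean_dist_center": ps.mean_dist_center,
                "n_samples": ps.n_samples,
            }
        )
    return pd.DataFrame(rows)
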