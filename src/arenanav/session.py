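"""Session containers: encoding paths, recall trials, and participants.

A session bundles everything recorded for one participant: the 1 Hz encoding
path through the arena (with the 16 object-collection events), the 16 recall
trials (8 per cue condition, each object tested twice per cue), and the
group label. Paths may be absent — real datasets lose files — and analyses
that need them skip such sessions while reporting the n actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import ArenaConfig, Point, distance

CUE_EGO = "ego"
CUE_ALLO = "allo"
CUES = (CUE_EGO, CUE_ALLO)

#: accepted spellings on file input, canonicalised to the short tokens
CUE_ALIASES = {
    "ego": CUE_EGO,
    "egocentric": CUE_EGO,
    "allo": CUE_ALLO,
    "allocentric": CUE_ALLO,
}

GROUP_HC = "HC"
GROUP_AMCI = "aMCI"


@dataclass(frozen=True)
class CollectionEvent:
    """One object pickup during encoding."""

    object_id: str
    repetition: int  # 1-4
    time_s: float


@dataclass
class EncodingPath:
    """A 1 Hz sampled trajectory plus its object-collection events."""

    participant_id: str
    times: np.ndarray  # (n,) seconds, strictly increasing
    points: np.ndarray  # (n, 2) virtual meters
    collections: tuple[CollectionEvent, ...] = ()
    phase: str = "encoding"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if len(self.times) != len(self.points):
            raise ValueError("times and points length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def in_arena(self, arena: ArenaConfig, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of samples inside the arena (boundary included)."""
        d = np.hypot(
            self.points[:, 0] - arena.center.x, self.points[:, 1] - arena.center.y
        )
        return d <= arena.radius + tol


@dataclass(frozen=True)
class RecallTrial:
    """One retrieval event: cue condition, cued object, response."""

    trial_index: int  # 1-based presentation order
    cue: str  # "ego" | "allo"
    object_id: str
    response: Point
    response_time_s: float

    def __post_init__(self):
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}; expected one of {CUES}")


@dataclass
class ParticipantSession:
    """All data for one participant."""

    participant_id: str
    group: str  # "HC" | "aMCI"
    recall_trials: tuple[RecallTrial, ...]
    encoding_path: Optional[EncodingPath] = None
    subtype: Optional[str] = None  # "aMCIsd" | "aMCImd"
    encoding_time_min: Optional[float] = None
    seed: Optional[int] = None

    def trials_for_cue(self, cue: str) -> list[RecallTrial]:
        return [t for t in self.recall_trials if t.cue == cue]

    def validate_structure(self, arena: ArenaConfig) -> list[str]:
        """Return a list of structural violations (empty = valid).

        Checks the task contract: 16 trials, 8 per cue, each object twice
        per cue, unique trial indices, in-arena responses and path points.
        """
        problems: list[str] = []
        pid = self.participant_id
        trials = self.recall_trials
        if len(trials) != 16:
            problems.append(f"{pid}: expected 16 recall trials, found {len(trials)}")
        idx = [t.trial_index for t in trials]
        if len(set(idx)) != len(idx):
            problems.append(f"{pid}: duplicate trial indices")
        for cue in CUES:
            per_cue = self.trials_for_cue(cue)
            if trials and len(per_cue) != 8:
                problems.append(
                    f"{pid}: expected 8 {cue} trials, found {len(per_cue)}"
                )
            counts: dict[str, int] = {}
            for t in per_cue:
                counts[t.object_id] = counts.get(t.object_id, 0) + 1
            bad = {o: c for o, c in counts.items() if c != 2}
            if trials and bad:
                problems.append(f"{pid}: object counts per {cue} cue != 2: {bad}")
        for t in trials:
            if t.object_id not in arena.objects:
                problems.append(f"{pid}: trial {t.trial_index} unknown object {t.object_id!r}")
            if distance(t.response, arena.center) > arena.radius + 1e-9:
                problems.append(
                    f"{pid}: trial {t.trial_index} response outside arena"
                )
        if self.encoding_path is not None:
            n_out = int((~self.encoding_path.in_arena(arena)).sum())
            if n_out:
                problems.append(f"{pid}: {n_out} path samples outside arena")
        return problems


def sessions_by_group(sessions: Sequence[ParticipantSession]) -> dict[str, list[ParticipantSession]]:
    out: dict[str, list[ParticipantSession]] = {}
    for s in sessions:
        out.setdefault(s.group, []).append(s)
    return out
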