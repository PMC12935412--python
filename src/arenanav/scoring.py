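"""Per-trial recall measures.

For each retrieval event this module computes:

* **error** — Euclidean distance between the response and the cued object's
  encoded location, in virtual meters;
* **attractor indices** — normalized displacement of the response toward a
  reference point. For a reference R (landmark or arena center),

      index = (d_target − d_response) / d_target,

  where d_target is the distance from the object's true location to R and
  d_response the distance from the response to R. The index is 1 when the
  response sits on R, 0 when it is as far from R as the target, and
  negative when the response is farther from R than the target — so
  positive values mean displacement toward the reference point. (For the
  center index this reading follows the formula as printed in the source
  analyses; their prose swaps the sign labels, which is inconsistent with
  the formula and with the reported group contrasts.)
* **binding flags** — a trial is an object-location binding error when the
  encoded object location nearest to the response is not the cued object's
  location (a swap of object-place associations). Ties between two equally
  near objects are flagged as ambiguous binding errors.
* **switch labels** — each trial (after the first) is labelled by the cue
  transition from the preceding trial: ``no_switch``, ``ego_to_allo`` or
  ``allo_to_ego``; trial 1 is ``first_trial`` and is excluded from
  switching models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ArenaNavError
from .geometry import ArenaConfig, distance
from .session import CUE_ALLO, CUE_EGO, ParticipantSession, RecallTrial

__all__ = [
    "TrialScore",
    "recall_error",
    "landmark_attractor_index",
    "center_attractor_index",
    "nearest_object",
    "binding_errors",
    "switch_labels",
    "score_session",
    "score_cohort",
]

FIRST_TRIAL = "first_trial"
NO_SWITCH = "no_switch"
EGO_TO_ALLO = "ego_to_allo"
ALLO_TO_EGO = "allo_to_ego"


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    cue: str
    object_id: str
    error: float
    landmark_index: float
    center_index: float
    switch_label: str
    binding_flag: bool
    binding_ambiguous: bool
    nearest_object: str


def recall_error(trial: RecallTrial, arena: ArenaConfig) -> float:
    """Euclidean distance from the response to the cued object's location."""
    return distance(trial.response, arena.object_location(trial.object_id))


def _attractor_index(response, target, reference) -> float:
    d_target = distance(target, reference)
    if d_target <= 0:
        raise ArenaNavError(
            "attractor index undefined: target coincides with the reference point"
        )
    return (d_target - distance(response, reference)) / d_target


def landmark_attractor_index(trial: RecallTrial, arena: ArenaConfig) -> float:
    """Normalized displacement of the response toward the landmark."""
    return _attractor_index(
        trial.response, arena.object_location(trial.object_id), arena.landmark
    )


def center_attractor_index(trial: RecallTrial, arena: ArenaConfig) -> float:
    """Normalized displacement of the response toward the arena center."""
    return _attractor_index(
        trial.response, arena.object_location(trial.object_id), arena.center
    )


def nearest_object(
    response, arena: ArenaConfig, tol: float = 1e-12
) -> tuple[str, bool]:
    """Encoded object location nearest to a response.

    Returns ``(object_id, ambiguous)``; ``ambiguous`` is True when two
    objects are equidistant (within ``tol``), in which case the
    lexicographically first id is returned for determinism.
    """
    dists = sorted(
        (distance(response, p), oid) for oid, p in arena.objects.items()
    )
    (d0, o0), (d1, _o1) = dists[0], dists[1]
    return o0, bool(d1 - d0 <= tol)


def binding_errors(
    session: ParticipantSession,
    arena: ArenaConfig,
    cue_filter: Optional[str] = None,
    max_radius: Optional[float] = None,
) -> tuple[int, list[bool]]:
    """Count object-location binding errors for one participant.

    A trial is flagged when the nearest encoded object location to the
    response is not the cued object's. No distance cap is applied by
    default; pass ``max_radius`` to only count swaps whose response lies
    within that distance of the wrong object.
    """
    flags: list[bool] = []
    for t in session.recall_trials:
        if cue_filter is not None and t.cue != cue_filter:
            continue
        near, ambiguous = nearest_object(t.response, arena)
        flag = near != t.object_id or ambiguous
        if flag and max_radius is not None:
            flag = distance(t.response, arena.object_location(near)) <= max_radius
        flags.append(flag)
    return sum(flags), flags


def switch_labels(trials: Sequence[RecallTrial]) -> list[str]:
    """Cue-transition labels in presentation order."""
    labels: list[str] = []
    prev: Optional[str] = None
    for t in trials:
        if prev is None:
            labels.append(FIRST_TRIAL)
        elif t.cue == prev:
            labels.append(NO_SWITCH)
        elif prev == CUE_EGO:
            labels.append(EGO_TO_ALLO)
        else:
            labels.append(ALLO_TO_EGO)
        prev = t.cue
    return labels


def score_session(
    session: ParticipantSession, arena: ArenaConfig
) -> list[TrialScore]:
    """All per-trial measures for one session, in presentation order."""
    trials = sorted(session.recall_trials, key=lambda t: t.trial_index)
    labels = switch_labels(trials)
    scores = []
    for t, lab in zip(trials, labels):
        near, ambiguous = nearest_object(t.response, arena)
        scores.append(
            TrialScore(
                trial_index=t.trial_index,
                cue=t.cue,
                object_id=t.object_id,
                error=recall_error(t, arena),
                landmark_index=landmark_attractor_index(t, arena),
                center_index=center_attractor_index(t, arena),
                switch_label=lab,
                binding_flag=near != t.object_id or ambiguous,
                binding_ambiguous=ambiguous,
                nearest_object=near,
            )
        )
    return scores


def score_cohort(
    sessions: Sequence[ParticipantSession], arena: ArenaConfig
) -> pd.DataFrame:
    """Long-format score table: one row per participant × trial."""
    rows = []
    for s in sessions:
        for sc in score_session(s, arena):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "group": s.group,
                    "subtype": s.subtype,
                    "trial_index": sc.trial_index,
                    "cue": sc.cue,
                    "object_id": sc.object_id,
                    "error": sc.error,
                    "landmark_index": sc.landmark_index,
                    "center_index": sc.center_index,
                    "switch_label": sc.switch_label,
                    "binding_flag": sc.binding_flag,
                    "binding_ambiguous": sc.binding_ambiguous,
                    "nearest_object": sc.nearest_object,
                    "response_time_s": next(
                        t.response_time_s
                        for t in s.recall_trials
                        if t.trial_index == sc.trial_index
                    ),
                }
            )
    return pd.DataFrame(rows)
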