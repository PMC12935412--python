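"""Synthetic-cohort generator: biased-random-walk encoding and noisy recall.

Encoding is a drift + noise walk: at each 1 Hz step the heading is the unit
vector toward the current target object, plus ``thigmotaxis_weight`` times
the outward radial unit vector, plus ``landmark_approach_weight`` times the
unit vector toward the landmark, perturbed by Gaussian heading noise; the
step length is ``step_speed`` and positions are clipped to the arena (the
invisible wall). A target counts as collected when the walker comes within
``capture_radius``; the final approach then snaps onto the exact object
location, mirroring the task rule that objects are collected by walking
over them.

Recall responses shrink the true object location toward an attractor —
the arena center on allocentric (boundary-cue) trials, the landmark on
egocentric (landmark-cue) trials — and add isotropic Gaussian noise:

    response = target + a · (attractor − target) + N(0, s² I),  clipped.

Everything is deterministic given the seed; per-participant seeds are
derived from the cohort seed with a stable hash and recorded on the session.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidScheduleError, SimulationError
from .geometry import ArenaConfig, Point, clip_to_arena, distance
from .profiles import BehaviorProfile, default_profiles
from .session import (
    CUE_ALLO,
    CUE_EGO,
    CollectionEvent,
    EncodingPath,
    ParticipantSession,
    RecallTrial,
)

__all__ = [
    "CohortSpec",
    "make_object_schedule",
    "simulate_encoding_path",
    "simulate_recall_trials",
    "simulate_session",
    "simulate_cohort",
    "participant_seed",
]

#: repetitions of each object during encoding
N_REPETITIONS = 4
#: drift (thigmotaxis/landmark) tapers off within this distance of the target
_DRIFT_TAPER_VM = 5.0
#: combined drift never exceeds this fraction of the unit goal vector
_DRIFT_CAP = 0.85
#: times each object is tested per recall cue
N_PER_OBJECT_PER_CUE = 2


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group synthetic cohort."""

    n_per_group: int = 40
    profiles: dict[str, BehaviorProfile] = field(default_factory=default_profiles)
    seed: int = 0
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    include_paths: bool = True  # skip encoding walks for recall-only studies

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def participant_seed(cohort_seed: int, group: str, index: int) -> int:
    """Deterministic per-participant seed below 2**31."""
    tag = f"{cohort_seed}:{group}:{index}".encode()
    return zlib.crc32(tag) % (2**31)


def make_object_schedule(arena: ArenaConfig, rng: random.Random) -> list[str]:
    """Random encoding order covering each object ``N_REPETITIONS`` times."""
    schedule = [o for o in arena.objects for _ in range(N_REPETITIONS)]
    rng.shuffle(schedule)
    return schedule


def _check_schedule(schedule: Sequence[str], arena: ArenaConfig) -> None:
    counts: dict[str, int] = {}
    for o in schedule:
        counts[o] = counts.get(o, 0) + 1
    expected = {o: N_REPETITIONS for o in arena.objects}
    if counts != expected:
        raise InvalidScheduleError(
            f"schedule must cover each object exactly {N_REPETITIONS} times; "
            f"got counts {counts}"
        )


def simulate_encoding_path(
    profile: BehaviorProfile,
    arena: ArenaConfig,
    object_schedule: Sequence[str],
    seed: int,
    participant_id: str = "sim",
    max_steps: int = 20000,
) -> EncodingPath:
    """Walk the object-collection schedule and return the 1 Hz path."""
    _check_schedule(object_schedule, arena)
    rng = random.Random(seed)

    cx, cy = arena.center
    lmx, lmy = arena.landmark
    radius = arena.radius
    speed = profile.step_speed
    w_t = profile.thigmotaxis_weight
    w_l = profile.landmark_approach_weight
    noise = profile.heading_noise_sd
    capture = profile.capture_radius
    gauss = rng.gauss

    x, y = arena.start
    t = 0.0
    xs = [x]
    ys = [y]
    ts = [t]
    collections: list[CollectionEvent] = []
    reps: dict[str, int] = {}
    steps = 0

    for target_id in object_schedule:
        tx, ty = arena.objects[target_id]
        while True:
            dx, dy = tx - x, ty - y
            dist_t = math.hypot(dx, dy)
            if dist_t <= capture:
                break
            steps += 1
            if steps > max_steps:
                raise SimulationError(
                    f"step cap {max_steps} exceeded for {participant_id!r} "
                    f"(collected {len(collections)}/{len(object_schedule)}, "
                    f"current target {target_id!r} at distance {dist_t:.2f})"
                )
            vx, vy = dx / dist_t, dy / dist_t
            bx = by = 0.0
            if w_t:
                rx, ry = x - cx, y - cy
                rd = math.hypot(rx, ry)
                if rd > 1e-12:
                    bx += w_t * rx / rd
                    by += w_t * ry / rd
            if w_l:
                gx, gy = lmx - x, lmy - y
                gd = math.hypot(gx, gy)
                if gd > 1e-12:
                    bx += w_l * gx / gd
                    by += w_l * gy / gd
            if bx or by:
                # drift fades on final approach and never outweighs the goal
                # vector, so every target stays reachable
                scale = dist_t / _DRIFT_TAPER_VM if dist_t < _DRIFT_TAPER_VM else 1.0
                bn = math.hypot(bx, by)
                if bn * scale > _DRIFT_CAP:
                    scale = _DRIFT_CAP / bn
                vx += bx * scale
                vy += by * scale
            if vx == 0.0 and vy == 0.0:
                ang = rng.uniform(-math.pi, math.pi)
            else:
                ang = math.atan2(vy, vx)
            if noise:
                ang += gauss(0.0, noise)
            nx = x + speed * math.cos(ang)
            ny = y + speed * math.sin(ang)
            # invisible wall: project back onto the boundary circle
            rd = math.hypot(nx - cx, ny - cy)
            if rd > radius:
                s = radius / rd
                nx = cx + (nx - cx) * s
                ny = cy + (ny - cy) * s
            x, y = nx, ny
            t += 1.0
            xs.append(x)
            ys.append(y)
            ts.append(t)
        # final approach: snap onto the exact object location
        x, y = tx, ty
        t += 1.0
        xs.append(x)
        ys.append(y)
        ts.append(t)
        reps[target_id] = reps.get(target_id, 0) + 1
        collections.append(CollectionEvent(target_id, reps[target_id], t))

    return EncodingPath(
        participant_id=participant_id,
        times=np.array(ts),
        points=np.column_stack([xs, ys]),
        collections=tuple(collections),
    )


def simulate_recall_trials(
    profile: BehaviorProfile,
    arena: ArenaConfig,
    seed: int,
    participant_id: str = "sim",
) -> list[RecallTrial]:
    """Generate the 16 recall trials (8 per cue, 2 per object per cue)."""
    rng = random.Random(seed)
    pairs = [
        (cue, obj)
        for cue in (CUE_EGO, CUE_ALLO)
        for obj in arena.objects
        for _ in range(N_PER_OBJECT_PER_CUE)
    ]
    rng.shuffle(pairs)

    # between-participant heterogeneity: lognormal jitter of response noise
    s_base = profile.recall_noise_sd * math.exp(
        profile.participant_variability * rng.gauss(0.0, 1.0)
    )

    trials: list[RecallTrial] = []
    for i, (cue, obj) in enumerate(pairs, start=1):
        target = arena.objects[obj]
        if cue == CUE_EGO:
            a, attractor = profile.landmark_attraction, arena.landmark
            s = s_base * profile.egocentric_noise_scale
        else:
            a, attractor = profile.center_attraction, arena.center
            s = s_base
        rx = target.x + a * (attractor.x - target.x)
        ry = target.y + a * (attractor.y - target.y)
        if s > 0:
            rx += rng.gauss(0.0, s)
            ry += rng.gauss(0.0, s)
        response = clip_to_arena(Point(rx, ry), arena)
        # nuisance covariate: straight-walk travel time plus lognormal jitter
        travel = distance(arena.start, response) / profile.step_speed
        rt = (2.0 + travel) * math.exp(rng.gauss(0.0, 0.25))
        trials.append(
            RecallTrial(
                trial_index=i,
                cue=cue,
                object_id=obj,
                response=response,
                response_time_s=rt,
            )
        )
    return trials


def simulate_session(
    profile: BehaviorProfile,
    arena: ArenaConfig,
    seed: int,
    participant_id: str,
    group: str,
    subtype: Optional[str] = None,
    include_path: bool = True,
) -> ParticipantSession:
    """One participant: encoding walk (optional) plus recall trials."""
    rng = random.Random(seed)
    path = None
    encoding_time = None
    if include_path:
        schedule = make_object_schedule(arena, rng)
        path = simulate_encoding_path(
            profile, arena, schedule, seed=rng.randrange(2**31), participant_id=participant_id
        )
        encoding_time = path.n_samples / 60.0  # 1 Hz samples -> minutes
    trials = simulate_recall_trials(
        profile, arena, seed=rng.randrange(2**31), participant_id=participant_id
    )
    return ParticipantSession(
        participant_id=participant_id,
        group=group,
        subtype=subtype,
        encoding_path=path,
        recall_trials=tuple(trials),
        encoding_time_min=encoding_time,
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> list[ParticipantSession]:
    """Simulate ``n_per_group`` participants for every profile group."""
    sessions: list[ParticipantSession] = []
    for group, profile in spec.profiles.items():
        for i in range(spec.n_per_group):
            pid = f"{group}{i + 1:03d}"
            seed = participant_seed(spec.seed, group, i)
            sessions.append(
                simulate_session(
                    profile,
                    spec.arena,
                    seed=seed,
                    participant_id=pid,
                    group=group,
                    include_path=spec.include_paths,
                )
            )
    return sessions
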