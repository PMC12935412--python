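"""Session file formats: long CSVs plus a cohort manifest.

* ``paths.csv`` — columns ``participant_id, phase, t_s, x_vm, y_vm``;
* ``trials.csv`` — columns ``participant_id, trial_index, cue, object_id,
  response_x_vm, response_y_vm, response_time_s`` (cue tokens ``ego`` /
  ``allo``; long spellings accepted on read);
* ``manifest.json`` — cohort id, schema version, arena configuration and
  per-participant metadata (group, subtype, seed, collection events).

Reading validates the task's structural contract (16 trials, 8 per cue,
2 per object per cue, in-arena coordinates). In lenient mode violations are
collected into a report and logged; strict mode raises.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SessionValidationError
from .geometry import ArenaConfig, Point
from .session import (
    CUE_ALIASES,
    CollectionEvent,
    EncodingPath,
    ParticipantSession,
    RecallTrial,
)

__all__ = ["SCHEMA_VERSION", "write_cohort", "read_sessions", "ValidationReport"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

PATHS_COLUMNS = ["participant_id", "phase", "t_s", "x_vm", "y_vm"]
TRIALS_COLUMNS = [
    "participant_id",
    "trial_index",
    "cue",
    "object_id",
    "response_x_vm",
    "response_y_vm",
    "response_time_s",
]


@dataclass
class ValidationReport:
    problems: list[str]

    @property
    def ok(self) -> bool:
        return not self.problems


def write_cohort(
    sessions: Sequence[ParticipantSession],
    out_dir,
    arena: ArenaConfig,
    cohort_id: str = "cohort",
) -> dict[str, Path]:
    """Write paths.csv, trials.csv and manifest.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    path_rows = []
    trial_rows = []
    manifest_participants = []
    for s in sessions:
        if s.encoding_path is not None:
            ep = s.encoding_path
            for t, (x, y) in zip(ep.times, ep.points):
                path_rows.append((s.participant_id, ep.phase, t, x, y))
        for tr in s.recall_trials:
            trial_rows.append(
                (
                    s.participant_id,
                    tr.trial_index,
                    tr.cue,
                    tr.object_id,
                    tr.response.x,
                    tr.response.y,
                    tr.response_time_s,
                )
            )
        manifest_participants.append(
            {
                "id": s.participant_id,
                "group": s.group,
                "subtype": s.subtype,
                "seed": s.seed,
                "encoding_time_min": s.encoding_time_min,
                "has_path": s.encoding_path is not None,
                "collections": [
                    [c.object_id, c.repetition, c.time_s]
                    for c in (s.encoding_path.collections if s.encoding_path else ())
                ],
            }
        )

    paths_file = out / "paths.csv"
    trials_file = out / "trials.csv"
    manifest_file = out / "manifest.json"
    pd.DataFrame(path_rows, columns=PATHS_COLUMNS).to_csv(paths_file, index=False)
    pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS).to_csv(trials_file, index=False)
    manifest = {
        "cohort_id": cohort_id,
        "schema_version": SCHEMA_VERSION,
        "arena": arena.to_dict(),
        "participants": manifest_participants,
    }
    manifest_file.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"paths": paths_file, "trials": trials_file, "manifest": manifest_file}


def read_sessions(
    paths_file,
    trials_file,
    manifest_file,
    strict: bool = False,
) -> tuple[list[ParticipantSession], ArenaConfig, ValidationReport]:
    """Load sessions back from the CSV pair plus manifest.

    Returns ``(sessions, arena, report)``; in strict mode any structural
    violation raises :class:`SessionValidationError` instead.
    """
    manifest = json.loads(Path(manifest_file).read_text())
    version = str(manifest.get("schema_version"))
    if version != SCHEMA_VERSION:
        raise SessionValidationError(
            f"unknown schema version {version!r} (supported: {SCHEMA_VERSION})"
        )
    arena = ArenaConfig.from_dict(manifest["arena"])

    paths_df = pd.read_csv(paths_file, float_precision="round_trip")
    trials_df = pd.read_csv(trials_file, float_precision="round_trip")
    problems: list[str] = []
    for name, df, cols in (
        ("paths", paths_df, PATHS_COLUMNS),
        ("trials", trials_df, TRIALS_COLUMNS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SessionValidationError(f"{name} file missing columns {missing}")

    bad_cues = set(trials_df["cue"].astype(str)) - set(CUE_ALIASES)
    if bad_cues:
        raise SessionValidationError(f"unknown cue tokens in trials file: {sorted(bad_cues)}")
    trials_df = trials_df.assign(cue=trials_df["cue"].astype(str).map(CUE_ALIASES))
    unknown_objects = set(trials_df["object_id"].astype(str)) - set(arena.objects)
    if unknown_objects:
        raise SessionValidationError(
            f"unknown object ids in trials file: {sorted(unknown_objects)}"
        )

    meta = {p["id"]: p for p in manifest["participants"]}
    sessions: list[ParticipantSession] = []
    paths_by_pid = dict(tuple(paths_df.groupby("participant_id", sort=False)))
    for pid, tdf in trials_df.groupby("participant_id", sort=False):
        m = meta.get(str(pid))
        if m is None:
            problems.append(f"{pid}: present in trials file but not in manifest")
            m = {"group": "unknown", "subtype": None, "seed": None,
                 "encoding_time_min": None, "collections": []}
        if tdf["trial_index"].duplicated().any():
            raise SessionValidationError(f"{pid}: duplicate trial indices")
        trials = tuple(
            RecallTrial(
                trial_index=int(r.trial_index),
                cue=r.cue,
                object_id=str(r.object_id),
                response=Point(float(r.response_x_vm), float(r.response_y_vm)),
                response_time_s=float(r.response_time_s),
            )
            for r in tdf.itertuples()
        )
        path = None
        if pid in paths_by_pid:
            pdf = paths_by_pid[pid].sort_values("t_s")
            path = EncodingPath(
                participant_id=str(pid),
                times=pdf["t_s"].to_numpy(float),
                points=pdf[["x_vm", "y_vm"]].to_numpy(float),
                collections=tuple(
                    CollectionEvent(str(o), int(rep), float(t))
                    for o, rep, t in m.get("collections", [])
                ),
                phase=str(pdf["phase"].iloc[0]),
            )
        session = ParticipantSession(
            participant_id=str(pid),
            group=str(m["group"]),
            subtype=m.get("subtype"),
            encoding_path=path,
            recall_trials=trials,
            encoding_time_min=m.get("encoding_time_min"),
            seed=m.get("seed"),
        )
        problems.extend(session.validate_structure(arena))
        sessions.append(session)

    report = ValidationReport(problems=problems)
    if problems:
        if strict:
            raise SessionValidationError(
                "session validation failed:\n" + "\n".join(problems)
            )
        for msg in problems:
            log.warning("validation: %s", msg)
    return sessions, arena, report
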