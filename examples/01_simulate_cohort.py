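"""Simulate a synthetic two-group cohort and write it to CSV.

Generates 10 healthy-control-like and 10 aMCI-like participants — each with
a 1 Hz encoding walk through the arena and 16 cued recall trials — and
writes the session files (paths.csv, trials.csv, manifest.json).
"""

from arenanav import ArenaConfig, CohortSpec, simulate_cohort, write_cohort

arena = ArenaConfig()
spec = CohortSpec(n_per_group=10, seed=7, arena=arena)
sessions = simulate_cohort(spec)
files = write_cohort(sessions, "example_cohort", arena)

for s in sessions[:3]:
    print(
        f"{s.participant_id} ({s.group}): "
        f"{s.encoding_path.n_samples} path samples, "
        f"encoding time {s.encoding_time_min:.1f} min, "
        f"{len(s.recall_trials)} recall trials"
    )
print(f"\nwrote {len(sessions)} sessions:")
for kind, path in files.items():
    print(f"  {kind}: {path}")
# Each participant walks until all 4 objects are collected 4 times; the
# sample count divided by 60 is the encoding time in minutes (1 Hz samples).
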