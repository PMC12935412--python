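import math

import numpy as np
import pytest

from arenanav import (
    AMCI_PROFILE,
    HC_PROFILE,
    ArenaConfig,
    BehaviorProfile,
    CohortSpec,
    InvalidScheduleError,
    SimulationError,
    center_attractor_index,
    distance,
    landmark_attractor_index,
    participant_seed,
    score_cohort,
    simulate_cohort,
    simulate_encoding_path,
    simulate_recall_trials,
    write_cohort,
)
from arenanav.session import CUE_ALLO, CUE_EGO


def quiet_profile(**kw) -> BehaviorProfile:
    base = dict(
        heading_noise_sd=0.0,
        thigmotaxis_weight=0.0,
        landmark_approach_weight=0.0,
        recall_noise_sd=0.0,
        center_attraction=0.0,
        landmark_attraction=0.0,
        participant_variability=0.0,
    )
    base.update(kw)
    return BehaviorProfile(**base)


def simple_schedule(arena):
    return [o for o in arena.objects for _ in range(4)]


class TestEncodingPath:
    def test_unbiased_limit_walks_straight_legs(self, arena):
        """With no noise or drift the walk is a chain of straight legs, so
        its length equals the sum of inter-target distances."""
        sched = simple_schedule(arena)
        path = simulate_encoding_path(quiet_profile(), arena, sched, seed=1)
        waypoints = [arena.start] + [arena.objects[o] for o in sched]
        legs = sum(distance(a, b) for a, b in zip(waypoints, waypoints[1:]))
        steps = np.hypot(*np.diff(path.points, axis=0).T)
        assert steps.sum() == pytest.approx(legs, abs=1e-9)

    def test_same_seed_reproduces_path(self, arena):
        sched = simple_schedule(arena)
        a = simulate_encoding_path(AMCI_PROFILE, arena, sched, seed=99)
        b = simulate_encoding_path(AMCI_PROFILE, arena, sched, seed=99)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.collections == b.collections

    def test_collections_cover_schedule(self, arena):
        sched = simple_schedule(arena)
        path = simulate_encoding_path(HC_PROFILE, arena, sched, seed=3)
        assert len(path.collections) == 16
        assert [c.object_id for c in path.collections] == sched
        reps = {}
        for c in path.collections:
            reps[c.object_id] = reps.get(c.object_id, 0) + 1
            assert c.repetition == reps[c.object_id]

    def test_path_respects_invisible_wall(self, arena):
        p = BehaviorProfile(thigmotaxis_weight=3.0, heading_noise_sd=0.8)
        path = simulate_encoding_path(p, arena, simple_schedule(arena), seed=5)
        assert path.in_arena(arena).all()

    def test_thigmotaxis_pushes_walks_outward(self, arena):
        """Monte-Carlo: outward drift must raise mean distance-to-center."""
        sched = simple_schedule(arena)

        def mean_dc(weight):
            vals = []
            for s in range(100):
                p = BehaviorProfile(thigmotaxis_weight=weight, heading_noise_sd=0.4)
                path = simulate_encoding_path(p, arena, sched, seed=1000 + s)
                vals.append(np.hypot(*path.points.T).mean())
            return np.mean(vals)

        assert mean_dc(1.0) > mean_dc(0.0)

    def test_landmark_weight_monotonically_attracts(self, arena):
        sched = simple_schedule(arena)

        def mean_dlm(weight):
            vals = []
            for s in range(60):
                p = BehaviorProfile(
                    landmark_approach_weight=weight, heading_noise_sd=0.4
                )
                path = simulate_encoding_path(p, arena, sched, seed=2000 + s)
                d = np.hypot(
                    path.points[:, 0] - arena.landmark.x,
                    path.points[:, 1] - arena.landmark.y,
                )
                vals.append(d.mean())
            return np.mean(vals)

        d = [mean_dlm(w) for w in (-0.3, 0.0, 0.6)]
        assert d[0] > d[1] > d[2]

    def test_bad_schedule_rejected(self, arena):
        with pytest.raises(InvalidScheduleError):
            simulate_encoding_path(HC_PROFILE, arena, ["cat"] * 16, seed=1)

    def test_step_cap_raises_simulation_error(self, arena):
        with pytest.raises(SimulationError):
            simulate_encoding_path(
                HC_PROFILE, arena, simple_schedule(arena), seed=1, max_steps=10
            )


class TestRecallTrials:
    def test_noiseless_unattracted_responses_hit_targets(self, arena):
        trials = simulate_recall_trials(quiet_profile(), arena, seed=7)
        for t in trials:
            assert distance(t.response, arena.objects[t.object_id]) < 1e-12

    def test_full_center_attraction_collapses_allo_responses(self, arena):
        p = quiet_profile(center_attraction=1.0)
        for t in simulate_recall_trials(p, arena, seed=8):
            if t.cue == CUE_ALLO:
                assert distance(t.response, arena.center) < 1e-12

    def test_half_landmark_attraction_hits_midpoint(self, arena):
        p = quiet_profile(landmark_attraction=0.5)
        trials = [
            t
            for t in simulate_recall_trials(p, arena, seed=9)
            if t.cue == CUE_EGO and t.object_id == "cat"
        ]
        cat, lm = arena.objects["cat"], arena.landmark
        mid = ((cat.x + lm.x) / 2, (cat.y + lm.y) / 2)
        for t in trials:
            assert t.response == pytest.approx(mid, abs=1e-12)
            # response halfway to the landmark gives index exactly 1/2
            assert landmark_attractor_index(t, arena) == pytest.approx(0.5)

    def test_trial_structure_contract(self, arena):
        trials = simulate_recall_trials(AMCI_PROFILE, arena, seed=10)
        assert len(trials) == 16
        assert [t.trial_index for t in trials] == list(range(1, 17))
        for cue in (CUE_EGO, CUE_ALLO):
            per = [t for t in trials if t.cue == cue]
            assert len(per) == 8
            for obj in arena.objects:
                assert sum(t.object_id == obj for t in per) == 2

    def test_center_attraction_raises_center_index(self, arena):
        def mean_ci(attr):
            vals = []
            for s in range(100):
                p = BehaviorProfile(
                    recall_noise_sd=10.0,
                    center_attraction=attr,
                    participant_variability=0.0,
                )
                for t in simulate_recall_trials(p, arena, seed=3000 + s):
                    if t.cue == CUE_ALLO:
                        vals.append(center_attractor_index(t, arena))
            return np.mean(vals)

        c = [mean_ci(a) for a in (0.0, 0.4, 0.9)]
        assert c[0] < c[1] < c[2]


class TestCohort:
    def test_cohort_is_byte_identical_given_seed(self, arena, tmp_path):
        spec = CohortSpec(n_per_group=3, seed=11, arena=arena)
        for d in ("a", "b"):
            write_cohort(simulate_cohort(spec), tmp_path / d, arena)
        for name in ("paths.csv", "trials.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_minimal_cohort_is_schema_valid(self, arena):
        spec = CohortSpec(n_per_group=1, seed=2, arena=arena)
        sessions = simulate_cohort(spec)
        assert len(sessions) == 2
        for s in sessions:
            assert s.validate_structure(arena) == []
            assert s.seed == participant_seed(2, s.group, 0)

    def test_all_generated_coordinates_inside_arena(self, small_cohort, arena):
        for s in small_cohort:
            assert s.encoding_path.in_arena(arena).all()
            for t in s.recall_trials:
                assert distance(t.response, arena.center) <= arena.radius + 1e-9

    def test_default_profiles_give_amci_higher_error(self, arena):
        spec = CohortSpec(n_per_group=40, seed=5, include_paths=False)
        scores = score_cohort(simulate_cohort(spec), arena)
        means = scores.groupby("group")["error"].mean()
        assert means["aMCI"] > means["HC"]

    def test_default_profiles_give_positive_attractor_contrast(self, arena):
        """aMCI responses sit closer to the cue anchors than HC responses:
        the group contrast of the cue-matched attractor indices is positive."""
        spec = CohortSpec(n_per_group=80, seed=6, include_paths=False)
        scores = score_cohort(simulate_cohort(spec), arena)
        ego = scores[scores["cue"] == "ego"]
        allo = scores[scores["cue"] == "allo"]
        lmi = ego.groupby("group")["landmark_index"].mean()
        ci = allo.groupby("group")["center_index"].mean()
        assert lmi["aMCI"] > lmi["HC"]
        assert ci["aMCI"] > ci["HC"]
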