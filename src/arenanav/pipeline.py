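"""End-to-end pipeline: simulate (or load) → score → paths → density → models → report.

A :class:`PipelineConfig` names either a simulation spec or an existing
cohort on disk, plus an output directory and a single seed from which all
randomness flows. :func:`run_pipeline` chains every analysis stage and
writes a bundle of CSV tables, a machine-readable ``summary.json`` and a
human-readable ``summary.md``. Every number in the summary is copied from a
table cell in one of the emitted CSVs — the report performs no computation
of its own. Runs are deterministic given the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as anio
from .density import (
    compare_group_densities,
    pooled_points,
    quadrant_density_report,
    radial_density_report,
)
from .errors import ArenaNavError
from .geometry import ArenaConfig
from .models import (
    binding_counts,
    fit_attractor_model,
    fit_binding_poisson,
    fit_error_mixed_anova,
    fit_logistic_diagnosis,
    fit_trial_polynomial_model,
    participant_cue_means,
    participant_switch_means,
    roc_curve_table,
    roc_youden,
)
from .paths import summarize_paths, welch_t
from .profiles import default_profiles
from .scoring import score_cohort
from .session import CUE_ALLO, CUE_EGO, GROUP_AMCI, GROUP_HC
from .simulate import CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    out_dir: str = "arenanav_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: bool = True
    n_per_group: int = 40
    include_paths: bool = True
    # ... or load one from disk
    paths_file: Optional[str] = None
    trials_file: Optional[str] = None
    manifest_file: Optional[str] = None
    strict: bool = False
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    groups: tuple[str, str] = (GROUP_HC, GROUP_AMCI)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "arena" in raw:
            raw["arena"] = ArenaConfig.from_dict(raw["arena"])
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


def _density_block(sessions, arena, groups):
    """Radial + quadrant density reports per group for encoding and both
    recall cue conditions, with the between-group comparisons."""
    rows = []
    comparisons = []
    specs = [
        ("encoding", None, "radial"),
        ("encoding", None, "quadrant_pair"),
        ("recall", CUE_ALLO, "radial"),
        ("recall", CUE_EGO, "quadrant_pair"),
    ]
    for source, cue, scheme in specs:
        reports = {}
        for group in groups:
            pts = pooled_points(sessions, source=source, cue=cue, group=group)
            if len(pts) == 0:
                continue
            rep = (
                radial_density_report(pts, arena)
                if scheme == "radial"
                else quadrant_density_report(pts, arena)
            )
            reports[group] = rep
            a, b = rep.ratio_labels
            rows.append(
                {
                    "source": source,
                    "cue": cue or "",
                    "scheme": scheme,
                    "group": group,
                    f"count_{a}": rep.counts[a],
                    f"count_{b}": rep.counts[b],
                    "n_used": rep.n_used,
                    "n_excluded": rep.n_excluded,
                    f"proportion_{a}": rep.proportions[a],
                    "density_ratio": rep.density_ratio,
                    "binomial_p": rep.binomial_p,
                }
            )
        if len(reports) == 2:
            g0, g1 = groups
            cmp = compare_group_densities(reports[g0], reports[g1])
            comparisons.append(
                {
                    "source": source,
                    "cue": cue or "",
                    "scheme": scheme,
                    "group_a": g0,
                    "group_b": g1,
                    "ratio_a": cmp.ratio_a,
                    "ratio_b": cmp.ratio_b,
                    "difference": cmp.difference,
                    "ratio_of_ratios": cmp.ratio_of_ratios,
                }
            )
    dens = pd.DataFrame(rows)
    comp = pd.DataFrame(comparisons)
    return dens, comp


def _stage(name):
    log.info("stage %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output file paths and key tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arena = config.arena
    failure_marker = out / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()

    stage = "setup"
    try:
        # ---- stage: sessions -------------------------------------------
        stage = "sessions"
        _stage(stage)
        if config.simulate:
            spec = CohortSpec(
                n_per_group=config.n_per_group,
                profiles=default_profiles(),
                seed=config.seed,
                arena=arena,
                include_paths=config.include_paths,
            )
            sessions = simulate_cohort(spec)
            files = anio.write_cohort(sessions, out / "cohort", arena)
            log.info("simulated %d sessions (seed=%d)", len(sessions), config.seed)
        else:
            if not (config.paths_file and config.trials_file and config.manifest_file):
                raise ArenaNavError(
                    "simulate=False requires paths_file, trials_file and manifest_file"
                )
            sessions, arena, report = anio.read_sessions(
                config.paths_file,
                config.trials_file,
                config.manifest_file,
                strict=config.strict,
            )
            files = {}
            log.info(
                "loaded %d sessions (%d validation notes)",
                len(sessions),
                len(report.problems),
            )
        groups = config.groups

        # ---- stage: scoring --------------------------------------------
        stage = "scoring"
        _stage(stage)
        scores = score_cohort(sessions, arena)
        scores.to_csv(out / "scores.csv", index=False)

        # ---- stage: path metrics ---------------------------------------
        stage = "paths"
        _stage(stage)
        summaries = summarize_paths(sessions, arena)
        summaries.to_csv(out / "path_summaries.csv", index=False)
        path_tests = []
        if not summaries.empty and summaries["group"].nunique() == 2:
            g0, g1 = groups
            for col in ("mean_step", "total_distance", "mean_dist_landmark", "mean_dist_center"):
                a = summaries.loc[summaries["group"] == g0, col]
                b = summaries.loc[summaries["group"] == g1, col]
                w = welch_t(a, b)
                path_tests.append(
                    {
                        "metric": col,
                        "group_a": g0,
                        "group_b": g1,
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "t": w.t,
                        "df": w.df,
                        "p": w.p,
                    }
                )
        path_tests_df = pd.DataFrame(path_tests)
        path_tests_df.to_csv(out / "path_tests.csv", index=False)

        # ---- stage: density --------------------------------------------
        stage = "density"
        _stage(stage)
        dens, comp = _density_block(sessions, arena, groups)
        dens.to_csv(out / "density_reports.csv", index=False)
        comp.to_csv(out / "density_comparisons.csv", index=False)

        # ---- stage: models ---------------------------------------------
        stage = "models"
        _stage(stage)
        ftest_frames = []
        term_frames = []
        skipped: list[dict] = []

        def try_fit(label, fn):
            """A model that cannot be fit on this cohort (tiny n, singular
            design) is recorded as skipped, not fatal."""
            try:
                return fn()
            except (ArenaNavError, ValueError) as exc:
                skipped.append({"model": label, "reason": str(exc)})
                log.warning("model %s skipped: %s", label, exc)
                return None

        anova = fit_error_mixed_anova(scores)
        ftest_frames.append(anova.ftests.assign(model=anova.name))
        term_frames.append(anova.terms.assign(model=anova.name))

        polym = try_fit(
            "trial_polynomial_model", lambda: fit_trial_polynomial_model(scores)
        )
        if polym is not None:
            ftest_frames.append(polym.ftests.assign(model=polym.name))

        for index_col in ("landmark_index", "center_index"):
            att = try_fit(
                f"attractor_{index_col}",
                lambda col=index_col: fit_attractor_model(scores, col),
            )
            if att is not None:
                ftest_frames.append(att.ftests.assign(model=att.name))
                term_frames.append(att.terms.assign(model=att.name))

        poisson = try_fit(
            "binding_poisson", lambda: fit_binding_poisson(binding_counts(scores))
        )
        if poisson is not None:
            term_frames.append(poisson.terms.assign(model=poisson.name))

        cue_means = participant_cue_means(scores)
        logit = try_fit(
            "logistic_diagnosis",
            lambda: fit_logistic_diagnosis(
                cue_means, predictors=["error_ego", "error_allo"]
            ),
        )
        if logit is not None:
            term_frames.append(logit.terms.assign(model="logistic_diagnosis"))

        switch_means = participant_switch_means(scores)
        logit_switch = try_fit(
            "logistic_switch",
            lambda: fit_logistic_diagnosis(
                switch_means,
                predictors=[
                    "error_no_switch",
                    "error_ego_to_allo",
                    "error_allo_to_ego",
                ],
            ),
        )
        if logit_switch is not None:
            term_frames.append(logit_switch.terms.assign(model="logistic_switch"))

        ftests_df = pd.concat(ftest_frames, ignore_index=True)
        terms_df = pd.concat(term_frames, ignore_index=True)
        ftests_df.to_csv(out / "model_ftests.csv", index=False)
        terms_df.to_csv(out / "model_terms.csv", index=False)

        # ---- stage: roc -------------------------------------------------
        stage = "roc"
        _stage(stage)
        y = (cue_means["group"] == GROUP_AMCI).astype(int).to_numpy()
        roc_inputs = [
            ("egocentric_error", cue_means["error_ego"].to_numpy()),
            ("allocentric_error", cue_means["error_allo"].to_numpy()),
        ]
        if logit is not None:
            roc_inputs.insert(0, ("full_model_probability", logit.fitted_probabilities))
        roc_rows = []
        roc_curves = []
        for label, s in roc_inputs:
            rr = roc_youden(s, y)
            roc_rows.append(
                {
                    "score": label,
                    "auc": rr.auc,
                    "optimal_cutoff": rr.optimal_cutoff,
                    "sensitivity": rr.sensitivity,
                    "specificity": rr.specificity,
                    "accuracy": rr.accuracy,
                    "youden": rr.youden,
                    "cutoff_tie": rr.cutoff_tie,
                }
            )
            roc_curves.append(roc_curve_table(s, y).assign(score=label))
        roc_df = pd.DataFrame(roc_rows)
        roc_df.to_csv(out / "roc.csv", index=False)
        pd.concat(roc_curves, ignore_index=True).to_csv(
            out / "roc_curves.csv", index=False
        )

        # ---- stage: report ---------------------------------------------
        stage = "report"
        _stage(stage)
        summary = _build_summary(
            groups, scores, summaries, dens, comp, ftests_df, terms_df, roc_df
        )
        if skipped:
            summary["skipped_models"] = skipped
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        (out / "summary.md").write_text(_render_markdown(summary))
    except Exception as exc:
        failure_marker.write_text(f"stage: {stage}\nerror: {exc!r}\n")
        raise ArenaNavError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "out_dir": str(out),
        "summary": summary,
        "scores": scores,
        "roc": roc_df,
        "ftests": ftests_df,
    }


def _build_summary(groups, scores, summaries, dens, comp, ftests, terms, roc) -> dict:
    g0, g1 = groups
    mean_err = scores.groupby("group")["error"].mean()
    summary: dict = {
        "n_participants": int(scores["participant_id"].nunique()),
        "groups": list(groups),
        "mean_error": {g: float(mean_err[g]) for g in groups if g in mean_err},
    }
    grp = ftests[(ftests["model"] == "error_mixed_anova") & (ftests["term"] == "group")]
    if not grp.empty:
        r = grp.iloc[0]
        summary["error_group_effect"] = {
            "F": float(r["F"]),
            "df_num": int(r["df_num"]),
            "df_den": int(r["df_den"]),
            "p": float(r["p"]),
            "cohens_f": float(r["f"]),
        }
    if not dens.empty:
        summary["density"] = dens.to_dict(orient="records")
    if not comp.empty:
        summary["density_comparisons"] = comp.to_dict(orient="records")
    if not summaries.empty:
        summary["path_n_used"] = int(len(summaries))
    ego = terms[(terms["model"] == "logistic_diagnosis") & (terms["term"] == "error_ego")]
    if not ego.empty:
        r = ego.iloc[0]
        summary["logistic_egocentric_error"] = {
            "beta": float(r["estimate"]),
            "or": float(r["or_"]),
            "p": float(r["p"]),
        }
    summary["roc"] = roc.to_dict(orient="records")
    return summary


def _render_markdown(summary: dict) -> str:
    lines = ["# Cohort analysis summary", ""]
    lines.append(f"Participants: {summary['n_participants']}")
    me = summary.get("mean_error", {})
    for g, v in me.items():
        lines.append(f"- mean recall error, {g}: {v:.2f} vm")
    eff = summary.get("error_group_effect")
    if eff:
        lines.append(
            f"- group effect on error: F({eff['df_num']},{eff['df_den']}) = "
            f"{eff['F']:.2f}, p = {eff['p']:.4g}, Cohen's f = {eff['cohens_f']:.2f}"
        )
    logit = summary.get("logistic_egocentric_error")
    if logit:
        lines.append(
            f"- egocentric error → diagnosis: β = {logit['beta']:.3f}, "
            f"OR = {logit['or']:.2f}, p = {logit['p']:.4g}"
        )
    comp = summary.get("density_comparisons", [])
    if comp:
        lines.append("")
        lines.append("## Density-ratio comparisons (group A − group B)")
        for c in comp:
            lines.append(
                f"- {c['source']} {c['cue'] or ''} {c['scheme']}: "
                f"{c['ratio_a']:.2f} vs {c['ratio_b']:.2f} "
                f"(difference {c['difference']:.2f})"
            )
    rocs = summary.get("roc", [])
    if rocs:
        lines.append("")
        lines.append("## ROC")
        for r in rocs:
            lines.append(
                f"- {r['score']}: AUC = {r['auc']:.2f}, cutoff = "
                f"{r['optimal_cutoff']:.2f}, sens = {r['sensitivity']:.2f}, "
                f"spec = {r['specificity']:.2f}"
            )
    lines.append("")
    return "\n".join(lines)
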