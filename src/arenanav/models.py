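"""Group-level statistical layer.

Implements the inferential analyses applied to the per-trial score table:

* a linear mixed-effects ANOVA for recall error with fixed effects group,
  cue and their interaction, a random intercept per participant, type-III
  Wald F-tests and Cohen's f effect sizes;
* a polynomial extension adding orthogonal trial-order terms (default
  degree 2) and their interactions, to probe learning/fatigue across the
  16 test trials;
* mixed models for the attractor indices with participants and objects as
  (crossed) random effects;
* Poisson regression for object-location binding-error counts;
* logistic regression for diagnostic classification (aMCI coded 1) with
  odds ratios and Wald confidence intervals, plus a ridge-penalized
  fallback for separated data;
* ROC analysis with the rank-based AUC and the Youden-index operating
  point.

F-tests follow the split-plot decomposition. Between-participant terms are
tested in the participant-mean stratum (OLS on per-participant means) with
``n_participants − p_between`` denominator df; within-participant terms use
Wald statistics from the mixed fit with ``n_obs − n_participants −
p_within`` df (a containment-style approximation). For a balanced
two-group, two-cue design with 80 participants this gives the classical
F(1, 78) for the group effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import FitError

__all__ = [
    "ModelResult",
    "RocResult",
    "cohens_f_from_F",
    "fit_error_mixed_anova",
    "fit_trial_polynomial_model",
    "fit_attractor_model",
    "fit_binding_poisson",
    "fit_logistic_diagnosis",
    "roc_youden",
    "roc_curve_table",
    "participant_cue_means",
    "participant_switch_means",
    "binding_counts",
]


@dataclass
class ModelResult:
    """Fitted-model summary: per-coefficient table and per-term F-tests."""

    name: str
    terms: pd.DataFrame  # term, estimate, se, stat, p [, or_, or_low, or_high]
    ftests: Optional[pd.DataFrame] = None  # term, df_num, df_den, F, p, f
    notes: tuple[str, ...] = ()

    def term(self, name: str) -> pd.Series:
        rows = self.terms[self.terms["term"].str.contains(name, regex=False)]
        if rows.empty:
            raise KeyError(f"no coefficient matching {name!r} in {self.name}")
        return rows.iloc[0]

    def ftest(self, name: str) -> pd.Series:
        if self.ftests is None:
            raise KeyError(f"{self.name} has no F-tests")
        rows = self.ftests[self.ftests["term"] == name]
        if rows.empty:
            raise KeyError(f"no F-test for term {name!r} in {self.name}")
        return rows.iloc[0]


@dataclass(frozen=True)
class RocResult:
    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    cutoff_tie: bool = False


def cohens_f_from_F(F: float, df_num: float, df_den: float) -> float:
    """Cohen's f from an F statistic: f = sqrt(F · df_num / df_den)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return math.sqrt(F * df_num / df_den)


# ---------------------------------------------------------------------------
# mixed-effects machinery
# ---------------------------------------------------------------------------

def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str, vc_formula=None,
                 re_formula=None):
    model = smf.mixedlm(
        formula, data, groups=data[groups], vc_formula=vc_formula,
        re_formula=re_formula,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            res = None
        if res is None or not np.all(np.isfinite(res.fe_params)):
            try:
                res = model.fit(reml=True, method="powell", maxiter=500)
            except Exception as exc:  # pragma: no cover - rare
                raise FitError(f"mixed model failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.fe_params)):
        raise FitError("mixed model produced non-finite fixed effects")
    return model, res


def _column_within_mask(model, data: pd.DataFrame, groups: str) -> np.ndarray:
    """True for design columns that vary within at least one participant."""
    exog = np.asarray(model.exog)
    frame = pd.DataFrame(exog)
    frame["_g"] = data[groups].to_numpy()
    nun = frame.groupby("_g").nunique()
    return np.array([(nun[j] > 1).any() for j in range(exog.shape[1])])


def _wald_ftests(model, res, data: pd.DataFrame, groups: str) -> pd.DataFrame:
    """Type-III F-tests per model term (Sum-coded factors).

    Within-participant terms use Wald statistics from the mixed fit with
    containment denominator df. Between-participant terms are tested at the
    participant level — OLS on per-participant means of the response and
    design (the classical split-plot between stratum) — because the Wald
    covariance understates between-participant uncertainty whenever the
    random-intercept variance estimate hits the REML boundary at zero.
    """
    design_info = model.data.design_info
    beta = np.asarray(res.fe_params)
    k = len(beta)
    V = np.asarray(res.cov_params())[:k, :k]
    col_within = _column_within_mask(model, data, groups)
    n_obs = len(data)
    n_groups = data[groups].nunique()
    p_within = int(col_within.sum())
    df_within = max(n_obs - n_groups - p_within, 1)

    # participant-level frame for the between stratum
    frame = pd.DataFrame(np.asarray(model.exog))
    frame["_g"] = data[groups].to_numpy()
    frame["_y"] = np.asarray(model.endog)
    agg = frame.groupby("_g").mean()
    between_cols = [j for j in range(k) if not col_within[j]]
    Xb = agg[between_cols].to_numpy()
    yb = agg["_y"].to_numpy()
    bhat, _, rank_b, _ = np.linalg.lstsq(Xb, yb, rcond=None)
    resid = yb - Xb @ bhat
    df_between = max(len(yb) - rank_b, 1)
    sigma2_b = float(resid @ resid) / df_between
    XtX_inv = np.linalg.pinv(Xb.T @ Xb)

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(sl.start, sl.stop))
        q = len(idx)
        within = bool(col_within[idx].any())
        if within:
            L = np.zeros((q, k))
            for i, j in enumerate(idx):
                L[i, j] = 1.0
            Lb = L @ beta
            M = L @ V @ L.T
            try:
                F = float(Lb @ np.linalg.solve(M, Lb) / q)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"rank-deficient covariance for term {term!r}") from exc
            df_den = df_within
        else:
            pos = [between_cols.index(j) for j in idx]
            Lb = bhat[pos]
            M = sigma2_b * XtX_inv[np.ix_(pos, pos)]
            try:
                F = float(Lb @ np.linalg.solve(M, Lb) / q)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"rank-deficient between design for term {term!r}") from exc
            df_den = df_between
        p = float(stats.f.sf(F, q, df_den))
        rows.append(
            {
                "term": term,
                "df_num": q,
                "df_den": df_den,
                "F": F,
                "p": p,
                "f": cohens_f_from_F(F, q, df_den),
            }
        )
    return pd.DataFrame(rows)


def _coef_table(res) -> pd.DataFrame:
    beta = res.fe_params
    se = np.sqrt(np.diag(np.asarray(res.cov_params())[: len(beta), : len(beta)]))
    stat = np.asarray(beta) / se
    p = 2 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "term": list(beta.index),
            "estimate": np.asarray(beta),
            "se": se,
            "stat": stat,
            "p": p,
        }
    )


def _base_formula(value_col: str, covariates: Optional[Sequence[str]]) -> str:
    f = f"{value_col} ~ C(group, Sum) * C(cue, Sum)"
    if covariates:
        f += " + " + " + ".join(covariates)
    return f


def fit_error_mixed_anova(
    scores: pd.DataFrame,
    value_col: str = "error",
    covariates: Optional[Sequence[str]] = None,
) -> ModelResult:
    """Mixed-effects ANOVA: group × cue with a participant random intercept.

    ``scores`` is the long per-trial table (one row per participant × trial)
    with columns ``participant_id``, ``group``, ``cue`` and ``value_col``.
    Covariates are extra column names added as fixed effects (interaction
    products may be passed as patsy expressions, e.g. ``"age:gender"``).
    """
    _require(scores, ["participant_id", "group", "cue", value_col])
    if scores.groupby("group")["participant_id"].nunique().min() < 2:
        raise FitError("need >=2 participants per group")
    formula = _base_formula(value_col, covariates)
    model, res = _fit_mixedlm(formula, scores, "participant_id")
    ftests = _wald_ftests(model, res, scores, "participant_id")
    ftests["term"] = ftests["term"].map(_clean_term)
    terms = _coef_table(res)
    return ModelResult(name="error_mixed_anova", terms=terms, ftests=ftests)


def _clean_term(term: str) -> str:
    return (
        term.replace("C(group, Sum)", "group")
        .replace("C(cue, Sum)", "cue")
        .replace(":", " x ")
    )


def _orthogonal_trial_poly(trial_index: pd.Series, degree: int) -> np.ndarray:
    """Orthonormal polynomial coding of the trial index (degree columns)."""
    x = trial_index.to_numpy(dtype=float)
    levels = np.unique(x)
    V = np.vander(levels - levels.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    # map each observation to its level's row; drop the constant column
    pos = np.searchsorted(levels, x)
    return Q[pos, 1 : degree + 1]


def fit_trial_polynomial_model(
    scores: pd.DataFrame,
    value_col: str = "error",
    degree: int = 2,
    covariates: Optional[Sequence[str]] = None,
) -> ModelResult:
    """Error model with orthogonal trial-order polynomial terms.

    Adds degree-``degree`` orthogonal polynomial terms in the trial index
    and their interactions with group and cue to the group × cue model.
    With ``degree=0`` this reduces exactly to :func:`fit_error_mixed_anova`.
    """
    _require(scores, ["participant_id", "group", "cue", "trial_index", value_col])
    if degree == 0:
        out = fit_error_mixed_anova(scores, value_col, covariates)
        out.name = "trial_polynomial_model"
        return out
    data = scores.copy()
    P = _orthogonal_trial_poly(data["trial_index"], degree)
    poly_names = [f"trial_poly{k}" for k in range(1, degree + 1)]
    for k, name in enumerate(poly_names):
        data[name] = P[:, k]
    poly = " + ".join(poly_names)
    formula = f"{value_col} ~ C(group, Sum) * C(cue, Sum) * ({poly})"
    if covariates:
        formula += " + " + " + ".join(covariates)
    model, res = _fit_mixedlm(formula, data, "participant_id")
    ftests = _wald_ftests(model, res, data, "participant_id")
    ftests["term"] = ftests["term"].map(_clean_term)
    return ModelResult(
        name="trial_polynomial_model", terms=_coef_table(res), ftests=ftests
    )


def fit_attractor_model(scores: pd.DataFrame, index_col: str) -> ModelResult:
    """Mixed model for an attractor index: group fixed effect, crossed
    random effects for participants and objects."""
    _require(scores, ["participant_id", "group", "object_id", index_col])
    data = scores.copy()
    data["_one"] = 1
    vc = {
        "participant": "0 + C(participant_id)",
        "object": "0 + C(object_id)",
    }
    model, res = _fit_mixedlm(
        f"{index_col} ~ C(group, Sum)", data, "_one", vc_formula=vc, re_formula="0"
    )
    terms = _coef_table(res)
    # group is a between-participant contrast: test it in the participant-
    # mean stratum (exact split-plot F), not against the trial-level Wald
    per = data.groupby(["participant_id", "group"], as_index=False)[index_col].mean()
    n_part = len(per)
    df_den = max(n_part - 2, 1)
    g0, g1 = sorted(per["group"].unique())
    a = per.loc[per["group"] == g0, index_col].to_numpy()
    b = per.loc[per["group"] == g1, index_col].to_numpy()
    sp2 = (
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df_den
    )
    F = float((a.mean() - b.mean()) ** 2 / (sp2 * (1 / len(a) + 1 / len(b))))
    ftests = pd.DataFrame(
        [
            {
                "term": "group",
                "df_num": 1,
                "df_den": df_den,
                "F": F,
                "p": float(stats.f.sf(F, 1, df_den)),
                "f": cohens_f_from_F(F, 1, df_den),
            }
        ]
    )
    return ModelResult(name=f"attractor_{index_col}", terms=terms, ftests=ftests)


# ---------------------------------------------------------------------------
# generalized linear models
# ---------------------------------------------------------------------------

def binding_counts(scores: pd.DataFrame) -> pd.DataFrame:
    """Binding-error counts per participant × cue from the score table."""
    _require(scores, ["participant_id", "group", "cue", "binding_flag"])
    out = (
        scores.groupby(["participant_id", "group", "cue"], as_index=False)[
            "binding_flag"
        ]
        .sum()
        .rename(columns={"binding_flag": "count"})
    )
    out["count"] = out["count"].astype(int)
    return out


def fit_binding_poisson(
    counts: pd.DataFrame, covariates: Optional[Sequence[str]] = None
) -> ModelResult:
    """Log-linear Poisson model for binding counts: group × cue."""
    _require(counts, ["participant_id", "group", "cue", "count"])
    if (counts["count"] < 0).any():
        raise ValueError("binding counts must be non-negative")
    formula = _base_formula("count", covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm(formula, counts, family=sm.families.Poisson()).fit()
    terms = pd.DataFrame(
        {
            "term": list(res.params.index),
            "estimate": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "stat": np.asarray(res.tvalues),
            "p": np.asarray(res.pvalues),
        }
    )
    terms["rate_ratio"] = np.exp(terms["estimate"])
    return ModelResult(name="binding_poisson", terms=terms)


def participant_cue_means(
    scores: pd.DataFrame, value_col: str = "error"
) -> pd.DataFrame:
    """Per-participant mean of ``value_col`` within each cue, wide format."""
    _require(scores, ["participant_id", "group", "cue", value_col])
    wide = (
        scores.pivot_table(
            index=["participant_id", "group"],
            columns="cue",
            values=value_col,
            aggfunc="mean",
        )
        .rename(columns={"ego": f"{value_col}_ego", "allo": f"{value_col}_allo"})
        .reset_index()
    )
    wide.columns.name = None
    return wide


def participant_switch_means(
    scores: pd.DataFrame, value_col: str = "error"
) -> pd.DataFrame:
    """Per-participant mean of ``value_col`` within each switch condition
    (first trials excluded), wide format."""
    _require(scores, ["participant_id", "group", "switch_label", value_col])
    sub = scores[scores["switch_label"] != "first_trial"]
    wide = (
        sub.pivot_table(
            index=["participant_id", "group"],
            columns="switch_label",
            values=value_col,
            aggfunc="mean",
        )
        .rename(
            columns={
                "no_switch": f"{value_col}_no_switch",
                "ego_to_allo": f"{value_col}_ego_to_allo",
                "allo_to_ego": f"{value_col}_allo_to_ego",
            }
        )
        .reset_index()
    )
    wide.columns.name = None
    return wide


def fit_logistic_diagnosis(
    data: pd.DataFrame,
    predictors: Sequence[str],
    covariates: Optional[Sequence[str]] = None,
    positive_group: str = "aMCI",
    penalized: bool = False,
    alpha: float = 1.0,
) -> ModelResult:
    """Logistic regression of diagnosis on per-participant predictors.

    The outcome codes ``positive_group`` as 1, so positive coefficients
    (OR > 1) mean the predictor increases the odds of that diagnosis.
    Reports β, Wald standard errors/p-values, OR = exp(β) and 95% Wald CIs.
    Perfect separation raises :class:`FitError`; pass ``penalized=True`` for
    a ridge-penalized fallback (flagged in ``notes``).
    """
    _require(data, ["group", *predictors])
    y = (data["group"] == positive_group).astype(int)
    if y.nunique() < 2:
        raise FitError("both groups must be present")
    cols = list(predictors) + list(covariates or [])
    rhs = " + ".join(cols)
    df = data.copy()
    df["_y"] = y
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(f"_y ~ {rhs}", df)
        if penalized:
            res = model.fit_regularized(
                alpha=alpha, L1_wt=0.0, disp=False, maxiter=500
            )
            notes.append(f"ridge-penalized fit (alpha={alpha})")
        else:
            try:
                res = model.fit(disp=False, maxiter=200)
            except Exception as exc:
                raise FitError(
                    f"logistic fit failed ({exc}); data may be separated — "
                    "retry with penalized=True"
                ) from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float) if hasattr(res, "bse") else np.full_like(params, np.nan)
    if not np.all(np.isfinite(params)) or np.nanmax(np.abs(params)) > 50:
        raise FitError(
            "logistic coefficients diverged (perfect separation?) — "
            "retry with penalized=True"
        )
    stat = params / bse
    p = 2 * stats.norm.sf(np.abs(stat))
    terms = pd.DataFrame(
        {
            "term": list(res.params.index),
            "estimate": params,
            "se": bse,
            "stat": stat,
            "p": p,
        }
    )
    terms["or_"] = np.exp(terms["estimate"])
    terms["or_low"] = np.exp(terms["estimate"] - 1.959963984540054 * terms["se"])
    terms["or_high"] = np.exp(terms["estimate"] + 1.959963984540054 * terms["se"])
    result = ModelResult(
        name="logistic_diagnosis", terms=terms, notes=tuple(notes)
    )
    result.fitted_probabilities = np.asarray(res.predict())  # type: ignore[attr-defined]
    result.outcome = y.to_numpy()  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def roc_youden(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Rank-based AUC and the Youden-optimal operating point.

    ``labels`` are 0/1 with 1 the positive class; a case is called positive
    when its score is >= the cutoff. AUC uses midranks, giving tied
    positive/negative pairs half credit. Candidate cutoffs are midpoints
    between adjacent distinct scores plus outer sentinels; among cutoffs
    maximizing Youden's J the smallest is returned (``cutoff_tie`` set when
    the maximum is not unique).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    cutoffs = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    best_j = -np.inf
    tie = False
    for c in cutoffs:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best, tie = j, (c, sens, spec), False
        elif abs(j - best_j) <= 1e-12:
            tie = True
    c, sens, spec = best
    pred = s >= c
    acc = float((pred == (y == 1)).mean())
    return RocResult(
        auc=float(auc),
        optimal_cutoff=float(c),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=acc,
        youden=float(best_j),
        cutoff_tie=tie,
    )


def roc_curve_table(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """Sensitivity/specificity at every candidate cutoff (for CSV export)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    cutoffs = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    rows = []
    for c in cutoffs:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        rows.append({"cutoff": c, "sensitivity": sens, "specificity": spec,
                     "youden": sens + spec - 1})
    return pd.DataFrame(rows)


def _require(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
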