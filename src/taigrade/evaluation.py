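"""Model comparison and cohort statistics for TAI grading systems.

Implements the prognostic-model battery: maximum-likelihood logistic
regression with Nagelkerke pseudo-R^2 and AIC, the Mann-Whitney AUC, the
DeLong test for correlated ROC curves, the likelihood-ratio test for nested
models, the Cochran-Armitage trend test, the per-lesion-type severity
table, and the 15-model grading-system comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .lesions import LESION_TYPES, SEQUENCES

PUPIL_LEVELS = ("responsive", "unilaterally_unresponsive", "bilaterally_unresponsive")
CORE_PREDICTORS: tuple[str, ...] = ("age", "gcs", "pupils")

GRADE_COLUMNS = {
    "adams": "grade_adams",
    "firsching": "grade_firsching",
    "abu_hamdeh": "grade_abu_hamdeh",
    "stockholm": "grade_stockholm",
}


@dataclass
class FittedModel:
    """A fitted binary-outcome logistic regression.

    ``predictors`` are the user-facing names (``pupils`` counts as one
    predictor though it enters as two indicator columns); ``n_params``
    counts estimated coefficients including the intercept.
    """

    predictors: tuple[str, ...]
    coefficients: np.ndarray
    column_names: tuple[str, ...]
    log_likelihood: float
    n: int
    n_params: int
    fitted_probs: np.ndarray
    separation_flag: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


@dataclass
class ModelComparison:
    """Nested-model and ROC comparisons between two fitted models."""

    model_a: FittedModel
    model_b: FittedModel
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    delong_z: float
    delong_p: float
    auc_a: float
    auc_b: float


def percentage(count: int, total: int, digits: int = 0) -> float:
    """``100 * count / total`` rounded to ``digits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, digits)


def design_matrix(frame: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Design matrix with intercept; ``pupils`` expands to two indicators.

    Grading-system scores and the Rotterdam score enter as single ordinal
    integers; age and GCS as continuous columns.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(frame))}
    for p in predictors:
        if p == "pupils":
            levels = frame["pupils"]
            if levels.dtype != object:  # already ordinally encoded
                levels = levels.map(dict(enumerate(PUPIL_LEVELS)))
            for lvl in PUPIL_LEVELS[1:]:
                cols[f"pupils_{lvl}"] = (levels == lvl).astype(float).to_numpy()
        else:
            cols[p] = frame[p].astype(float).to_numpy()
    return pd.DataFrame(cols, index=frame.index)


def fit_logistic(frame: pd.DataFrame, predictors: Sequence[str]) -> FittedModel:
    """Maximum-likelihood logistic regression of ``unfavorable``.

    Perfect separation (or non-convergence) triggers a warning and a
    ridge-penalized fallback whose reported log-likelihood is the Bernoulli
    log-likelihood of its fitted probabilities.
    """
    y = frame["unfavorable"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = design_matrix(frame, predictors)
    Xv = X.to_numpy(dtype=float)

    params = None
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xv).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 50):
            params = np.asarray(res.params)
            probs = np.asarray(res.predict(Xv))
            llf = float(res.llf)
    except Exception:
        params = None
    if params is None:
        separation = True
        warnings.warn(
            "logistic fit did not converge cleanly (possible separation); "
            "falling back to a ridge-penalized fit",
            RuntimeWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(C=1.0, fit_intercept=False, max_iter=2000)
        clf.fit(Xv, y)
        params = clf.coef_.ravel()
        probs = clf.predict_proba(Xv)[:, 1]
        llf = float(np.sum(y * np.log(probs) + (1 - y) * np.log1p(-probs)))

    return FittedModel(
        predictors=tuple(predictors),
        coefficients=params,
        column_names=tuple(X.columns),
        log_likelihood=llf,
        n=len(y),
        n_params=Xv.shape[1],
        fitted_probs=probs,
        separation_flag=separation,
    )


def fit_null(frame: pd.DataFrame) -> FittedModel:
    """Intercept-only model (closed-form MLE: the outcome prevalence)."""
    y = frame["unfavorable"].astype(int).to_numpy()
    p = y.mean()
    if p in (0.0, 1.0):
        raise ValueError("outcome must contain both classes")
    llf = float(len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p)))
    return FittedModel(
        predictors=(),
        coefficients=np.array([np.log(p / (1 - p))]),
        column_names=("const",),
        log_likelihood=llf,
        n=len(y),
        n_params=1,
        fitted_probs=np.full(len(y), p),
    )


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes required to compute an AUC")
    return float(roc_auc_score(labels, scores))


def nagelkerke_r2(model: FittedModel, null_loglik: float) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell rescaled to a [0, 1] maximum."""
    ll1, ll0, n = model.log_likelihood, null_loglik, model.n
    if ll1 < ll0 - 1e-8:
        raise ValueError("model log-likelihood below the null: models are not nested")
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    return float(cox_snell / max_cs)


def _midrank_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong midrank placements V10 (cases), V01 (controls) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01, _ = _midrank_placements(scores, labels)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """DeLong test for two correlated ROC curves on the same patients.

    Returns ``(z, p, auc_a, auc_b)`` with a two-sided normal p-value.  A
    degenerate variance (e.g. identical score vectors) yields ``z=0, p=1``
    with a warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have identical length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes required")

    v10a, v01a, auc_a = _midrank_placements(scores_a, labels)
    v10b, v01b, auc_b = _midrank_placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 1e-16:
        warnings.warn("degenerate DeLong variance; returning p = 1", RuntimeWarning, stacklevel=2)
        return 0.0, 1.0, auc_a, auc_b
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p), auc_a, auc_b


def likelihood_ratio_test(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """LRT of a nested against a full logistic model on the same patients."""
    if nested.n != full.n:
        raise ValueError("models must be fitted on the same patients")
    if not set(nested.predictors) < set(full.predictors) and nested.predictors != full.predictors:
        raise ValueError("nested model's predictors must be a subset of the full model's")
    stat = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    df = full.n_params - nested.n_params
    if nested.predictors == full.predictors:
        return 0.0, 0, 1.0
    if df <= 0:
        raise ValueError("full model must have more parameters than the nested model")
    return float(stat), int(df), float(chi2.sf(stat, df))


def cochran_armitage_trend(table: np.ndarray, scores: Sequence[float]) -> tuple[float, float]:
    """Cochran-Armitage test for trend in a 2 x k table.

    ``table[0]`` holds event counts, ``table[1]`` non-event counts per
    ordered category; ``scores`` are the category scores.  Returns the
    standard normal statistic and a two-sided p-value.
    """
    table = np.asarray(table, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if table.shape[1] != len(scores):
        raise ValueError("one score per category required")
    n_i = table.sum(axis=0)
    if np.any(n_i == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    N = n_i.sum()
    p_bar = table[0].sum() / N
    num = float(np.dot(scores, table[0] - n_i * p_bar))
    var = p_bar * (1 - p_bar) * (np.dot(n_i, scores**2) - np.dot(n_i, scores) ** 2 / N)
    if var <= 0:
        raise ValueError("degenerate trend variance")
    z = num / np.sqrt(var)
    return float(z), float(2.0 * norm.sf(abs(z)))


def severity_table(cohort) -> pd.DataFrame:
    """Per-(sequence, lesion type) severity summary.

    For each sequence family and lesion type: the number of patients with
    at least one such lesion and the percentage with unfavorable outcome
    (NaN when no patient qualifies).  A ``no_detected_tai`` row per sequence
    summarizes patients without any lesion on that family.
    """
    rows = []
    for seq in SEQUENCES:
        for name, crit in LESION_TYPES:
            hits = [bool(r.lesions.match(sequence=seq, **crit)) for r in cohort]
            n = int(sum(hits))
            if n:
                pct = 100.0 * np.mean([r.unfavorable for r, h in zip(cohort, hits) if h])
            else:
                pct = np.nan
            rows.append({"sequence": seq, "lesion_type": name, "n": n, "pct_unfavorable": pct})
        none = [len(r.lesions.match(sequence=seq)) == 0 for r in cohort]
        n = int(sum(none))
        pct = 100.0 * np.mean([r.unfavorable for r, h in zip(cohort, none) if h]) if n else np.nan
        rows.append({"sequence": seq, "lesion_type": "no_detected_tai", "n": n, "pct_unfavorable": pct})
    return pd.DataFrame(rows)


def render_severity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable severity table: zero-count percentages become '-'."""
    out = table.copy()
    out["pct_unfavorable"] = [
        "-" if np.isnan(v) else f"{v:.0f}" for v in table["pct_unfavorable"]
    ]
    return out


@dataclass
class GradingComparison:
    """The grading-system comparison battery.

    ``models``: 15 rows (each grading system alone, core, Rotterdam,
    core+system, core+Rotterdam+system) with Nagelkerke pseudo-R^2, AIC and
    AUC.  ``lrt``: each system's addition to the core and to the
    core+Rotterdam baselines.  ``delong``: pairwise DeLong tests among the
    four univariate grading-system models.
    """

    models: pd.DataFrame
    lrt: pd.DataFrame
    delong: pd.DataFrame


def compare_grading_systems(frame: pd.DataFrame) -> GradingComparison:
    """Fit and compare the 15 benchmark models on a graded cohort frame.

    ``frame`` needs the covariates, ``unfavorable``, and one
    ``grade_<system>`` ordinal column per grading system.  Results are
    invariant to patient row order.
    """
    frame = frame.sort_values("patient_id").reset_index(drop=True) if "patient_id" in frame else frame
    for col in GRADE_COLUMNS.values():
        if col not in frame.columns:
            raise KeyError(f"missing grade column {col!r}; grade the cohort first")

    core = list(CORE_PREDICTORS)
    specs: list[tuple[str, list[str]]] = [
        ("core", core),
        ("rotterdam", ["rotterdam"]),
    ]
    for sys_name, col in GRADE_COLUMNS.items():
        specs.append((sys_name, [col]))
    specs.append(("core_rotterdam", core + ["rotterdam"]))
    for sys_name, col in GRADE_COLUMNS.items():
        specs.append((f"core_{sys_name}", core + [col]))
    for sys_name, col in GRADE_COLUMNS.items():
        specs.append((f"core_rotterdam_{sys_name}", core + ["rotterdam", col]))

    null = fit_null(frame)
    y = frame["unfavorable"].astype(int).to_numpy()
    fits: dict[str, FittedModel] = {}
    rows = []
    for name, preds in specs:
        m = fit_logistic(frame, preds)
        fits[name] = m
        rows.append(
            {
                "model": name,
                "predictors": "+".join(preds),
                "pseudo_r2": nagelkerke_r2(m, null.log_likelihood),
                "aic": m.aic,
                "auc": auc_roc(m.fitted_probs, y),
            }
        )
    models = pd.DataFrame(rows)

    lrt_rows = []
    for sys_name in GRADE_COLUMNS:
        for base_name, full_name in (
            ("core", f"core_{sys_name}"),
            ("core_rotterdam", f"core_rotterdam_{sys_name}"),
        ):
            stat, df, p = likelihood_ratio_test(fits[base_name], fits[full_name])
            lrt_rows.append(
                {"system": sys_name, "baseline": base_name, "stat": stat, "df": df, "p": p}
            )
    lrt = pd.DataFrame(lrt_rows)

    delong_rows = []
    for a, b in combinations(GRADE_COLUMNS, 2):
        z, p, auc_a, auc_b = delong_test(fits[a].fitted_probs, fits[b].fitted_probs, y)
        delong_rows.append(
            {"system_a": a, "system_b": b, "z": z, "p": p, "auc_a": auc_a, "auc_b": auc_b}
        )
    delong = pd.DataFrame(delong_rows)
    return GradingComparison(models, lrt, delong)
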