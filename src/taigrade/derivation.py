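"""Data-driven derivation of a TAI grading system.

The derivation pipeline mirrors how the Stockholm grading system was built:

1. split the cohort 2/3 train : 1/3 test, stratified by outcome;
2. run a genetic algorithm (GA) over binary feature-inclusion chromosomes,
   scoring each candidate lesion-feature subset by a *desirability* that
   rewards cross-validated discrimination and penalizes model complexity;
3. internally validate the selected features with a random forest on the
   held-out test set, comparing against a core-variables-only forest and
   reporting mean-decrease-in-Gini variable importances.

Candidate features are binary indicators per (lesion type x sequence
family); the lesion-type row set lives in :mod:`taigrade.lesions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .lesions import LESION_TYPES, SEQUENCES

CORE_VARIABLES: tuple[str, ...] = ("age", "gcs", "pupils")

_PUPIL_ORDINAL = {"responsive": 0, "unilaterally_unresponsive": 1, "bilaterally_unresponsive": 2}


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults follow common GA practice: modest population, uniform
    crossover, per-bit mutation at 1/L, tournament selection with light
    elitism, and a complexity penalty ``lambda_complexity`` feeding the
    desirability fitness.
    """

    population_size: int = 50
    generations: int = 40
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1/L
    tournament_size: int = 3
    elitism: int = 2
    lambda_complexity: float = 0.1
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than population_size")
        if self.lambda_complexity < 0:
            raise ValueError("lambda_complexity must be >= 0")


@dataclass
class Chromosome:
    """Binary feature-inclusion vector with its evaluated fitness."""

    bits: np.ndarray
    fitness: float | None = None

    def features(self, names: Sequence[str]) -> tuple[str, ...]:
        return tuple(n for n, b in zip(names, self.bits) if b)


@dataclass
class DerivationReport:
    """Random-forest internal validation of a selected feature set."""

    selected_features: tuple[str, ...]
    test_auc_with_tai: float
    test_auc_core_only: float
    gini_importances: dict[str, float]


def lesion_feature_frame(cohort) -> pd.DataFrame:
    """Binary candidate-feature matrix: one column per lesion type x sequence.

    Columns are named ``<lesion_type>__<sequence>``; rows align with the
    cohort order and carry ``patient_id`` plus ``unfavorable``.
    """
    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id, "unfavorable": int(bool(rec.unfavorable))}
        present = rec.lesions
        for name, crit in LESION_TYPES:
            for seq in SEQUENCES:
                row[f"{name}__{seq}"] = int(bool(present.match(sequence=seq, **crit)))
        rows.append(row)
    return pd.DataFrame(rows)


def candidate_feature_names() -> tuple[str, ...]:
    return tuple(f"{name}__{seq}" for name, _ in LESION_TYPES for seq in SEQUENCES)


def split_train_test(frame: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 2/3 : 1/3 split on ``unfavorable``.

    ``len(train) == round(2n/3)`` exactly; per-class training quotas are
    allocated by largest remainder so the unfavorable fraction is preserved
    within one patient.
    """
    n = len(frame)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    n_train = round(2 * n / 3)
    rng = np.random.default_rng(seed)
    y = frame["unfavorable"].astype(int).to_numpy()
    idx_by_class = {c: np.flatnonzero(y == c) for c in np.unique(y)}
    quotas = {c: 2 * len(ix) / 3 for c, ix in idx_by_class.items()}
    base = {c: math.floor(q) for c, q in quotas.items()}
    short = n_train - sum(base.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - base[c], reverse=True)[:short]:
        base[c] += 1
    train_idx = []
    for c, ix in idx_by_class.items():
        perm = rng.permutation(ix)
        train_idx.extend(perm[: base[c]])
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.array(train_idx, dtype=int)] = True
    return frame.iloc[train_mask].copy(), frame.iloc[~train_mask].copy()


def desirability(auc: float, n_features: int, lambda_complexity: float) -> float:
    """Composite desirability of a candidate model, in [0, 1].

    Geometric mean of a discrimination desirability
    ``d_auc = max(0, (auc - 0.5) / 0.5)`` and a parsimony desirability
    ``d_size = exp(-lambda * k)``; strictly increasing in AUC above 0.5 and
    strictly decreasing in the feature count.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    d_auc = max(0.0, (auc - 0.5) / 0.5)
    d_size = math.exp(-lambda_complexity * n_features)
    return math.sqrt(d_auc * d_size)


def cv_auc(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Mean held-out logistic-regression AUC over stratified CV folds.

    An empty design matrix scores 0.5 (intercept-only: no discrimination).
    """
    if X.shape[1] == 0:
        return 0.5
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(C=1e6, max_iter=1000)
        clf.fit(X[tr], y[tr])
        p = clf.predict_proba(X[te])[:, 1]
        if len(np.unique(y[te])) < 2:  # tiny-fold degenerate case
            continue
        aucs.append(roc_auc_score(y[te], p))
    return float(np.mean(aucs)) if aucs else 0.5


def evaluate_subset(
    train: pd.DataFrame, features: Sequence[str], config: GAConfig
) -> float:
    """Desirability fitness of one feature subset on the training data."""
    y = train["unfavorable"].astype(int).to_numpy()
    X = train[list(features)].to_numpy(dtype=float)
    auc = cv_auc(X, y, config.cv_folds, config.seed)
    return desirability(auc, len(features), config.lambda_complexity)


@dataclass
class GAHistory:
    """Best-ever chromosome plus the per-generation best-fitness trace."""

    best: Chromosome
    best_fitness_per_generation: list[float] = field(default_factory=list)
    evaluations: int = 0


def run_ga(
    train: pd.DataFrame, candidate_features: Sequence[str], config: GAConfig
) -> GAHistory:
    """Generational GA over feature-inclusion chromosomes.

    Tournament selection, uniform crossover, per-bit mutation, elitism.
    The initial population always contains the empty and the all-features
    chromosomes, so the result can never score below either.  Fitness is the
    desirability of the subset's cross-validated logistic AUC.  Deterministic
    given ``config.seed``.
    """
    y = train["unfavorable"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome must contain both classes")
    names = list(candidate_features)
    L = len(names)
    if L == 0:
        raise ValueError("need at least one candidate feature")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    cache: dict[bytes, float] = {}
    n_evals = 0

    def fitness(bits: np.ndarray) -> float:
        nonlocal n_evals
        key = bits.tobytes()
        if key not in cache:
            feats = [n for n, b in zip(names, bits) if b]
            cache[key] = evaluate_subset(train, feats, config)
            n_evals += 1
        return cache[key]

    pop = [np.zeros(L, dtype=bool), np.ones(L, dtype=bool)]
    while len(pop) < config.population_size:
        pop.append(rng.random(L) < 0.3)
    pop = pop[: config.population_size]
    fits = np.array([fitness(b) for b in pop])

    best_bits = pop[int(np.argmax(fits))].copy()
    best_fit = float(np.max(fits))
    trace = [best_fit]

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, len(pop), size=config.tournament_size)
        return pop[contenders[np.argmax(fits[contenders])]]

    for _ in range(config.generations):
        order = np.argsort(-fits)
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                mask = rng.random(L) < 0.5
                c1 = np.where(mask, p1, p2)
                c2 = np.where(mask, p2, p1)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                flip = rng.random(L) < mut
                child = child ^ flip
                new_pop.append(child)
        pop = new_pop[: config.population_size]
        fits = np.array([fitness(b) for b in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_bits = pop[gen_best].copy()
        trace.append(best_fit)

    return GAHistory(Chromosome(best_bits, best_fit), trace, n_evals)


def ga_select(
    train: pd.DataFrame, candidate_features: Sequence[str], config: GAConfig
) -> Chromosome:
    """Best-ever chromosome from :func:`run_ga`."""
    return run_ga(train, candidate_features, config).best


def encode_core(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the core variables for tree models.

    Pupillary status becomes an ordinal 0/1/2 (responsive, unilaterally
    unresponsive, bilaterally unresponsive).
    """
    out = pd.DataFrame(index=frame.index)
    out["age"] = frame["age"].astype(float)
    out["gcs"] = frame["gcs"].astype(float)
    pupils = frame["pupils"]
    if pupils.dtype == object:
        out["pupils"] = pupils.map(_PUPIL_ORDINAL).astype(float)
    else:
        out["pupils"] = pupils.astype(float)
    return out


def rf_validate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    selected_features: Sequence[str],
    core_variables: Sequence[str] = CORE_VARIABLES,
    seed: int = 0,
    n_estimators: int = 500,
) -> DerivationReport:
    """Random-forest internal validation on the held-out test set.

    Trains one forest on core variables + selected TAI features and one on
    core variables only, reports both test AUCs and the Gini importances of
    the combined forest.  Deterministic given ``seed``.
    """
    selected = list(selected_features)
    for col in selected:
        if col not in train.columns or col not in test.columns:
            raise KeyError(f"feature column {col!r} missing from the data")
    y_tr = train["unfavorable"].astype(int).to_numpy()
    y_te = test["unfavorable"].astype(int).to_numpy()

    core_tr, core_te = encode_core(train), encode_core(test)
    X_tr = pd.concat([core_tr, train[selected].astype(float)], axis=1)
    X_te = pd.concat([core_te, test[selected].astype(float)], axis=1)

    ss = np.random.SeedSequence(seed).spawn(2)
    rf_full = RandomForestClassifier(
        n_estimators=n_estimators, random_state=np.random.default_rng(ss[0]).integers(2**31)
    )
    rf_core = RandomForestClassifier(
        n_estimators=n_estimators, random_state=np.random.default_rng(ss[1]).integers(2**31)
    )
    rf_full.fit(X_tr.to_numpy(), y_tr)
    rf_core.fit(core_tr.to_numpy(), y_tr)

    auc_full = float(roc_auc_score(y_te, rf_full.predict_proba(X_te.to_numpy())[:, 1]))
    auc_core = float(roc_auc_score(y_te, rf_core.predict_proba(core_te.to_numpy())[:, 1]))
    importances = dict(zip(X_tr.columns, (float(v) for v in rf_full.feature_importances_)))
    return DerivationReport(tuple(selected), auc_full, auc_core, importances)
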