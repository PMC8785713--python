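"""Independent oracles used by the test suite.

Everything here re-derives expected results by brute force or direct
declarative interpretation, independent of the implementation paths it is
used to check.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Declarative grading-rule tables.  A rule is (grade, [criteria]); a map
# earns the highest grade for which any site satisfies any criterion.
# Criterion keys: region, region_in, subregion, subregion_not, laterality,
# sequence; {"always": True} is the unconditional fallback.
# ---------------------------------------------------------------------------

_SUPRA = ("basal_ganglia", "corpus_callosum", "internal_capsule_plic", "subcortical", "thalamus")
_HEMI = ("subcortical", "basal_ganglia", "internal_capsule_plic", "thalamus")
_BRAINSTEM = ("midbrain", "pons")

STOCKHOLM_RULES = [
    (4, [dict(region="pons", laterality="bilateral")]),
    (
        3,
        [
            dict(region="midbrain", subregion="tegmentum"),
            dict(region="thalamus", laterality="bilateral"),
            dict(region="internal_capsule_plic"),
        ],
    ),
    (
        2,
        [
            dict(region="corpus_callosum"),
            dict(region="thalamus", laterality="unilateral"),
            dict(region="pons", laterality="unilateral"),
            dict(region="midbrain", subregion_not="tegmentum"),
        ],
    ),
    (1, [dict(always=True)]),
]

ADAMS_RULES = [
    (3, [dict(region_in=_BRAINSTEM)]),
    (2, [dict(region="corpus_callosum")]),
    (1, [dict(region_in=_HEMI)]),
    (0, [dict(always=True)]),
]

FIRSCHING_RULES = [
    (4, [dict(region="pons", laterality="bilateral")]),
    (3, [dict(region="midbrain", laterality="bilateral")]),
    (2, [dict(region_in=_BRAINSTEM, laterality="unilateral")]),
    (1, [dict(region_in=_SUPRA)]),
    (0, [dict(always=True)]),
]

ABU_HAMDEH_RULES = [
    (4, [dict(region="midbrain", subregion="tegmentum", sequence="susceptibility")]),
    (3, [dict(region_in=_BRAINSTEM, subregion_not="tegmentum")]),
    (2, [dict(region="corpus_callosum")]),
    (1, [dict(region_in=_HEMI)]),
    (0, [dict(always=True)]),
]

RULE_TABLES = {
    "stockholm": STOCKHOLM_RULES,
    "adams": ADAMS_RULES,
    "firsching": FIRSCHING_RULES,
    "abu_hamdeh": ABU_HAMDEH_RULES,
}


def _site_satisfies(site, crit: dict) -> bool:
    if crit.get("always"):
        return True
    if "region" in crit and site.region != crit["region"]:
        return False
    if "region_in" in crit and site.region not in crit["region_in"]:
        return False
    if "subregion" in crit and site.subregion != crit["subregion"]:
        return False
    if "subregion_not" in crit and site.subregion == crit["subregion_not"]:
        return False
    if "laterality" in crit and site.laterality != crit["laterality"]:
        return False
    if "sequence" in crit and site.sequence != crit["sequence"]:
        return False
    return True


def interpret_grade(system: str, sites) -> int:
    """Brute-force rule-table interpretation of a collection of sites."""
    for grade, criteria in RULE_TABLES[system]:
        for crit in criteria:
            if crit.get("always"):
                return grade
            if any(_site_satisfies(s, crit) for s in sites):
                return grade
    raise AssertionError("rule tables are exhaustive")


# ---------------------------------------------------------------------------
# Statistical oracles
# ---------------------------------------------------------------------------


def pairwise_auc(scores, labels) -> float:
    """O(m*n) Mann-Whitney AUC with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def bootstrap_auc_diff_p(scores_a, scores_b, labels, reps: int, seed: int) -> float:
    """Stratified-bootstrap z-test p-value for a paired AUC difference."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)

    def fast_auc(sa_pos, sa_neg):
        # rank-based Mann-Whitney with ties
        comb = np.concatenate([sa_pos, sa_neg])
        order = np.argsort(comb, kind="mergesort")
        ranks = np.empty(len(comb))
        sorted_vals = comb[order]
        # midranks
        i = 0
        r = np.empty(len(comb))
        while i < len(comb):
            j = i
            while j < len(comb) and sorted_vals[j] == sorted_vals[i]:
                j += 1
            r[i:j] = 0.5 * (i + j - 1) + 1
            i = j
        ranks[order] = r
        m = len(sa_pos)
        n = len(sa_neg)
        return (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)

    diffs = np.empty(reps)
    for k in range(reps):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        da = fast_auc(scores_a[bp], scores_a[bn])
        db = fast_auc(scores_b[bp], scores_b[bn])
        diffs[k] = da - db
    from scipy.stats import norm

    observed = fast_auc(scores_a[pos_idx], scores_a[neg_idx]) - fast_auc(
        scores_b[pos_idx], scores_b[neg_idx]
    )
    se = diffs.std(ddof=1)
    z = observed / se
    return float(2.0 * norm.sf(abs(z)))


def permutation_trend_p(table, scores, reps: int, seed: int) -> float:
    """Permutation p-value for the Cochran-Armitage trend statistic."""
    table = np.asarray(table, float)
    scores = np.asarray(scores, float)
    k = table.shape[1]
    cats = np.repeat(np.arange(k), table.sum(axis=0).astype(int))
    outcomes = np.concatenate(
        [np.concatenate([np.ones(int(table[0, j])), np.zeros(int(table[1, j]))]) for j in range(k)]
    )

    def stat(y):
        n_i = np.bincount(cats, minlength=k).astype(float)
        e1 = np.bincount(cats, weights=y, minlength=k)
        p_bar = y.sum() / len(y)
        num = np.dot(scores, e1 - n_i * p_bar)
        var = p_bar * (1 - p_bar) * (np.dot(n_i, scores**2) - np.dot(n_i, scores) ** 2 / len(y))
        return num / np.sqrt(var)

    z_obs = abs(stat(outcomes))
    rng = np.random.default_rng(seed)
    hits = 0
    y = outcomes.copy()
    for _ in range(reps):
        rng.shuffle(y)
        if abs(stat(y)) >= z_obs - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def exhaustive_best_subset(train, features, config):
    """Enumerate every feature subset; return (best subset, fitness, all)."""
    from itertools import combinations

    from taigrade.derivation import evaluate_subset

    best, best_fit = (), -1.0
    all_fits = []
    for k in range(len(features) + 1):
        for combo in combinations(features, k):
            f = evaluate_subset(train, list(combo), config)
            all_fits.append(f)
            if f > best_fit:
                best, best_fit = combo, f
    return best, best_fit, np.array(all_fits)
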