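"""Synthetic cohorts of critically ill TBI patients with TAI annotations.

The generator emulates the statistical structure of a single-centre
neurointensive-care MRI cohort: per-site lesion prevalences, covariate
distributions (age, admission GCS, pupillary responsiveness, Rotterdam CT
score, scan delay), an overall TAI detection prevalence of 73%, and
unfavorable-outcome probabilities conditional on the Stockholm grade
(97/74/40/28% for grades IV/III/II/I).

Mechanism
---------
Each patient carries a latent injury-severity scalar ``z ~ N(0, sd)``.

* Every lesion site has a logistic model ``P(site | z) = expit(c_s + b z)``
  whose intercept ``c_s`` is solved numerically so that the site's marginal
  prevalence matches a target table of per-site rates; a single global
  intercept shift is then solved so that the probability of at least one
  *observed* lesion (after detectability decay at the patient's scan delay)
  equals the configured TAI prevalence.
* Covariates are coupled to ``z`` through Gaussian copulas: the coupled
  percentile is pushed through each covariate's marginal quantile function,
  so marginals match their targets exactly while lower GCS, worse pupils,
  higher Rotterdam scores and (weakly) higher age co-occur with severe
  injury.
* Non-hemorrhagic lesions (DWI, FLAIR) become harder to detect as the
  MRI is delayed; susceptibility-sensitive lesions decay strictly more
  slowly.  Decay thins the *observed* lesion map; grading and outcome are
  based on what the scan shows.
* The outcome is drawn conditional on the Stockholm grade of the observed
  lesion map, then expanded to a 5-level Glasgow Outcome Scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import lognorm, norm, truncnorm

from .grading import grade_stockholm
from .lesions import SITE_CATALOG, LesionMap, LesionSite

# ---------------------------------------------------------------------------
# Default calibration targets
# ---------------------------------------------------------------------------

#: Reference cohort size behind the per-site lesion counts below.
_REFERENCE_N = 351

#: Patients per lesion row (dwi, flair, susceptibility) in a 351-patient
#: neuro-ICU TBI cohort; the basis for default per-site prevalences.
_LESION_COUNTS: Mapping[tuple[str, str], tuple[int, int, int]] = {
    ("basal_ganglia", "unilateral"): (5, 18, 44),
    ("basal_ganglia", "bilateral"): (0, 3, 7),
    ("corpus_callosum", "trunk"): (23, 57, 68),
    ("corpus_callosum", "splenium"): (82, 111, 88),
    ("corpus_callosum", "genu_rostrum"): (23, 27, 41),
    ("internal_capsule_plic", "unilateral"): (18, 36, 40),
    ("internal_capsule_plic", "bilateral"): (3, 11, 15),
    ("midbrain", "unilateral"): (35, 55, 43),
    ("midbrain", "tegmentum"): (24, 57, 58),
    ("midbrain", "tectum"): (9, 21, 15),
    ("midbrain", "cerebral_peduncles"): (18, 32, 30),
    ("midbrain", "bilateral"): (11, 24, 39),
    ("pons", "ventral"): (8, 25, 26),
    ("pons", "unilateral"): (17, 33, 25),
    ("pons", "dorsal"): (13, 33, 35),
    ("pons", "bilateral"): (4, 15, 22),
    ("subcortical", "unilateral"): (16, 51, 67),
    ("subcortical", "bilateral"): (8, 57, 106),
    ("thalamus", "unilateral"): (18, 39, 37),
    ("thalamus", "bilateral"): (4, 16, 29),
}

_SEQ_INDEX = {"dwi": 0, "flair": 1, "susceptibility": 2}

#: Fraction of subregion-specific midbrain/pons lesions assigned unilateral
#: (the rest bilateral); subregion rows do not record laterality.
_UNILATERAL_SHARE = 0.7

#: Floor applied to zero-count cells (half a patient out of 351).
_RATE_FLOOR = 0.5 / _REFERENCE_N


def default_lesion_base_rates() -> dict[LesionSite, float]:
    """Target marginal prevalence per lesion site."""
    rates: dict[LesionSite, float] = {}
    for (region, row), counts in _LESION_COUNTS.items():
        for seq, j in _SEQ_INDEX.items():
            p = max(counts[j] / _REFERENCE_N, _RATE_FLOOR)
            if region == "corpus_callosum":
                rates[LesionSite(region, row, "not_applicable", seq)] = p
            elif row in ("unilateral", "bilateral"):
                rates[LesionSite(region, "unspecified", row, seq)] = p
            else:
                # laterality split for localized midbrain/pons lesions
                rates[LesionSite(region, row, "unilateral", seq)] = max(
                    p * _UNILATERAL_SHARE, _RATE_FLOOR
                )
                rates[LesionSite(region, row, "bilateral", seq)] = max(
                    p * (1.0 - _UNILATERAL_SHARE), _RATE_FLOOR
                )
    assert set(rates) == set(SITE_CATALOG)
    return rates


#: GCS distribution over 3..15 with median 4, Q1 3, Q3 7 (neuro-ICU casemix).
_GCS_VALUES = np.arange(3, 16)
_GCS_PROBS = np.array(
    [0.30, 0.22, 0.10, 0.08, 0.08, 0.05, 0.04, 0.03, 0.03, 0.02, 0.02, 0.02, 0.01]
)

_PUPIL_LEVELS = ("responsive", "unilaterally_unresponsive", "bilaterally_unresponsive")
_PUPIL_PROBS = np.array([243.0, 34.0, 66.0]) / 343.0

_ROTTERDAM_VALUES = np.arange(1, 7)
_ROTTERDAM_PROBS = np.array([0.05, 0.25, 0.30, 0.20, 0.12, 0.08])

#: GOS composition: unfavorable split 1:2:3 and favorable split 4:5.
_GOS_UNFAV_PROBS = np.array([38.0, 9.0, 136.0]) / 183.0
_GOS_FAV_PROBS = np.array([106.0, 62.0]) / 168.0

#: Age marginal: truncated normal on [15, 82] years whose underlying
#: location/scale are solved so the *truncated* mean and SD are 43.8 and
#: 18.6 (the reference cohort's moments; truncation would otherwise bias
#: the mean upward).
_AGE_LOC, _AGE_SCALE, _AGE_LO, _AGE_HI = 1.0629, 59.8065, 15.0, 82.0

#: Scan-delay marginal: lognormal with median 7 d and Q3 = 13 d, truncated
#: to the 28-day inclusion window and rounded to whole days.
_DELAY_MU = math.log(7.0)
_DELAY_SIGMA = math.log(13.0 / 7.0) / norm.ppf(0.75)

#: Copula coupling strengths (latent = coef * z + N(0,1)).
_COEF_GCS = -1.3
_COEF_PUPILS = 1.0
_COEF_ROTTERDAM = 1.0
_COEF_AGE = 0.5

COVARIATE_COLUMNS = ("age", "gcs", "pupils", "rotterdam")


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the reference cohort.

    Parameters
    ----------
    n_patients
        Cohort size (default: the 351 patients of the reference study).
    seed
        Root seed; every random stream is derived from it.
    latent_severity_sd
        Standard deviation of the latent injury-severity scalar.
    lesion_slope
        Log-odds increase in each site's detection probability per unit of
        latent severity; controls lesion co-occurrence.
    lesion_base_rates
        Target marginal prevalence per :class:`LesionSite`; default derived
        from the reference severity table.
    grade_outcome_probs
        P(unfavorable outcome | Stockholm grade) for grades I..IV.
    tai_prevalence_target
        Target fraction of patients with >= 1 observed lesion.
    detectability_decay
        Per-sequence daily retention multiplier (probability that a lesion
        is still conspicuous after each additional day of scan delay).
    missingness_rate
        MCAR masking rate used by :func:`inject_missingness`.
    """

    n_patients: int = 351
    seed: int = 0
    latent_severity_sd: float = 1.0
    lesion_slope: float = 1.6
    lesion_base_rates: Mapping[LesionSite, float] | None = None
    grade_outcome_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.28, 2: 0.40, 3: 0.74, 4: 0.97}
    )
    tai_prevalence_target: float = 0.73
    detectability_decay: Mapping[str, float] = field(
        default_factory=lambda: {"dwi": 0.955, "flair": 0.975, "susceptibility": 0.995}
    )
    missingness_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("latent_severity_sd", "lesion_slope", "tai_prevalence_target"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.tai_prevalence_target <= 1.0:
            raise ValueError("tai_prevalence_target must be in [0, 1]")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")
        for g in (1, 2, 3, 4):
            p = float(self.grade_outcome_probs[g])
            if not (math.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError("grade_outcome_probs must be probabilities")
        for seq, m in self.detectability_decay.items():
            if not (math.isfinite(float(m)) and 0.0 <= float(m) <= 1.0):
                raise ValueError(f"detectability_decay[{seq!r}] must be in [0, 1]")
        if self.lesion_base_rates is not None:
            for site, p in self.lesion_base_rates.items():
                if not (math.isfinite(float(p)) and 0.0 <= float(p) <= 1.0):
                    raise ValueError(f"lesion_base_rates[{site}] must be in [0, 1]")

    def base_rates(self) -> dict[LesionSite, float]:
        if self.lesion_base_rates is None:
            return default_lesion_base_rates()
        return dict(self.lesion_base_rates)


@dataclass
class PatientRecord:
    """One simulated (or loaded) patient.

    Covariates may be ``None`` after missingness injection; the outcome and
    the lesion map are never masked.  ``unfavorable`` is GOS 1-3.
    """

    patient_id: str
    age: float | None
    gcs: int | None
    pupils: str | None
    rotterdam: int | None
    scan_delay: int
    lesions: LesionMap
    gos: int | None
    extras: dict = field(default_factory=dict)

    @property
    def unfavorable(self) -> bool | None:
        if self.gos is None:
            return None
        return self.gos <= 3

    def __post_init__(self) -> None:
        if self.gos is not None and not 1 <= int(self.gos) <= 5:
            raise ValueError(f"GOS must be 1-5, got {self.gos}")
        if self.gcs is not None and not 3 <= int(self.gcs) <= 15:
            raise ValueError(f"GCS must be 3-15, got {self.gcs}")
        if self.rotterdam is not None and not 1 <= int(self.rotterdam) <= 6:
            raise ValueError(f"Rotterdam score must be 1-6, got {self.rotterdam}")
        if self.pupils is not None and self.pupils not in _PUPIL_LEVELS:
            raise ValueError(f"unknown pupillary status {self.pupils!r}")
        if not 0 <= self.scan_delay <= 28:
            raise ValueError("scan_delay must be within 0-28 days")


# ---------------------------------------------------------------------------
# Calibration: per-site intercepts + global prevalence shift
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(25)


def _z_quadrature(sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(z)], z ~ N(0, sd), via Gauss-Hermite."""
    return math.sqrt(2.0) * sd * _GH_NODES, _GH_WEIGHTS / math.sqrt(math.pi)


def _solve_site_intercept(target: float, slope: float, zs: np.ndarray, ws: np.ndarray) -> float:
    """Solve c so that E_z[expit(c + slope z)] = target."""

    def f(c: float) -> float:
        return float(np.dot(ws, expit(c + slope * zs))) - target

    lo, hi = logit(target) - 8.0 * abs(slope) - 1.0, logit(target) + 8.0 * abs(slope) + 1.0
    return brentq(f, lo, hi, xtol=1e-10)


def _delay_pmf() -> tuple[np.ndarray, np.ndarray]:
    """Probability mass over whole scan-delay days 0..28."""
    days = np.arange(29)
    dist = lognorm(s=_DELAY_SIGMA, scale=math.exp(_DELAY_MU))
    upper = dist.cdf(days + 0.5)
    lower = dist.cdf(np.maximum(days - 0.5, 0.0))
    lower[0] = 0.0
    pmf = upper - lower
    pmf[-1] += dist.sf(28.5)  # truncation mass folded into day 28
    return days, pmf / pmf.sum()


def _calibrate(config: CohortConfig) -> tuple[list[LesionSite], np.ndarray]:
    """Return (site order, per-site intercepts incl. global shift)."""
    rates = config.base_rates()
    sites = [s for s in SITE_CATALOG if s in rates]
    sd, slope = config.latent_severity_sd, config.lesion_slope
    zs, ws = _z_quadrature(sd)
    c = np.array([_solve_site_intercept(rates[s], slope, zs, ws) for s in sites])

    if config.tai_prevalence_target <= 0.0:
        return sites, np.full(len(sites), -np.inf)

    days, day_pmf = _delay_pmf()
    retention = np.array(
        [[config.detectability_decay[s.sequence] ** d for s in sites] for d in days]
    )  # (days, sites)

    def p_any(delta: float) -> float:
        p = expit(c[None, :] + delta + slope * zs[:, None])  # (z, sites)
        # P(no observed lesion | z, d) = prod_s (1 - p_s(z) * r_s(d))
        none_zd = np.prod(1.0 - p[:, None, :] * retention[None, :, :], axis=2)
        none = float(ws @ none_zd @ day_pmf)
        return 1.0 - none

    target = config.tai_prevalence_target

    def g(delta: float) -> float:
        return p_any(delta) - target

    lo, hi = -12.0, 12.0
    if g(lo) > 0 or g(hi) < 0:  # degenerate target; clamp to nearest end
        delta = lo if g(lo) > 0 else hi
    else:
        delta = brentq(g, lo, hi, xtol=1e-9)
    return sites, c + delta


# ---------------------------------------------------------------------------
# Covariate copulas
# ---------------------------------------------------------------------------


def _coupled_u(z: np.ndarray, z_sd: float, coef: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform(0,1) marginally, monotone-coupled to z via a Gaussian copula."""
    latent = coef * z + rng.standard_normal(z.shape)
    return norm.cdf(latent / math.sqrt(coef**2 * z_sd**2 + 1.0))


def _categorical_from_u(u: np.ndarray, values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return values[np.searchsorted(cum, u, side="left")]


def _age_from_u(u: np.ndarray) -> np.ndarray:
    a = (_AGE_LO - _AGE_LOC) / _AGE_SCALE
    b = (_AGE_HI - _AGE_LOC) / _AGE_SCALE
    return truncnorm.ppf(u, a, b, loc=_AGE_LOC, scale=_AGE_SCALE)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def sample_outcome(grade: int, config: CohortConfig, rng: np.random.Generator) -> int:
    """Draw a 5-level GOS conditional on a Stockholm grade (1..4).

    P(GOS <= 3) equals ``config.grade_outcome_probs[grade]``; within the
    unfavorable and favorable halves the level is drawn with the reference
    cohort's relative frequencies (38:9:136 for GOS 1:2:3, 106:62 for 4:5).
    """
    if grade not in (1, 2, 3, 4):
        raise ValueError(f"Stockholm grade must be 1-4, got {grade}")
    p = float(config.grade_outcome_probs[grade])
    if rng.random() < p:
        return int(_categorical_from_u(np.array([rng.random()]), np.array([1, 2, 3]), _GOS_UNFAV_PROBS)[0])
    return int(_categorical_from_u(np.array([rng.random()]), np.array([4, 5]), _GOS_FAV_PROBS)[0])


def apply_detectability_decay(
    lesions: LesionMap, scan_delay: float, config: CohortConfig, rng: np.random.Generator
) -> LesionMap:
    """Thin a lesion map by per-sequence detectability decay.

    Each site survives with probability ``m_seq ** scan_delay`` where
    ``m_seq`` is the sequence family's daily retention multiplier; the
    output is always a subset of the input.  With the default multipliers,
    DWI lesions fade fastest and susceptibility-sensitive (hemorrhagic)
    lesions the slowest.
    """
    if scan_delay < 0:
        raise ValueError("scan_delay must be >= 0")
    kept = [
        s
        for s in sorted(lesions)
        if rng.random() < config.detectability_decay[s.sequence] ** scan_delay
    ]
    return LesionMap(kept)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a cohort; deterministic given ``config`` (including seed)."""
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    streams = dict(
        zip(
            ("severity", "lesions", "decay", "covariates", "outcome", "delay"),
            (np.random.default_rng(c) for c in ss.spawn(6)),
        )
    )
    sd = config.latent_severity_sd
    z = streams["severity"].normal(0.0, sd, size=n)

    # scan delay (whole days, 0..28)
    days, day_pmf = _delay_pmf()
    delay = streams["delay"].choice(days, size=n, p=day_pmf)

    # true lesions, then decay thinning -> observed lesions
    sites, intercepts = _calibrate(config)
    if np.all(np.isneginf(intercepts)):
        observed = np.zeros((n, len(sites)), dtype=bool)
    else:
        p_true = expit(intercepts[None, :] + config.lesion_slope * z[:, None])
        true = streams["lesions"].random((n, len(sites))) < p_true
        retention = np.array(
            [config.detectability_decay[s.sequence] for s in sites]
        )[None, :] ** delay[:, None]
        observed = true & (streams["decay"].random((n, len(sites))) < retention)

    # covariates via severity-coupled copulas (marginals exact)
    rng_cov = streams["covariates"]
    gcs = _categorical_from_u(_coupled_u(z, sd, _COEF_GCS, rng_cov), _GCS_VALUES, _GCS_PROBS)
    pupils_idx = _categorical_from_u(
        _coupled_u(z, sd, _COEF_PUPILS, rng_cov), np.arange(3), _PUPIL_PROBS
    )
    rotterdam = _categorical_from_u(
        _coupled_u(z, sd, _COEF_ROTTERDAM, rng_cov), _ROTTERDAM_VALUES, _ROTTERDAM_PROBS
    )
    age = _age_from_u(_coupled_u(z, sd, _COEF_AGE, rng_cov))

    rng_out = streams["outcome"]
    records: list[PatientRecord] = []
    for i in range(n):
        lesion_map = LesionMap(s for s, flag in zip(sites, observed[i]) if flag)
        grade = grade_stockholm(lesion_map).grade
        gos = sample_outcome(grade, config, rng_out)
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                age=float(np.round(age[i], 1)),
                gcs=int(gcs[i]),
                pupils=_PUPIL_LEVELS[int(pupils_idx[i])],
                rotterdam=int(rotterdam[i]),
                scan_delay=int(delay[i]),
                lesions=lesion_map,
                gos=gos,
            )
        )
    return records


def inject_missingness(
    cohort: Sequence[PatientRecord], rate: float, rng: np.random.Generator
) -> list[PatientRecord]:
    """Mask covariate cells (age, GCS, pupils, Rotterdam) MCAR at ``rate``.

    Outcome, scan delay and lesion annotations are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    out = []
    for rec in cohort:
        mask = rng.random(len(COVARIATE_COLUMNS)) < rate
        changes = {col: None for col, m in zip(COVARIATE_COLUMNS, mask) if m}
        out.append(replace(rec, **changes) if changes else replace(rec))
    return out
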