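"""Rule engines for four MRI-based traumatic axonal injury grading systems.

Each grader maps a :class:`~taigrade.lesions.LesionMap` (and, for the
Abu Hamdeh system, patient age) to a single ordinal grade.  All four systems
share two conventions:

* **Most-severe-grade precedence.**  Rules are evaluated from the most to
  the least severe grade, across all three sequence families; the first rule
  with at least one matching site wins, and additional qualifying sites do
  not change the grade.
* **Exhaustive fallback.**  Adams, Firsching and Abu Hamdeh return grade 0
  when no rule matches (including the empty map).  The Stockholm system has
  no grade 0: grade I absorbs both lesion-free patients and patients whose
  lesions lie only in regions the higher grades do not mention.

Grade ladders
-------------
Adams (0-III)
    I hemispheric, II corpus callosum, III brainstem.
Firsching (0-IV)
    I supratentorial only, II unilateral brainstem at any level,
    III bilateral midbrain, IV bilateral pons.
Abu Hamdeh (0-IV, age-stratified a/b)
    I hemispheric, II corpus callosum, III brainstem except the
    tegmental midbrain, IV midbrain tegmentum (substantia nigra included)
    on the susceptibility-sensitive family.
Stockholm (I-IV)
    II corpus callosum / unilateral thalamus / unilateral pons /
    extra-tegmental midbrain; III midbrain tegmentum / bilateral thalamus /
    posterior limb of the internal capsule; IV bilateral pons; I otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lesions import BRAINSTEM, HEMISPHERIC, SUPRATENTORIAL, LesionMap

SYSTEMS: tuple[str, ...] = ("adams", "firsching", "abu_hamdeh", "stockholm")

_ROMAN = {0: "0", 1: "I", 2: "II", 3: "III", 4: "IV"}


@dataclass(frozen=True)
class GradeResult:
    """Outcome of one grading system applied to one patient.

    ``triggering_sites`` holds the sites that satisfy the awarded grade's
    rule; it is empty only for fallback grades (grade 0, Stockholm I).
    ``age_stratum`` is ``'a'`` (age < 30) or ``'b'`` for the Abu Hamdeh
    system and ``None`` otherwise.
    """

    system: str
    grade: int
    age_stratum: str | None
    triggering_sites: frozenset

    @property
    def label(self) -> str:
        """Roman-numeral grade label, e.g. ``'IVa'`` or ``'II'``."""
        return _ROMAN[self.grade] + (self.age_stratum or "")


def grade_stockholm(lesions: LesionMap) -> GradeResult:
    """Stockholm MRI grading system (grades I-IV, no grade 0).

    Grade IV: bilateral pontine TAI.  Grade III: TAI in the midbrain
    tegmentum (either laterality), bilateral thalamic TAI, or TAI in the
    posterior limb of the internal capsule (either laterality).  Grade II:
    TAI in the corpus callosum, unilateral thalamic TAI, unilateral pontine
    TAI, or midbrain TAI outside the tegmentum.  Grade I: everything else,
    including no detected TAI.
    """
    hit = lesions.match(region="pons", laterality="bilateral")
    if hit:
        return GradeResult("stockholm", 4, None, hit)
    hit = (
        lesions.match(region="midbrain", subregion="tegmentum")
        | lesions.match(region="thalamus", laterality="bilateral")
        | lesions.match(region="internal_capsule_plic")
    )
    if hit:
        return GradeResult("stockholm", 3, None, hit)
    midbrain_extrategmental = lesions.match(region="midbrain") - lesions.match(
        region="midbrain", subregion="tegmentum"
    )
    hit = (
        lesions.match(region="corpus_callosum")
        | lesions.match(region="thalamus", laterality="unilateral")
        | lesions.match(region="pons", laterality="unilateral")
        | midbrain_extrategmental
    )
    if hit:
        return GradeResult("stockholm", 2, None, hit)
    return GradeResult("stockholm", 1, None, frozenset())


def grade_adams(lesions: LesionMap) -> GradeResult:
    """Adams grading adapted to MRI: I hemispheric, II callosal, III brainstem."""
    hit = lesions.match_regions(BRAINSTEM)
    if hit:
        return GradeResult("adams", 3, None, hit)
    hit = lesions.match(region="corpus_callosum")
    if hit:
        return GradeResult("adams", 2, None, hit)
    hit = lesions.match_regions(HEMISPHERIC)
    if hit:
        return GradeResult("adams", 1, None, hit)
    return GradeResult("adams", 0, None, frozenset())


def grade_firsching(lesions: LesionMap) -> GradeResult:
    """Firsching brainstem-weighted grading (0-IV).

    Laterality is assessed per region: a unilateral midbrain lesion plus a
    unilateral pontine lesion counts as unilateral brainstem involvement
    (grade II), not as a bilateral pattern.
    """
    hit = lesions.match(region="pons", laterality="bilateral")
    if hit:
        return GradeResult("firsching", 4, None, hit)
    hit = lesions.match(region="midbrain", laterality="bilateral")
    if hit:
        return GradeResult("firsching", 3, None, hit)
    hit = lesions.match(region="midbrain", laterality="unilateral") | lesions.match(
        region="pons", laterality="unilateral"
    )
    if hit:
        return GradeResult("firsching", 2, None, hit)
    hit = lesions.match_regions(SUPRATENTORIAL)
    if hit:
        # reaching this branch implies no brainstem site remains
        return GradeResult("firsching", 1, None, hit)
    return GradeResult("firsching", 0, None, frozenset())


def grade_abu_hamdeh(lesions: LesionMap, age: float, swi_available: bool = True) -> GradeResult:
    """Abu Hamdeh grading with age strata (a: age < 30, b: age >= 30).

    Grade IV requires a midbrain-tegmentum lesion (the substantia nigra is
    part of the tegmental compartment) on the susceptibility-sensitive
    family; when SWI was not acquired (``swi_available=False``) T2*GRE
    stands in, which is the same sequence family here, so the rule is
    unchanged.  Grade III covers brainstem lesions *excluding* the tegmental
    midbrain on any sequence, per the system's own footnote; a tegmental
    lesion seen only on DWI/FLAIR therefore does not qualify for III (nor
    for IV).  Age exactly 30 falls in stratum b.
    """
    if age < 15:
        raise ValueError("grading is defined for adult patients (age >= 15)")
    stratum = "a" if age < 30 else "b"
    hit = lesions.match(region="midbrain", subregion="tegmentum", sequence="susceptibility")
    if hit:
        return GradeResult("abu_hamdeh", 4, stratum, hit)
    hit = lesions.match_regions(BRAINSTEM) - lesions.match(
        region="midbrain", subregion="tegmentum"
    )
    if hit:
        return GradeResult("abu_hamdeh", 3, stratum, hit)
    hit = lesions.match(region="corpus_callosum")
    if hit:
        return GradeResult("abu_hamdeh", 2, stratum, hit)
    hit = lesions.match_regions(HEMISPHERIC)
    if hit:
        return GradeResult("abu_hamdeh", 1, stratum, hit)
    return GradeResult("abu_hamdeh", 0, stratum, frozenset())


def grade_one(system: str, lesions: LesionMap, age: float | None = None) -> GradeResult:
    """Apply one named grading system."""
    if system == "stockholm":
        return grade_stockholm(lesions)
    if system == "adams":
        return grade_adams(lesions)
    if system == "firsching":
        return grade_firsching(lesions)
    if system == "abu_hamdeh":
        if age is None:
            raise ValueError("abu_hamdeh grading requires patient age")
        return grade_abu_hamdeh(lesions, age)
    raise ValueError(f"unknown grading system {system!r}")


def grade_cohort(cohort, systems=SYSTEMS) -> pd.DataFrame:
    """Grade every patient under every requested system.

    Parameters
    ----------
    cohort
        Sequence of :class:`~taigrade.cohort.PatientRecord`.
    systems
        Subset of :data:`SYSTEMS`.

    Returns
    -------
    Long-format frame with one row per (patient, system):
    ``patient_id, system, grade, age_stratum, label``.
    """
    for s in systems:
        if s not in SYSTEMS:
            raise ValueError(f"unknown grading system {s!r}")
    rows = []
    for rec in cohort:
        for system in systems:
            res = grade_one(system, rec.lesions, age=rec.age)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "system": system,
                    "grade": res.grade,
                    "age_stratum": res.age_stratum,
                    "label": res.label,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "system", "grade", "age_stratum", "label"])


def grades_wide(cohort, systems=SYSTEMS) -> pd.DataFrame:
    """One row per patient with a ``grade_<system>`` column per system."""
    long = grade_cohort(cohort, systems)
    wide = long.pivot(index="patient_id", columns="system", values="grade")
    wide.columns = [f"grade_{c}" for c in wide.columns]
    return wide.reset_index()
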