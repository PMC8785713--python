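"""Cohort flat-file I/O and chained-equation imputation.

Cohorts are stored as a single CSV (one row per patient, lesion indicators
as 0/1 columns named ``<region>_<subregion>_<laterality>_<sequence>``) with
an optional JSON sidecar recording the generating configuration, seed
included, for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .cohort import COVARIATE_COLUMNS, CohortConfig, PatientRecord
from .lesions import SITE_COLUMNS, LesionMap

MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "gcs",
    "pupils",
    "rotterdam",
    "scan_delay",
    "gos",
) + SITE_COLUMNS

_PUPIL_LEVELS = ("responsive", "unilaterally_unresponsive", "bilaterally_unresponsive")
_INT_RANGES = {"gcs": (3, 15), "gos": (1, 5), "rotterdam": (1, 6), "scan_delay": (0, 28)}


class CohortSchemaError(ValueError):
    """The file does not match the cohort schema."""


class CohortValidationError(ValueError):
    """A row carries an out-of-range or malformed value."""


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flat one-row-per-patient representation of a cohort."""
    rows = []
    for rec in cohort:
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "gcs": rec.gcs,
            "pupils": rec.pupils,
            "rotterdam": rec.rotterdam,
            "scan_delay": rec.scan_delay,
            "gos": rec.gos,
            "unfavorable": rec.unfavorable,
        }
        row.update(rec.lesions.to_columns())
        row.update(rec.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from a flat frame."""
    records = []
    extra_cols = [c for c in frame.columns if c not in MANDATORY_COLUMNS and c != "unfavorable"]
    for i, row in frame.iterrows():
        _validate_row(i, row)
        lesions = LesionMap.from_columns(row)
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=None if pd.isna(row["age"]) else float(row["age"]),
                gcs=None if pd.isna(row["gcs"]) else int(row["gcs"]),
                pupils=None if pd.isna(row["pupils"]) else str(row["pupils"]),
                rotterdam=None if pd.isna(row["rotterdam"]) else int(row["rotterdam"]),
                scan_delay=int(row["scan_delay"]),
                lesions=lesions,
                gos=None if pd.isna(row["gos"]) else int(row["gos"]),
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def _validate_row(index, row) -> None:
    for col, (lo, hi) in _INT_RANGES.items():
        v = row[col]
        if pd.isna(v):
            continue
        if not float(v).is_integer() or not lo <= int(v) <= hi:
            raise CohortValidationError(
                f"row {index}: {col}={v!r} outside the valid range {lo}-{hi}"
            )
    if not pd.isna(row["age"]) and float(row["age"]) < 15:
        raise CohortValidationError(f"row {index}: age={row['age']!r} below the adult minimum of 15")
    if not pd.isna(row["pupils"]) and row["pupils"] not in _PUPIL_LEVELS:
        raise CohortValidationError(f"row {index}: unknown pupillary status {row['pupils']!r}")


def write_cohort_csv(
    cohort: Sequence[PatientRecord], path, config: CohortConfig | None = None
) -> Path:
    """Write a cohort CSV; with ``config``, also a ``.json`` sidecar."""
    path = Path(path)
    frame = cohort_to_frame(cohort)
    frame.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        payload = dataclasses.asdict(config)
        if payload.get("lesion_base_rates") is not None:
            payload["lesion_base_rates"] = {
                site.column: p for site, p in payload["lesion_base_rates"].items()
            }
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Unknown columns are preserved in each record's ``extras`` and written
    back on the next round trip.  An empty file yields an empty cohort with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path} is empty; returning an empty cohort", UserWarning, stacklevel=2)
        return []
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path} has no data rows; returning an empty cohort", UserWarning, stacklevel=2)
        return []
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return frame_to_cohort(frame)


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------


def impute_chained(
    cohort: Sequence[PatientRecord], n_iterations: int = 10, seed: int = 0
) -> list[PatientRecord]:
    """Impute missing covariates by chained regression equations.

    Each incomplete covariate is regressed on the other covariates plus the
    dichotomized outcome (multinomial logistic for pupillary status, linear
    otherwise) and replaced by the regression prediction; the cycle repeats
    ``n_iterations`` times from a random-draw initialization.  Predictions
    rather than posterior draws are used: the imputations feed point
    prediction downstream, where the conditional mean is the better guess.
    Observed cells are never altered.  Deterministic given ``seed``.
    """
    frame = cohort_to_frame(cohort)
    work = frame[list(COVARIATE_COLUMNS)].copy()
    work["pupils"] = work["pupils"].map(
        {lvl: i for i, lvl in enumerate(_PUPIL_LEVELS)}
    )
    work = work.astype(float)
    work["unfavorable"] = frame["unfavorable"].astype(float)

    observed = {c: work[c].notna().to_numpy() for c in COVARIATE_COLUMNS}
    incomplete = [c for c in COVARIATE_COLUMNS if not observed[c].all()]
    for c in incomplete:
        if not observed[c].any():
            raise ValueError(f"covariate {c!r} is entirely missing; cannot impute")
    if not incomplete:
        return list(cohort)

    rng = np.random.default_rng(seed)
    for c in incomplete:
        obs_vals = work.loc[observed[c], c].to_numpy()
        fill = rng.choice(obs_vals, size=int((~observed[c]).sum()))
        work.loc[~observed[c], c] = fill

    bounds = {"age": (15.0, 82.0), "gcs": (3, 15), "rotterdam": (1, 6)}
    for _ in range(n_iterations):
        for c in incomplete:
            others = [x for x in COVARIATE_COLUMNS if x != c] + ["unfavorable"]
            X = work[others].to_numpy()
            y_obs = work.loc[observed[c], c].to_numpy()
            X_obs, X_mis = X[observed[c]], X[~observed[c]]
            if c == "pupils":
                if len(np.unique(y_obs)) < 2:
                    pred = np.full(len(X_mis), y_obs[0])
                else:
                    clf = LogisticRegression(max_iter=1000)
                    clf.fit(X_obs, y_obs.astype(int))
                    pred = clf.predict(X_mis).astype(float)
            else:
                reg = LinearRegression().fit(X_obs, y_obs)
                pred = reg.predict(X_mis)
                lo, hi = bounds[c]
                pred = np.clip(pred, lo, hi)
                if c in ("gcs", "rotterdam"):
                    pred = np.round(pred)
            work.loc[~observed[c], c] = pred

    out = []
    rev_pupils = dict(enumerate(_PUPIL_LEVELS))
    for i, rec in enumerate(cohort):
        changes = {}
        if rec.age is None:
            changes["age"] = float(np.round(work.at[i, "age"], 1))
        if rec.gcs is None:
            changes["gcs"] = int(work.at[i, "gcs"])
        if rec.rotterdam is None:
            changes["rotterdam"] = int(work.at[i, "rotterdam"])
        if rec.pupils is None:
            changes["pupils"] = rev_pupils[int(work.at[i, "pupils"])]
        out.append(dataclasses.replace(rec, **changes) if changes else rec)
    return out
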