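"""Readers and writers for cohorts, encoded matrices and reports.

CSV layout: one row per visit; diagnoses and medications are
semicolon-delimited; labs are ``name:value:flag`` triples and lab-variation
entries ``name:flag`` pairs, both semicolon-delimited; dates are ISO-8601.
A JSON alternative keeps the nested lists as-is.
"""

from __future__ import annotations

import datetime as dt
import json

import numpy as np
import pandas as pd

from .prep import EncodedCohort
from .simulate import EXCLUSION_RULES, VisitRecord

__all__ = [
    "cohort_to_dataframe",
    "dataframe_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_json",
    "read_cohort_json",
    "write_encoded_csv",
    "read_encoded_csv",
]

_SCALAR_FIELDS = [
    "visit_id", "patient_id", "admit_date", "discharge_date", "visit_type",
    "admit_source", "age", "gender", "marital_status", "family_support",
    "er_visits_6mo", "admissions_6mo", "admissions_12mo", "isolated_room",
    "outcome_R", "readmit_cost", "readmit_outside", "true_p",
]


def cohort_to_dataframe(cohort: list[VisitRecord]) -> pd.DataFrame:
    rows = []
    for v in cohort:
        row = {f: getattr(v, f) for f in _SCALAR_FIELDS}
        row["admit_date"] = v.admit_date.isoformat()
        row["discharge_date"] = v.discharge_date.isoformat()
        row["diagnoses"] = ";".join(v.diagnoses)
        row["medications"] = ";".join(v.medications)
        row["labs"] = ";".join(f"{n}:{x}:{f}" for n, x, f in v.labs)
        row["lab_variation"] = ";".join(f"{n}:{f}" for n, f in v.lab_variation)
        for rule in EXCLUSION_RULES:
            row[f"excl_{rule}"] = v.exclusion_flags.get(rule, False)
        rows.append(row)
    return pd.DataFrame(rows)


def _split(text):
    if text is None or pd.isna(text) or text == "":
        return []
    return str(text).split(";")


def dataframe_to_cohort(df: pd.DataFrame) -> list[VisitRecord]:
    cohort = []
    for _, row in df.iterrows():
        labs = []
        for item in _split(row.get("labs")):
            name, value, flag = item.rsplit(":", 2)
            labs.append((name, float(value), flag))
        variation = []
        for item in _split(row.get("lab_variation")):
            name, flag = item.rsplit(":", 1)
            variation.append((name, flag))
        true_p = row.get("true_p")
        if true_p is not None and isinstance(true_p, float) and np.isnan(true_p):
            true_p = None
        cohort.append(VisitRecord(
            visit_id=str(row["visit_id"]),
            patient_id=str(row["patient_id"]),
            admit_date=dt.date.fromisoformat(row["admit_date"]),
            discharge_date=dt.date.fromisoformat(row["discharge_date"]),
            visit_type=str(row["visit_type"]),
            admit_source=str(row["admit_source"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            marital_status=str(row["marital_status"]),
            family_support=str(row["family_support"]),
            diagnoses=_split(row.get("diagnoses")),
            labs=labs,
            lab_variation=variation,
            medications=_split(row.get("medications")),
            er_visits_6mo=int(row["er_visits_6mo"]),
            admissions_6mo=int(row["admissions_6mo"]),
            admissions_12mo=int(row["admissions_12mo"]),
            isolated_room=bool(row["isolated_room"]),
            exclusion_flags={r: bool(row.get(f"excl_{r}", False))
                             for r in EXCLUSION_RULES},
            outcome_R=int(row["outcome_R"]),
            readmit_cost=float(row["readmit_cost"]),
            readmit_outside=bool(row["readmit_outside"]),
            true_p=None if true_p is None else float(true_p),
        ))
    return cohort


def write_cohort_csv(cohort: list[VisitRecord], path) -> None:
    # %.17g keeps float64 round-trippable (pandas' default drops a digit)
    cohort_to_dataframe(cohort).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> list[VisitRecord]:
    df = pd.read_csv(path, keep_default_na=True, float_precision="round_trip",
                     dtype={"diagnoses": "string", "medications": "string",
                            "labs": "string", "lab_variation": "string"})
    return dataframe_to_cohort(df)


def write_cohort_json(cohort: list[VisitRecord], path) -> None:
    from .simulate import visit_to_dict

    with open(path, "w") as fh:
        json.dump([visit_to_dict(v) for v in cohort], fh, indent=1)


def read_cohort_json(path) -> list[VisitRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    cohort = []
    for d in payload:
        d = dict(d)
        d["admit_date"] = dt.date.fromisoformat(d["admit_date"])
        d["discharge_date"] = dt.date.fromisoformat(d["discharge_date"])
        d["labs"] = [tuple(x) for x in d["labs"]]
        d["lab_variation"] = [tuple(x) for x in d["lab_variation"]]
        cohort.append(VisitRecord(**d))
    return cohort


def write_encoded_csv(encoded: EncodedCohort, path) -> None:
    """Dense CSV: visit_id, outcome, then one column per feature name."""
    df = pd.DataFrame(encoded.features, columns=encoded.feature_names)
    df.insert(0, "outcome", encoded.outcome)
    df.insert(0, "visit_id", encoded.visit_ids)
    df.to_csv(path, index=False)


def read_encoded_csv(path) -> EncodedCohort:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("visit_id", "outcome")]
    return EncodedCohort(
        features=df[names].to_numpy(dtype=np.uint8),
        outcome=df["outcome"].to_numpy(dtype=int),
        feature_names=names,
        visit_ids=[str(v) for v in df["visit_id"]],
    )
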