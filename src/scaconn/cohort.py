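"""Subject metadata and cohort-level I/O.

Tables are tab-separated UTF-8 with a header row; absent values are empty
cells (never 0, since 0 is a legal SARA score).  Patients carry the three
clinical covariates (years of symptoms, CAG repeat count, SARA score);
controls may omit them.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .timeseries import MotionTrace, RoiTimeSeries

GROUPS = ("patient", "control")
COHORT_COLUMNS = ("id", "group", "age", "gender", "years_of_symptoms",
                  "cag_expansion", "sara")


@dataclass
class SubjectRecord:
    id: str
    group: str                         # "patient" | "control"
    age: int
    gender: str                        # "F" | "M"
    years_of_symptoms: Optional[float] = None
    cag_expansion: Optional[int] = None
    sara: Optional[float] = None       # 0-40 ataxia severity score

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.id}: unknown group {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValueError(f"subject {self.id}: gender must be F or M")
        if self.age <= 0:
            raise ValueError(f"subject {self.id}: age must be positive")
        if self.group == "patient":
            for name in ("years_of_symptoms", "cag_expansion", "sara"):
                if getattr(self, name) is None:
                    raise ValueError(
                        f"patient {self.id} is missing {name}")
        if self.sara is not None and not 0 <= self.sara <= 40:
            raise ValueError(f"subject {self.id}: SARA {self.sara} outside [0, 40]")


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("no subjects in table")
    ids = df["id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        cag = _opt(row["cag_expansion"])
        records.append(SubjectRecord(
            id=str(row["id"]),
            group=str(row["group"]),
            age=int(row["age"]),
            gender=str(row["gender"]),
            years_of_symptoms=_opt(row["years_of_symptoms"]),
            cag_expansion=None if cag is None else int(cag),
            sara=_opt(row["sara"]),
        ))
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "id": r.id, "group": r.group, "age": r.age, "gender": r.gender,
            "years_of_symptoms": r.years_of_symptoms,
            "cag_expansion": r.cag_expansion, "sara": r.sara,
        } for r in records],
        columns=list(COHORT_COLUMNS),
    )


def read_subject_table(path) -> list[SubjectRecord]:
    return records_from_frame(pd.read_csv(path, sep="\t"))


def write_subject_table(records: Sequence[SubjectRecord], path) -> None:
    df = records_to_frame(records)
    # integers stay integers in the written table; absent values are empty
    df["cag_expansion"] = df["cag_expansion"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


def read_cohort(subject_table, timeseries_dir, motion_dir=None):
    """Load a full cohort: metadata, ROI time series and motion traces.

    One ``<id>.tsv`` (plus ``<id>.json`` sidecar) per subject is expected in
    ``timeseries_dir``, and one ``<id>.tsv`` in ``motion_dir`` when given.
    All subjects must share the same regions in the same order; a mismatch
    is an error, never a silent reorder.
    """
    records = read_subject_table(subject_table)
    timeseries_dir = Path(timeseries_dir)
    motion_dir = None if motion_dir is None else Path(motion_dir)
    series: dict[str, RoiTimeSeries] = {}
    motion: dict[str, MotionTrace] = {}
    reference: Optional[list[str]] = None
    for rec in records:
        ts_path = timeseries_dir / f"{rec.id}.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(
                f"no time-series file for subject {rec.id!r} ({ts_path})")
        ts = RoiTimeSeries.from_tsv(ts_path)
        if reference is None:
            reference = ts.region_names
        elif ts.region_names != reference:
            raise ValueError(
                f"subject {rec.id!r}: region names/order differ from the "
                "first subject's")
        series[rec.id] = ts
        if motion_dir is not None:
            m_path = motion_dir / f"{rec.id}.tsv"
            if not m_path.exists():
                raise FileNotFoundError(
                    f"no motion file for subject {rec.id!r} ({m_path})")
            trace = MotionTrace.from_tsv(m_path)
            if trace.n_volumes != ts.n_volumes:
                raise ValueError(
                    f"subject {rec.id!r}: motion trace has {trace.n_volumes} "
                    f"volumes but time series has {ts.n_volumes}")
            motion[rec.id] = trace
    return records, series, motion


def cohort_summary(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-group demographics: n, mean age (1 decimal), female count, mean SARA."""
    if not records:
        raise ValueError("no subject records")
    rows = []
    for group in GROUPS:
        sub = [r for r in records if r.group == group]
        if not sub:
            continue
        saras = [r.sara for r in sub if r.sara is not None]
        rows.append({
            "group": group,
            "n": len(sub),
            "mean_age": round(sum(r.age for r in sub) / len(sub), 1),
            "female_count": sum(1 for r in sub if r.gender == "F"),
            "mean_sara": round(sum(saras) / len(saras), 1) if saras else None,
        })
    return pd.DataFrame(rows)


def load_sca7_demographics() -> list[SubjectRecord]:
    """The packaged 26-patient SCA7 demographic table."""
    ref = importlib.resources.files("scaconn.data") / "sca7_demographics.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_subject_table(path)


def load_abnormal_connections() -> pd.DataFrame:
    """The packaged table of 19 abnormal SCA7 connections.

    Columns: printed labels, canonical AAL region names, the reported
    two-tailed p-value of the patient-vs-control edge difference, and the
    direction of the abnormality (increase/decrease in patients).
    """
    ref = importlib.resources.files("scaconn.data") / "abnormal_connections.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
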