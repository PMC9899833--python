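"""NONMEM-dialect longitudinal PK datasets: records, I/O, BQL filtering, summaries.

The on-disk dialect is a comma-separated table with columns
``ID, TIME, AMT, EVID, MDV, DV, BSA, TP, SEX, TYPE, AGE, ALB`` where
``EVID`` 1 marks a dose and 0 an observation, ``SEX`` is 0=male / 1=female and
``TYPE`` is 0=melanoma / 1=NF1.  Time is hours since first dose, doses are mg,
concentrations ng/mL.  A row is flagged below the quantification limit (BQL)
when it is a non-missing observation with DV below the assay LLOQ
(0.2 ng/mL by default).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CovariateVector",
    "PKRecord",
    "PKDataset",
    "DataSummary",
    "BQLReport",
    "SchemaError",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "filter_bql",
    "summarize_dataset",
    "DEFAULT_LLOQ",
]

DEFAULT_LLOQ = 0.2  # ng/mL, lower end of the validated assay range

SEX_LEVELS = ("male", "female")
CANCER_LEVELS = ("melanoma", "nf1")

_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "BSA", "TP", "SEX", "TYPE", "AGE", "ALB"]


class SchemaError(ValueError):
    """Structural problem in a dataset (missing column, invariant violation)."""


class ParseError(ValueError):
    """Non-numeric content where a number was required."""


@dataclass(frozen=True)
class CovariateVector:
    """Per-subject covariates entering the covariate submodel.

    ``bsa`` body surface area (m^2), ``tp`` total plasma protein (g/L),
    ``sex`` in {male, female}, ``cancer_type`` in {melanoma, nf1},
    ``age`` in years; ``albumin`` (g/L) and ``weight`` (kg) are carried but
    not used by the final model.
    """

    bsa: float
    tp: float | None = None
    sex: str | None = None
    cancer_type: str | None = None
    age: float | None = None
    albumin: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if not (self.bsa > 0):
            raise SchemaError(f"bsa must be positive, got {self.bsa}")
        if self.tp is not None and not (self.tp > 0):
            raise SchemaError(f"tp must be positive when present, got {self.tp}")
        if self.age is not None and self.age < 0:
            raise SchemaError(f"age must be non-negative, got {self.age}")
        if self.sex is not None and self.sex not in SEX_LEVELS:
            raise SchemaError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.cancer_type is not None and self.cancer_type not in CANCER_LEVELS:
            raise SchemaError(
                f"cancer_type must be one of {CANCER_LEVELS}, got {self.cancer_type!r}"
            )


@dataclass(frozen=True)
class PKRecord:
    """One dosing or observation event for one subject."""

    subject_id: str
    time: float  # h since first dose
    amt: float  # mg; 0 for observations
    evid: int  # 1 dose, 0 observation
    dv: float | None  # ng/mL; None for doses or missing observations
    mdv: int  # missing-DV flag
    bql: bool
    covariates: CovariateVector

    def __post_init__(self) -> None:
        if self.evid == 1:
            if not (self.amt > 0):
                raise SchemaError(f"dose record must have amt > 0, got {self.amt}")
            if self.dv is not None:
                raise SchemaError("dose record must not carry a DV")
        elif self.evid == 0:
            if self.amt != 0:
                raise SchemaError(f"observation record must have amt = 0, got {self.amt}")
        else:
            raise SchemaError(f"evid must be 0 or 1, got {self.evid}")

    @property
    def is_dose(self) -> bool:
        return self.evid == 1

    @property
    def is_observation(self) -> bool:
        return self.evid == 0


@dataclass
class PKDataset:
    """Ordered event records plus the assay quantification limit."""

    records: list[PKRecord]
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if not (self.lloq > 0):
            raise SchemaError(f"lloq must be positive, got {self.lloq}")
        last_time: dict[str, float] = {}
        for i, rec in enumerate(self.records):
            prev = last_time.get(rec.subject_id)
            if prev is not None and rec.time < prev - 1e-12:
                raise SchemaError(
                    f"record {i}: time {rec.time} decreases within subject {rec.subject_id}"
                )
            last_time[rec.subject_id] = rec.time

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def observations(self) -> list[PKRecord]:
        return [r for r in self.records if r.is_observation]

    @property
    def doses(self) -> list[PKRecord]:
        return [r for r in self.records if r.is_dose]

    def subject_records(self, subject_id: str) -> list[PKRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            c = rec.covariates
            rows.append(
                {
                    "ID": rec.subject_id,
                    "TIME": rec.time,
                    "AMT": rec.amt,
                    "EVID": rec.evid,
                    "MDV": rec.mdv,
                    "DV": np.nan if rec.dv is None else rec.dv,
                    "BSA": c.bsa,
                    "TP": np.nan if c.tp is None else c.tp,
                    "SEX": np.nan if c.sex is None else SEX_LEVELS.index(c.sex),
                    "TYPE": np.nan if c.cancer_type is None else CANCER_LEVELS.index(c.cancer_type),
                    "AGE": np.nan if c.age is None else c.age,
                    "ALB": np.nan if c.albumin is None else c.albumin,
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)


@dataclass(frozen=True)
class BQLReport:
    n_total: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_removed

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


@dataclass
class DataSummary:
    n_subjects: int
    n_observations: int
    n_bql: int
    covariates: pd.DataFrame  # rows: covariate; columns: median, p5, p25, p75, p95

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "n_bql": self.n_bql,
            "covariates": {
                name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for name, row in self.covariates.iterrows()
            },
        }


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _row_to_record(row: Mapping, index, lloq: float) -> PKRecord:
    try:
        time = float(row["TIME"])
        amt = float(row["AMT"])
        evid = int(float(row["EVID"]))
        mdv = int(float(row["MDV"])) if not pd.isna(row["MDV"]) else 0
        dv = _opt(row["DV"])
        bsa = float(row["BSA"])
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {index}: non-numeric value ({exc})") from exc
    sex = _opt(row.get("SEX"))
    ctype = _opt(row.get("TYPE"))
    cov = CovariateVector(
        bsa=bsa,
        tp=_opt(row.get("TP")),
        sex=None if sex is None else SEX_LEVELS[int(sex)],
        cancer_type=None if ctype is None else CANCER_LEVELS[int(ctype)],
        age=_opt(row.get("AGE")),
        albumin=_opt(row.get("ALB")),
    )
    if evid == 1:
        dv = None
        mdv = 1
    bql = evid == 0 and mdv == 0 and dv is not None and dv < lloq
    try:
        return PKRecord(
            subject_id=str(row["ID"]),
            time=time,
            amt=amt,
            evid=evid,
            dv=dv if mdv == 0 else None,
            mdv=mdv,
            bql=bql,
            covariates=cov,
        )
    except SchemaError as exc:
        raise SchemaError(f"row {index}: {exc}") from exc


def read_dataset(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    lloq: float = DEFAULT_LLOQ,
) -> PKDataset:
    """Read a delimiter-separated PK dataset.

    ``column_map`` maps canonical column names (``ID``, ``TIME``, ...) to the
    names used in the file; identity by default.  Rows violating record
    invariants are rejected with their row index in the error message.
    """
    df = pd.read_csv(source)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "BSA"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = [_row_to_record(row, idx, lloq) for idx, row in df.iterrows()]
    return PKDataset(records=records, lloq=lloq)


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if float(value) == int(value) and abs(value) < 1e15:
        return str(int(value))
    return format(float(value), ".10g")


def write_dataset(ds: PKDataset, sink: str | IO[str]) -> None:
    """Write ``ds`` in the canonical dialect; read_dataset round-trips it."""
    frame = ds.to_frame()
    lines = [",".join(_COLUMNS)]
    for _, row in frame.iterrows():
        lines.append(
            ",".join(
                [str(row["ID"])]
                + [_fmt(row[c]) for c in _COLUMNS[1:]]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str,)):
        with open(sink, "w") as fh:
            fh.write(text)
    else:
        sink.write(text)


def filter_bql(ds: PKDataset) -> tuple[PKDataset, BQLReport]:
    """Drop BQL observations (exclusion handling); dose records untouched."""
    kept: list[PKRecord] = []
    n_total = 0
    n_removed = 0
    for rec in ds.records:
        if rec.is_observation:
            n_total += 1
            is_bql = rec.bql or (rec.dv is not None and rec.dv < ds.lloq)
            if is_bql:
                n_removed += 1
                continue
        kept.append(rec)
    return PKDataset(records=kept, lloq=ds.lloq), BQLReport(n_total=n_total, n_removed=n_removed)


_SUMMARY_COVARIATES = ["bsa", "tp", "age", "albumin", "weight"]
_QUANTS = {"p5": 0.05, "p25": 0.25, "median": 0.5, "p75": 0.75, "p95": 0.95}


def summarize_dataset(ds: PKDataset) -> DataSummary:
    """Subject count, observation/BQL counts, per-covariate percentiles.

    Percentiles use one covariate value per subject (first record's value).
    """
    if not ds.records:
        raise SchemaError("cannot summarize an empty dataset")
    first_cov: dict[str, CovariateVector] = {}
    n_obs = 0
    n_bql = 0
    for rec in ds.records:
        first_cov.setdefault(rec.subject_id, rec.covariates)
        if rec.is_observation:
            n_obs += 1
            if rec.bql or (rec.dv is not None and rec.dv < ds.lloq):
                n_bql += 1
    rows = {}
    for name in _SUMMARY_COVARIATES:
        values = np.array(
            [getattr(c, name) for c in first_cov.values() if getattr(c, name) is not None],
            dtype=float,
        )
        if values.size == 0:
            rows[name] = {k: np.nan for k in ["median", "p5", "p25", "p75", "p95"]}
        else:
            rows[name] = {k: float(np.quantile(values, q)) for k, q in _QUANTS.items()}
    cov_df = pd.DataFrame(rows).T[["median", "p5", "p25", "p75", "p95"]]
    return DataSummary(
        n_subjects=len(first_cov), n_observations=n_obs, n_bql=n_bql, covariates=cov_df
    )
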