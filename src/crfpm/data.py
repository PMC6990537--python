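"""Data model, validation and delimited-file I/O for competing-risks cohorts.

One row per subject: a unique id, follow-up time (the minimum of the true
event time and the censoring time), an integer event code (0 = censored,
1..K = cause of the first event), and a numeric covariate matrix.
Categorical covariates are expanded to indicator columns at read time so
every model sees a plain design matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompetingRisksDataset",
    "EventSpec",
    "ValidationError",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "complete_cases",
    "truncate_followup",
]


class ValidationError(ValueError):
    """Input data violates a dataset invariant."""


class SchemaError(KeyError):
    """Declared column missing from the input file."""


@dataclass(frozen=True)
class EventSpec:
    """Labels for event codes and the cause currently of interest."""

    cause_labels: dict[int, str]
    cause_of_interest: int = 1

    def __post_init__(self) -> None:
        causes = [c for c in self.cause_labels if c != 0]
        if self.cause_of_interest not in causes:
            raise ValidationError(
                f"cause_of_interest={self.cause_of_interest} not among event codes {sorted(causes)}"
            )


@dataclass
class CompetingRisksDataset:
    """Validated subject-level competing-risks data.

    Attributes
    ----------
    subject_id : array of identifiers, unique.
    time : follow-up times in years, strictly positive.
    event : integer codes 0..K (0 = censored).
    covariates : DataFrame of numeric covariate columns, no missing values.
    K : number of competing causes; every cause 1..K occurs at least once.
    """

    subject_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    K: int = field(default=0)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.time.size
        if not (self.subject_id.size == n == self.event.size == len(self.covariates)):
            raise ValidationError("field lengths differ")
        bad = np.nonzero(~(self.time > 0) | ~np.isfinite(self.time))[0]
        if bad.size:
            raise ValidationError(
                f"time must be > 0 and finite; first offending row index {bad[0]}"
            )
        if self.K == 0:
            self.K = int(self.event.max(initial=0))
        if np.any(self.event < 0) or np.any(self.event > self.K):
            bad = np.nonzero((self.event < 0) | (self.event > self.K))[0]
            raise ValidationError(
                f"event codes must lie in 0..{self.K}; first offending row index {bad[0]}"
            )
        for k in range(1, self.K + 1):
            if not np.any(self.event == k):
                raise ValidationError(f"no rows with event = {k}; cannot model cause {k}")
        if len(np.unique(self.subject_id)) != n:
            raise ValidationError("subject_id not unique")
        if self.covariates.isna().any().any():
            cols = list(self.covariates.columns[self.covariates.isna().any()])
            raise ValidationError(
                f"covariate columns contain missing values: {cols}; apply complete_cases first"
            )
        self.covariates = self.covariates.reset_index(drop=True).astype(float)

    def __len__(self) -> int:
        return self.time.size

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def X(self, names: list[str] | None = None) -> np.ndarray:
        cols = names if names is not None else self.covariate_names
        return self.covariates[cols].to_numpy(dtype=float)

    def event_counts(self) -> dict[int, int]:
        return {k: int(np.sum(self.event == k)) for k in range(self.K + 1)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.subject_id, "time": self.time, "event": self.event})
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)

    def summary(self) -> str:
        """Structured text summary: counts per event and follow-up quantiles,
        with covariate prevalences broken down by first-event type."""
        counts = self.event_counts()
        qs = np.quantile(self.time, [0.25, 0.5, 0.75])
        buf = io.StringIO()
        buf.write(f"subjects: {len(self)}   competing causes: {self.K}\n")
        buf.write("events:  " + "  ".join(
            f"{('censored' if k == 0 else f'cause {k}')}={v}" for k, v in counts.items()
        ) + "\n")
        buf.write(
            f"follow-up quartiles (years): {qs[0]:.2f} / {qs[1]:.2f} / {qs[2]:.2f}\n"
        )
        buf.write("covariate prevalence by first event (column mean):\n")
        groups = {"all": np.ones(len(self), bool)}
        for k in range(self.K + 1):
            groups["censored" if k == 0 else f"cause {k}"] = self.event == k
        header = "  ".join(f"{g:>10}" for g in groups)
        buf.write(f"{'':<20}{header}\n")
        for c in self.covariate_names:
            vals = "  ".join(
                f"{self.covariates.loc[m, c].mean():10.3f}" if m.any() else f"{'--':>10}"
                for m in groups.values()
            )
            buf.write(f"{c:<20}{vals}\n")
        return buf.getvalue()


def _expand_categoricals(df: pd.DataFrame, categorical: dict[str, list] | None) -> pd.DataFrame:
    """Expand declared categorical columns to indicators; reference level is
    the first declared category and gets no column."""
    if not categorical:
        return df
    out = df.copy()
    for col, levels in categorical.items():
        if col not in out.columns:
            raise SchemaError(f"categorical column '{col}' not in data")
        observed = set(out[col].dropna().unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValidationError(f"column '{col}' has undeclared levels: {sorted(map(str, unknown))}")
        for level in levels[1:]:
            out[f"{col}_{level}"] = (out[col] == level).astype(float)
            out.loc[out[col].isna(), f"{col}_{level}"] = np.nan
        out = out.drop(columns=[col])
    return out


def read_dataset(
    path,
    schema: dict | None = None,
    sep: str | None = None,
    validate: bool = True,
) -> CompetingRisksDataset:
    """Read a delimited competing-risks table.

    Parameters
    ----------
    path
        Delimited text file with a header row; comma/tab autodetected
        unless ``sep`` is given.
    schema
        Column-name mapping with keys ``id``, ``time``, ``event``,
        optional ``covariates`` (list; default = all remaining columns)
        and optional ``categorical`` ({column: [levels]}, reference level
        first).
    validate
        Set False to defer invariant checks (needed to read data that
        still contains missing covariates before :func:`complete_cases`).
    """
    schema = dict(schema or {})
    id_col = schema.get("id", "id")
    time_col = schema.get("time", "time")
    event_col = schema.get("event", "event")
    if sep is None:
        # autodetect delimiter from the header line, then use the C engine
        # with exact float parsing so read(write(ds)) is the identity
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"declared column '{col}' missing from {path}")
    if id_col not in df.columns:
        df[id_col] = np.arange(len(df))
    cov_cols = schema.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in (id_col, time_col, event_col)]
    missing = [c for c in cov_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"declared covariate columns missing: {missing}")
    cov = _expand_categoricals(df[cov_cols], schema.get("categorical"))
    ds = CompetingRisksDataset.__new__(CompetingRisksDataset)
    ds.subject_id = df[id_col].to_numpy()
    ds.time = df[time_col].to_numpy(dtype=float)
    ds.event = df[event_col].to_numpy()
    ds.covariates = cov
    ds.K = int(schema.get("K", 0))
    if validate:
        if np.any(pd.isna(ds.event)):
            raise ValidationError("event column contains missing values")
        ds.event = ds.event.astype(int)
        ds.__post_init__()
    return ds


def write_dataset(dataset: CompetingRisksDataset, path, sep: str = ",") -> None:
    """Write the dataset back to delimited text (inverse of read_dataset)."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def complete_cases(dataset: CompetingRisksDataset) -> tuple[CompetingRisksDataset, int]:
    """Drop rows with any missing covariate value; return (dataset, n dropped).

    Accepts a dataset that has not yet been validated (as produced by
    ``read_dataset(..., validate=False)``).
    """
    cov = dataset.covariates
    keep = ~cov.isna().any(axis=1).to_numpy()
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("all rows dropped: every row has a missing covariate")
    out = CompetingRisksDataset(
        subject_id=np.asarray(dataset.subject_id)[keep],
        time=np.asarray(dataset.time, dtype=float)[keep],
        event=np.asarray(dataset.event)[keep].astype(int),
        covariates=cov.loc[keep].reset_index(drop=True),
        K=dataset.K,
    )
    return out, dropped


def truncate_followup(dataset: CompetingRisksDataset, cap: float) -> CompetingRisksDataset:
    """Administrative censoring at ``cap`` years: time > cap becomes
    (time = cap, event = 0)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    time = dataset.time.copy()
    event = dataset.event.copy()
    over = time > cap
    time[over] = cap
    event[over] = 0
    return CompetingRisksDataset(
        subject_id=dataset.subject_id.copy(),
        time=time,
        event=event,
        covariates=dataset.covariates.copy(),
        K=dataset.K,
    )
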