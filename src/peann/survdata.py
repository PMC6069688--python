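"""Subject-level survival data, covariate encoding and person-period expansion.

The piecewise exponential likelihood works on an expanded ("person-period")
table with one row per subject per time interval, carrying the event indicator
``d_ij``, the exposure ``tau_ij`` (months spent by subject *i* in interval *j*)
and the interval midpoint ``t_j``.  This module owns that expansion, the
interval grid and the covariate encoding that turns a cohort into the numeric
matrix the network consumes.

Conventions
-----------
* Intervals are left-open right-closed ``(a_{j-1}, a_j]``; an event exactly at
  a boundary belongs to the interval ending there (standard life-table rule).
* Follow-up beyond the last boundary ``a_J`` is administratively censored at
  ``a_J``.
* Categorical covariates are dummy-coded against a reference level; continuous
  covariates are min-max scaled to [0, 1]; time enters the network as
  ``t / a_J``.  All scaling metadata is recorded so that prediction-time inputs
  are transformed identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "SurvivalCohort",
    "IntervalGrid",
    "EncodingMap",
    "PersonPeriodTable",
    "build_interval_grid",
    "encode_covariates",
    "encode_new",
    "expand_person_period",
    "read_cohort_csv",
    "write_curves_csv",
    "read_curves_csv",
]


@dataclass(frozen=True)
class Covariate:
    """Descriptor for one covariate column.

    Parameters
    ----------
    name : str
        Column name in the subject table.
    kind : {"categorical", "continuous"}
    levels : tuple of str, optional
        Declared levels for a categorical covariate, in encoding order.
    reference : str, optional
        Reference level (absorbed into the intercept).  Defaults to the first
        declared level.
    """

    name: str
    kind: str = "categorical"
    levels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(
                    f"categorical covariate {self.name!r} needs >= 2 levels"
                )
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"covariate {self.name!r}: reference {ref!r} not among levels"
                )
            object.__setattr__(self, "reference", ref)
            object.__setattr__(self, "levels", tuple(self.levels))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": list(self.levels),
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Covariate":
        return cls(
            name=d["name"],
            kind=d.get("kind", "categorical"),
            levels=tuple(d.get("levels", ())),
            reference=d.get("reference"),
        )


@dataclass
class SurvivalCohort:
    """Right-censored cohort: one record per subject.

    ``data`` holds one row per subject with columns ``subject_id``, ``time``
    (months, > 0), ``event`` (0/1) and one column per schema covariate.
    Validation is strict: unknown categorical levels, nonpositive times and
    missing values are rejected, never repaired.
    """

    data: pd.DataFrame
    schema: tuple[Covariate, ...]
    treatment_name: str | None = None

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        df = self.data
        required = ["subject_id", "time", "event"] + [c.name for c in self.schema]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"cohort table is missing column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if df[required].isna().any().any():
            col = df[required].columns[df[required].isna().any()][0]
            row = int(df.index[df[col].isna()][0])
            raise ValueError(f"missing value in column {col!r} (row {row})")
        times = pd.to_numeric(df["time"], errors="raise").to_numpy(float)
        if not np.all(times > 0):
            row = int(np.flatnonzero(times <= 0)[0])
            raise ValueError(f"nonpositive follow-up time at row {row}")
        events = df["event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        for cov in self.schema:
            if cov.kind == "categorical":
                vals = df[cov.name].astype(str)
                bad = ~vals.isin(cov.levels)
                if bad.any():
                    v = vals[bad].iloc[0]
                    raise ValueError(
                        f"covariate {cov.name!r}: value {v!r} not among declared "
                        f"levels {list(cov.levels)}"
                    )
            else:
                pd.to_numeric(df[cov.name], errors="raise")
        if self.treatment_name is not None and self.treatment_name not in (
            c.name for c in self.schema
        ):
            raise ValueError(
                f"treatment covariate {self.treatment_name!r} not in schema"
            )
        self.data = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def covariate(self, name: str) -> Covariate:
        for c in self.schema:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, mask: np.ndarray) -> "SurvivalCohort":
        """Cohort restricted to the subjects where ``mask`` is True."""
        return SurvivalCohort(
            self.data.loc[np.asarray(mask, bool)].reset_index(drop=True),
            self.schema,
            self.treatment_name,
        )

    def resample(self, rng: np.random.Generator) -> "SurvivalCohort":
        """Bootstrap resample of subjects, with replacement."""
        idx = rng.integers(0, self.n, size=self.n)
        df = self.data.iloc[idx].reset_index(drop=True)
        df = df.assign(subject_id=np.arange(self.n))
        return SurvivalCohort(df, self.schema, self.treatment_name)


@dataclass(frozen=True)
class IntervalGrid:
    """Piecewise-exponential time partition.

    ``boundaries`` are ``a_0 = 0 < a_1 < ... < a_J`` in months; ``midpoints``
    are ``t_j = (a_{j-1} + a_j) / 2``.  The last boundary ``a_J`` doubles as
    the administrative censoring (truncation) time.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("grid needs at least one interval")
        if b[0] != 0.0:
            raise ValueError("grid must start at 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        b = self.boundaries
        return (b[:-1] + b[1:]) / 2.0

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def horizon(self) -> float:
        return float(self.boundaries[-1])

    def to_dict(self) -> dict:
        return {"boundaries": self.boundaries.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntervalGrid":
        return cls(np.asarray(d["boundaries"], float))


def build_interval_grid(width: float, horizon: float) -> IntervalGrid:
    """Regular grid of ``width``-month intervals up to ``horizon``.

    If ``horizon`` is not an integer multiple of ``width`` the last interval
    is shortened to end exactly at ``horizon``.
    """
    if width <= 0 or horizon <= 0:
        raise ValueError("width and horizon must be positive")
    n_full = int(np.floor(horizon / width + 1e-12))
    bounds = [i * width for i in range(n_full + 1)]
    if bounds[-1] < horizon - 1e-12 * horizon:
        bounds.append(horizon)
    else:
        bounds[-1] = horizon
    return IntervalGrid(np.asarray(bounds, float))


@dataclass(frozen=True)
class EncodingMap:
    """Deterministic map from schema covariates to numeric columns.

    ``columns`` lists encoded column labels in order.  For each categorical
    covariate there is one 0/1 column per non-reference level (label
    ``name=level``); each continuous covariate yields a single column scaled
    to [0, 1] using the recorded ``(min, max)``.
    """

    schema: tuple[Covariate, ...]
    columns: tuple[str, ...]
    continuous_range: dict  # name -> (min, max)

    @property
    def p(self) -> int:
        return len(self.columns)

    def to_dict(self) -> dict:
        return {
            "schema": [c.to_dict() for c in self.schema],
            "columns": list(self.columns),
            "continuous_range": {
                k: [float(v[0]), float(v[1])] for k, v in self.continuous_range.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingMap":
        return cls(
            schema=tuple(Covariate.from_dict(c) for c in d["schema"]),
            columns=tuple(d["columns"]),
            continuous_range={k: tuple(v) for k, v in d["continuous_range"].items()},
        )


def encode_covariates(cohort: SurvivalCohort) -> tuple[EncodingMap, np.ndarray]:
    """Encode a cohort's covariates into a numeric design matrix.

    Returns the encoding map (reusable for new data) and the N x p matrix.
    Column order is deterministic: schema order, then declared level order.
    """
    columns: list[str] = []
    cont_range: dict[str, tuple[float, float]] = {}
    for cov in cohort.schema:
        if cov.kind == "categorical":
            for lvl in cov.levels:
                if lvl != cov.reference:
                    columns.append(f"{cov.name}={lvl}")
        else:
            vals = cohort.data[cov.name].to_numpy(float)
            lo, hi = float(vals.min()), float(vals.max())
            cont_range[cov.name] = (lo, hi)
            columns.append(cov.name)
    emap = EncodingMap(cohort.schema, tuple(columns), cont_range)
    return emap, encode_new(emap, cohort.data)


def encode_new(emap: EncodingMap, df: pd.DataFrame) -> np.ndarray:
    """Apply a fitted encoding to new subject rows (strict on unseen levels)."""
    n = len(df)
    out = np.empty((n, emap.p), float)
    col = 0
    for cov in emap.schema:
        if cov.kind == "categorical":
            vals = df[cov.name].astype(str)
            bad = ~vals.isin(cov.levels)
            if bad.any():
                raise ValueError(
                    f"covariate {cov.name!r}: unseen level {vals[bad].iloc[0]!r}"
                )
            for lvl in cov.levels:
                if lvl != cov.reference:
                    out[:, col] = (vals == lvl).to_numpy(float)
                    col += 1
        else:
            lo, hi = emap.continuous_range[cov.name]
            vals = df[cov.name].to_numpy(float)
            span = hi - lo if hi > lo else 1.0
            out[:, col] = (vals - lo) / span
            col += 1
    return out


@dataclass
class PersonPeriodTable:
    """Expanded table: one row per (subject, interval) the subject was at risk.

    Arrays are flat and row-aligned: ``subject`` / ``interval`` are integer
    indices (interval counted from 1), ``d`` the event indicator, ``tau`` the
    exposure in months, ``t_mid`` the interval midpoint in months,
    ``t_scaled = t_mid / a_J`` the network's time input, and ``X`` the encoded
    covariate rows (repeated per interval).
    """

    subject: np.ndarray
    interval: np.ndarray
    d: np.ndarray
    tau: np.ndarray
    t_mid: np.ndarray
    t_scaled: np.ndarray
    X: np.ndarray
    encoding: EncodingMap
    grid: IntervalGrid
    n_subjects: int

    @property
    def n_rows(self) -> int:
        return self.d.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def rows_of(self, subject_idx: int) -> np.ndarray:
        return np.flatnonzero(self.subject == subject_idx)


def expand_person_period(
    cohort: SurvivalCohort, grid: IntervalGrid, encoding: EncodingMap | None = None
) -> PersonPeriodTable:
    """Materialize the likelihood's (d_ij, tau_ij, t_j) person-period rows.

    For subject *i* with follow-up ``time_i`` and event flag ``e_i``:
    ``J_i`` is the first interval whose right boundary reaches
    ``min(time_i, a_J)``; exposures are ``tau_ij = min(time_i, a_j) - a_{j-1}``;
    the event (if any, and if ``time_i <= a_J``) sits in interval ``J_i``.
    Subjects followed beyond ``a_J`` are administratively censored there.

    Pass a pre-fitted ``encoding`` (e.g. from the full cohort) when expanding
    a subset, so continuous-covariate scaling stays consistent.
    """
    if encoding is None:
        emap, Xsub = encode_covariates(cohort)
    else:
        emap, Xsub = encoding, encode_new(encoding, cohort.data)
    bounds = grid.boundaries
    aJ = grid.horizon
    mids = grid.midpoints
    times = cohort.times
    events = cohort.events
    if not np.all(times > 0):
        raise ValueError("all follow-up times must be positive")

    t_eff = np.minimum(times, aJ)
    # J_i = smallest j with t_eff <= a_j; right-closed intervals.
    J = np.searchsorted(bounds[1:], t_eff, side="left") + 1
    J = np.minimum(J, grid.n_intervals)

    n_rows = int(J.sum())
    subj = np.repeat(np.arange(cohort.n), J)
    interval = np.concatenate([np.arange(1, j + 1) for j in J])
    lower = bounds[interval - 1]
    upper = bounds[interval]
    tau = np.minimum(t_eff[subj], upper) - lower
    d = np.zeros(n_rows, int)
    last = np.cumsum(J) - 1
    d[last] = np.where(times <= aJ, events, 0)
    t_mid = mids[interval - 1]
    tab = PersonPeriodTable(
        subject=subj,
        interval=interval,
        d=d,
        tau=tau,
        t_mid=t_mid,
        t_scaled=t_mid / aJ,
        X=Xsub[subj],
        encoding=emap,
        grid=grid,
        n_subjects=cohort.n,
    )
    assert np.all(tab.tau > 0)
    return tab


# ---------------------------------------------------------------------------
# I/O


def read_cohort_csv(path, schema_config: Mapping | str) -> SurvivalCohort:
    """Load a cohort from a delimited file plus a schema description.

    ``schema_config`` is a mapping (or path to a JSON file) with keys
    ``time`` / ``event`` / optional ``subject_id`` column names, a
    ``covariates`` list of descriptors and an optional ``treatment`` name.
    """
    if isinstance(schema_config, (str, bytes)) or hasattr(schema_config, "read_text"):
        with open(schema_config) as fh:
            schema_config = json.load(fh)
    df = pd.read_csv(path)
    time_col = schema_config.get("time", "time")
    event_col = schema_config.get("event", "event")
    id_col = schema_config.get("subject_id")
    schema = tuple(Covariate.from_dict(c) for c in schema_config["covariates"])
    for col in [time_col, event_col] + [c.name for c in schema]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = pd.DataFrame(
        {
            "subject_id": df[id_col] if id_col else np.arange(len(df)),
            "time": pd.to_numeric(df[time_col]),
            "event": pd.to_numeric(df[event_col]).astype(int),
        }
    )
    for c in schema:
        out[c.name] = df[c.name].astype(str) if c.kind == "categorical" else df[c.name]
    return SurvivalCohort(out, schema, schema_config.get("treatment"))


def write_curves_csv(bands: Iterable, path) -> None:
    """Write curve bands as a long-format table.

    Columns: ``curve_id, t, estimate, lower, upper`` (lower/upper empty when
    the band carries only a point estimate).  Accepts any iterable of objects
    with ``label``, ``t_grid``, ``estimate`` and optional ``lower``/``upper``.
    """
    frames = []
    for band in bands:
        lower = getattr(band, "lower", None)
        upper = getattr(band, "upper", None)
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": band.label,
                    "t": np.asarray(band.t_grid, float),
                    "estimate": np.asarray(band.estimate, float),
                    "lower": np.nan if lower is None else np.asarray(lower, float),
                    "upper": np.nan if upper is None else np.asarray(upper, float),
                }
            )
        )
    # default float formatting is shortest-exact repr: values round-trip
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> pd.DataFrame:
    """Read back a long-format curve table written by :func:`write_curves_csv`."""
    df = pd.read_csv(path)
    for col in ("curve_id", "t", "estimate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
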