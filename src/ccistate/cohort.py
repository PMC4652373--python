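"""Domain types and discretization of follow-up into person-period (long) format.

A subject's follow-up is a continuous-time record: entry, dated irreversible
increments of the Charlson Comorbidity Index (CCI, weights 1/2/3/6), optional
treatment-procedure dates, and a terminal death or censoring date.  The
transition regressions consume a discretized version of this record: one row
per subject per started time step (default four weeks), with age, CCI and the
three "clock" categories updated at each step.

Conventions
-----------
* Steps are half-open intervals ``[entry + k*step, entry + (k+1)*step)``; an
  event on day ``d`` (offset from entry) belongs to step ``floor(d / step)``.
* A subject contributes one row per started interval up to and including the
  interval containing the end date.
* Multiple CCI events inside one interval are pooled (weights summed) into a
  single change.
* Death takes precedence over change: CCI events falling in the terminal
  interval of a subject who died are discarded (and counted in the
  :class:`PoolingReport`), so a row never carries both outcomes.
* A clock (time since CCI change / RP / RT) takes the value ``k - j`` at step
  ``k`` for a qualifying event in step ``j < k``; an event in the current
  interval does not qualify, so the smallest clock value is 1.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "CCI_WEIGHTS",
    "CLOCK_LABELS",
    "CCI_LABELS",
    "StepConfig",
    "SubjectRecord",
    "PersonStep",
    "Cohort",
    "PoolingReport",
    "categorize_clock",
    "cci_category",
    "discretize_followup",
]

TREATMENTS = ("AS", "RP", "RT")
CCI_WEIGHTS = (1, 2, 3, 6)

#: Clock categories: time since qualifying event, in steps.
CLOCK_LABELS = ("1", "2-3", "4-6", ">6/none")

#: CCI level categories used by the change/size regressions.
CCI_LABELS = ("0", "1", "2", "3", "4+")

_DAYS_PER_YEAR = 365.25


@dataclasses.dataclass(frozen=True)
class StepConfig:
    """Discretization settings.

    Parameters
    ----------
    step_days:
        Length of one time step in days.  Default 28 (four weeks).
    category_breaks:
        Upper bounds (inclusive) of the first three clock categories, in
        steps: ``(1, 3, 6)`` yields the categories 1, 2-3, 4-6, >6/none.
    """

    step_days: int = 28
    category_breaks: tuple[int, int, int] = (1, 3, 6)

    def __post_init__(self) -> None:
        if self.step_days < 1:
            raise ValueError("step_days must be >= 1 day")
        b = self.category_breaks
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise ValueError("category_breaks must be three increasing positive ints")


def categorize_clock(steps_since_event: Optional[int], config: StepConfig = StepConfig()) -> str:
    """Categorize time since a qualifying event (in steps) into a clock label.

    ``None`` means "no previous event" and maps to the open top category,
    which also absorbs all values above the last break.
    """
    if steps_since_event is None:
        return CLOCK_LABELS[3]
    s = int(steps_since_event)
    if s < 1:
        raise ValueError(
            f"steps_since_event must be >= 1 or None, got {steps_since_event}; "
            "an event in the current interval sets the next interval's clock to 1"
        )
    b1, b2, b3 = config.category_breaks
    if s <= b1:
        return CLOCK_LABELS[0]
    if s <= b2:
        return CLOCK_LABELS[1]
    if s <= b3:
        return CLOCK_LABELS[2]
    return CLOCK_LABELS[3]


def cci_category(cci: int) -> str:
    """Map a CCI value to the 0/1/2/3/4+ category used as a regressor."""
    c = int(cci)
    if c < 0:
        raise ValueError(f"CCI must be non-negative, got {cci}")
    return CCI_LABELS[min(c, 4)]


def _as_date(x: Union[str, datetime.date, None]) -> Optional[datetime.date]:
    if x is None:
        return None
    if isinstance(x, datetime.datetime):
        return x.date()
    if isinstance(x, datetime.date):
        return x
    return datetime.date.fromisoformat(str(x))


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One subject's raw (continuous-time) follow-up record."""

    subject_id: str
    treatment: str
    entry_date: datetime.date
    age_at_entry: float
    baseline_cci: int
    cci_events: tuple[tuple[datetime.date, int], ...] = ()
    rp_date: Optional[datetime.date] = None
    rt_date: Optional[datetime.date] = None
    end_date: Optional[datetime.date] = None
    end_status: str = "censored"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_date", _as_date(self.entry_date))
        object.__setattr__(self, "end_date", _as_date(self.end_date))
        object.__setattr__(self, "rp_date", _as_date(self.rp_date))
        object.__setattr__(self, "rt_date", _as_date(self.rt_date))
        object.__setattr__(
            self,
            "cci_events",
            tuple(sorted((_as_date(d), int(w)) for d, w in self.cci_events)),
        )
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r} for subject {self.subject_id}")
        if self.end_status not in ("died", "censored"):
            raise ValueError(f"unknown end_status {self.end_status!r}")
        if self.end_date is None or self.end_date < self.entry_date:
            raise ValueError(f"end_date must be >= entry_date for subject {self.subject_id}")
        if self.baseline_cci < 0:
            raise ValueError("baseline_cci must be >= 0")
        for d, w in self.cci_events:
            if w not in CCI_WEIGHTS:
                raise ValueError(f"CCI event weight {w} not in {CCI_WEIGHTS}")
            if not (self.entry_date <= d <= self.end_date):
                raise ValueError(
                    f"event date {d} outside follow-up window for subject {self.subject_id}"
                )


@dataclasses.dataclass(frozen=True)
class PersonStep:
    """One row of the discretized long-format dataset."""

    subject_id: str
    step_index: int
    age: float
    cci: int
    cci_cat: str
    t_since_change_cat: str
    t_since_rp_cat: str
    t_since_rt_cat: str
    treatment: str
    died: bool
    changed: bool
    change_size: Optional[int] = None
    transformed_size: Optional[int] = None
    ge6: Optional[bool] = None


# Column order of the long-format DataFrame (mirrors PersonStep fields).
STEP_COLUMNS = [f.name for f in dataclasses.fields(PersonStep)]


@dataclasses.dataclass
class Cohort:
    """Tabular container for a cohort: one subjects table, one events table.

    This is the bulk representation used throughout the package; it is
    interconvertible with a list of :class:`SubjectRecord` and with the
    two-CSV external interface.
    """

    subjects: pd.DataFrame
    events: pd.DataFrame

    SUBJECT_COLUMNS = [
        "subject_id", "treatment", "entry_date", "age_at_entry", "baseline_cci",
        "rp_date", "rt_date", "end_date", "end_status",
    ]
    EVENT_COLUMNS = ["subject_id", "event_date", "weight"]

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        for c in ("entry_date", "end_date", "rp_date", "rt_date"):
            self.subjects[c] = pd.to_datetime(self.subjects[c]).astype("datetime64[ns]")
        self.events = self.events.reset_index(drop=True)
        self.events["event_date"] = pd.to_datetime(self.events["event_date"]).astype(
            "datetime64[ns]"
        )
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord]) -> "Cohort":
        records = list(records)
        subs = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "treatment": [r.treatment for r in records],
                "entry_date": [r.entry_date for r in records],
                "age_at_entry": [r.age_at_entry for r in records],
                "baseline_cci": [r.baseline_cci for r in records],
                "rp_date": [r.rp_date for r in records],
                "rt_date": [r.rt_date for r in records],
                "end_date": [r.end_date for r in records],
                "end_status": [r.end_status for r in records],
            }
        )
        ev_rows = [
            (r.subject_id, d, w) for r in records for d, w in r.cci_events
        ]
        events = pd.DataFrame(ev_rows, columns=cls.EVENT_COLUMNS)
        return cls(subs, events)

    def to_records(self) -> list[SubjectRecord]:
        ev_by_subject: dict[str, list[tuple[datetime.date, int]]] = {}
        for sid, d, w in self.events.itertuples(index=False):
            ev_by_subject.setdefault(sid, []).append((d.date(), int(w)))
        out = []
        for row in self.subjects.itertuples(index=False):
            out.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    treatment=row.treatment,
                    entry_date=row.entry_date.date(),
                    age_at_entry=float(row.age_at_entry),
                    baseline_cci=int(row.baseline_cci),
                    cci_events=tuple(ev_by_subject.get(row.subject_id, ())),
                    rp_date=None if pd.isna(row.rp_date) else row.rp_date.date(),
                    rt_date=None if pd.isna(row.rt_date) else row.rt_date.date(),
                    end_date=row.end_date.date(),
                    end_status=row.end_status,
                )
            )
        return out

    @classmethod
    def from_csv(cls, subjects_path, events_path) -> "Cohort":
        subs = pd.read_csv(subjects_path, dtype={"subject_id": str})
        events = pd.read_csv(events_path, dtype={"subject_id": str})
        missing = [c for c in cls.SUBJECT_COLUMNS if c not in subs.columns]
        if missing:
            raise ValueError(f"subjects CSV missing columns: {missing}")
        missing = [c for c in cls.EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise ValueError(f"events CSV missing columns: {missing}")
        return cls(subs[cls.SUBJECT_COLUMNS], events[cls.EVENT_COLUMNS])

    def to_csv(self, subjects_path, events_path) -> None:
        subs = self.subjects.copy()
        for c in ("entry_date", "end_date", "rp_date", "rt_date"):
            subs[c] = subs[c].dt.strftime("%Y-%m-%d")
        subs.to_csv(subjects_path, index=False)
        ev = self.events.copy()
        ev["event_date"] = ev["event_date"].dt.strftime("%Y-%m-%d")
        ev.to_csv(events_path, index=False)


@dataclasses.dataclass
class PoolingReport:
    """Diagnostics of the discretization: pooling, discards, rejections."""

    n_subjects: int = 0
    n_rejected: int = 0
    rejected: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    n_rows: int = 0
    n_events_input: int = 0
    n_events_discarded_death_interval: int = 0
    n_events_kept: int = 0
    n_changes: int = 0
    n_events_pooled: int = 0

    @property
    def frac_events_pooled(self) -> float:
        """Fraction of kept daily-resolution events sharing an interval with
        at least one other event (the information cost of the step grid)."""
        if self.n_events_kept == 0:
            return 0.0
        return self.n_events_pooled / self.n_events_kept

    def summary(self) -> str:
        lines = [
            f"subjects: {self.n_subjects} (rejected: {self.n_rejected})",
            f"person-step rows: {self.n_rows}",
            f"events: {self.n_events_input} input, "
            f"{self.n_events_discarded_death_interval} discarded (death interval), "
            f"{self.n_events_kept} kept",
            f"pooled changes: {self.n_changes} intervals with >=1 change; "
            f"{self.n_events_pooled} events pooled with another "
            f"({100 * self.frac_events_pooled:.2f}% of kept events)",
        ]
        for sid, reason in self.rejected[:20]:
            lines.append(f"rejected {sid}: {reason}")
        return "\n".join(lines)


def _clock_codes(since: np.ndarray, config: StepConfig) -> np.ndarray:
    """Vectorized clock categorisation.  ``since`` uses values > breaks[2]
    (or any large sentinel) for 'none'; returns int8 codes into CLOCK_LABELS."""
    b = config.category_breaks
    return np.digitize(since, [b[0] + 1, b[1] + 1, b[2] + 1]).astype(np.int8)


def discretize_followup(
    cohort: Union[Cohort, Sequence[SubjectRecord]],
    config: StepConfig = StepConfig(),
) -> tuple[pd.DataFrame, PoolingReport]:
    """Convert continuous-time records into the long-format person-period table.

    Returns a DataFrame with one row per subject per started step (columns as
    in :class:`PersonStep`; categorical columns are pandas Categoricals) and a
    :class:`PoolingReport`.  Subjects whose records are invalid (unknown
    treatment, event outside the follow-up window) are rejected with a
    diagnostic rather than aborting the whole run.
    """
    if not isinstance(cohort, Cohort):
        cohort = Cohort.from_records(cohort)
    subs = cohort.subjects
    events = cohort.events
    report = PoolingReport(n_subjects=len(subs), n_events_input=len(events))
    step_days = config.step_days

    # --- validation / rejection -------------------------------------------
    entry = subs["entry_date"].to_numpy("datetime64[D]")
    end = subs["end_date"].to_numpy("datetime64[D]")
    ok = np.ones(len(subs), dtype=bool)
    reasons: dict[int, str] = {}
    bad = ~subs["treatment"].isin(TREATMENTS).to_numpy()
    for i in np.flatnonzero(bad):
        reasons[i] = f"unknown treatment {subs['treatment'].iloc[i]!r}"
    ok &= ~bad
    bad = end < entry
    for i in np.flatnonzero(bad & ok):
        reasons[i] = "end_date before entry_date"
    ok &= ~bad

    sid_to_idx = pd.Series(np.arange(len(subs)), index=subs["subject_id"])
    if len(events):
        ev_sub = sid_to_idx.reindex(events["subject_id"]).to_numpy()
        if np.isnan(ev_sub).any():
            unknown = events["subject_id"][np.isnan(ev_sub)].unique()
            raise ValueError(f"events reference unknown subject ids: {list(unknown)[:5]}")
        ev_sub = ev_sub.astype(np.int64)
        ev_day = (
            events["event_date"].to_numpy("datetime64[D]") - entry[ev_sub]
        ).astype(np.int64)
        ev_w = events["weight"].to_numpy(np.int64)
        bad_w = ~np.isin(ev_w, CCI_WEIGHTS)
        for i in np.unique(ev_sub[bad_w]):
            reasons.setdefault(i, "event weight not in {1,2,3,6}")
            ok[i] = False
        span = (end - entry).astype(np.int64)
        out_of_window = (ev_day < 0) | (ev_day > span[ev_sub])
        for i in np.unique(ev_sub[out_of_window]):
            reasons.setdefault(i, "event date outside follow-up window")
            ok[i] = False
    else:
        ev_sub = np.empty(0, dtype=np.int64)
        ev_day = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0, dtype=np.int64)

    report.rejected = [(subs["subject_id"].iloc[i], r) for i, r in sorted(reasons.items())]
    report.n_rejected = len(report.rejected)
    if report.n_rejected:
        keep_mask = ok
        old_to_new = np.cumsum(keep_mask) - 1
        ev_keep = keep_mask[ev_sub]
        ev_sub = old_to_new[ev_sub[ev_keep]]
        ev_day, ev_w = ev_day[ev_keep], ev_w[ev_keep]
        subs = subs[keep_mask].reset_index(drop=True)
        entry, end = entry[keep_mask], end[keep_mask]

    n_sub = len(subs)
    if n_sub == 0:
        empty = pd.DataFrame(columns=STEP_COLUMNS)
        return empty, report

    # --- row skeleton ------------------------------------------------------
    span_days = (end - entry).astype(np.int64)
    n_steps = span_days // step_days + 1
    row_offset = np.concatenate([[0], np.cumsum(n_steps)])
    n_rows = int(row_offset[-1])
    sub_idx = np.repeat(np.arange(n_sub), n_steps)
    step = np.arange(n_rows) - row_offset[sub_idx]
    died_sub = (subs["end_status"] == "died").to_numpy()
    is_terminal = step == (n_steps[sub_idx] - 1)
    died = is_terminal & died_sub[sub_idx]

    # --- events: discard death-interval events, pool the rest --------------
    ev_step = ev_day // step_days
    terminal_step = n_steps - 1
    discard = died_sub[ev_sub] & (ev_step == terminal_step[ev_sub])
    report.n_events_discarded_death_interval = int(discard.sum())
    ev_sub, ev_step, ev_w = ev_sub[~discard], ev_step[~discard], ev_w[~discard]
    report.n_events_kept = len(ev_w)

    change_size_by_row = np.zeros(n_rows, dtype=np.int64)
    if len(ev_w):
        ev_row = row_offset[ev_sub] + ev_step
        np.add.at(change_size_by_row, ev_row, ev_w)
        counts = np.zeros(n_rows, dtype=np.int64)
        np.add.at(counts, ev_row, 1)
        report.n_events_pooled = int(counts[ev_row][counts[ev_row] >= 2].shape[0])
    report.n_changes = int((change_size_by_row > 0).sum())

    # --- per-row state -----------------------------------------------------
    incl = np.cumsum(change_size_by_row)
    excl = incl - change_size_by_row
    cci = subs["baseline_cci"].to_numpy(np.int64)[sub_idx] + (
        excl - excl[row_offset[:-1]][sub_idx]
    )
    age = subs["age_at_entry"].to_numpy(float)[sub_idx] + step * (step_days / _DAYS_PER_YEAR)
    changed = change_size_by_row > 0
    change_size = change_size_by_row

    # time since last change (in steps): running max of change-step within subject
    big = int(n_steps.max()) + 2
    marker = np.where(changed, step + sub_idx * big, -1)
    runmax = np.maximum.accumulate(marker)
    prev = np.empty(n_rows, dtype=np.int64)
    prev[1:] = runmax[:-1]
    prev[row_offset[:-1]] = -1
    last_change_step = prev - sub_idx * big
    since_change = step - last_change_step
    none_val = config.category_breaks[2] + 1  # any value beyond the last break
    since_change = np.where(last_change_step >= 0, since_change, none_val + 1)

    def _since_proc(col: str) -> np.ndarray:
        dates = subs[col].to_numpy("datetime64[D]")
        has = ~pd.isna(subs[col]).to_numpy()
        proc_step = np.zeros(n_sub, dtype=np.int64)
        d = (dates[has] - entry[has]).astype(np.int64)
        proc_step_has = np.floor_divide(d, step_days)
        proc_step[has] = proc_step_has
        since = step - proc_step[sub_idx]
        return np.where(has[sub_idx] & (since >= 1), since, none_val + 1)

    since_rp = _since_proc("rp_date")
    since_rt = _since_proc("rt_date")

    clock_cat = pd.CategoricalDtype(CLOCK_LABELS)
    cci_cat_dtype = pd.CategoricalDtype(CCI_LABELS)
    df = pd.DataFrame(
        {
            "subject_id": pd.Categorical.from_codes(
                sub_idx, categories=subs["subject_id"].astype(str)
            ),
            "step_index": step.astype(np.int32),
            "age": age,
            "cci": cci.astype(np.int32),
            "cci_cat": pd.Categorical.from_codes(
                np.minimum(cci, 4).astype(np.int8), dtype=cci_cat_dtype
            ),
            "t_since_change_cat": pd.Categorical.from_codes(
                _clock_codes(since_change, config), dtype=clock_cat
            ),
            "t_since_rp_cat": pd.Categorical.from_codes(
                _clock_codes(since_rp, config), dtype=clock_cat
            ),
            "t_since_rt_cat": pd.Categorical.from_codes(
                _clock_codes(since_rt, config), dtype=clock_cat
            ),
            "treatment": pd.Categorical(subs["treatment"], categories=TREATMENTS)[
                sub_idx
            ],
            "died": died,
            "changed": changed,
            "change_size": pd.arrays.IntegerArray(
                change_size.astype(np.int64), mask=~changed
            ),
        }
    )
    ge6 = change_size >= 6
    transformed = change_size - np.where(ge6, 6, 1)
    df["transformed_size"] = pd.arrays.IntegerArray(
        np.maximum(transformed, 0).astype(np.int64), mask=~changed
    )
    df["ge6"] = pd.arrays.BooleanArray(ge6, mask=~changed)
    report.n_rows = n_rows

    # output invariant: CCI non-decreasing within every subject
    d_cci = np.diff(cci)
    same_subject = np.diff(sub_idx) == 0
    if np.any(same_subject & (d_cci < 0)):
        raise AssertionError("internal error: CCI decreased within a subject")
    return df, report


def iter_person_steps(df: pd.DataFrame) -> Iterator[PersonStep]:
    """View long-format rows as :class:`PersonStep` objects (small data only)."""
    for row in df.itertuples(index=False):
        changed = bool(row.changed)
        yield PersonStep(
            subject_id=str(row.subject_id),
            step_index=int(row.step_index),
            age=float(row.age),
            cci=int(row.cci),
            cci_cat=str(row.cci_cat),
            t_since_change_cat=str(row.t_since_change_cat),
            t_since_rp_cat=str(row.t_since_rp_cat),
            t_since_rt_cat=str(row.t_since_rt_cat),
            treatment=str(row.treatment),
            died=bool(row.died),
            changed=changed,
            change_size=int(row.change_size) if changed else None,
            transformed_size=int(row.transformed_size) if changed else None,
            ge6=bool(row.ge6) if changed else None,
        )
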