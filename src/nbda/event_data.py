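"""Study data: event logs, covariates, presence schedules and derived tables.

The unit of observation is a single performance of a target behavior
(e.g. moss-sponging ``"M"`` or leaf-sponge re-use ``"RU1"``) by one
individual in front of a recorded audience.  From a time-sorted event log we
derive, per individual and behavior, the *acquisition*: the first recorded
performance, with its time and rank in the diffusion.  Individuals that
never perform are right-censored.  Covariates (individual-level variables,
ILVs) are age in years, sex coded 0/1 for female/male, and tenure (years
spent in the community); an exposure score (rate of ordinary interactions
with the study site) can be derived from the same event log.

All timestamps are continuous "study-clock" values (e.g. minutes since the
first observation session), strictly orderable; per-day wall-clock times are
converted upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "ObservationEvent",
    "AcquisitionRecord",
    "PresenceInterval",
    "DiffusionDataset",
    "read_dataset",
    "write_dataset",
    "derive_acquisitions",
    "compute_exposure",
    "standardize_covariates",
]

CRITERIA = ("standard", "strict")


class DatasetError(ValueError):
    """Raised when input data violate a dataset invariant."""


@dataclass(frozen=True)
class Individual:
    """One group member with its individual-level variables."""

    id: str
    age: float
    sex: int
    tenure: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise DatasetError(f"individual {self.id!r}: age must be finite and >= 0")
        if self.sex not in (0, 1):
            raise DatasetError(f"individual {self.id!r}: sex must be 0 (female) or 1 (male)")
        if not np.isfinite(self.tenure) or self.tenure < 0:
            raise DatasetError(f"individual {self.id!r}: tenure must be finite and >= 0")


@dataclass(frozen=True)
class ObservationEvent:
    """One performance of a target behavior and the audience that saw it.

    ``criterion`` records under which audience definition the observer list
    was coded: ``"standard"`` (within 1 m with unobstructed view) or
    ``"strict"`` (additionally judged to be actively watching).
    """

    time: float
    behavior: str
    performer: str
    observers: frozenset[str]
    criterion: str = "standard"
    order_hint: int | None = None

    def __post_init__(self) -> None:
        if self.performer in self.observers:
            raise DatasetError(
                f"event at t={self.time}: performer {self.performer!r} listed among observers"
            )
        if self.criterion not in CRITERIA:
            raise DatasetError(f"event at t={self.time}: unknown criterion {self.criterion!r}")
        if not np.isfinite(self.time):
            raise DatasetError(f"event time {self.time!r} is not finite")


@dataclass(frozen=True)
class AcquisitionRecord:
    """First performance (acquisition) of a behavior, or censoring.

    ``order_index`` ranks acquirers within a behavior, starting at 1 for the
    innovator; censored individuals carry neither time nor order.
    """

    individual: str
    behavior: str
    acquired: bool
    acquisition_time: float | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.acquired and (self.acquisition_time is None or self.order_index is None):
            raise DatasetError(
                f"{self.individual}/{self.behavior}: acquired record needs time and order"
            )
        if not self.acquired and (self.acquisition_time is not None or self.order_index is not None):
            raise DatasetError(
                f"{self.individual}/{self.behavior}: censored record must have no time/order"
            )


@dataclass(frozen=True)
class PresenceInterval:
    """Half-open study-clock interval [start, end) during which the group was on site."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise DatasetError(f"presence interval [{self.start}, {self.end}) has start >= end")


@dataclass
class DiffusionDataset:
    """A validated bundle of individuals, events, acquisitions and presence.

    Construction runs full cross-validation: every referenced id exists,
    every performer has an acquisition record no later than its performance,
    and for each behavior the innovator (order 1) has seen no performance of
    that behavior before acquiring it.
    """

    individuals: list[Individual]
    events: list[ObservationEvent]
    acquisitions: list[AcquisitionRecord]
    presence: list[PresenceInterval] = field(default_factory=list)
    behaviors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time, e.performer, e.behavior))
        self.presence = _normalize_presence(self.presence)
        if not self.behaviors:
            self.behaviors = tuple(sorted({a.behavior for a in self.acquisitions}))
        self._validate()

    # -- lookups -------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def individual(self, id_: str) -> Individual:
        return self._by_id[id_]

    def acquisition(self, individual: str, behavior: str) -> AcquisitionRecord:
        return self._acq_by_key[(individual, behavior)]

    def acquisition_time(self, individual: str, behavior: str) -> float:
        """Acquisition time, or +inf for censored individuals."""
        rec = self._acq_by_key.get((individual, behavior))
        if rec is None or not rec.acquired:
            return np.inf
        return rec.acquisition_time

    def ordered_acquisitions(self, behavior: str) -> list[AcquisitionRecord]:
        recs = [a for a in self.acquisitions if a.behavior == behavior and a.acquired]
        return sorted(recs, key=lambda a: a.order_index)

    def events_of(self, behavior: str) -> list[ObservationEvent]:
        return [e for e in self.events if e.behavior == behavior]

    def ilv_frame(self) -> pd.DataFrame:
        """Covariate table indexed by individual id (columns age, sex, tenure)."""
        return pd.DataFrame(
            {"age": [i.age for i in self.individuals],
             "sex": [i.sex for i in self.individuals],
             "tenure": [i.tenure for i in self.individuals]},
            index=pd.Index(self.ids, name="id"),
        )

    @property
    def total_onsite_time(self) -> float:
        return sum(p.end - p.start for p in self.presence)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate individual ids: {dupes}")
        self._by_id = {ind.id: ind for ind in self.individuals}
        known = set(ids)

        for ev in self.events:
            missing = ({ev.performer} | ev.observers) - known
            if missing:
                raise DatasetError(
                    f"event at t={ev.time} references unknown ids {sorted(missing)}"
                )

        keys = [(a.individual, a.behavior) for a in self.acquisitions]
        if len(set(keys)) != len(keys):
            raise DatasetError("duplicate (individual, behavior) acquisition records")
        self._acq_by_key = {(a.individual, a.behavior): a for a in self.acquisitions}
        unknown = {a.individual for a in self.acquisitions} - known
        if unknown:
            raise DatasetError(f"acquisition records reference unknown ids {sorted(unknown)}")

        for b in self.behaviors:
            acq = self.ordered_acquisitions(b)
            orders = [a.order_index for a in acq]
            if orders != list(range(1, len(acq) + 1)):
                raise DatasetError(f"behavior {b!r}: order indices are not 1..n ({orders})")
            times = [a.acquisition_time for a in acq]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise DatasetError(f"behavior {b!r}: order indices disagree with times")

        # every performance must postdate (or coincide with) the performer's acquisition
        for ev in self.events:
            if ev.behavior not in self.behaviors:
                continue
            t_acq = self.acquisition_time(ev.performer, ev.behavior)
            if not np.isfinite(t_acq) or ev.time < t_acq:
                raise DatasetError(
                    f"{ev.performer} performs {ev.behavior} at t={ev.time} "
                    f"before/without an acquisition record"
                )

        # innovator property: the first acquirer observed no prior performance
        for b in self.behaviors:
            acq = self.ordered_acquisitions(b)
            if not acq:
                continue
            innovator = acq[0]
            offending = [
                ev for ev in self.events_of(b)
                if innovator.individual in ev.observers and ev.time < innovator.acquisition_time
            ]
            if offending:
                raise DatasetError(
                    f"behavior {b!r}: innovator {innovator.individual} observed "
                    f"{len(offending)} performance(s) before acquiring (e.g. at "
                    f"t={offending[0].time})"
                )


def _normalize_presence(presence: Iterable[PresenceInterval]) -> list[PresenceInterval]:
    """Sort and merge overlapping/abutting intervals."""
    ivs = sorted(presence, key=lambda p: p.start)
    merged: list[PresenceInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            merged[-1] = PresenceInterval(merged[-1].start, max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# derivations


def derive_acquisitions(
    events: Sequence[ObservationEvent],
    individuals: Iterable[str] | None = None,
    behaviors: Iterable[str] | None = None,
) -> list[AcquisitionRecord]:
    """Derive acquisition records: first performance per individual per behavior.

    Individuals that never perform a behavior are censored for it.  Exact
    ties in first-performance time are refused unless every tied event
    carries a distinct ``order_hint`` (the field data had distinct times;
    guessing an order would silently bias the order-based likelihood).
    """
    behaviors = sorted(behaviors) if behaviors is not None else sorted({e.behavior for e in events})
    if individuals is None:
        pool: set[str] = set()
        for e in events:
            pool.add(e.performer)
            pool.update(e.observers)
        individuals = pool
    individuals = sorted(individuals)

    records: list[AcquisitionRecord] = []
    for b in behaviors:
        first: dict[str, ObservationEvent] = {}
        for ev in sorted((e for e in events if e.behavior == b), key=lambda e: e.time):
            if ev.performer not in first:
                first[ev.performer] = ev
        # rank by time, using order_hint only to break exact ties
        def _key(item: tuple[str, ObservationEvent]):
            return item[1].time

        ranked = sorted(first.items(), key=_key)
        for (id1, e1), (id2, e2) in zip(ranked, ranked[1:]):
            if e1.time == e2.time:
                if e1.order_hint is None or e2.order_hint is None or e1.order_hint == e2.order_hint:
                    raise DatasetError(
                        f"behavior {b!r}: simultaneous first performances by {id1!r} and "
                        f"{id2!r} at t={e1.time}; supply distinct order_hint values"
                    )
        ranked = sorted(first.items(), key=lambda it: (it[1].time, it[1].order_hint or 0))
        order = {id_: k + 1 for k, (id_, _) in enumerate(ranked)}
        for id_ in individuals:
            if id_ in first:
                records.append(
                    AcquisitionRecord(id_, b, True, first[id_].time, order[id_])
                )
            else:
                records.append(AcquisitionRecord(id_, b, False))
    return records


def _onsite_elapsed(presence: Sequence[PresenceInterval], t: float) -> float:
    """Cumulative on-site time up to study-clock time t (0 before the first interval)."""
    if not presence:
        return t
    total = 0.0
    for iv in presence:
        if t <= iv.start:
            break
        total += min(t, iv.end) - iv.start
    return total


def compute_exposure(
    dataset: DiffusionDataset,
    behavior: str,
    baseline_behavior: str = "LS",
) -> dict[str, float]:
    """Exposure score: rate of ordinary site interactions per unit on-site time.

    Interactions are event rows whose behavior equals ``baseline_behavior``
    (bouts of the group's routine technique, e.g. normal leaf-sponging).
    For individuals that never acquired ``behavior`` the rate is total
    interactions over total observation time; for acquirers both numerator
    and denominator are truncated at their acquisition time of ``behavior``,
    since later exposure cannot have caused the acquisition.
    """
    if behavior not in dataset.behaviors:
        raise DatasetError(f"unknown behavior {behavior!r}")
    total_time = dataset.total_onsite_time
    if total_time <= 0:
        raise DatasetError("total observation time must be > 0 to compute exposure rates")
    interactions = [e for e in dataset.events if e.behavior == baseline_behavior]

    rates: dict[str, float] = {}
    for ind in dataset.individuals:
        t_acq = dataset.acquisition_time(ind.id, behavior)
        if np.isfinite(t_acq):
            denom = _onsite_elapsed(dataset.presence, t_acq)
            if denom <= 0:
                raise DatasetError(
                    f"{ind.id}: acquisition of {behavior!r} at zero elapsed observation "
                    f"time; exposure rate undefined"
                )
            n = sum(1 for e in interactions if e.performer == ind.id and e.time < t_acq)
        else:
            denom = total_time
            n = sum(1 for e in interactions if e.performer == ind.id)
        rates[ind.id] = n / denom
    return rates


def standardize_covariates(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale each column to mean 0, SD 1 (sample SD, ddof=1).

    Returns the transformed table and a map ``column -> (mean, sd)`` so that
    effects per standard deviation can be reported back on the raw scale.
    """
    if len(table) < 2:
        raise DatasetError("need at least 2 individuals to standardize covariates")
    params: dict[str, tuple[float, float]] = {}
    out = table.copy().astype(float)
    for col in table.columns:
        mu = float(table[col].mean())
        sd = float(table[col].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise DatasetError(f"covariate {col!r} has zero variance; cannot standardize")
        out[col] = (table[col] - mu) / sd
        params[col] = (mu, sd)
    return out, params


# ---------------------------------------------------------------------------
# I/O


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing required columns {sorted(missing)}")
    return df


def read_dataset(
    event_path: str | Path,
    ilv_path: str | Path,
    presence_path: str | Path | None = None,
    criterion: str = "standard",
    behaviors: Sequence[str] | None = None,
    baseline_behavior: str | None = "LS",
) -> DiffusionDataset:
    """Read and validate a dataset from CSV files.

    ``events.csv`` needs columns ``time,behavior,performer,observers,criterion``
    (observers a ``;``-separated id list, empty allowed; optional
    ``order_hint``); ``ilv.csv`` needs ``id,age,sex,tenure``; ``presence.csv``
    needs ``start,end``.  Events are filtered to rows coded under the
    requested audience ``criterion``.  Acquisitions are derived from the
    filtered log; target ``behaviors`` default to every label present except
    ``baseline_behavior``, the label of the routine interaction stream used
    for exposure scores (rows with that label stay in the event list but are
    not treated as a diffusing behavior).
    """
    if criterion not in CRITERIA:
        raise DatasetError(f"unknown audience criterion {criterion!r}")

    ilv_df = _read_csv(ilv_path, ["id", "age", "sex", "tenure"])
    individuals = []
    for row in ilv_df.itertuples(index=True):
        try:
            individuals.append(
                Individual(row.id, float(row.age), int(row.sex), float(row.tenure))
            )
        except (ValueError, DatasetError) as exc:
            raise DatasetError(f"{ilv_path} line {row.Index + 2}: {exc}") from None
    known = {ind.id for ind in individuals}

    ev_df = _read_csv(event_path, ["time", "behavior", "performer", "observers", "criterion"])
    events: list[ObservationEvent] = []
    for row in ev_df.itertuples(index=True):
        line = row.Index + 2  # header + 1-based
        if row.criterion != criterion:
            continue
        try:
            t = float(row.time)
        except ValueError:
            raise DatasetError(f"{event_path} line {line}: bad time {row.time!r}") from None
        observers = frozenset(x for x in str(row.observers).split(";") if x)
        hint = None
        if "order_hint" in ev_df.columns:
            raw = getattr(row, "order_hint")
            hint = int(raw) if raw not in ("", None) else None
        try:
            ev = ObservationEvent(t, row.behavior, row.performer, observers, row.criterion, hint)
        except DatasetError as exc:
            raise DatasetError(f"{event_path} line {line}: {exc}") from None
        missing = ({ev.performer} | ev.observers) - known
        if missing:
            raise DatasetError(f"{event_path} line {line}: unknown ids {sorted(missing)}")
        events.append(ev)

    presence: list[PresenceInterval] = []
    if presence_path is not None:
        pr_df = _read_csv(presence_path, ["start", "end"])
        for row in pr_df.itertuples(index=True):
            try:
                presence.append(PresenceInterval(float(row.start), float(row.end)))
            except (ValueError, DatasetError) as exc:
                raise DatasetError(f"{presence_path} line {row.Index + 2}: {exc}") from None

    if behaviors is None:
        behaviors = sorted({e.behavior for e in events} - {baseline_behavior})
    acquisitions = derive_acquisitions(
        [e for e in events if e.behavior in behaviors], individuals=known, behaviors=behaviors
    )
    return DiffusionDataset(individuals, events, acquisitions, presence, tuple(behaviors))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_dataset(
    dataset: DiffusionDataset,
    event_path: str | Path,
    ilv_path: str | Path,
    presence_path: str | Path | None = None,
) -> None:
    """Write a dataset back to canonical CSV (sorted rows, ``;``-joined observers).

    Reading then writing is byte-stable, so datasets can be round-tripped.
    """
    ev_lines = ["time,behavior,performer,observers,criterion"]
    for e in dataset.events:
        obs = ";".join(sorted(e.observers))
        ev_lines.append(f"{_fmt(e.time)},{e.behavior},{e.performer},{obs},{e.criterion}")
    Path(event_path).write_text("\n".join(ev_lines) + "\n")

    ilv_lines = ["id,age,sex,tenure"]
    for ind in sorted(dataset.individuals, key=lambda i: i.id):
        ilv_lines.append(f"{ind.id},{_fmt(ind.age)},{ind.sex},{_fmt(ind.tenure)}")
    Path(ilv_path).write_text("\n".join(ilv_lines) + "\n")

    if presence_path is not None:
        pr_lines = ["start,end"]
        for p in dataset.presence:
            pr_lines.append(f"{_fmt(p.start)},{_fmt(p.end)}")
        Path(presence_path).write_text("\n".join(pr_lines) + "\n")
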