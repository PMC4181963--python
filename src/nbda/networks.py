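"""Observation networks: static, count-dynamic and binary-dynamic.

A directed edge runs from observer X to performer Y when X was recorded in
the audience of Y performing the target behavior *before X acquired that
behavior itself*.  The pre-acquisition filter is causal: an observation made
after the observer already knows the behavior cannot have transmitted it,
and without the filter a positive social effect could simply reflect
knowledgeable individuals preferring each other's company (homophily).

Static networks aggregate qualifying observations over the whole study;
dynamic networks expose the running count a(observer, performer, t) of
observations made strictly before time t, as a right-continuous step
function.  The binary-dynamic variant thresholds the count at >= 1,
modelling a maximal transmission effect from a single observation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from nbda.event_data import DatasetError, DiffusionDataset

__all__ = ["StaticNetwork", "DynamicNetwork", "build_static", "build_dynamic", "social_input"]


@dataclass
class StaticNetwork:
    """Directed weighted network of pre-acquisition observation counts."""

    behavior: str
    weights: dict[tuple[str, str], int]  # (observer, performer) -> count

    def __post_init__(self) -> None:
        for (obs, perf), w in self.weights.items():
            if obs == perf:
                raise DatasetError(f"self-edge {obs!r} in static network")
            if w < 0:
                raise DatasetError(f"negative weight on edge ({obs}, {perf})")
        self.weights = {k: w for k, w in self.weights.items() if w > 0}

    def weight(self, observer: str, performer: str) -> int:
        return self.weights.get((observer, performer), 0)

    def to_edgelist_csv(self, path: str | Path) -> None:
        lines = ["observer,performer,weight"]
        for (obs, perf), w in sorted(self.weights.items()):
            lines.append(f"{obs},{perf},{w}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DynamicNetwork:
    """Time-indexed observation counts a(observer, performer, t).

    ``mode`` is ``"count"`` (number of qualifying observations strictly
    before t) or ``"binary"`` (1 once at least one has occurred).  The step
    function increments just *after* each qualifying event: an observation
    at exactly t does not count at t, since it cannot influence a
    simultaneous acquisition.
    """

    behavior: str
    mode: str
    # (observer, performer) -> sorted observation times
    _times: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("count", "binary"):
            raise DatasetError(f"unknown dynamic network mode {self.mode!r}")
        for (obs, perf) in self._times:
            if obs == perf:
                raise DatasetError(f"self-edge {obs!r} in dynamic network")

    @property
    def breakpoints(self) -> list[float]:
        return sorted({t for ts in self._times.values() for t in ts})

    def weight(self, observer: str, performer: str, t: float) -> int:
        ts = self._times.get((observer, performer))
        if not ts:
            return 0
        n = bisect.bisect_left(ts, t)  # strictly before t
        if self.mode == "binary":
            return 1 if n >= 1 else 0
        return n

    def to_edgelist_csv(self, path: str | Path) -> None:
        lines = ["observer,performer,time,weight"]
        for (obs, perf), ts in sorted(self._times.items()):
            for k, t in enumerate(ts, start=1):
                w = 1 if self.mode == "binary" else k
                lines.append(f"{obs},{perf},{t!r},{w}")
        Path(path).write_text("\n".join(lines) + "\n")


def _qualifying_pairs(dataset: DiffusionDataset, behavior: str):
    """Yield (observer, performer, time) for pre-acquisition observations."""
    if behavior not in dataset.behaviors:
        raise DatasetError(f"unknown behavior {behavior!r}")
    for ev in dataset.events_of(behavior):
        for obs in ev.observers:
            if ev.time < dataset.acquisition_time(obs, behavior):
                yield obs, ev.performer, ev.time


def build_static(dataset: DiffusionDataset, behavior: str) -> StaticNetwork:
    """Aggregate pre-acquisition observation counts into a static network."""
    weights: dict[tuple[str, str], int] = {}
    for obs, perf, _t in _qualifying_pairs(dataset, behavior):
        key = (obs, perf)
        weights[key] = weights.get(key, 0) + 1
    return StaticNetwork(behavior, weights)


def build_dynamic(dataset: DiffusionDataset, behavior: str, mode: str = "count") -> DynamicNetwork:
    """Build the time-indexed network of observation counts before t."""
    times: dict[tuple[str, str], list[float]] = {}
    for obs, perf, t in _qualifying_pairs(dataset, behavior):
        times.setdefault((obs, perf), []).append(t)
    for ts in times.values():
        ts.sort()
    return DynamicNetwork(behavior, mode, times)


def social_input(
    network: StaticNetwork | DynamicNetwork,
    z_state: Iterable[str] | Mapping[str, int],
    i: str,
    t: float,
) -> float:
    """Total social input S_i(t) = sum over informed j of a(i, j[, t]).

    ``z_state`` is the set of individuals informed at time t (or a mapping
    id -> 0/1).  Performers in an event-derived network are informed at
    every queried time by construction, so the gate is usually a no-op, but
    it is applied for generality (e.g. user-supplied association networks).
    """
    if isinstance(z_state, Mapping):
        informed = {j for j, z in z_state.items() if z}
    else:
        informed = set(z_state)
    if isinstance(network, StaticNetwork):
        return float(sum(w for (obs, perf), w in network.weights.items()
                         if obs == i and perf in informed))
    return float(sum(network.weight(i, j, t) for j in informed if j != i))
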