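"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's likelihood code paths:
they recount observations by scanning the raw event log and enumerate risk
sets directly, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nbda.event_data import (
    AcquisitionRecord,
    DiffusionDataset,
    Individual,
    ObservationEvent,
    PresenceInterval,
    derive_acquisitions,
)
from nbda.simulate import SimulationConfig, simulate_diffusion


def make_individuals(ids, age=20.0, sex=0, tenure=10.0):
    return [Individual(i, age, sex, tenure) for i in ids]


def dataset_from_events(ids, events, behaviors=None, presence=None):
    acq = derive_acquisitions(events, individuals=ids, behaviors=behaviors)
    return DiffusionDataset(
        make_individuals(ids), list(events), acq, presence or [],
        tuple(sorted(behaviors)) if behaviors else (),
    )


@pytest.fixture
def abc_dataset():
    """Three individuals: A innovates, B then C each watch A three times and learn.

    The classic illustration of why a time-indexed network matters: a static
    network gives B and C identical links of strength 3 from A, while the
    dynamic network knows B had all three observations before its
    acquisition and C had none by then.
    """
    ev = [
        ObservationEvent(1.0, "M", "A", frozenset()),
        ObservationEvent(2.0, "M", "A", frozenset({"B"})),
        ObservationEvent(3.0, "M", "A", frozenset({"B"})),
        ObservationEvent(4.0, "M", "A", frozenset({"B"})),
        ObservationEvent(5.0, "M", "B", frozenset()),
        ObservationEvent(6.0, "M", "A", frozenset({"C"})),
        ObservationEvent(7.0, "M", "A", frozenset({"C"})),
        ObservationEvent(8.0, "M", "A", frozenset({"C"})),
        ObservationEvent(9.0, "M", "C", frozenset()),
    ]
    return dataset_from_events(["A", "B", "C"], ev, behaviors=["M"])


@pytest.fixture
def two_behavior_toy():
    """Four individuals, two behaviors diffusing in parallel."""
    ev = [
        ObservationEvent(1.0, "M", "A", frozenset({"B", "C"})),
        ObservationEvent(1.5, "R", "D", frozenset({"C"})),
        ObservationEvent(2.0, "M", "B", frozenset({"C"})),
        ObservationEvent(2.5, "M", "A", frozenset({"D"})),
        ObservationEvent(3.0, "R", "C", frozenset({"A", "B"})),
        ObservationEvent(4.0, "M", "C", frozenset({"D"})),
        ObservationEvent(5.0, "R", "A", frozenset()),
        ObservationEvent(6.0, "M", "D", frozenset()),
    ]
    return dataset_from_events(["A", "B", "C", "D"], ev, behaviors=["M", "R"])


def small_sim(seed, **kw):
    """A quick simulated study for oracle checks (single behavior, small group)."""
    defaults = dict(
        n_individuals=8,
        behaviors=("M",),
        s_true={"M": 1.0},
        lambda0=0.05,
        baseline_behavior=None,
        seed=seed,
    )
    defaults.update(kw)
    ds, truth = simulate_diffusion(SimulationConfig(**defaults))
    return ds, truth


@pytest.fixture
def sim_dataset():
    ds, _ = small_sim(42, n_individuals=12)
    return ds


# ---------------------------------------------------------------------------
# oracle 1: brute-force risk-set enumeration straight off the event log


def _obs_count(dataset, behavior, observer, t, binary=False):
    """Observations by `observer` of `behavior` strictly before t (pre-acquisition only),
    grouped by performer when `binary`."""
    per_performer: dict[str, int] = {}
    t_own = dataset.acquisition_time(observer, behavior)
    for ev in dataset.events:
        if ev.behavior != behavior or observer not in ev.observers:
            continue
        if ev.time < t and ev.time < t_own:
            per_performer[ev.performer] = per_performer.get(ev.performer, 0) + 1
    if binary:
        return float(sum(1 for v in per_performer.values() if v >= 1))
    return float(sum(per_performer.values()))


def _static_count(dataset, behavior, observer, informed):
    t_own = dataset.acquisition_time(observer, behavior)
    n = 0
    for ev in dataset.events:
        if (ev.behavior == behavior and observer in ev.observers
                and ev.time < t_own and ev.performer in informed):
            n += 1
    return float(n)


def brute_force_oada_loglik(
    dataset,
    s_map,
    form="log_linear",
    interaction="multiplicative",
    network_mode="dynamic_count",
    beta=None,
    ilv_values=None,
    excluded=(),
):
    """Enumerate risk sets event by event and multiply conditional probabilities."""
    beta = beta or {}
    total = 0.0
    for b in dataset.behaviors:
        acq = dataset.ordered_acquisitions(b)
        informed: set[str] = set()
        for rec in acq:
            t = rec.acquisition_time
            risk = [i for i in dataset.ids
                    if i not in informed and dataset.acquisition_time(i, b) >= t]
            rs = []
            for i in risk:
                if network_mode == "static":
                    S = _static_count(dataset, b, i, informed)
                elif network_mode == "dynamic_binary":
                    S = _obs_count(dataset, b, i, t, binary=True)
                else:
                    S = _obs_count(dataset, b, i, t)
                lp = sum(beta[c] * ilv_values[c][i] for c in beta) if beta else 0.0
                s = s_map.get(b, 0.0)
                if form == "log_linear" and interaction == "multiplicative":
                    R = math.exp(s * S + lp)
                elif form == "log_linear":
                    R = (math.exp(s * S) - 1.0) + math.exp(lp)
                elif interaction == "additive":
                    R = s * S + math.exp(lp)
                else:
                    R = (s * S + 1.0) * math.exp(lp)
                rs.append(R)
            if (rec.individual, b) not in excluded:
                p = rs[risk.index(rec.individual)] / sum(rs)
                total += math.log(p)
            informed.add(rec.individual)
    return total


# ---------------------------------------------------------------------------
# oracle 2: Cox partial likelihood with the observation count as a
# time-varying covariate (long-format episode construction)


def cox_partial_loglik(dataset, behavior, beta):
    """Partial likelihood of a proportional-hazards model, covariate = running
    observation count.  Built from (start, stop] episodes like a survival
    long-format table: the covariate on an episode is the count of
    observations at or before its start, so the value in force at an event
    time is the count strictly before it."""
    obs_times = {i: sorted(e.time for e in dataset.events
                           if e.behavior == behavior and i in e.observers)
                 for i in dataset.ids}
    acq = dataset.ordered_acquisitions(behavior)
    ll = 0.0
    for rec in acq:
        t = rec.acquisition_time
        risk, x = [], []
        for i in dataset.ids:
            t_stop = dataset.acquisition_time(i, behavior)
            if t_stop < t:  # episode already closed by an event
                continue
            risk.append(i)
            x.append(float(sum(1 for u in obs_times[i] if u < t)))
        eta = beta * np.asarray(x)
        m = max(eta)
        ll += eta[risk.index(rec.individual)] - (m + math.log(np.exp(eta - m).sum()))
    return float(ll)
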