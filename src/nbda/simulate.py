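"""Generative diffusion simulator for testing and parameter recovery.

The simulator mirrors the fitted model: a closed group makes scheduled
visits to a study site; while on site, each naive individual i learns
behavior b at hazard

    lambda_i(t) = lambda0 * gamma * tau^(gamma-1) * f(s_b, n_i(t)) * exp(sum_k beta_k x_ik)

per unit on-site time tau, where n_i(t) counts i's prior observations of
informed individuals performing b and f is the transmission function
(exp(s*n) for the log-linear form, 1 + s*n for the linear form).  Informed
individuals on site perform the behavior as a Poisson process; every
performance (including the performance that marks an acquisition) is logged
as an event with an audience sampled from the rest of the party, which is
how observation counts accrue.  The first acquisition of each behavior is
therefore drawn from purely asocial hazards - the innovator has nobody to
watch.

Simulation is continuous-time (Gillespie): within each presence interval
competing exponential clocks run for every possible learning event and
every possible performance; all randomness flows from the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from nbda.event_data import (
    AcquisitionRecord,
    DiffusionDataset,
    Individual,
    ObservationEvent,
    PresenceInterval,
    derive_acquisitions,
)

__all__ = ["SimulationConfig", "simulate_diffusion", "recovery_experiment", "default_schedule"]


def small_audience(rng: np.random.Generator, n_others: int) -> int:
    """Default audience size: a handful of close-range onlookers (1 + Poisson(2))."""
    return min(n_others, 1 + int(rng.poisson(2.0)))


def default_schedule(n_days: int = 6, blocks_per_day: int = 6, block_hours: float = 1.0) -> tuple[PresenceInterval, ...]:
    """Daily visit blocks: ``blocks_per_day`` one-hour site visits per day.

    Times are in hours on the study clock; a day is 24 h with visits spread
    through a 10 h observation window.
    """
    out = []
    for d in range(n_days):
        for k in range(blocks_per_day):
            start = 24.0 * d + 7.0 + k * (10.0 / blocks_per_day)
            out.append(PresenceInterval(start, start + block_hours))
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic diffusion study.

    Defaults mimic a small habituated community repeatedly visiting one
    site: 30 individuals, 6 days of 6 one-hour visit blocks, two behaviors
    spreading in parallel.  ``s_true`` is on the scale of the chosen
    ``form`` (log-linear: log of the per-observation rate multiplier;
    linear: additive rate units per observation).  ``lambda0`` is the
    asocial learning rate per hour on site; ``performance_rate`` is each
    informed individual's performance rate per hour on site.
    ``party_size_dist`` and ``audience_size_dist`` draw, per visit block
    and per performance, how many individuals are present and how many of
    them are close enough to watch (None = everyone).
    """

    n_individuals: int = 30
    behaviors: tuple[str, ...] = ("M", "RU1")
    s_true: Mapping[str, float] = field(default_factory=lambda: {"M": float(np.log(15.0)), "RU1": 0.0})
    form: str = "log_linear"
    lambda0: float = 0.02
    gamma: float = 1.0
    beta_true: Mapping[str, float] = field(default_factory=dict)
    visit_schedule: tuple[PresenceInterval, ...] = field(default_factory=default_schedule)
    party_size_dist: Callable[[np.random.Generator, int], int] | None = None
    audience_size_dist: Callable[[np.random.Generator, int], int] | None = small_audience
    performance_rate: float = 1.0
    baseline_behavior: str | None = "LS"
    baseline_rate: float = 2.0
    strict_subsample: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.performance_rate <= 0 or self.gamma <= 0:
            raise ValueError("rates and shape must be positive")
        if self.form not in ("linear", "log_linear"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "linear" and any(v < 0 for v in self.s_true.values()):
            raise ValueError("linear form requires s_true >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def _make_individuals(n: int, rng: np.random.Generator) -> list[Individual]:
    """Covariates loosely matching an adult/subadult chimpanzee community."""
    ids = [f"I{k:02d}" for k in range(n)]
    age = np.round(rng.uniform(8.0, 45.0, size=n), 1)
    sex = rng.integers(0, 2, size=n)
    natal = rng.random(n) < 0.5
    tenure = np.where(natal, age, np.round(rng.uniform(1.0, 15.0, size=n), 1))
    tenure = np.minimum(tenure, age)
    return [Individual(i, float(a), int(s), float(t)) for i, a, s, t in zip(ids, age, sex, tenure)]


_MAX_FACTOR = 1e12  # beyond this the acquisition is effectively instantaneous


def _transmission_factor(form: str, s: float, n_obs: float) -> float:
    """Multiplier on the asocial rate after n_obs observations.

    Capped so that inter-event waiting times stay representable: once the
    rate is ~1e12 times baseline, learning happens at the next float tick
    anyway and an unbounded exp() would only overflow.
    """
    if form == "log_linear":
        return float(min(np.exp(min(s * n_obs, 700.0)), _MAX_FACTOR))
    return float(min(1.0 + s * n_obs, _MAX_FACTOR))


def simulate_diffusion(config: SimulationConfig) -> tuple[DiffusionDataset, dict]:
    """Simulate one study and return (dataset, truth record).

    The truth record holds the generating parameters and the realized
    acquisition times, for use in recovery experiments.
    """
    rng = np.random.default_rng(config.seed)
    individuals = _make_individuals(config.n_individuals, rng)
    ids = [ind.id for ind in individuals]
    n = len(ids)

    beta = config.beta_true
    if beta:
        from nbda.event_data import standardize_covariates

        frame = pd.DataFrame(
            {"age": [i.age for i in individuals],
             "sex": [i.sex for i in individuals],
             "tenure": [i.tenure for i in individuals]},
            index=ids,
        )
        cols = [c for c in beta if c in frame.columns]
        std, _ = standardize_covariates(frame[cols]) if cols else (pd.DataFrame(index=ids), {})
        lp = np.zeros(n)
        for c in cols:
            lp += beta[c] * std[c].to_numpy()
        ilv_mult = np.exp(lp)
    else:
        ilv_mult = np.ones(n)

    informed: dict[str, set[int]] = {b: set() for b in config.behaviors}
    n_obs: dict[str, np.ndarray] = {b: np.zeros(n) for b in config.behaviors}
    events: list[ObservationEvent] = []
    onsite_elapsed = 0.0  # cumulative tau at the start of the current interval

    def learn_rates(b: str, present: np.ndarray, tau: float) -> np.ndarray:
        rates = np.zeros(n)
        base = config.lambda0 * config.gamma * tau ** (config.gamma - 1.0) if config.gamma != 1.0 else config.lambda0
        for i in np.flatnonzero(present):
            if i in informed[b]:
                continue
            rates[i] = base * _transmission_factor(config.form, config.s_true.get(b, 0.0), n_obs[b][i]) * ilv_mult[i]
        return rates

    last_logged = [-np.inf]

    def log_performance(t: float, b: str, performer: int, present_idx: np.ndarray) -> float:
        # event times must stay strictly increasing even when waiting times
        # underflow below one float ulp (near-instant social cascades)
        if t <= last_logged[0]:
            t = float(np.nextafter(last_logged[0], np.inf))
        last_logged[0] = t
        others = [j for j in present_idx if j != performer]
        if config.audience_size_dist is None:
            audience = others
        else:
            k = min(config.audience_size_dist(rng, len(others)), len(others))
            audience = list(rng.choice(others, size=k, replace=False)) if k else []
        obs_std = frozenset(ids[j] for j in audience)
        events.append(ObservationEvent(t, b, ids[performer], obs_std, "standard"))
        keep = [ids[j] for j in audience if rng.random() < config.strict_subsample]
        events.append(ObservationEvent(t, b, ids[performer], frozenset(keep), "strict"))
        if b in config.behaviors:
            for j in audience:
                if j not in informed[b]:
                    n_obs[b][j] += 1.0
        return t

    for iv in config.visit_schedule:
        if config.party_size_dist is None:
            present_idx = np.arange(n)
        else:
            k = max(1, min(config.party_size_dist(rng, n), n))
            present_idx = np.sort(rng.choice(n, size=k, replace=False))
        present = np.zeros(n, dtype=bool)
        present[present_idx] = True

        def blocks_at(tau: float) -> list[tuple[float, str, str, int]]:
            out: list[tuple[float, str, str, int]] = []  # (rate, kind, behavior, individual)
            for b in config.behaviors:
                lr = learn_rates(b, present, max(tau, 1e-9))
                for i in np.flatnonzero(lr > 0):
                    out.append((lr[i], "learn", b, i))
                for i in informed[b] & set(present_idx.tolist()):
                    out.append((config.performance_rate, "perform", b, i))
            if config.baseline_behavior is not None:
                for i in present_idx:
                    out.append((config.baseline_rate, "perform", config.baseline_behavior, i))
            return out

        t = iv.start
        while t < iv.end:
            tau = onsite_elapsed + (t - iv.start)
            tau_end = onsite_elapsed + (iv.end - iv.start)
            # Ogata thinning: the only time dependence between events is the
            # monotone baseline factor, so the rate at whichever end of the
            # remaining interval is larger bounds the total rate throughout it.
            tau_bound = max(tau, 1e-9) if config.gamma <= 1.0 else tau_end
            bound_blocks = blocks_at(tau_bound)
            bound_total = sum(r for r, *_ in bound_blocks)
            if bound_total <= 0:
                break
            dt = rng.exponential(1.0 / bound_total)
            t = t + dt
            if t >= iv.end:
                break
            blocks = blocks_at(onsite_elapsed + (t - iv.start)) if config.gamma != 1.0 else bound_blocks
            total = sum(r for r, *_ in blocks)
            if rng.random() > total / bound_total:
                continue  # thinned: no event at t
            probs = np.array([r for r, *_ in blocks]) / total
            _, kind, b, i = blocks[rng.choice(len(blocks), p=probs)]
            if kind == "learn":
                informed[b].add(int(i))
                log_performance(t, b, int(i), present_idx)  # acquisition = first performance
            else:
                log_performance(t, b, int(i), present_idx)
        onsite_elapsed += iv.end - iv.start

    target_events = [e for e in events if e.behavior in config.behaviors and e.criterion == "standard"]
    acquisitions = derive_acquisitions(target_events, individuals=ids, behaviors=config.behaviors)
    dataset = DiffusionDataset(
        individuals,
        [e for e in events if e.criterion == "standard"],
        acquisitions,
        list(config.visit_schedule),
        tuple(config.behaviors),
    )
    for b in config.behaviors:
        if not informed[b]:
            warnings.warn(f"schedule too short: no acquisitions of {b!r}; innovator-only dataset")
    truth = {
        "s_true": dict(config.s_true),
        "form": config.form,
        "lambda0": config.lambda0,
        "gamma": config.gamma,
        "beta_true": dict(config.beta_true),
        "seed": config.seed,
        "n_acquired": {b: len(informed[b]) for b in config.behaviors},
        "final_obs_counts": {
            b: {ids[i]: float(n_obs[b][i]) for i in range(n)} for b in config.behaviors
        },
        "acquisition_times": {
            b: {a.individual: a.acquisition_time
                for a in dataset.ordered_acquisitions(b)}
            for b in config.behaviors
        },
        "strict_events": [e for e in events if e.criterion == "strict"],
    }
    return dataset, truth


def write_simulation(dataset: DiffusionDataset, truth: dict, outdir: str | Path) -> None:
    """Write events.csv / ilv.csv / presence.csv / truth.json for a simulated study.

    The event log carries both audience criteria: each performance appears
    once with its full (``standard``) observer list and once with the
    restricted (``strict``) one, so the reader can filter on either.
    """
    from nbda.event_data import write_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, outdir / "events.csv", outdir / "ilv.csv", outdir / "presence.csv")
    strict = truth.get("strict_events", [])
    if strict:
        with (outdir / "events.csv").open("a") as fh:
            for e in sorted(strict, key=lambda e: (e.time, e.performer, e.behavior)):
                obs = ";".join(sorted(e.observers))
                fh.write(f"{float(e.time)!r},{e.behavior},{e.performer},{obs},strict\n")
    clean = {k: v for k, v in truth.items() if k != "strict_events"}
    (outdir / "truth.json").write_text(json.dumps(clean, indent=2, default=str) + "\n")


def recovery_experiment(
    config: SimulationConfig,
    reps: int,
    fit_spec=None,
    profile: bool = True,
    level: float = 0.95,
    min_events: int = 5,
) -> pd.DataFrame:
    """Simulate ``reps`` diffusions, refit the generating model, summarize recovery.

    Returns one row per replicate with the estimated transmission strength
    per behavior, its profile-CI endpoints and coverage of the truth.
    Replicate seeds derive deterministically from ``config.seed``.
    Replicates with fewer than ``min_events`` acquisitions of a behavior
    are recorded with NaN estimates for it; more than 10% non-convergent
    fits abort with a diagnostic.
    """
    from nbda.model_selection import profile_ci
    from nbda.oada import ModelSpec, fit_oada

    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if fit_spec is None:
        fit_spec = ModelSpec(
            network_mode="dynamic_count",
            form=config.form,
            transmission="separate_s" if len(config.behaviors) > 1 else "shared_s",
        )
    rows = []
    n_bad = 0
    for r in range(reps):
        sub_seed = (config.seed * 100003 + r) % (2**31 - 1)
        ds, truth = simulate_diffusion(replace(config, seed=sub_seed))
        enough = all(truth["n_acquired"][b] >= min_events for b in config.behaviors)
        row: dict[str, float] = {"rep": r, "seed": sub_seed}
        if not enough:
            n_bad += 1
            rows.append(row)
            continue
        fit = fit_oada(fit_spec, ds, seed=sub_seed)
        if not fit.converged:
            n_bad += 1
            rows.append(row)
            continue
        for b in config.behaviors:
            s_hat = fit.params.s.get(b, 0.0)
            row[f"s_hat:{b}"] = s_hat
            row[f"s_true:{b}"] = config.s_true.get(b, 0.0)
            if profile:
                pname = "s" if "s" in fit.param_names else f"s:{b}"
                ci = profile_ci(fit, pname, level=level)
                row[f"ci_lo:{b}"], row[f"ci_hi:{b}"] = ci.lo, ci.hi
                row[f"covered:{b}"] = float(ci.lo <= config.s_true.get(b, 0.0) <= ci.hi)
        rows.append(row)
        if n_bad > 0.1 * reps:
            raise RuntimeError(
                f"{n_bad} of {r + 1} replicates unusable (non-convergence or too few "
                f"events); check the generating configuration"
            )
    return pd.DataFrame(rows)
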