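"""Time-of-acquisition diffusion analysis (TADA).

TADA uses the actual acquisition *times*, so unlike OADA the baseline rate
lambda0 does not cancel and must be specified.  Time runs on an "on-site"
clock: cumulative time during which the group was present at the study
site, so the learning rate is zero whenever nobody is there.  Supported
baseline families:

- constant:  lambda0(tau) = lambda0
- weibull:   lambda0(tau) = lambda0 * gamma * tau**(gamma - 1),

the Weibull shape gamma allowing a baseline that systematically increases
(gamma > 1) or decreases (gamma < 1) over the study; gamma = 1 recovers the
constant family.  The baseline (and shape) may be shared across behaviors
or fitted per behavior.

The log-likelihood is the standard survival form: each acquirer m
contributes ln lambda0(tau_m) + ln R_m(tau_m); every individual contributes
minus the integrated hazard over its naive period, computed exactly over
the piecewise-constant segments of the relative hazard R (breakpoints at
acquisitions and network steps).  Censored individuals are integrated to
the end of the last presence interval.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from nbda import _optim
from nbda.event_data import DatasetError, DiffusionDataset, PresenceInterval, standardize_covariates
from nbda.networks import DynamicNetwork, StaticNetwork, social_input
from nbda.oada import FitResult, ModelSpec, Params, _hazard_vec, build_networks

__all__ = ["BaselineSpec", "OnsiteClock", "TadaParams", "onsite_clock", "tada_loglik", "fit_tada"]


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline-rate family for TADA."""

    family: str = "constant"  # constant | weibull
    shared_across_behaviors: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("constant", "weibull"):
            raise ValueError(f"unknown baseline family {self.family!r}")


@dataclass
class TadaParams(Params):
    """TADA parameters: transmission s, ILV betas, plus baseline rate/shape."""

    lambda0: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)


class OnsiteClock:
    """Map study-clock time to cumulative on-site time.

    Piecewise linear with slope 1 inside presence intervals and 0 outside;
    zero at the start of the first interval.  Querying a time before the
    first interval is an error (no observation can predate the study).
    """

    def __init__(self, presence: Sequence[PresenceInterval]):
        if not presence:
            raise DatasetError("onsite clock needs at least one presence interval")
        self.starts = [p.start for p in presence]
        self.ends = [p.end for p in presence]
        self.cum = np.concatenate([[0.0], np.cumsum(np.diff(np.array([self.starts, self.ends]).T).ravel())])

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def elapsed(self, t: float) -> float:
        if t < self.starts[0]:
            raise DatasetError(f"time {t} predates the first presence interval")
        k = bisect.bisect_right(self.starts, t) - 1
        return float(self.cum[k] + min(max(t - self.starts[k], 0.0), self.ends[k] - self.starts[k]))


def onsite_clock(presence: Sequence[PresenceInterval]) -> OnsiteClock:
    """Build the cumulative on-site clock from normalized presence intervals."""
    return OnsiteClock(presence)


def _baseline_log_hazard(family: str, lam: float, gam: float, tau: np.ndarray) -> np.ndarray:
    if family == "constant":
        return np.full_like(tau, np.log(lam), dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(lam) + np.log(gam) + (gam - 1.0) * np.log(tau)


def _baseline_cum(family: str, lam: float, gam: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integral of lambda0 over [a, b] per segment."""
    if family == "constant":
        return lam * (b - a)
    return lam * (b**gam - a**gam)


class TadaDesign:
    """Precomputed segments and event terms for the TADA likelihood.

    Per behavior, study time is cut at every acquisition and qualifying
    observation time; on each resulting piece every naive individual's
    relative hazard is constant.  Pieces are mapped through the on-site
    clock (absences collapse to zero length) and clipped to each
    individual's naive period.
    """

    def __init__(
        self,
        spec: ModelSpec,
        baseline: BaselineSpec,
        dataset: DiffusionDataset,
        networks: Mapping[str, StaticNetwork | DynamicNetwork] | None = None,
    ):
        self.spec = spec
        self.baseline = baseline
        self.behaviors = tuple(dataset.behaviors)
        self.s_names = spec.s_param_names(self.behaviors)
        self.ilv_names = list(spec.ilvs)
        if networks is None:
            networks = build_networks(dataset, spec.network_mode)
        if dataset.presence:
            clock = OnsiteClock(dataset.presence)
            horizon = clock.total
        else:
            t_max = max((e.time for e in dataset.events), default=0.0)
            clock = None
            horizon = t_max
        self.horizon = horizon

        ilv_cols: dict[str, Mapping[str, float]] = {}
        if self.ilv_names:
            cols = [c for c in self.ilv_names if c != "exposure"]
            if cols:
                std, _ = standardize_covariates(dataset.ilv_frame()[cols])
                for c in cols:
                    ilv_cols[c] = std[c].to_dict()
            if "exposure" in self.ilv_names:
                import pandas as pd

                from nbda.event_data import compute_exposure

                for b in self.behaviors:
                    raw = compute_exposure(dataset, b)
                    std, _ = standardize_covariates(pd.DataFrame({"exposure": raw}))
                    ilv_cols[f"exposure:{b}"] = std["exposure"].to_dict()

        def tau_of(t: float) -> float:
            return clock.elapsed(t) if clock is not None else t

        def xrow(i: str, b: str) -> list[float]:
            row = []
            for c in self.ilv_names:
                key = f"exposure:{b}" if c == "exposure" else c
                row.append(ilv_cols[key][i])
            return row

        # per behavior: segment arrays and event arrays
        self.seg: dict[str, dict[str, np.ndarray]] = {}
        self.ev: dict[str, dict[str, np.ndarray]] = {}
        for b in self.behaviors:
            net = networks[b]
            acq = dataset.ordered_acquisitions(b)
            change_t = sorted(
                {r.acquisition_time for r in acq}
                | {e.time for e in dataset.events_of(b)}
            )
            if clock is not None:
                grid = [dataset.presence[0].start]
            else:
                grid = [min(0.0, change_t[0])] if change_t else [0.0]
            grid += [t for t in change_t if t > grid[0]]
            informed_at: dict[float, set[str]] = {}
            running: set[str] = set()
            acq_time = {r.individual: r.acquisition_time for r in acq}
            by_time: dict[float, list[str]] = {}
            for r in acq:
                by_time.setdefault(r.acquisition_time, []).append(r.individual)

            seg_S, seg_a, seg_b_, seg_X = [], [], [], []
            ev_S, ev_tau, ev_X, ev_excl = [], [], [], []
            # walk the grid once, maintaining the informed set
            for j, t_lo in enumerate(grid):
                t_hi = grid[j + 1] if j + 1 < len(grid) else None
                # events at t_lo: acquisitions (event term uses pre-t_lo state)
                for m in by_time.get(t_lo, []):
                    if (m, b) not in spec.excluded_events:
                        ev_S.append(social_input(net, running, m, t_lo))
                        ev_tau.append(tau_of(t_lo))
                        ev_X.append(xrow(m, b))
                running |= set(by_time.get(t_lo, []))
                # exposure segment (t_lo, t_hi] for every individual naive past t_lo
                t_probe = t_lo + 0.5 * ((t_hi - t_lo) if t_hi is not None else 1.0)
                tau_lo = tau_of(t_lo)
                tau_hi = tau_of(t_hi) if t_hi is not None else horizon
                for i in dataset.ids:
                    t_acq = acq_time.get(i, np.inf)
                    if t_acq <= t_lo:
                        continue
                    a = tau_lo
                    bb = min(tau_hi, tau_of(t_acq) if np.isfinite(t_acq) else horizon)
                    if bb <= a:
                        continue
                    seg_S.append(social_input(net, running, i, t_probe))
                    seg_a.append(a)
                    seg_b_.append(bb)
                    seg_X.append(xrow(i, b))
            p = len(self.ilv_names)
            self.seg[b] = {
                "S": np.array(seg_S, dtype=float),
                "a": np.array(seg_a, dtype=float),
                "b": np.array(seg_b_, dtype=float),
                "X": np.array(seg_X, dtype=float).reshape(len(seg_S), p),
            }
            self.ev[b] = {
                "S": np.array(ev_S, dtype=float),
                "tau": np.array(ev_tau, dtype=float),
                "X": np.array(ev_X, dtype=float).reshape(len(ev_S), p),
            }

        base = ["log_lambda0"] if baseline.shared_across_behaviors else [
            f"log_lambda0:{b}" for b in self.behaviors
        ]
        shape: list[str] = []
        if baseline.family == "weibull":
            shape = ["log_gamma"] if baseline.shared_across_behaviors else [
                f"log_gamma:{b}" for b in self.behaviors
            ]
        self.param_names = self.s_names + [f"beta:{c}" for c in self.ilv_names] + base + shape
        self._n_base = len(base)
        self._n_shape = len(shape)
        self.n_events = sum(len(self.ev[b]["tau"]) for b in self.behaviors)

    # -- parameters ----------------------------------------------------

    def unpack(self, theta: np.ndarray) -> TadaParams:
        ns, p = len(self.s_names), len(self.ilv_names)
        s_map = self.spec.s_map(self.behaviors, theta[:ns])
        beta = {c: float(v) for c, v in zip(self.ilv_names, theta[ns:ns + p])}
        base = theta[ns + p: ns + p + self._n_base]
        lam = {b: float(np.exp(base[0] if self._n_base == 1 else base[k]))
               for k, b in enumerate(self.behaviors)}
        gam = {b: 1.0 for b in self.behaviors}
        if self._n_shape:
            sh = theta[ns + p + self._n_base:]
            gam = {b: float(np.exp(sh[0] if self._n_shape == 1 else sh[k]))
                   for k, b in enumerate(self.behaviors)}
        return TadaParams(s=s_map, beta=beta, lambda0=lam, gamma=gam)

    def pack(self, params: TadaParams) -> np.ndarray:
        s_vals = []
        for name in self.s_names:
            if name == "s":
                s_vals.append(params.s[self.behaviors[0]])
            else:
                s_vals.append(params.s.get(name.split(":", 1)[1], 0.0))
        betas = [params.beta.get(c, 0.0) for c in self.ilv_names]
        if self._n_base == 1:
            base = [np.log(params.lambda0[self.behaviors[0]])]
        else:
            base = [np.log(params.lambda0[b]) for b in self.behaviors]
        shape: list[float] = []
        if self._n_shape == 1:
            shape = [np.log(params.gamma[self.behaviors[0]])]
        elif self._n_shape:
            shape = [np.log(params.gamma[b]) for b in self.behaviors]
        return np.array(s_vals + betas + base + shape, dtype=float)

    def loglik(self, theta: np.ndarray) -> float:
        params = self.unpack(theta)
        beta = np.array([params.beta[c] for c in self.ilv_names])
        total = 0.0
        fam = self.baseline.family
        for b in self.behaviors:
            s = params.s.get(b, 0.0)
            lam, gam = params.lambda0[b], params.gamma[b]
            seg = self.seg[b]
            lp = seg["X"] @ beta if self.ilv_names else np.zeros(len(seg["S"]))
            try:
                R = _hazard_vec(self.spec.form, self.spec.ilv_interaction, s, seg["S"], lp)
            except ValueError:
                return -np.inf
            if not np.all(np.isfinite(R)) or np.any(R < 0):
                return -np.inf
            total -= float(np.sum(R * _baseline_cum(fam, lam, gam, seg["a"], seg["b"])))
            ev = self.ev[b]
            if len(ev["tau"]):
                lp_e = ev["X"] @ beta if self.ilv_names else np.zeros(len(ev["S"]))
                Re = _hazard_vec(self.spec.form, self.spec.ilv_interaction, s, ev["S"], lp_e)
                if np.any(Re <= 0) or not np.all(np.isfinite(Re)):
                    return -np.inf
                lh = _baseline_log_hazard(fam, lam, gam, ev["tau"])
                if not np.all(np.isfinite(lh)):
                    return -np.inf
                total += float(np.sum(lh + np.log(Re)))
        return total if np.isfinite(total) else -np.inf

    def bounds(self) -> list[tuple[float | None, float | None]]:
        s_lo = 0.0 if self.spec.form == "linear" else None
        return ([(s_lo, None)] * len(self.s_names)
                + [(None, None)] * len(self.ilv_names)
                + [(-30.0, 30.0)] * self._n_base
                + [(-5.0, 5.0)] * self._n_shape)


def tada_loglik(
    spec: ModelSpec,
    baseline: BaselineSpec,
    params: TadaParams,
    dataset: DiffusionDataset,
    design: TadaDesign | None = None,
) -> float:
    """Full TADA log-likelihood (event terms plus integrated hazards)."""
    if design is None:
        design = TadaDesign(spec, baseline, dataset)
    return design.loglik(design.pack(params))


def fit_tada(
    spec: ModelSpec,
    baseline: BaselineSpec,
    dataset: DiffusionDataset,
    networks: Mapping[str, StaticNetwork | DynamicNetwork] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit one TADA model by maximum likelihood.

    Baseline rate (and Weibull shape, if requested) are optimized on the
    log scale; per-behavior baselines are reported when the baseline spec
    is not shared across behaviors.
    """
    from nbda.model_selection import aicc as _aicc

    design = TadaDesign(spec, baseline, dataset, networks)
    if design.n_events < 1:
        raise DatasetError("no acquisition events enter the likelihood")
    k = len(design.param_names)
    x0 = np.zeros(k)
    if spec.form == "linear":
        x0[: len(design.s_names)] = 1.0
    # start the baseline near events / total exposure
    crude = design.n_events / max(design.horizon, 1e-12) / max(1, len(dataset.ids))
    x0[len(design.s_names) + len(design.ilv_names):
       len(design.s_names) + len(design.ilv_names) + design._n_base] = np.log(max(crude, 1e-10))
    theta, loglik, converged = _optim.maximize(
        design.loglik, x0, design.bounds(), n_starts=n_starts, seed=seed
    )
    cov, hessian_ok = _optim.covariance_from_loglik(design.loglik, theta)
    se = {}
    if hessian_ok and k:
        se = {name: float(np.sqrt(cov[i, i])) for i, name in enumerate(design.param_names)}
    return FitResult(
        spec=spec,
        params=design.unpack(theta),
        loglik=float(loglik),
        k=k,
        n=design.n_events,
        aicc=_aicc(loglik, k, design.n_events),
        converged=converged,
        hessian_ok=hessian_ok,
        param_names=list(design.param_names),
        theta=theta,
        se=se,
        design=design,
    )
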