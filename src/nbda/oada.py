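"""Order-of-acquisition diffusion analysis (OADA).

OADA conditions on the *order* in which individuals acquire a behavior.
Each naive individual i carries a learning hazard

    lambda_i(t) = lambda0(t) * (1 - z_i(t)) * R_i(t),

where z_i(t) indicates prior acquisition and R_i(t) is the relative hazard
combining social input S_i(t) (weighted observations of informed
individuals, from a static or dynamic network) with individual-level
variables (ILVs).  Because every naive individual shares the same baseline
lambda0(t), the probability that the observed acquirer m was the one to
learn at event l is R_m(t_l) / sum over naive i of R_i(t_l): the baseline
cancels and never needs to be specified.  The diffusion log-likelihood sums
ln of these probabilities over acquisition events, and over behaviors when
several diffusions are modelled jointly.

Relative-hazard forms (lp = sum_k beta_k x_ik):

- linear, additive ILVs:          R = s*S + exp(lp)
- linear, multiplicative ILVs:    R = (s*S + 1) * exp(lp)
- log-linear, multiplicative:     R = exp(s*S + lp)
- log-linear, additive:           R = (exp(s*S) - 1) + exp(lp)

In the log-linear forms each single observation multiplies the learning
rate by exp(s); with the binary dynamic network S counts informed models
observed at least once, so one observation per model saturates the effect.
The linear form requires s >= 0 (hazards must stay positive); log-linear s
is unconstrained, allowing per-observation multipliers below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from nbda import _optim
from nbda.event_data import DatasetError, DiffusionDataset, compute_exposure, standardize_covariates
from nbda.networks import DynamicNetwork, StaticNetwork, build_dynamic, build_static, social_input

__all__ = [
    "ModelSpec",
    "Params",
    "FitResult",
    "relative_hazard",
    "oada_event_loglik",
    "oada_loglik",
    "fit_oada",
    "build_networks",
    "OadaDesign",
]

NETWORK_MODES = ("static", "dynamic_count", "dynamic_binary")
FORMS = ("linear", "log_linear")
INTERACTIONS = ("additive", "multiplicative")
TRANSMISSIONS = (
    "asocial",
    "shared_s",
    "separate_s",
    "first_behavior_only",
    "second_behavior_only",
)
ILV_NAMES = ("age", "sex", "tenure", "exposure")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    ``transmission`` picks which behaviors get a social term: none
    (``asocial``), one shared s, one s per behavior (``separate_s``), or a
    social effect on only the first / second behavior in the dataset's
    (sorted) behavior tuple.  ``excluded_events`` lists (individual,
    behavior) acquisition events dropped from the likelihood, e.g. for a
    reanalysis excluding an acquisition suspected to have happened through a
    pathway the network does not capture; the individual still becomes
    informed at its recorded time.
    """

    network_mode: str = "dynamic_count"
    form: str = "log_linear"
    ilv_interaction: str = "multiplicative"
    transmission: str = "shared_s"
    ilvs: tuple[str, ...] = ()
    excluded_events: frozenset[tuple[str, str]] = frozenset()
    innovation_in_likelihood: bool = True

    def __post_init__(self) -> None:
        if self.network_mode not in NETWORK_MODES:
            raise ValueError(f"unknown network_mode {self.network_mode!r}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.ilv_interaction not in INTERACTIONS:
            raise ValueError(f"unknown ilv_interaction {self.ilv_interaction!r}")
        if self.transmission not in TRANSMISSIONS:
            raise ValueError(f"unknown transmission {self.transmission!r}")
        if self.network_mode == "dynamic_binary" and self.form != "log_linear":
            raise ValueError("the binary dynamic network is specified with the log-linear form")
        unknown = set(self.ilvs) - set(ILV_NAMES)
        if unknown:
            raise ValueError(f"unknown ILVs {sorted(unknown)}")
        object.__setattr__(self, "ilvs", tuple(self.ilvs))
        object.__setattr__(self, "excluded_events", frozenset(self.excluded_events))

    def s_param_names(self, behaviors: Sequence[str]) -> list[str]:
        """Names of free social-transmission parameters for these behaviors."""
        if self.transmission == "asocial":
            return []
        if self.transmission == "shared_s" or len(behaviors) == 1:
            if self.transmission == "second_behavior_only" and len(behaviors) == 1:
                raise ValueError("second_behavior_only needs >= 2 behaviors")
            return ["s"]
        if self.transmission == "separate_s":
            return [f"s:{b}" for b in behaviors]
        if self.transmission == "first_behavior_only":
            return [f"s:{behaviors[0]}"]
        return [f"s:{behaviors[1]}"]

    def s_map(self, behaviors: Sequence[str], s_values: Sequence[float]) -> dict[str, float]:
        """Map free s parameters onto per-behavior transmission strengths."""
        names = self.s_param_names(behaviors)
        assert len(s_values) == len(names)
        out = {b: 0.0 for b in behaviors}
        for name, v in zip(names, s_values):
            if name == "s":
                out = {b: float(v) for b in behaviors}
            else:
                out[name.split(":", 1)[1]] = float(v)
        return out


@dataclass
class Params:
    """Fitted or hypothesised parameter values.

    ``s`` maps each behavior to its transmission strength (0 = no social
    effect); ``beta`` maps ILV names to log-scale effects per standard
    deviation (per unit for sex).
    """

    s: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)


def _hazard_vec(form: str, interaction: str, s: float, S: np.ndarray, lp: np.ndarray) -> np.ndarray:
    """Vector of relative hazards R_i over a risk set."""
    if form == "linear":
        if s < 0:
            raise ValueError("linear form requires s >= 0")
        if interaction == "additive":
            return s * S + np.exp(lp)
        return (s * S + 1.0) * np.exp(lp)
    if interaction == "multiplicative":
        return np.exp(s * S + lp)
    return np.expm1(s * S) + np.exp(lp)


def _log_event_prob(
    form: str, interaction: str, s: float, S: np.ndarray, lp: np.ndarray, acquirer: int
) -> float:
    """ln of the probability that ``acquirer`` is the one to learn, given one does."""
    if form == "log_linear" and interaction == "multiplicative":
        # exact and overflow-safe for the headline model
        eta = s * S + lp
        return float(eta[acquirer] - logsumexp(eta))
    R = _hazard_vec(form, interaction, s, S, lp)
    if not np.all(np.isfinite(R)) or np.any(R < 0) or R[acquirer] <= 0:
        return -np.inf
    return float(np.log(R[acquirer]) - np.log(R.sum()))


# ---------------------------------------------------------------------------
# design: per-event risk sets with precomputed social inputs and ILVs


@dataclass
class EventDesign:
    behavior: str
    individual: str
    order: int
    time: float
    risk_ids: list[str]
    acquirer: int  # position of the acquirer within risk_ids
    S: np.ndarray  # social input per risk-set member
    X: np.ndarray  # standardized ILVs per risk-set member, columns = spec.ilvs
    included: bool


def build_networks(
    dataset: DiffusionDataset, network_mode: str
) -> dict[str, StaticNetwork | DynamicNetwork]:
    """Per-behavior networks of the requested mode."""
    if network_mode == "static":
        return {b: build_static(dataset, b) for b in dataset.behaviors}
    mode = "binary" if network_mode == "dynamic_binary" else "count"
    return {b: build_dynamic(dataset, b, mode) for b in dataset.behaviors}


class OadaDesign:
    """Precomputed per-event quantities for fast likelihood evaluation.

    Building the design walks each behavior's acquisition sequence once,
    recording for every event the risk set (all individuals still naive
    just before the event, censored individuals included), the acquirer's
    position, each member's social input S_i(t_l) under the requested
    network mode, and the standardized ILV matrix.
    """

    def __init__(
        self,
        spec: ModelSpec,
        dataset: DiffusionDataset,
        networks: Mapping[str, StaticNetwork | DynamicNetwork] | None = None,
        baseline_behavior: str = "LS",
    ):
        self.spec = spec
        self.behaviors = tuple(dataset.behaviors)
        self.s_names = spec.s_param_names(self.behaviors)
        self.ilv_names = list(spec.ilvs)
        if networks is None:
            networks = build_networks(dataset, spec.network_mode)

        # standardized ILV columns; exposure is behavior-specific
        ilv_cols: dict[str, Mapping[str, float]] = {}
        static_ilvs = [c for c in self.ilv_names if c != "exposure"]
        if static_ilvs:
            std, self.ilv_transform = standardize_covariates(dataset.ilv_frame()[static_ilvs])
            for c in static_ilvs:
                ilv_cols[c] = std[c].to_dict()
        else:
            self.ilv_transform = {}
        exposure: dict[str, Mapping[str, float]] = {}
        if "exposure" in self.ilv_names:
            import pandas as pd

            for b in self.behaviors:
                raw = compute_exposure(dataset, b, baseline_behavior)
                std, tr = standardize_covariates(pd.DataFrame({"exposure": raw}))
                exposure[b] = std["exposure"].to_dict()
                self.ilv_transform[f"exposure:{b}"] = tr["exposure"]

        self.events: list[EventDesign] = []
        for b in self.behaviors:
            net = networks[b]
            acq = dataset.ordered_acquisitions(b)
            informed: set[str] = set()
            for rec in acq:
                t = rec.acquisition_time
                risk = [i for i in dataset.ids if dataset.acquisition_time(i, b) >= t
                        and i not in informed]
                if rec.individual not in risk:
                    raise DatasetError(
                        f"acquirer {rec.individual} not in the {b!r} risk set at t={t}"
                    )
                S = np.array([social_input(net, informed, i, t) for i in risk])
                cols = []
                for c in self.ilv_names:
                    col = exposure[b] if c == "exposure" else ilv_cols[c]
                    cols.append([col[i] for i in risk])
                X = np.array(cols, dtype=float).T if cols else np.zeros((len(risk), 0))
                included = (rec.individual, b) not in spec.excluded_events and (
                    spec.innovation_in_likelihood or rec.order_index > 1
                )
                self.events.append(
                    EventDesign(b, rec.individual, rec.order_index, t,
                                risk, risk.index(rec.individual), S, X, included)
                )
                informed.add(rec.individual)

        self.param_names = self.s_names + [f"beta:{c}" for c in self.ilv_names]
        self.n_events = sum(1 for e in self.events if e.included)

    # -- likelihood ----------------------------------------------------

    def unpack(self, theta: np.ndarray) -> Params:
        ns = len(self.s_names)
        s_map = self.spec.s_map(self.behaviors, theta[:ns])
        beta = {c: float(v) for c, v in zip(self.ilv_names, theta[ns:])}
        return Params(s=s_map, beta=beta)

    def pack(self, params: Params) -> np.ndarray:
        s_vals = []
        for name in self.s_names:
            if name == "s":
                vals = {params.s.get(b, 0.0) for b in self.behaviors}
                s_vals.append(next(iter(vals)) if len(vals) == 1 else params.s[self.behaviors[0]])
            else:
                s_vals.append(params.s.get(name.split(":", 1)[1], 0.0))
        return np.array(s_vals + [params.beta.get(c, 0.0) for c in self.ilv_names], dtype=float)

    def loglik(self, theta: np.ndarray) -> float:
        params = self.unpack(theta)
        beta = np.array([params.beta.get(c, 0.0) for c in self.ilv_names])
        total = 0.0
        for ev in self.events:
            if not ev.included:
                continue
            lp = ev.X @ beta if self.ilv_names else np.zeros(len(ev.risk_ids))
            try:
                ll = _log_event_prob(
                    self.spec.form, self.spec.ilv_interaction,
                    params.s.get(ev.behavior, 0.0), ev.S, lp, ev.acquirer,
                )
            except ValueError:  # out-of-domain probe (e.g. s < 0, linear form)
                return -np.inf
            if not np.isfinite(ll):
                return -np.inf
            total += ll
        return total

    def bounds(self) -> list[tuple[float | None, float | None]]:
        s_lo = 0.0 if self.spec.form == "linear" else None
        return [(s_lo, None)] * len(self.s_names) + [(None, None)] * len(self.ilv_names)


# ---------------------------------------------------------------------------
# public operations


def relative_hazard(
    spec: ModelSpec,
    params: Params,
    i: str,
    t: float,
    behavior: str,
    networks: Mapping[str, StaticNetwork | DynamicNetwork],
    z_state: Mapping[str, int] | set[str],
    ilvs: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Relative hazard R_i(t) for a naive individual under a model spec.

    ``ilvs`` maps ILV name -> (id -> standardized value); omit for a no-ILV
    model.  Raises if the result is not finite or not positive.
    """
    S = social_input(networks[behavior], z_state, i, t)
    lp = 0.0
    if ilvs:
        lp = sum(params.beta.get(c, 0.0) * ilvs[c][i] for c in spec.ilvs)
    R = _hazard_vec(
        spec.form, spec.ilv_interaction, params.s.get(behavior, 0.0),
        np.array([S]), np.array([lp]),
    )[0]
    if not np.isfinite(R) or R <= 0:
        raise ValueError(
            f"non-positive/non-finite relative hazard for {i!r} at t={t} "
            f"(s={params.s}, beta={params.beta}, S={S})"
        )
    return float(R)


def oada_event_loglik(spec: ModelSpec, params: Params, event: EventDesign) -> float:
    """ln P(the observed acquirer learned at event l | one naive individual did).

    Independent of the baseline rate: any common factor applied to all
    relative hazards cancels between numerator and denominator.
    """
    if event.acquirer < 0 or event.acquirer >= len(event.risk_ids):
        raise ValueError("acquirer not in risk set")
    beta = np.array([params.beta.get(c, 0.0) for c in spec.ilvs])
    lp = event.X @ beta if len(spec.ilvs) else np.zeros(len(event.risk_ids))
    return _log_event_prob(
        spec.form, spec.ilv_interaction, params.s.get(event.behavior, 0.0),
        event.S, lp, event.acquirer,
    )


def oada_loglik(
    spec: ModelSpec,
    params: Params,
    dataset: DiffusionDataset,
    design: OadaDesign | None = None,
) -> float:
    """Joint OADA log-likelihood over all behaviors' acquisition events."""
    if design is None:
        design = OadaDesign(spec, dataset)
    return design.loglik(design.pack(params))


@dataclass
class FitResult:
    """A maximum-likelihood fit of one model spec.

    ``params`` holds per-behavior s and per-ILV beta at the MLE; ``se``
    holds observed-information standard errors per free parameter (empty if
    the Hessian was singular, ``hessian_ok`` False).  ``n`` is the number of
    acquisition events entering the likelihood, used as the AICc sample
    size.
    """

    spec: ModelSpec
    params: Params
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    hessian_ok: bool
    param_names: list[str]
    theta: np.ndarray
    se: dict[str, float]
    design: OadaDesign | None = None

    def get_param(self, name: str) -> tuple[float, float] | None:
        """(estimate, variance) for a named parameter, or None if absent.

        ``"s:<behavior>"`` resolves through the transmission hypothesis: in
        a shared-s model the single s applies to every behavior.  ``"s"``
        refers to the shared parameter.  Betas are ``"beta:<ilv>"``.
        """
        if name in self.param_names:
            idx = self.param_names.index(name)
            var = self.se[name] ** 2 if name in self.se else np.nan
            return float(self.theta[idx]), var
        if name.startswith("s:") and "s" in self.param_names:
            behavior = name.split(":", 1)[1]
            if self.params.s.get(behavior) is not None and (
                self.design is None or behavior in self.design.behaviors
            ):
                var = self.se["s"] ** 2 if "s" in self.se else np.nan
                return float(self.params.s[behavior]), var
        return None

    def profile_loglik(self, param: str, value: float) -> float:
        """Profile log-likelihood: fix ``param`` at ``value``, re-optimize the rest."""
        if self.design is None:
            raise ValueError("fit carries no design; cannot profile")
        idx = self.param_names.index(param)
        bounds = self.design.bounds()
        lo, hi = bounds[idx]
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            return -np.inf
        free = [j for j in range(len(self.param_names)) if j != idx]
        if not free:
            theta = np.array([value])
            return self.design.loglik(theta)

        def fixed_loglik(sub: np.ndarray) -> float:
            theta = np.empty(len(self.param_names))
            theta[idx] = value
            theta[free] = sub
            return self.design.loglik(theta)

        x0 = self.theta[free]
        _, val, _ = _optim.maximize(fixed_loglik, x0, [bounds[j] for j in free],
                                    n_starts=2, seed=0)
        return val

    def to_dict(self) -> dict:
        return {
            "spec": {
                "network_mode": self.spec.network_mode,
                "form": self.spec.form,
                "ilv_interaction": self.spec.ilv_interaction,
                "transmission": self.spec.transmission,
                "ilvs": list(self.spec.ilvs),
                "excluded_events": sorted(map(list, self.spec.excluded_events)),
            },
            "s": self.params.s,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "converged": self.converged,
            "hessian_ok": self.hessian_ok,
            "se": self.se,
        }


def fit_oada(
    spec: ModelSpec,
    dataset: DiffusionDataset,
    networks: Mapping[str, StaticNetwork | DynamicNetwork] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    baseline_behavior: str = "LS",
) -> FitResult:
    """Fit one OADA model spec by maximum likelihood.

    Optimization is bounded quasi-Newton from ``n_starts`` jittered starts
    (deterministic given ``seed``).  Standard errors come from the inverse
    observed information at the MLE; an non-invertible Hessian is flagged
    rather than fatal.
    """
    from nbda.model_selection import aicc as _aicc

    design = OadaDesign(spec, dataset, networks, baseline_behavior=baseline_behavior)
    if design.n_events < 1:
        raise DatasetError("no acquisition events enter the likelihood")
    k = len(design.param_names)
    x0 = np.zeros(k)
    if spec.form == "linear":
        x0[: len(design.s_names)] = 1.0
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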