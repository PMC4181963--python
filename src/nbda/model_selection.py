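"""Model selection and multimodel inference.

AICc-based comparison of NBDA model grids: Akaike weights, total support
for hypothesis classes (e.g. "asocial", "same social effect", "social
transmission of one behavior only"), support ratios between model subsets,
model-averaged effect estimates with unconditional standard errors, and
profile-likelihood confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from nbda.oada import FitResult

__all__ = [
    "aicc",
    "akaike_weights",
    "model_table",
    "model_grid",
    "hypothesis_support",
    "support_ratio",
    "model_average",
    "ProfileCI",
    "profile_ci",
]


def model_grid(
    network_modes: Sequence[str] = ("static", "dynamic_count", "dynamic_binary"),
    forms: Sequence[str] = ("linear", "log_linear"),
    interactions: Sequence[str] = ("additive", "multiplicative"),
    transmissions: Sequence[str] = (
        "asocial", "shared_s", "separate_s", "first_behavior_only", "second_behavior_only",
    ),
    ilvs: Sequence[str] = (),
    excluded_events: Iterable[tuple[str, str]] = (),
) -> list:
    """Enumerate a deduplicated grid of model specs.

    ILV subsets run over all 2^k subsets of ``ilvs``.  Models that coincide
    are kept once: the no-ILV variant of a form counts as a single model
    though it qualifies as both an additive and a multiplicative one, and
    an asocial model is unaffected by network mode, functional form or
    interaction, so only one asocial model per ILV subset enters the grid.

    The log-linear form describes the effect of *successive* observations
    and is therefore paired only with the dynamic networks; the static
    network enters with the linear form (s >= 0).  Pairing a static network
    with an unconstrained log-linear s is statistically treacherous on
    near-complete diffusions: a static weight aggregates an individual's
    whole pre-acquisition history, so late acquirers carry large weights at
    *early* events and a negative s can "predict" the order from its own
    consequence.  Such a spec can still be built by hand via ModelSpec.
    """
    from itertools import chain, combinations

    from nbda.oada import ModelSpec

    subsets = list(chain.from_iterable(combinations(ilvs, r) for r in range(len(ilvs) + 1)))
    specs, seen = [], set()
    for trans in transmissions:
        for sub in subsets:
            if trans == "asocial":
                key = ("asocial", sub)
                if key not in seen:
                    seen.add(key)
                    specs.append(ModelSpec(
                        network_mode="dynamic_count", form="log_linear",
                        ilv_interaction="multiplicative", transmission="asocial",
                        ilvs=sub, excluded_events=frozenset(excluded_events),
                    ))
                continue
            for net in network_modes:
                for form in forms:
                    if net == "dynamic_binary" and form != "log_linear":
                        continue
                    if net == "static" and form == "log_linear":
                        continue
                    for inter in interactions:
                        if not sub and inter == "additive":
                            continue  # no-ILV model counted once
                        key = (trans, sub, net, form, inter)
                        if key in seen:
                            continue
                        seen.add(key)
                        specs.append(ModelSpec(
                            network_mode=net, form=form, ilv_interaction=inter,
                            transmission=trans, ilvs=sub,
                            excluded_events=frozenset(excluded_events),
                        ))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike's information criterion corrected for small samples.

    AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1), with n the effective sample
    size (here: acquisition events entering the likelihood).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    Invariant to adding a constant to every AICc value.
    """
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def model_table(fits: Sequence[FitResult], drop_nonconverged: bool = True) -> pd.DataFrame:
    """One row per fitted model, with delta-AICc and Akaike weight.

    Non-converged fits are excluded from the comparison set (with a
    warning) unless ``drop_nonconverged`` is False.
    """
    usable = list(fits)
    if drop_nonconverged:
        bad = [f for f in usable if not f.converged]
        if bad:
            warnings.warn(f"excluding {len(bad)} non-converged fit(s) from the model table")
            usable = [f for f in usable if f.converged]
    if not usable:
        raise ValueError("no converged fits to compare")
    a = np.array([f.aicc for f in usable])
    w = akaike_weights(a)
    rows = []
    for f, wi in zip(usable, w):
        rows.append({
            "network_mode": f.spec.network_mode,
            "form": f.spec.form,
            "ilv_interaction": f.spec.ilv_interaction,
            "transmission": f.spec.transmission,
            "ilvs": "+".join(f.spec.ilvs) or "-",
            "k": f.k,
            "loglik": f.loglik,
            "aicc": f.aicc,
            "delta_aicc": f.aicc - a.min(),
            "weight": wi,
            "fit": f,
        })
    return pd.DataFrame(rows).sort_values("aicc", ignore_index=True)


def hypothesis_support(
    table: pd.DataFrame,
    class_map: Mapping[str, str] | Callable[[FitResult], str] = None,
) -> dict[str, float]:
    """Total Akaike weight per hypothesis class.

    ``class_map`` maps a model's transmission hypothesis (or, if callable,
    its FitResult) to a class label; default groups by the transmission
    hypothesis itself.  Every model must land in exactly one class; class
    supports sum to 1 over the comparison set.
    """
    out: dict[str, float] = {}
    for _, row in table.iterrows():
        if class_map is None:
            cls = row["transmission"]
        elif callable(class_map):
            cls = class_map(row["fit"])
        else:
            cls = class_map.get(row["transmission"])
        if cls is None:
            raise ValueError(f"model with transmission {row['transmission']!r} has no class")
        out[cls] = out.get(cls, 0.0) + float(row["weight"])
    return out


def support_ratio(
    table: pd.DataFrame,
    subset_a: Callable[[pd.Series], bool],
    subset_b: Callable[[pd.Series], bool],
) -> float:
    """Ratio of total Akaike weight of subset a over subset b.

    Subsets are predicates over table rows, evaluated within the combined
    comparison set; a zero-weight denominator yields +inf with a warning.
    """
    wa = float(sum(row["weight"] for _, row in table.iterrows() if subset_a(row)))
    wb = float(sum(row["weight"] for _, row in table.iterrows() if subset_b(row)))
    if wa == 0 and wb == 0:
        raise ValueError("both subsets are empty or unweighted")
    if wb == 0:
        warnings.warn("support ratio denominator has zero weight; returning inf")
        return np.inf
    return wa / wb


def model_average(
    table: pd.DataFrame,
    param: str,
    shrinkage: bool = True,
    missing_var: str = "error",
    level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Model-averaged estimate with unconditional SE and Wald CI.

    The estimate is the weight-sum of per-model estimates.  Under the
    shrinkage convention (default) models lacking ``param`` contribute an
    estimate of 0 with zero variance; otherwise weights are renormalized
    over the models containing it.  The unconditional standard error
    follows Burnham & Anderson:

        SE = sum_i w_i * sqrt(var_i + (theta_i - theta_bar)^2).

    A contributing model whose Hessian could not be inverted has no
    variance; ``missing_var`` selects the fallback: ``"error"`` (raise),
    ``"zero"`` or ``"drop"`` (renormalize without it), each with a warning.
    """
    rows = []
    for _, row in table.iterrows():
        fit: FitResult = row["fit"]
        got = fit.get_param(param)
        w = float(row["weight"])
        if got is None:
            if shrinkage:
                rows.append((w, 0.0, 0.0))
            continue
        est, var = got
        if not np.isfinite(var):
            warnings.warn(f"model without invertible Hessian contributes to {param!r}")
            if missing_var == "error":
                raise ValueError(f"no variance available for {param!r} in a contributing model")
            if missing_var == "drop":
                continue
            var = 0.0
        rows.append((w, est, var))
    if not rows:
        raise ValueError(f"parameter {param!r} absent from every model")
    w = np.array([r[0] for r in rows])
    est = np.array([r[1] for r in rows])
    var = np.array([r[2] for r in rows])
    w = w / w.sum()
    theta_bar = float(w @ est)
    se = float(w @ np.sqrt(var + (est - theta_bar) ** 2))
    zcrit = float(norm.ppf(0.5 + level / 2.0))
    return theta_bar, se, (theta_bar - zcrit * se, theta_bar + zcrit * se)


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood interval; ``*_at_bound`` flags an endpoint that hit
    a parameter bound or the search limit (one-sided / open interval)."""

    lo: float
    hi: float
    lo_at_bound: bool = False
    hi_at_bound: bool = False

    def __iter__(self):
        return iter((self.lo, self.hi))


def profile_ci(
    fit: FitResult | Callable[[float], float],
    param: str | None = None,
    level: float = 0.95,
    mle: float | None = None,
    max_loglik: float | None = None,
    bounds: tuple[float | None, float | None] = (None, None),
    max_expansions: int = 60,
) -> ProfileCI:
    """Profile-likelihood confidence interval for one parameter.

    Endpoints are where the profile log-likelihood has dropped by
    chi2_1(level)/2 (1.9207 at 95%) from its maximum, found by bracketed
    root search; nuisance parameters are re-optimized at every probe.  If
    the profile never reaches the cutoff before a parameter bound (e.g.
    s = 0 under the linear form), that endpoint is reported at the bound
    and flagged one-sided.

    Accepts either a FitResult plus parameter name, or a bare profile
    log-likelihood callable together with ``mle`` (and optionally
    ``max_loglik``).
    """
    if callable(fit) and not isinstance(fit, FitResult):
        prof = fit
        if mle is None:
            raise ValueError("profiling a bare callable requires mle=")
        theta_hat = float(mle)
        lo_b, hi_b = bounds
    else:
        assert param is not None
        idx = fit.param_names.index(param)
        theta_hat = float(fit.theta[idx])
        lo_b, hi_b = fit.design.bounds()[idx]
        prof = lambda v: fit.profile_loglik(param, v)
        if max_loglik is None:
            max_loglik = fit.loglik
    if max_loglik is None:
        max_loglik = prof(theta_hat)
    target = max_loglik - chi2.ppf(level, df=1) / 2.0

    def endpoint(direction: int) -> tuple[float, bool]:
        bound = hi_b if direction > 0 else lo_b
        step = max(1.0, abs(theta_hat)) * 0.5
        x_in = theta_hat
        for _ in range(max_expansions):
            x_out = x_in + direction * step
            if bound is not None and (x_out - bound) * direction >= 0:
                x_out = bound
            val = prof(x_out)
            if val < target:
                f = lambda x: prof(x) - target
                lo, hi = sorted((x_in, x_out))
                root = optimize.brentq(f, lo, hi, xtol=1e-8, rtol=1e-10)
                return float(root), False
            if bound is not None and x_out == bound:
                return float(bound), True
            x_in = x_out
            step *= 2.0
        warnings.warn("profile likelihood never crossed the cutoff; endpoint open")
        return float(x_in), True

    hi, hi_flag = endpoint(+1)
    lo, lo_flag = endpoint(-1)
    return ProfileCI(lo=lo, hi=hi, lo_at_bound=lo_flag, hi_at_bound=hi_flag)
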