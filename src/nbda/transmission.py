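"""Estimated proportion of acquisitions attributable to social transmission.

For each non-innovation acquisition event the fitted model implies a
probability that the event happened through the social pathway rather than
asocially.  Writing A for the asocial component of the acquirer's relative
hazard and S for its social input at acquisition:

- linear forms:      p = s*S / (s*S + A)
  (numerator: rate of social transmission relative to asocial learning;
  denominator: total relative rate)
- log-linear forms:  p = (e^{s*S + lp} - e^{lp}) / e^{s*S + lp} = 1 - e^{-s*S}
  (total rate at acquisition minus the asocial expectation, over the total
  rate; multiplicative ILV terms cancel from the ratio)

Averaging p over all events after the first gives the estimated % of
acquisitions by social transmission, excluding the innovation, which by
definition was not social.  A negative social effect (log-linear s < 0)
would give p < 0; such events are counted as zero social transmission.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from nbda.oada import EventDesign, FitResult, _hazard_vec

__all__ = ["prop_social_event", "prop_social_total", "attribution_table"]


def _p_social(form: str, interaction: str, s: float, S: float, lp: float) -> float:
    if S == 0 or s == 0:
        return 0.0
    if form == "log_linear":
        if interaction == "additive":
            total = np.expm1(s * S) + np.exp(lp)
            p = np.expm1(s * S) / total if total > 0 else 0.0
        else:
            p = -np.expm1(-s * S)
    else:
        asocial = np.exp(lp)
        if interaction == "additive":
            p = s * S / (s * S + asocial)
        else:
            # (sS + 1)e^lp total; asocial part e^lp
            p = s * S / (s * S + 1.0)
    return float(min(max(p, 0.0), 1.0))  # negative s -> counted as zero social events


def prop_social_event(fit: FitResult, event: EventDesign) -> float:
    """P(event occurred by social transmission) under the fitted model."""
    s = fit.params.s.get(event.behavior, 0.0)
    beta = np.array([fit.params.beta.get(c, 0.0) for c in fit.spec.ilvs])
    lp = float(event.X[event.acquirer] @ beta) if len(fit.spec.ilvs) else 0.0
    return _p_social(fit.spec.form, fit.spec.ilv_interaction, s,
                     float(event.S[event.acquirer]), lp)


def _behavior_events(fit: FitResult, behavior: str) -> list[EventDesign]:
    if fit.design is None:
        raise ValueError("fit carries no design; refit with fit_oada to attribute events")
    return [e for e in fit.design.events if e.behavior == behavior and e.included]


def prop_social_total(fit: FitResult, behavior: str, s_override: float | None = None) -> float:
    """% of acquisitions by social transmission, averaged over events l > 1.

    ``s_override`` substitutes a different transmission strength (e.g. a
    profile-CI endpoint) while keeping everything else from the fit, so
    interval endpoints for the percentage can be reported alongside it.
    """
    events = [e for e in _behavior_events(fit, behavior) if e.order > 1]
    if not events:
        raise ValueError(f"behavior {behavior!r} has no non-innovation acquisition events")
    s = fit.params.s.get(behavior, 0.0) if s_override is None else s_override
    beta = np.array([fit.params.beta.get(c, 0.0) for c in fit.spec.ilvs])
    ps = []
    for ev in events:
        lp = float(ev.X[ev.acquirer] @ beta) if len(fit.spec.ilvs) else 0.0
        ps.append(_p_social(fit.spec.form, fit.spec.ilv_interaction, s,
                            float(ev.S[ev.acquirer]), lp))
    return 100.0 * float(np.mean(ps))


def attribution_table(fit: FitResult, behaviors: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-event attribution: individual, behavior, order, S at acquisition, p_social."""
    if fit.design is None:
        raise ValueError("fit carries no design")
    behaviors = list(behaviors) if behaviors is not None else list(fit.design.behaviors)
    rows = []
    for b in behaviors:
        for ev in _behavior_events(fit, b):
            rows.append({
                "individual": ev.individual,
                "behavior": b,
                "order": ev.order,
                "S_at_acquisition": float(ev.S[ev.acquirer]),
                "p_social": 0.0 if ev.order == 1 else prop_social_event(fit, ev),
            })
    return pd.DataFrame(rows)


def write_attribution_csv(fit: FitResult, path: str | Path) -> None:
    attribution_table(fit).to_csv(path, index=False)
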