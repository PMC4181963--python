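# Methods

## Scope and data model

The package analyses *diffusions*: the spread of one or more novel
behaviors through a closed, individually identified group under continuous
observation at a focal site.  The primary record is the observation event —
one performance of a target behavior with a timestamp, a performer and the
set of individuals coded as its audience.  Two audience criteria can
coexist in one log: a permissive one (close enough with an unobstructed
view) and a strict one (actively watching); rows are tagged and the reader
filters on either, so the robustness of any result to the audience
judgment can be checked by re-running with `criterion="strict"`.

Acquisition is defined operationally as the first recorded performance.
Individuals that never perform are right-censored; they still contribute to
OADA risk sets and to TADA survival terms.  Exact ties in first-performance
times are refused unless the log carries an explicit `order_hint` column:
the order-based likelihood is meaningless under an arbitrary tie-break, and
silently guessing one would bias it.  Timestamps are continuous study-clock
values; any wall-clock-to-study-clock conversion happens upstream.

## Networks

An edge a(X→Y) counts occasions on which X observed Y performing the target
behavior **strictly before X acquired it** ("prior to" is `<`, not `<=`: an
observation cannot influence a simultaneous acquisition).  The
pre-acquisition filter is causal and also guards against homophily —
without it, knowledgeable individuals seeking each other's company after
learning would inflate apparent transmission.  Networks are strictly
per-behavior: watching one behavior never enters another behavior's
network, since the diffusions are modelled as independent.

Three modes are supported: `static` (counts aggregated over the study),
`dynamic_count` (a(X,Y,t) = qualifying observations before t, a
right-continuous step function), and `dynamic_binary` (1 once at least one
observation has occurred, for the hypothesis that a single observation
saturates the social effect; it is specified with the log-linear form so
the social term is exp(s·#models observed)).  The dynamic count at t→∞
equals the static weight by construction, and the binary network is the
thresholded count network — both are asserted by tests.

## Likelihoods

**OADA.** At acquisition event *l* the probability that the observed
acquirer *m* was the one to learn is R_m(t_l)/Σ_{naive i} R_i(t_l); the
baseline cancels, which is why OADA is preferred when the site's
attractiveness fluctuates (weather, competition) in ways no parametric
baseline would capture.  The joint log-likelihood sums event terms over all
behaviors.  Each behavior's innovation event is included as a risk-set
event by default: with no informed individuals the social term is zero for
everyone, so the term is constant in s but informative about ILVs
(`innovation_in_likelihood=False` drops these terms for comparison with
conventions that exclude them).  Excluding a named acquisition event — for
re-analyses where an acquisition is suspected to have occurred through a
pathway the network does not capture, e.g. learning from a discarded
artefact rather than from watching — removes exactly that event's term
while the individual still becomes informed at its recorded time.

**TADA.** The full survival likelihood on the on-site clock τ (piecewise
linear in study time: slope 1 during presence intervals, 0 outside, zero at
the first interval's start).  Acquirers contribute
ln λ0(τ_m) + ln R_m(τ_m); every individual contributes minus the integrated
hazard over its naive period.  R_i(τ) is piecewise constant between
acquisitions and network steps, so the integral is computed exactly
segment by segment; a test checks it against an independent
piecewise sweep to 1e-6.  Baseline families: constant, and Weibull
λ0·γ·τ^(γ−1) for a baseline that systematically rises (γ>1) or falls
(γ<1) over the study — the natural two-parameter family that nests the
constant case at γ=1 (asserted to 1e-10).  The censoring horizon is the end
of the last presence interval.

**Functional forms.** Linear and log-linear transmission, each with
additive or multiplicative ILV interaction (table in the README).  The
linear form constrains s ≥ 0 (the hazard must stay positive); log-linear s
is unconstrained, so a per-observation multiplier exp(s) below 1 — each
observation *slowing* learning — is expressible, and confidence intervals
for multipliers may straddle 1.  The log-linear additive-ILV variant is
defined here as R = (exp(s·S) − 1) + exp(Σβx): the social increment
vanishes at S = 0, the form nests the no-ILV model, and it reduces to the
multiplicative variant when no ILVs are present.  Other conventions for
this (rarely preferred) variant exist; it is isolated behind
`ilv_interaction="additive"` and none of the headline outputs depend on it.

## Fitting and inference

Maximum likelihood via bounded L-BFGS-B from five jittered starts
(deterministic given the seed); baseline rate and Weibull shape are
optimized on the log scale.  Standard errors come from the inverse observed
information (central-difference Hessian); a non-invertible Hessian is
flagged per fit (`hessian_ok=False`) rather than fatal, and model averaging
lets the caller choose whether such models raise, contribute zero variance,
or are dropped with renormalized weights.

AICc uses n = the number of acquisition events entering the likelihood
(across all behaviors, minus exclusions).  This is a convention — the
method's literature does not fix an effective sample size for AICc — and n
is carried on every `FitResult` so alternatives can be recomputed.  Model
grids deduplicate models that coincide: a no-ILV model counts once although
it qualifies as both an additive and a multiplicative model, and a single
asocial model per ILV subset serves every network mode and form.  The
default grid pairs the static network with the linear form only and the
log-linear form with the dynamic networks, mirroring the model family the
method was introduced with; beyond fidelity there is a statistical reason
to keep unconstrained log-linear s away from static weights.  A static
weight aggregates the observer's entire pre-acquisition history, so on a
near-complete diffusion individuals who acquire *late* carry large weights
already at early events, and a negative s can "predict" the acquisition
order from its own consequence — a reversed-causality artifact the
time-indexed network is immune to.  The combination remains constructible
by hand via `ModelSpec` for users who want it.
Hypothesis-class supports are computed within each network mode's
comparison set; dynamic and static sets are pooled only for the
dynamic-vs-static support ratio.

Model-averaged transmission effects use the shrinkage convention by default
(models without the parameter contribute an estimate of 0 at their weight),
with the unconditional standard error
SE = Σ w_i sqrt(var_i + (θ_i − θ̄)²) and a Wald interval.  Profile-likelihood
intervals re-optimize all nuisance parameters at each probe and place
endpoints where the profile drops by χ²₁(0.95)/2 = 1.9207; an endpoint that
hits a parameter bound (e.g. s = 0 under the linear form) or never crosses
the cutoff is reported at the bound / search limit and flagged one-sided.
Reported effect scale: exp(ŝ) (per-observation multiplier) for log-linear
fits, ŝ itself for linear fits.

The % of acquisitions by social transmission is the mean over
non-innovation events of the per-event social probability (README formulas;
multiplicative ILV terms cancel from the log-linear ratio).  Negative
probabilities from ŝ < 0 are counted as zero social events.  Interval
endpoints for the percentage are obtained by plugging the profile-CI
endpoints of s into the same estimator, pairing the reported percentage
with its s-interval.

## Simulator

The generator mirrors the fitted model so that recovery experiments are
exact model-in-model checks: naive individuals present at the site learn at
λ0·(baseline shape)·f(s, n_i(t))·exp(Σβx), informed present individuals
perform as a Poisson process (rate 1/h by default), and every performance —
including the first performance that marks an acquisition — is logged with
an audience drawn from the rest of the party (default: 1 + Poisson(2)
close-range onlookers, mirroring small coded audiences; a strict
sub-audience is retained at rate 0.7 per observer).  Simulation is
continuous-time Gillespie with Ogata thinning when the baseline is
non-constant.  The default configuration emulates the target study's
scale: 30 individuals, 6 days × 6 one-hour visit blocks, two behaviors with
s_true = {ln 15, 0}, λ0 = 0.02/h on site, and a routine-behavior stream
(label "LS", 2 bouts/h per individual) from which exposure scores are
computed.  By default the whole group attends every visit block; partial
parties are available through `party_size_dist` but are not the default,
because the order-based likelihood places every naive individual in every
risk set and calibration experiments should satisfy the model's own
assumptions.

What the simulator does *not* emulate: kinship and rank structure in who
watches whom, observer recording error (missed or spurious observers),
inter-behavior interference, and environmental fluctuation of motivation.
Passing recovery tests therefore show the estimator is correct *under the
model*; they cannot show robustness to coding error or unmodelled
heterogeneity in real field data.

Transmission factors are capped at 1e12× baseline: beyond that the waiting
time to the next acquisition falls below the floating-point resolution of
the clock, and event times are nudged by one ulp where needed to keep the
log strictly ordered.

## Problem sizes and numerical choices

Test-suite and acceptance-script experiment sizes were chosen as the
smallest that make the statistical assertions stable: 20 datasets × 4
parameter values for oracle agreement (tolerance 1e-8; observed ~1e-13),
200 replicates for recovery and interval coverage at study scale, 60
replicates for specificity, 30–40 for the TADA recovery and
OADA/TADA-concordance checks.  Optimizer tolerances: ftol 1e-12 on the
objective, gtol 1e-9; profile endpoints solved to 1e-8.  Degenerate inputs
are refused loudly: empty risk sets, acquisitions at zero elapsed
observation time (undefined exposure rate), zero-variance covariates,
simultaneous acquisitions without an order hint.

## Known limitations

- The % social transmission interval is a plug-in of the s-interval, not a
  full delta-method or bootstrap interval for the percentage itself.
- TADA inference is conditional on the chosen baseline family; only
  constant and Weibull are built in.
- Asocial and social models are compared within the AICc framework only;
  no likelihood-ratio boundary corrections (for s on the linear-form
  boundary) are applied.
- The OADA risk set always contains every naive group member; absence from
  the site at an event time is not modelled in OADA (it is in TADA, through
  the on-site clock, but only group-level presence, not per-individual).
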