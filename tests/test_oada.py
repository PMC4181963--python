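import math

import numpy as np
import pytest

from conftest import brute_force_oada_loglik, cox_partial_loglik, small_sim
from nbda.networks import build_dynamic, build_static
from nbda.oada import (
    ModelSpec,
    OadaDesign,
    Params,
    build_networks,
    fit_oada,
    oada_event_loglik,
    oada_loglik,
    relative_hazard,
)


def design_for(ds, **spec_kw):
    return OadaDesign(ModelSpec(**spec_kw), ds)


class TestRelativeHazard:
    def test_asocial_reduction_gives_unit_hazard(self, abc_dataset):
        nets = build_networks(abc_dataset, "dynamic_count")
        spec = ModelSpec(transmission="shared_s")
        for i in ("B", "C"):
            r = relative_hazard(spec, Params(s={"M": 0.0}), i, 4.5, "M", nets, {"A"})
            assert r == pytest.approx(1.0)

    def test_log_linear_single_observation_multiplies_by_exp_s(self, abc_dataset):
        nets = build_networks(abc_dataset, "dynamic_count")
        spec = ModelSpec(form="log_linear")
        s = 0.7
        r0 = relative_hazard(spec, Params(s={"M": s}), "B", 1.5, "M", nets, {"A"})  # S=0
        r1 = relative_hazard(spec, Params(s={"M": s}), "B", 2.5, "M", nets, {"A"})  # S=1
        assert r1 / r0 == pytest.approx(math.exp(s))

    def test_log_linear_closed_form(self, abc_dataset):
        nets = build_networks(abc_dataset, "dynamic_count")
        spec = ModelSpec(form="log_linear")
        r = relative_hazard(spec, Params(s={"M": 0.5}), "B", 4.5, "M", nets, {"A"})  # S=3
        assert r == pytest.approx(math.exp(1.5))

    def test_linear_form_rejects_negative_s(self, abc_dataset):
        nets = build_networks(abc_dataset, "static")
        spec = ModelSpec(network_mode="static", form="linear")
        with pytest.raises(ValueError):
            relative_hazard(spec, Params(s={"M": -1.0}), "B", 4.5, "M", nets, {"A"})


class TestEventLoglik:
    def test_single_naive_individual_certain(self, abc_dataset):
        design = design_for(abc_dataset)
        last = design.events[-1]
        assert len(last.risk_ids) == 1
        assert oada_event_loglik(design.spec, Params(s={"M": 2.0}), last) == pytest.approx(0.0)

    def test_asocial_uniform_over_risk_set(self, two_behavior_toy):
        design = design_for(two_behavior_toy, transmission="asocial")
        first = design.events[0]
        assert oada_event_loglik(design.spec, Params(), first) == pytest.approx(math.log(1 / 4))

    def test_dynamic_network_distinguishes_b_from_c(self, abc_dataset):
        """At B's acquisition the dynamic model gives B its 3 prior observations."""
        design = design_for(abc_dataset, form="log_linear")
        ev_b = next(e for e in design.events if e.individual == "B")
        ll = oada_event_loglik(design.spec, Params(s={"M": 1.0}), ev_b)
        e3 = math.exp(3.0)
        assert ll == pytest.approx(math.log(e3 / (e3 + 1.0)), abs=1e-9)
        assert ll == pytest.approx(-0.04859, abs=1e-5)

    def test_static_network_cannot_distinguish(self, abc_dataset):
        """Static links of strength 3 to both B and C predict a coin flip."""
        design = design_for(abc_dataset, network_mode="static", form="log_linear")
        ev_b = next(e for e in design.events if e.individual == "B")
        ll = oada_event_loglik(design.spec, Params(s={"M": 1.0}), ev_b)
        assert ll == pytest.approx(math.log(0.5))

    def test_probability_normalization_across_possible_acquirers(self, sim_dataset):
        design = design_for(sim_dataset, form="log_linear")
        params = Params(s={"M": 0.8})
        for ev in design.events:
            probs = []
            for pos in range(len(ev.risk_ids)):
                shuffled = type(ev)(ev.behavior, ev.risk_ids[pos], ev.order, ev.time,
                                    ev.risk_ids, pos, ev.S, ev.X, True)
                probs.append(math.exp(oada_event_loglik(design.spec, params, shuffled)))
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_common_ilv_shift_cancels(self, sim_dataset):
        """A constant added to every linear predictor is a baseline rescaling."""
        spec = ModelSpec(form="log_linear", ilvs=("age",))
        design = OadaDesign(spec, sim_dataset)
        ev = design.events[2]
        ev_shifted = type(ev)(ev.behavior, ev.individual, ev.order, ev.time,
                              ev.risk_ids, ev.acquirer, ev.S, ev.X + 5.0, True)
        p = Params(s={"M": 0.5}, beta={"age": 0.3})
        assert oada_event_loglik(spec, p, ev) == pytest.approx(
            oada_event_loglik(spec, p, ev_shifted), abs=1e-10)

    def test_probability_increases_with_acquirer_social_input(self, abc_dataset):
        design = design_for(abc_dataset, form="log_linear")
        ev = next(e for e in design.events if e.individual == "B")
        lls = []
        for extra in (0.0, 1.0, 2.0):
            S = ev.S.copy()
            S[ev.acquirer] += extra
            bumped = type(ev)(ev.behavior, ev.individual, ev.order, ev.time,
                              ev.risk_ids, ev.acquirer, S, ev.X, True)
            lls.append(oada_event_loglik(design.spec, Params(s={"M": 0.5}), bumped))
        assert lls[0] < lls[1] < lls[2]


class TestJointLoglik:
    @pytest.mark.parametrize("network_mode,form,interaction", [
        ("dynamic_count", "log_linear", "multiplicative"),
        ("dynamic_count", "log_linear", "additive"),
        ("dynamic_count", "linear", "additive"),
        ("dynamic_count", "linear", "multiplicative"),
        ("dynamic_binary", "log_linear", "multiplicative"),
        ("static", "log_linear", "multiplicative"),
        ("static", "linear", "additive"),
    ])
    def test_matches_brute_force_enumeration(self, two_behavior_toy, network_mode, form, interaction):
        ds = two_behavior_toy
        spec = ModelSpec(network_mode=network_mode, form=form,
                         ilv_interaction=interaction, transmission="separate_s")
        s_map = {"M": 0.9, "R": 0.4}
        ll = oada_loglik(spec, Params(s=s_map), ds)
        oracle = brute_force_oada_loglik(ds, s_map, form=form, interaction=interaction,
                                         network_mode=network_mode)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_matches_brute_force_on_simulated_group(self):
        ds, _ = small_sim(3, n_individuals=6)
        spec = ModelSpec(form="log_linear", transmission="shared_s")
        for s in (0.0, 0.5, 1.5):
            ll = oada_loglik(spec, Params(s={"M": s}), ds)
            assert ll == pytest.approx(brute_force_oada_loglik(ds, {"M": s}), abs=1e-10)

    def test_excluding_event_removes_exactly_its_term(self, two_behavior_toy):
        ds = two_behavior_toy
        base_spec = ModelSpec(form="log_linear", transmission="shared_s")
        design = OadaDesign(base_spec, ds)
        params = Params(s={"M": 0.7, "R": 0.7})
        target = next(e for e in design.events if e.behavior == "M" and e.order == 3)
        term = oada_event_loglik(base_spec, params, target)
        excl_spec = ModelSpec(form="log_linear", transmission="shared_s",
                              excluded_events=frozenset({(target.individual, "M")}))
        assert oada_loglik(excl_spec, params, ds) == pytest.approx(
            oada_loglik(base_spec, params, ds) - term, abs=1e-10)

    def test_shared_and_separate_s_coincide_at_equal_values(self, two_behavior_toy):
        ds = two_behavior_toy
        shared = oada_loglik(ModelSpec(transmission="shared_s"), Params(s={"M": 0.6, "R": 0.6}), ds)
        sep = oada_loglik(ModelSpec(transmission="separate_s"), Params(s={"M": 0.6, "R": 0.6}), ds)
        assert shared == pytest.approx(sep, abs=1e-12)

    def test_innovation_flag_drops_first_event_terms(self, two_behavior_toy):
        ds = two_behavior_toy
        params = Params(s={"M": 0.3, "R": 0.3})
        with_innov = oada_loglik(ModelSpec(), params, ds)
        without = oada_loglik(ModelSpec(innovation_in_likelihood=False), params, ds)
        # no-ILV innovations are uniform over the full risk set of 4
        assert with_innov - without == pytest.approx(2 * math.log(1 / 4), abs=1e-10)


class TestCoxEquivalence:
    def test_log_linear_dynamic_equals_partial_likelihood(self):
        ds, _ = small_sim(11, n_individuals=10)
        spec = ModelSpec(network_mode="dynamic_count", form="log_linear")
        for s in (-0.3, 0.0, 0.4, 1.2):
            ours = oada_loglik(spec, Params(s={"M": s}), ds)
            cox = cox_partial_loglik(ds, "M", s)
            assert ours == pytest.approx(cox, abs=1e-8)


class TestFit:
    def test_asocial_no_ilv_has_no_free_parameters(self, two_behavior_toy):
        fit = fit_oada(ModelSpec(transmission="asocial"), two_behavior_toy)
        assert fit.k == 0
        assert fit.converged
        # uniform risk-set probabilities: 1/4 * 1/3 * 1/2 * 1 per behavior
        assert fit.loglik == pytest.approx(2 * math.log(1 / 24), abs=1e-12)

    def test_nested_model_never_beats_parent(self):
        ds, _ = small_sim(19, n_individuals=12, behaviors=("M", "R"),
                          s_true={"M": 1.0, "R": 0.2})
        shared = fit_oada(ModelSpec(transmission="shared_s"), ds, seed=1)
        separate = fit_oada(ModelSpec(transmission="separate_s"), ds, seed=1)
        asocial = fit_oada(ModelSpec(transmission="asocial"), ds, seed=1)
        assert asocial.loglik <= shared.loglik + 1e-6
        assert shared.loglik <= separate.loglik + 1e-6

    def test_mle_beats_neighbouring_values(self):
        ds, _ = small_sim(23, n_individuals=10)
        fit = fit_oada(ModelSpec(form="log_linear"), ds, seed=2)
        s_hat = fit.params.s["M"]
        for delta in (-0.2, 0.2):
            assert oada_loglik(fit.spec, Params(s={"M": s_hat + delta}), ds) <= fit.loglik + 1e-9

    def test_null_truth_cis_cover_no_effect(self):
        """With no true social effect, the profile CI for the per-observation
        multiplier exp(s) contains 1 in about 95% of replicates."""
        from nbda.simulate import SimulationConfig, recovery_experiment

        cfg = SimulationConfig(n_individuals=30, behaviors=("M",), s_true={"M": 0.0},
                               baseline_behavior=None, seed=1)
        res = recovery_experiment(cfg, reps=50, profile=True)
        ok = res.dropna(subset=["covered:M"])
        assert len(ok) >= 45
        assert ok["covered:M"].mean() >= 0.9

    def test_fit_with_ilvs_runs_and_reports_se(self):
        ds, _ = small_sim(29, n_individuals=12)
        fit = fit_oada(ModelSpec(form="log_linear", ilvs=("age", "sex")), ds, seed=3)
        assert set(fit.param_names) == {"s", "beta:age", "beta:sex"}
        if fit.hessian_ok:
            assert all(v > 0 for v in fit.se.values())
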