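"""Generative-model terms: stage priors, marginal likelihood, joint density."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mirvb.model_core import (
    Hyperparameters,
    LatentState,
    ModelConfig,
    candidate_mirs_of,
    interaction_prior_logdensity,
    joint_log_density,
    mir_stage_prior,
    mrna_stage_prior,
    observation_loglik,
)
from mirvb.ordering import PartialOrder
from mirvb.predictions import PredictionSet
from mirvb.preprocessing import ExpressionDataset, ExpressionMatrix

HYPER = Hyperparameters()


def small_state(order, predictions, rng=None):
    """A complete random-but-fixed LatentState for 2 miRs, 2 genes."""
    rng = rng or np.random.default_rng(42)
    mirs, genes = ["m1", "m2"], ["g1", "g2"]
    edges = order.edges()
    return LatentState(
        x={(m, s): float(rng.normal()) for m in mirs for s in order.stages},
        y={(g, s): float(rng.normal()) for g in genes for s in order.stages},
        tau={m: float(rng.normal(0, 0.3)) for m in mirs},
        lambda_mir={m: 2.0 for m in mirs},
        lambda_mrna={g: 3.0 for g in genes},
        delta_mir={e: 0.8 for e in edges},
        delta_mrna={e: 1.3 for e in edges},
        r={p: float(rng.normal(-0.4, 0.2)) for p in predictions.pairs()},
        beta=np.array([-0.2, 0.5]),
        phi_r=4.0,
        phi_set_mir=10.0,
        phi_rep_mir=20.0,
        phi_set_mrna=10.0,
        phi_rep_mrna=20.0,
    )


def chain3():
    order = PartialOrder(
        ("A", "B", "C"),
        {"B": frozenset("A"), "C": frozenset("B")},
        {"A": ("sA",), "B": ("sB",), "C": ("sC",)},
    )
    predictions = PredictionSet(
        ["alg"],
        {("m1", "g1"): {"alg": -0.5}, ("m2", "g1"): {"alg": -0.1},
         ("m1", "g2"): {"alg": -0.9}},
    )
    return order, predictions


class TestMirStagePrior:
    def make(self, **kw):
        order, predictions = chain3()
        state = small_state(order, predictions)
        for k, v in kw.items():
            setattr(state, k, v)
        return order, state

    def test_single_parent_formula(self):
        order, state = self.make()
        state.x[("m1", "A")] = 1.0
        state.tau["m1"] = 0.5
        state.delta_mir[("A", "B")] = 2.0
        mean, prec = mir_stage_prior("m1", "B", state, order)
        assert mean == pytest.approx(1.0 + 0.5 * 2.0)
        assert prec == pytest.approx(state.lambda_mir["m1"] / 2.0)

    def test_two_equal_parents_average(self):
        order = PartialOrder(
            ("A", "B", "C"), {"C": frozenset({"A", "B"})}, {s: () for s in "ABC"}
        )
        _, predictions = chain3()
        state = small_state(order, predictions)
        state.x[("m1", "A")], state.x[("m1", "B")] = 3.0, 7.0
        state.tau["m1"] = 0.0
        state.delta_mir = {("A", "C"): 1.5, ("B", "C"): 1.5}
        mean, _ = mir_stage_prior("m1", "C", state, order)
        assert mean == pytest.approx(5.0)

    def test_distant_parent_influence_vanishes(self):
        order = PartialOrder(
            ("A", "B", "C"), {"C": frozenset({"A", "B"})}, {s: () for s in "ABC"}
        )
        _, predictions = chain3()
        state = small_state(order, predictions)
        state.x[("m1", "A")], state.x[("m1", "B")] = 100.0, 1.0
        state.tau["m1"] = 0.0
        state.delta_mir = {("A", "C"): 1e6, ("B", "C"): 1.0}
        mean, prec = mir_stage_prior("m1", "C", state, order)
        assert mean == pytest.approx(1.0, abs=1e-3)
        # precision is dominated by the near parent, barely above lambda
        assert prec == pytest.approx(state.lambda_mir["m1"], rel=1e-5)

    def test_initial_stage_vague_prior(self):
        order, state = self.make()
        mean, prec = mir_stage_prior("m1", "A", state, order)
        assert (mean, prec) == (0.0, HYPER.normal_prior_precision)

    def test_precision_increases_as_any_delta_shrinks(self):
        order, state = self.make()
        _, p1 = mir_stage_prior("m1", "B", state, order)
        state.delta_mir[("A", "B")] /= 2
        _, p2 = mir_stage_prior("m1", "B", state, order)
        assert p2 > p1

    def test_parent_weights_are_convex(self):
        # mean with zero trend lies between the parent values
        order = PartialOrder(
            ("A", "B", "C"), {"C": frozenset({"A", "B"})}, {s: () for s in "ABC"}
        )
        _, predictions = chain3()
        state = small_state(order, predictions)
        state.tau["m1"] = 0.0
        state.delta_mir = {("A", "C"): 0.4, ("B", "C"): 2.5}
        a, b = state.x[("m1", "A")], state.x[("m1", "B")]
        mean, _ = mir_stage_prior("m1", "C", state, order)
        assert min(a, b) - 1e-12 <= mean <= max(a, b) + 1e-12


class TestMrnaStagePrior:
    def test_zero_interactions_reduce_to_trendless_mir_form(self):
        order, predictions = chain3()
        state = small_state(order, predictions)
        state.r = {p: 0.0 for p in state.r}
        state.tau = {m: 0.0 for m in state.tau}
        state.delta_mir = dict(state.delta_mrna)
        state.lambda_mir = {"m1": state.lambda_mrna["g1"], "m2": 1.0}
        state.x[("m1", "A")] = state.y[("g1", "A")]
        m_mean, m_prec = mir_stage_prior("m1", "B", state, order)
        g_mean, g_prec = mrna_stage_prior("g1", "B", state, order, predictions)
        assert g_mean == pytest.approx(m_mean)
        assert g_prec == pytest.approx(m_prec)

    def test_single_parent_interaction_offset(self):
        order, predictions = chain3()
        state = small_state(order, predictions)
        state.y[("g1", "A")] = 0.0
        state.delta_mrna[("A", "B")] = 1.0
        mirs = candidate_mirs_of(predictions, "g1")
        dot = sum(state.r[(m, "g1")] * state.x[(m, "B")] for m in mirs)
        mean, _ = mrna_stage_prior("g1", "B", state, order, predictions)
        assert mean == pytest.approx(dot)

    def test_two_parent_hand_formula(self):
        order = PartialOrder(
            ("A", "B", "C"), {"C": frozenset({"A", "B"})}, {s: () for s in "ABC"}
        )
        _, predictions = chain3()
        state = small_state(order, predictions)
        d = 1.7
        state.delta_mrna = {("A", "C"): d, ("B", "C"): d}
        a, b = state.y[("g1", "A")], state.y[("g1", "B")]
        mirs = candidate_mirs_of(predictions, "g1")
        dot = sum(state.r[(m, "g1")] * state.x[(m, "C")] for m in mirs)
        mean, _ = mrna_stage_prior("g1", "C", state, order, predictions)
        assert mean == pytest.approx((a + b) / 2.0 + dot * d)


def two_set_dataset(values_by_set, stage="A"):
    """One probe per platform, several sets of replicates at one stage."""
    obs, rows, vals = [], [], []
    for si, reps in enumerate(values_by_set):
        for ri, v in enumerate(reps):
            o = f"set{si}_r{ri}"
            obs.append(o)
            vals.append(v)
            rows.append(
                {"observation_id": o, "sample_id": f"set{si}", "stage": stage,
                 "set_id": f"set{si}", "replicate_id": f"r{ri}"}
            )
    frame = pd.DataFrame([vals], index=["m1"], columns=obs)
    gframe = pd.DataFrame([vals], index=["g1"], columns=obs)
    return ExpressionDataset(
        mir=ExpressionMatrix(frame, "miR"),
        mrna=ExpressionMatrix(gframe, "mRNA"),
        design=pd.DataFrame(rows),
    )


def single_stage_state(mu=0.7, phi_set=3.0, phi_rep=5.0):
    return LatentState(
        x={("m1", "A"): mu}, y={("g1", "A"): mu},
        tau={"m1": 0.0}, lambda_mir={"m1": 1.0}, lambda_mrna={"g1": 1.0},
        delta_mir={}, delta_mrna={}, r={}, beta=np.zeros(2),
        phi_r=1.0, phi_set_mir=phi_set, phi_rep_mir=phi_rep,
        phi_set_mrna=phi_set, phi_rep_mrna=phi_rep,
    )


class TestObservationLoglik:
    def test_matches_quadrature_over_set_latents(self):
        rng = np.random.default_rng(7)
        sets = [list(rng.normal(0.5, 1.0, 3)) for _ in range(2)]
        data = two_set_dataset(sets)
        state = single_stage_state(mu=0.4, phi_set=2.0, phi_rep=6.0)

        def set_marginal(reps, mu, ps, pr):
            def integrand(u):
                lik = np.prod(stats.norm.pdf(reps, loc=u, scale=pr**-0.5))
                return lik * stats.norm.pdf(u, loc=mu, scale=ps**-0.5)

            # center on the conditional mode of the set latent, otherwise
            # the quadrature can step over the narrow likelihood peak
            k = reps.size
            center = (ps * mu + pr * reps.sum()) / (ps + k * pr)
            width = 10.0 / math.sqrt(ps + k * pr)
            val, _ = integrate.quad(
                integrand, center - width, center + width, limit=200
            )
            return math.log(val)

        expected = 2 * sum(
            set_marginal(np.array(s), 0.4, 2.0, 6.0) for s in sets
        )  # same values on both platforms
        assert observation_loglik(data, state) == pytest.approx(expected, abs=1e-8)

    def test_infinite_set_precision_collapses_to_replicate_noise(self):
        sets = [[0.1, 0.6, -0.2]]
        data = two_set_dataset(sets)
        tight = single_stage_state(mu=0.2, phi_set=1e12, phi_rep=4.0)
        expected = 2 * float(
            stats.norm.logpdf(np.array(sets[0]), loc=0.2, scale=0.5).sum()
        )
        assert observation_loglik(data, tight) == pytest.approx(expected, abs=1e-6)

    def test_unmapped_stage_is_an_error(self):
        data = two_set_dataset([[0.0, 0.1]])
        state = single_stage_state()
        state.x = {("m1", "ZZ"): 0.0}
        with pytest.raises(ValueError, match="stage"):
            observation_loglik(data, state)


class TestInteractionPrior:
    def test_mean_is_feature_dot_coefficients(self):
        ps = PredictionSet(["a", "b"], {("m", "g"): {"a": -0.5}})
        c = ps.feature_vector(("m", "g"))
        beta = np.array([-1.0, 2.0, 0.0, 0.0])
        dens_at_mean = interaction_prior_logdensity(-2.0, c, beta, 4.0)
        assert dens_at_mean == pytest.approx(
            float(stats.norm.logpdf(0.0, scale=0.5))
        )

    def test_zero_coefficients_center_at_zero(self):
        ps = PredictionSet(["a"], {("m", "g"): {"a": -0.5}})
        c = ps.feature_vector(("m", "g"))
        assert interaction_prior_logdensity(
            0.0, c, np.zeros(2), 1.0
        ) == pytest.approx(float(stats.norm.logpdf(0.0)))

    def test_density_integrates_to_one(self):
        ps = PredictionSet(["a"], {("m", "g"): {"a": -0.7}})
        c = ps.feature_vector(("m", "g"))
        beta = np.array([0.3, -1.1])
        val, _ = integrate.quad(
            lambda r: math.exp(interaction_prior_logdensity(r, c, beta, 2.5)),
            -15, 15,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_dimension_mismatch(self):
        ps = PredictionSet(["a"], {("m", "g"): {"a": -0.7}})
        with pytest.raises(ValueError, match="mismatch"):
            interaction_prior_logdensity(0.0, ps.feature_vector(("m", "g")), np.zeros(4), 1.0)


def independent_joint_density(data, state, order, predictions, hyper, config):
    """Term-by-term reimplementation with scipy.stats only (test oracle)."""
    total = observation_loglik(data, state)
    for (i, s) in state.x:
        mean, prec = mir_stage_prior(i, s, state, order, hyper, config)
        total += float(stats.norm.logpdf(state.x[(i, s)], mean, prec**-0.5))
    for (g, s) in state.y:
        mean, prec = mrna_stage_prior(g, s, state, order, predictions, hyper, config)
        total += float(stats.norm.logpdf(state.y[(g, s)], mean, prec**-0.5))
    sd0 = hyper.normal_prior_precision**-0.5
    for (m, g), r in state.r.items():
        mu = float(predictions.feature_vector((m, g)).values @ state.beta)
        total += float(stats.norm.logpdf(r, mu, state.phi_r**-0.5))
    for v in list(state.tau.values()) + list(np.asarray(state.beta)):
        total += float(stats.norm.logpdf(v, 0.0, sd0))
    gs = stats.gamma(a=hyper.gamma_shape, scale=1.0 / hyper.gamma_rate)
    for lam in list(state.lambda_mir.values()) + list(state.lambda_mrna.values()):
        total += float(gs.logpdf(lam))
    for phi in (state.phi_set_mir, state.phi_rep_mir, state.phi_set_mrna,
                state.phi_rep_mrna, state.phi_r):
        total += float(gs.logpdf(phi))
    ds = stats.gamma(a=hyper.development_shape, scale=1.0 / hyper.development_rate)
    for d in list(state.delta_mir.values()) + list(state.delta_mrna.values()):
        total += float(ds.logpdf(d))
    return total


class TestJointLogDensity:
    def build(self):
        order, predictions = chain3()
        rng = np.random.default_rng(3)
        sets = {s: [list(rng.normal(0, 1, 2))] for s in order.stages}
        obs, rows = [], []
        mir_vals, mrna_vals = [], []
        for s in order.stages:
            for si, reps in enumerate(sets[s]):
                for ri, v in enumerate(reps):
                    o = f"{s}_set{si}_r{ri}"
                    obs.append(o)
                    rows.append({"observation_id": o, "sample_id": f"s{s}",
                                 "stage": s, "set_id": f"{s}_set{si}",
                                 "replicate_id": f"r{ri}"})
        mir_vals = rng.normal(size=(2, len(obs)))
        mrna_vals = rng.normal(size=(2, len(obs)))
        # samples must be members of the order's stages
        order = PartialOrder(
            order.stages, order.parents, {s: (f"s{s}",) for s in order.stages}
        )
        data = ExpressionDataset(
            mir=ExpressionMatrix(pd.DataFrame(mir_vals, index=["m1", "m2"], columns=obs), "miR"),
            mrna=ExpressionMatrix(pd.DataFrame(mrna_vals, index=["g1", "g2"], columns=obs), "mRNA"),
            design=pd.DataFrame(rows),
        )
        state = small_state(order, predictions)
        return data, state, order, predictions

    def test_matches_independent_reimplementation(self):
        data, state, order, predictions = self.build()
        cfg = ModelConfig()
        ours = joint_log_density(data, state, order, predictions, HYPER, cfg)
        oracle = independent_joint_density(data, state, order, predictions, HYPER, cfg)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_removing_an_observation_changes_only_its_marginal_term(self):
        data, state, order, predictions = self.build()
        full = joint_log_density(data, state, order, predictions)
        drop = data.mir.observation_ids[-1]
        # removing the miR observation from a 2-replicate set leaves a 1-rep set
        reduced = ExpressionDataset(
            mir=ExpressionMatrix(data.mir.values.drop(columns=[drop]), "miR"),
            mrna=data.mrna,
            design=data.design,
        )
        partial = joint_log_density(reduced, state, order, predictions)
        delta = full - partial
        expected = observation_loglik(data, state) - observation_loglik(reduced, state)
        assert delta == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_precision_rejected(self):
        data, state, order, predictions = self.build()
        state.lambda_mir["m1"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            joint_log_density(data, state, order, predictions)

    def test_finite_for_extreme_but_positive_parameters(self):
        data, state, order, predictions = self.build()
        state.lambda_mir["m1"] = 1e8
        state.delta_mir[("A", "B")] = 1e-6
        val = joint_log_density(data, state, order, predictions)
        assert math.isfinite(val)
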