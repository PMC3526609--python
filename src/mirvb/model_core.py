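"""The generative model for partially ordered paired expression data.

Latent per-stage log expressions propagate along the stage DAG.  For a miR
``i`` at a non-initial stage ``s`` with parents ``P(s)`` and per-edge
development distances ``delta_ps``::

    mean(x_is)      = sum_p (1/delta_ps) (x_ip + tau_i delta_ps) / W_s
    precision(x_is) = lambda_i * W_s,        W_s = sum_p 1/delta_ps

so a short development (small delta) ties the child tightly to that parent,
and the per-miR trend ``tau_i`` drifts expression by ``tau_i`` per unit of
development.  mRNA expression follows the same form with the trend term
replaced by an interaction term ``r_g . x`` over the gene's candidate miRs,
where ``r_jg ~ Normal(c_jg . beta, 1/phi_r)`` centres each interaction
coefficient on a linear combination of its target-prediction features.
Observations sit under a two-level technical hierarchy: a set-level latent
(one per physical array) around the stage latent with precision ``phi_set``,
and replicate observations around the set latent with precision ``phi_rep``.

Initial stages (no parents) receive a vague ``Normal(0, alpha0)`` prior.
All precisions carry vague conjugate Gamma priors; the developments carry a
Gamma(1, 1) prior, which pins down their otherwise scale-unidentified values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from mirvb.ordering import PartialOrder
from mirvb.predictions import FeatureVector, PredictionSet
from mirvb.preprocessing import ExpressionDataset

__all__ = [
    "Hyperparameters",
    "ModelConfig",
    "LatentState",
    "mir_stage_prior",
    "mrna_stage_prior",
    "observation_loglik",
    "interaction_prior_logdensity",
    "joint_log_density",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed hyperparameters of all prior distributions.

    ``normal_prior_precision`` governs the vague normal priors on trends,
    prediction coefficients and initial-stage latents; ``gamma_shape`` /
    ``gamma_rate`` the vague gamma priors on every precision; and
    ``development_shape`` / ``development_rate`` the Gamma(1, 1) prior that
    identifies the developments.

    The precision priors default to shape 1 with a small rate (an
    exponential with mean 1000): essentially flat over the plausible range
    but *bounded* at zero.  A shape below 1 puts a density pole at zero
    precision, and because only the ratio lambda/delta is identified by the
    likelihood, that pole drives a joint collapse of the stage precisions
    and the developments toward zero under the development point updates.
    """

    normal_prior_precision: float = 0.01
    gamma_shape: float = 1.0
    gamma_rate: float = 0.001
    development_shape: float = 1.0
    development_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("normal_prior_precision", "development_shape", "development_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # gamma_shape/gamma_rate of exactly 0 (improper flat prior) is
        # permitted for oracle reductions; negative values are not.
        if self.gamma_shape < 0 or self.gamma_rate < 0:
            raise ValueError("gamma_shape and gamma_rate must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Structural choices of the model that the data cannot pin down.

    ``interaction_stage`` selects which miR expression enters the mRNA
    stage-transition term: the child-stage level (default), the parent-stage
    level, or the parent-to-child difference.  ``precision_form`` selects
    between ``lambda * sum(1/delta)`` ("sum", default: one parent at
    delta = 1 gives precision exactly lambda, and multi-parent information is
    additive) and the weighted-average form
    ``lambda * sum(1/delta^2)/sum(1/delta)`` ("wavg").
    """

    interaction_stage: Literal["child", "parent", "difference"] = "child"
    precision_form: Literal["sum", "wavg"] = "sum"
    trend_enabled: bool = True

    def __post_init__(self) -> None:
        if self.interaction_stage not in ("child", "parent", "difference"):
            raise ValueError(f"unknown interaction_stage {self.interaction_stage!r}")
        if self.precision_form not in ("sum", "wavg"):
            raise ValueError(f"unknown precision_form {self.precision_form!r}")


@dataclass
class LatentState:
    """A complete point assignment of every model parameter.

    Used by the synthetic generator and by the joint-density oracle; the
    variational engine keeps distributions instead (see
    :class:`mirvb.vb_engine.PosteriorState`).
    """

    x: dict[tuple[str, str], float]  # (miR, stage) -> latent log expression
    y: dict[tuple[str, str], float]  # (gene, stage) -> latent log expression
    tau: dict[str, float]  # miR -> trend
    lambda_mir: dict[str, float]  # miR -> stage-wise precision
    lambda_mrna: dict[str, float]  # gene -> stage-wise precision
    delta_mir: dict[tuple[str, str], float]  # (parent, child) -> development
    delta_mrna: dict[tuple[str, str], float]
    r: dict[tuple[str, str], float]  # (miR, gene) -> interaction coefficient
    beta: np.ndarray  # prediction-feature coefficients
    phi_r: float
    phi_set_mir: float
    phi_rep_mir: float
    phi_set_mrna: float
    phi_rep_mrna: float

    def check_positive(self) -> None:
        for name in ("phi_r", "phi_set_mir", "phi_rep_mir", "phi_set_mrna", "phi_rep_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for d in (self.lambda_mir, self.lambda_mrna, self.delta_mir, self.delta_mrna):
            for key, val in d.items():
                if val <= 0:
                    raise ValueError(f"non-positive precision/development at {key}: {val}")


def _edge_weights(
    deltas: Mapping[tuple[str, str], float],
    parents: Sequence[str],
    child: str,
    precision_form: str,
) -> tuple[np.ndarray, float, float]:
    """Inverse-development weights into ``child``: (1/delta per parent, W, Wprec)."""
    inv = np.array([1.0 / deltas[(p, child)] for p in parents])
    w = float(inv.sum())
    wprec = w if precision_form == "sum" else float((inv**2).sum()) / w
    return inv, w, wprec


def mir_stage_prior(
    i: str,
    s: str,
    state: LatentState,
    order: PartialOrder,
    hyper: Hyperparameters = Hyperparameters(),
    config: ModelConfig = ModelConfig(),
) -> tuple[float, float]:
    """Prior (mean, precision) of the latent miR expression ``x_is``.

    Initial stages return ``(0, normal_prior_precision)``.
    """
    parents = sorted(order.parents.get(s, frozenset()))
    if not parents:
        return 0.0, hyper.normal_prior_precision
    inv, w, wprec = _edge_weights(state.delta_mir, parents, s, config.precision_form)
    xp = np.array([state.x[(i, p)] for p in parents])
    tau = state.tau[i] if config.trend_enabled else 0.0
    mean = float((inv * xp).sum() / w) + tau * len(parents) / w
    return mean, state.lambda_mir[i] * wprec


def _interaction_effect(
    g: str,
    s: str,
    parents: Sequence[str],
    inv: np.ndarray,
    w: float,
    state: LatentState,
    candidate_mirs: Sequence[str],
    config: ModelConfig,
) -> float:
    """Total interaction contribution to the mRNA prior mean at stage ``s``.

    Per parent edge the interaction input is the candidate-miR expression
    vector at the child stage, the parent stage, or their difference; the
    per-edge terms ``(r_g . v_p)`` are averaged with the same inverse-
    development weights as the parent expressions (the per-edge development
    factor cancels against its weight).
    """
    r = np.array([state.r[(m, g)] for m in candidate_mirs])
    total = 0.0
    for p in parents:
        if config.interaction_stage == "child":
            v = np.array([state.x[(m, s)] for m in candidate_mirs])
        elif config.interaction_stage == "parent":
            v = np.array([state.x[(m, p)] for m in candidate_mirs])
        else:  # difference
            v = np.array(
                [state.x[(m, s)] - state.x[(m, p)] for m in candidate_mirs]
            )
        total += float(r @ v)
    return total / w


def mrna_stage_prior(
    g: str,
    s: str,
    state: LatentState,
    order: PartialOrder,
    predictions: PredictionSet,
    hyper: Hyperparameters = Hyperparameters(),
    config: ModelConfig = ModelConfig(),
) -> tuple[float, float]:
    """Prior (mean, precision) of the latent mRNA expression ``y_gs``."""
    parents = sorted(order.parents.get(s, frozenset()))
    if not parents:
        return 0.0, hyper.normal_prior_precision
    inv, w, wprec = _edge_weights(state.delta_mrna, parents, s, config.precision_form)
    yp = np.array([state.y[(g, p)] for p in parents])
    mirs = candidate_mirs_of(predictions, g)
    effect = _interaction_effect(g, s, parents, inv, w, state, mirs, config)
    mean = float((inv * yp).sum() / w) + effect
    return mean, state.lambda_mrna[g] * wprec


def candidate_mirs_of(predictions: PredictionSet, gene: str) -> list[str]:
    """The gene's candidate miRs, in deterministic (sorted) order."""
    return sorted({m for m, g in predictions.entries if g == gene})


def _set_marginal_loglik(
    obs: np.ndarray, mu: float, phi_set: float, phi_rep: float
) -> float:
    """Exact log density of one set's replicates with the set latent integrated.

    The replicates are jointly normal with mean ``mu`` and covariance
    ``(1/phi_set) J + (1/phi_rep) I`` (normal-normal convolution).
    """
    k = obs.size
    vr = 1.0 / phi_rep
    vs = 1.0 / phi_set
    d = obs - mu
    total = float(d.sum())
    logdet = (k - 1) * math.log(vr) + math.log(vr + k * vs)
    quad = float((d**2).sum()) / vr - vs * total**2 / (vr * (vr + k * vs))
    return -0.5 * (k * LOG2PI + logdet + quad)


def observation_loglik(data: ExpressionDataset, state: LatentState) -> float:
    """Exact marginal log likelihood of all observations given stage latents.

    Set-level latents are integrated out analytically, so the value depends
    only on the stage latents and the four technical precisions.
    """
    state.check_positive()
    total = 0.0
    for platform, mat, latents, phi_set, phi_rep in (
        ("miR", data.mir, state.x, state.phi_set_mir, state.phi_rep_mir),
        ("mRNA", data.mrna, state.y, state.phi_set_mrna, state.phi_rep_mrna),
    ):
        idx = data.design.set_index(data.design["observation_id"].astype(str))
        sub = idx.loc[mat.observation_ids]
        stages = sub["stage"].astype(str)
        sets = sub["set_id"].astype(str)
        for set_id in sets.unique():
            cols = sets[sets == set_id].index.tolist()
            stage_vals = stages.loc[cols].unique()
            if len(stage_vals) != 1:
                raise ValueError(f"set {set_id!r} spans stages {list(stage_vals)}")
            stage = stage_vals[0]
            block = mat.values[cols].to_numpy(dtype=float)
            for probe, row in zip(mat.probe_ids, block):
                key = (probe, stage)
                if key not in latents:
                    raise ValueError(
                        f"no latent {platform} expression for probe {probe!r} "
                        f"at stage {stage!r}"
                    )
                total += _set_marginal_loglik(row, latents[key], phi_set, phi_rep)
    return total


def interaction_prior_logdensity(
    r_jg: float,
    c_jg: FeatureVector,
    beta: np.ndarray,
    phi_r: float,
) -> float:
    """Normal log density of an interaction coefficient under its score prior."""
    beta = np.asarray(beta, dtype=float)
    if c_jg.values.shape != beta.shape:
        raise ValueError(
            f"feature/coefficient dimension mismatch: {c_jg.values.shape} vs {beta.shape}"
        )
    if phi_r <= 0:
        raise ValueError("phi_r must be > 0")
    mean = float(c_jg.values @ beta)
    return float(stats.norm.logpdf(r_jg, loc=mean, scale=phi_r**-0.5))


def _normal_logpdf(x: float, mean: float, precision: float) -> float:
    return 0.5 * (math.log(precision) - LOG2PI) - 0.5 * precision * (x - mean) ** 2


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return float(stats.gamma.logpdf(x, a=shape, scale=1.0 / rate))


def joint_log_density(
    data: ExpressionDataset,
    state: LatentState,
    order: PartialOrder,
    predictions: PredictionSet,
    hyper: Hyperparameters = Hyperparameters(),
    config: ModelConfig = ModelConfig(),
) -> float:
    """Log joint density of data and every model parameter at a point.

    The sum of the marginal observation likelihood, all stage-prior terms,
    all interaction priors, and every hyperprior.  Serves as the independent
    accounting oracle for the variational engine's objective.
    """
    state.check_positive()
    total = observation_loglik(data, state)

    for (i, s) in state.x:
        mean, prec = mir_stage_prior(i, s, state, order, hyper, config)
        total += _normal_logpdf(state.x[(i, s)], mean, prec)
    for (g, s) in state.y:
        mean, prec = mrna_stage_prior(g, s, state, order, predictions, hyper, config)
        total += _normal_logpdf(state.y[(g, s)], mean, prec)

    for (m, g), r in state.r.items():
        total += interaction_prior_logdensity(
            r, predictions.feature_vector((m, g)), state.beta, state.phi_r
        )

    for tau in state.tau.values():
        total += _normal_logpdf(tau, 0.0, hyper.normal_prior_precision)
    for b in np.asarray(state.beta, dtype=float):
        total += _normal_logpdf(float(b), 0.0, hyper.normal_prior_precision)

    a0, b0 = hyper.gamma_shape, hyper.gamma_rate
    for lam in list(state.lambda_mir.values()) + list(state.lambda_mrna.values()):
        total += _gamma_logpdf(lam, a0, b0)
    for phi in (
        state.phi_set_mir,
        state.phi_rep_mir,
        state.phi_set_mrna,
        state.phi_rep_mrna,
        state.phi_r,
    ):
        total += _gamma_logpdf(phi, a0, b0)
    for delta in list(state.delta_mir.values()) + list(state.delta_mrna.values()):
        total += _gamma_logpdf(delta, hyper.development_shape, hyper.development_rate)
    return float(total)
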