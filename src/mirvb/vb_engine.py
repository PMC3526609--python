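"""Mean-field variational Bayes coordinate ascent for the staged model.

Every conjugate parameter (latent expressions at the stage and set levels,
trends, interaction coefficients, prediction coefficients, and all
precisions) carries a fully factorized variational factor — normal for
location parameters, gamma for precisions — updated in closed form by
coordinate ascent.  The per-edge development distances have no conjugate
form and are point-optimized once per outer iteration by bounded 1-D search
on the evidence lower bound (ELBO).  Correctly implemented, each conjugate
update and each accepted development step cannot decrease the ELBO, which
the test-suite leans on as the strongest global check of every update
equation.

The sweep order is fixed: set-level latents, stage latents x then y in
topological order, trends, interactions, prediction coefficients, and the
precisions; any order is valid for correctness, this one simply lets
information flow from the data upward before the structural parameters move.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from mirvb.model_core import LOG2PI, Hyperparameters, ModelConfig
from mirvb.ordering import PartialOrder
from mirvb.predictions import PredictionSet
from mirvb.preprocessing import ExpressionDataset

__all__ = ["PosteriorState", "FitOptions", "VBEngine", "fit", "CONJUGATE_GROUPS"]

log = logging.getLogger(__name__)

PRECISION_FLOOR = 1e-12

CONJUGATE_GROUPS = (
    "set_latents",
    "x",
    "y",
    "tau",
    "r",
    "beta",
    "phi_r",
    "lambda",
    "phi_technical",
)

FIXABLE = (
    "lambda_mir",
    "lambda_mrna",
    "phi_set_mir",
    "phi_rep_mir",
    "phi_set_mrna",
    "phi_rep_mrna",
    "phi_r",
)


@dataclass
class FitOptions:
    """Run-control options that are not part of the model itself.

    ``fixed`` pins named precision parameters (see ``FIXABLE``) at point
    values: they are excluded from updates, priors and entropies, which is
    what makes exact analytic reductions (and empirical-Bayes runs)
    possible.  ``early_stop_tol``, if set, stops when the relative ELBO
    change falls below it; the default honors a fixed iteration count.

    ``delta_warmup`` holds the developments at their initial values for the
    first few outer iterations so the conjugate factors settle before the
    point estimates commit — part of initializing the variables to
    reasonable values, and it reaches visibly better ELBO optima than
    optimizing the developments from the very first sweep.
    """

    update_developments: bool = True
    delta_warmup: int = 10
    fixed: dict[str, float] = field(default_factory=dict)
    early_stop_tol: float | None = None
    delta_bounds: tuple[float, float] = (1e-6, 1e6)

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(FIXABLE)
        if unknown:
            raise ValueError(f"cannot fix unknown parameters {sorted(unknown)}")


class _Gamma:
    """A gamma variational factor over one or more precision parameters.

    When ``fixed`` is set the factor is a point mass excluded from updates,
    prior and entropy accounting.
    """

    def __init__(self, shape, rate, n: int, fixed: float | None = None):
        self.n = n
        self.fixed = fixed
        if fixed is None:
            self.shape = np.broadcast_to(np.asarray(shape, float), (n,)).copy()
            self.rate = np.broadcast_to(np.asarray(rate, float), (n,)).copy()
        else:
            self.shape = None
            self.rate = None

    def mean(self) -> np.ndarray:
        if self.fixed is not None:
            return np.full(self.n, self.fixed)
        return self.shape / self.rate

    def mean_log(self) -> np.ndarray:
        if self.fixed is not None:
            return np.full(self.n, math.log(self.fixed))
        return special.digamma(self.shape) - np.log(self.rate)

    def set(self, shape, rate, clamp_counter: list[int]) -> None:
        if self.fixed is not None:
            return
        rate = np.broadcast_to(np.asarray(rate, float), (self.n,)).copy()
        low = rate < PRECISION_FLOOR
        if low.any():
            clamp_counter[0] += int(low.sum())
            rate[low] = PRECISION_FLOOR
        self.shape = np.broadcast_to(np.asarray(shape, float), (self.n,)).copy()
        self.rate = rate

    def entropy(self) -> float:
        if self.fixed is not None:
            return 0.0
        a, b = self.shape, self.rate
        return float(
            np.sum(a - np.log(b) + special.gammaln(a) + (1.0 - a) * special.digamma(a))
        )


@dataclass
class PosteriorState:
    """The factorized variational posterior.

    Normal factors are stored as (mean, variance) arrays; gamma factors as
    :class:`_Gamma` shape/rate pairs (or fixed points); developments as
    positive point values per DAG edge and platform.  ``elbo_trace`` holds
    one ELBO value per completed outer iteration.
    """

    mirs: list[str]
    genes: list[str]
    stages: list[str]
    pairs: list[tuple[str, str]]
    edges: list[tuple[str, str]]
    algorithms: list[str]

    x_mean: np.ndarray
    x_var: np.ndarray
    y_mean: np.ndarray
    y_var: np.ndarray
    u_mir_mean: np.ndarray
    u_mir_var: np.ndarray
    u_mrna_mean: np.ndarray
    u_mrna_var: np.ndarray
    tau_mean: np.ndarray
    tau_var: np.ndarray
    r_mean: np.ndarray
    r_var: np.ndarray
    beta_mean: np.ndarray
    beta_var: np.ndarray

    lam_mir: _Gamma
    lam_mrna: _Gamma
    phi_set_mir: _Gamma
    phi_rep_mir: _Gamma
    phi_set_mrna: _Gamma
    phi_rep_mrna: _Gamma
    phi_r: _Gamma

    delta_mir: np.ndarray
    delta_mrna: np.ndarray

    elbo_trace: list[float] = field(default_factory=list)
    n_clamped: int = 0
    seed: int | None = None

    # -- reporting ---------------------------------------------------------

    def interaction_posterior(self):
        """Per-pair posterior mean, sd and z of the interaction coefficients."""
        import pandas as pd

        sd = np.sqrt(self.r_var)
        return pd.DataFrame(
            {
                "mir": [m for m, _ in self.pairs],
                "gene": [g for _, g in self.pairs],
                "mean": self.r_mean,
                "sd": sd,
                "z": self.r_mean / sd,
            }
        )

    def trend_posterior(self):
        """Per-miR posterior mean, sd and z of the trend parameters."""
        import pandas as pd

        sd = np.sqrt(self.tau_var)
        return pd.DataFrame(
            {"mir": self.mirs, "mean": self.tau_mean, "sd": sd, "z": self.tau_mean / sd}
        )

    def delta_point(self) -> dict[str, dict[tuple[str, str], float]]:
        return {
            "miR": dict(zip(self.edges, self.delta_mir.tolist())),
            "mRNA": dict(zip(self.edges, self.delta_mrna.tolist())),
        }

    def q_normal(self) -> dict[str, tuple[float, float]]:
        """Spec-shaped map: parameter id -> (mean, precision)."""
        out: dict[str, tuple[float, float]] = {}
        for a, s in np.ndindex(self.x_mean.shape):
            out[f"x[{self.mirs[a]},{self.stages[s]}]"] = (
                float(self.x_mean[a, s]),
                1.0 / float(self.x_var[a, s]),
            )
        for a, s in np.ndindex(self.y_mean.shape):
            out[f"y[{self.genes[a]},{self.stages[s]}]"] = (
                float(self.y_mean[a, s]),
                1.0 / float(self.y_var[a, s]),
            )
        for i, m in enumerate(self.mirs):
            out[f"tau[{m}]"] = (float(self.tau_mean[i]), 1.0 / float(self.tau_var[i]))
        for p, (m, g) in enumerate(self.pairs):
            out[f"r[{m},{g}]"] = (float(self.r_mean[p]), 1.0 / float(self.r_var[p]))
        for k in range(self.beta_mean.size):
            out[f"beta[{k}]"] = (float(self.beta_mean[k]), 1.0 / float(self.beta_var[k]))
        return out

    def q_gamma(self) -> dict[str, tuple[float, float] | float]:
        """Spec-shaped map: precision id -> (shape, rate) or fixed value."""
        out: dict[str, tuple[float, float] | float] = {}

        def put(name: str, fac: _Gamma, labels: Sequence[str] | None = None):
            if fac.fixed is not None:
                if labels is None:
                    out[name] = fac.fixed
                else:
                    for lab in labels:
                        out[f"{name}[{lab}]"] = fac.fixed
            elif labels is None:
                out[name] = (float(fac.shape[0]), float(fac.rate[0]))
            else:
                for i, lab in enumerate(labels):
                    out[f"{name}[{lab}]"] = (float(fac.shape[i]), float(fac.rate[i]))

        put("lambda_mir", self.lam_mir, self.mirs)
        put("lambda_mrna", self.lam_mrna, self.genes)
        put("phi_set_mir", self.phi_set_mir)
        put("phi_rep_mir", self.phi_rep_mir)
        put("phi_set_mrna", self.phi_set_mrna)
        put("phi_rep_mrna", self.phi_rep_mrna)
        put("phi_r", self.phi_r)
        return out


class VBEngine:
    """Compiled model structure plus the coordinate-ascent update equations."""

    def __init__(
        self,
        data: ExpressionDataset,
        order: PartialOrder,
        predictions: PredictionSet,
        hyper: Hyperparameters = Hyperparameters(),
        config: ModelConfig = ModelConfig(),
        options: FitOptions | None = None,
    ):
        self.data = data
        self.order = order
        self.predictions = predictions
        self.hyper = hyper
        self.config = config
        self.options = options or FitOptions()
        self._compile()

    # ------------------------------------------------------------------
    # compilation

    def _compile(self) -> None:
        order = self.order
        violations = []
        from mirvb.ordering import validate_order

        violations = validate_order(order)
        if violations:
            raise ValueError(f"invalid partial order: {violations}")

        self.stages = order.topological_order()
        self.S = len(self.stages)
        sidx = {s: k for k, s in enumerate(self.stages)}
        self.parents: list[np.ndarray] = [
            np.array([sidx[p] for p in sorted(order.parents.get(s, frozenset()))], dtype=int)
            for s in self.stages
        ]
        self.children: list[list[int]] = [[] for _ in range(self.S)]
        self.edges: list[tuple[str, str]] = []
        self.edges_into: list[np.ndarray] = []
        eidx: dict[tuple[int, int], int] = {}
        for s in range(self.S):
            ids = []
            for p in self.parents[s]:
                eidx[(int(p), s)] = len(self.edges)
                ids.append(len(self.edges))
                self.edges.append((self.stages[int(p)], self.stages[s]))
                self.children[int(p)].append(s)
            self.edges_into.append(np.array(ids, dtype=int))
        self.n_edges = len(self.edges)
        self.noninit = np.array([s for s in range(self.S) if len(self.parents[s])], dtype=int)
        self.init = np.array([s for s in range(self.S) if not len(self.parents[s])], dtype=int)

        self.mirs = self.data.mir.probe_ids
        self.genes = self.data.mrna.probe_ids
        self.I, self.G = len(self.mirs), len(self.genes)
        midx = {m: i for i, m in enumerate(self.mirs)}
        gidx = {g: i for i, g in enumerate(self.genes)}

        self.pairs = [
            (m, g) for m, g in self.predictions.pairs() if m in midx and g in gidx
        ]
        if not self.pairs:
            raise ValueError("empty candidate set: no predicted pair matches the data")
        self.P = len(self.pairs)
        self.pair_mir = np.array([midx[m] for m, _ in self.pairs], dtype=int)
        self.pair_gene = np.array([gidx[g] for _, g in self.pairs], dtype=int)
        self.C = self.predictions.design_matrix(self.pairs)
        self.K = self.C.shape[1]

        self.mir_pairs: list[np.ndarray] = [
            np.flatnonzero(self.pair_mir == i) for i in range(self.I)
        ]
        gene_pairs = [np.flatnonzero(self.pair_gene == g) for g in range(self.G)]
        max_slot = max((len(a) for a in gene_pairs), default=0)
        # slot k holds the k-th candidate pair of every gene that has one:
        # pairs within a slot belong to distinct genes and can be updated
        # as a block without breaking coordinate ascent.
        self.slots = [
            np.array([a[k] for a in gene_pairs if len(a) > k], dtype=int)
            for k in range(max_slot)
        ]

        stage_of_sample = order.stage_of()
        self._compile_platform("mir", self.data.mir, stage_of_sample, sidx)
        self._compile_platform("mrna", self.data.mrna, stage_of_sample, sidx)

    def _compile_platform(self, tag, mat, stage_of_sample, sidx) -> None:
        design = self.data.design.set_index(
            self.data.design["observation_id"].astype(str)
        )
        cols = mat.observation_ids
        sub = design.loc[cols]
        samples = sub["sample_id"].astype(str)
        set_ids = sub["set_id"].astype(str)
        set_order = list(dict.fromkeys(set_ids))
        set_pos = {e: k for k, e in enumerate(set_order)}

        n_obs = len(cols)
        obs_set = np.array([set_pos[set_ids.iloc[j]] for j in range(n_obs)], dtype=int)
        set_stage = np.full(len(set_order), -1, dtype=int)
        for j in range(n_obs):
            samp = samples.iloc[j]
            if samp not in stage_of_sample:
                raise ValueError(
                    f"sample {samp!r} (observation {cols[j]!r}) is not a member "
                    "of any stage in the partial order"
                )
            st = sidx[stage_of_sample[samp]]
            e = obs_set[j]
            if set_stage[e] not in (-1, st):
                raise ValueError(f"expression set {set_order[e]!r} spans multiple stages")
            set_stage[e] = st

        vals = mat.values.to_numpy(dtype=float)
        n_sets = len(set_order)
        reps = np.bincount(obs_set, minlength=n_sets).astype(float)
        zsum = np.zeros((vals.shape[0], n_sets))
        np.add.at(zsum.T, obs_set, vals.T)
        sets_in_stage = [np.flatnonzero(set_stage == s) for s in range(self.S)]

        setattr(self, f"data_{tag}", vals)
        setattr(self, f"obs_set_{tag}", obs_set)
        setattr(self, f"set_stage_{tag}", set_stage)
        setattr(self, f"reps_{tag}", reps)
        setattr(self, f"zsum_{tag}", zsum)
        setattr(self, f"sets_in_stage_{tag}", sets_in_stage)
        setattr(self, f"n_sets_{tag}", n_sets)

    # ------------------------------------------------------------------
    # stage weights

    def _weights(self, deltas: np.ndarray):
        """Per-stage inverse-development weights.

        Returns (inv, W, pm, K): ``inv[s]`` the 1/delta array over parents,
        ``W`` the weight sums, ``pm`` the precision multipliers (the "sum"
        form W or the weighted-average form sum(inv^2)/W), ``K`` parent
        counts.  Entries of initial stages are zero and never used.
        """
        inv = [1.0 / deltas[self.edges_into[s]] for s in range(self.S)]
        W = np.array([iv.sum() if iv.size else 0.0 for iv in inv])
        if self.config.precision_form == "sum":
            pm = W.copy()
        else:
            pm = np.array(
                [(iv**2).sum() / iv.sum() if iv.size else 0.0 for iv in inv]
            )
        K = np.array([float(iv.size) for iv in inv])
        return inv, W, pm, K

    # ------------------------------------------------------------------
    # initialization

    def initialize(self, seed: int = 0) -> PosteriorState:
        """Deterministic initial state: stage means from data, unit variances,
        zero trends/interactions/coefficients, gamma factors at their priors,
        unit developments."""
        hyper = self.hyper

        def stage_means(vals, obs_set, set_stage):
            n_probe = vals.shape[0]
            means = np.zeros((n_probe, self.S))
            filled = np.zeros(self.S, dtype=bool)
            for s in range(self.S):
                cols = np.flatnonzero(np.isin(obs_set, np.flatnonzero(set_stage == s)))
                if cols.size:
                    means[:, s] = vals[:, cols].mean(axis=1)
                    filled[s] = True
            for s in self.stages_topo_indices():
                if not filled[s]:
                    ps = self.parents[s]
                    if ps.size:
                        means[:, s] = means[:, ps].mean(axis=1)
                    filled[s] = True
            return means

        x_mean = stage_means(self.data_mir, self.obs_set_mir, self.set_stage_mir)
        y_mean = stage_means(self.data_mrna, self.obs_set_mrna, self.set_stage_mrna)

        def set_means(zsum, reps):
            return zsum / np.maximum(reps, 1.0)[None, :]

        a0, b0 = hyper.gamma_shape, hyper.gamma_rate
        ga, gb = (a0, b0) if (a0 > 0 and b0 > 0) else (1.0, 1.0)
        fx = self.options.fixed

        def gamma(name: str, n: int) -> _Gamma:
            return _Gamma(ga, gb, n, fixed=fx.get(name))

        state = PosteriorState(
            mirs=self.mirs,
            genes=self.genes,
            stages=self.stages,
            pairs=self.pairs,
            edges=self.edges,
            algorithms=list(self.predictions.algorithms),
            x_mean=x_mean,
            x_var=np.ones_like(x_mean),
            y_mean=y_mean,
            y_var=np.ones_like(y_mean),
            u_mir_mean=set_means(self.zsum_mir, self.reps_mir),
            u_mir_var=np.ones((self.I, self.n_sets_mir)),
            u_mrna_mean=set_means(self.zsum_mrna, self.reps_mrna),
            u_mrna_var=np.ones((self.G, self.n_sets_mrna)),
            tau_mean=np.zeros(self.I),
            tau_var=np.ones(self.I),
            r_mean=np.zeros(self.P),
            r_var=np.ones(self.P),
            beta_mean=np.zeros(self.K),
            beta_var=np.ones(self.K),
            lam_mir=gamma("lambda_mir", self.I),
            lam_mrna=gamma("lambda_mrna", self.G),
            phi_set_mir=gamma("phi_set_mir", 1),
            phi_rep_mir=gamma("phi_rep_mir", 1),
            phi_set_mrna=gamma("phi_set_mrna", 1),
            phi_rep_mrna=gamma("phi_rep_mrna", 1),
            phi_r=gamma("phi_r", 1),
            delta_mir=np.ones(self.n_edges),
            delta_mrna=np.ones(self.n_edges),
            seed=seed,
        )
        return state

    def stages_topo_indices(self) -> range:
        return range(self.S)  # self.stages is already topologically sorted

    # ------------------------------------------------------------------
    # interaction bookkeeping

    def _xi(self, st: PosteriorState):
        """Mean and variance of the per-miR interaction input xi_j(s).

        xi is the linear combination of latent miR expressions that the
        interaction coefficient multiplies in the mRNA prior mean at stage
        s, aggregated over the stage's parent edges with the mRNA weights.
        """
        inv, W, pm, K = self._weights(st.delta_mrna)
        xi_mean = np.zeros((self.I, self.S))
        xi_var = np.zeros((self.I, self.S))
        for s in self.noninit:
            a = K[s] / W[s]
            ps = self.parents[s]
            if self.config.interaction_stage == "child":
                xi_mean[:, s] = a * st.x_mean[:, s]
                xi_var[:, s] = a**2 * st.x_var[:, s]
            elif self.config.interaction_stage == "parent":
                xi_mean[:, s] = st.x_mean[:, ps].sum(axis=1) / W[s]
                xi_var[:, s] = st.x_var[:, ps].sum(axis=1) / W[s] ** 2
            else:  # difference
                xi_mean[:, s] = (
                    K[s] * st.x_mean[:, s] - st.x_mean[:, ps].sum(axis=1)
                ) / W[s]
                xi_var[:, s] = (
                    a**2 * st.x_var[:, s] + st.x_var[:, ps].sum(axis=1) / W[s] ** 2
                )
        return xi_mean, xi_var

    def _interaction_moments(self, st: PosteriorState):
        """E and Var of the total interaction effect per (gene, stage)."""
        xi_mean, xi_var = self._xi(st)
        r2 = st.r_mean**2 + st.r_var
        xi2 = xi_mean**2 + xi_var
        M = np.zeros((self.G, self.S))
        V = np.zeros((self.G, self.S))
        contrib_m = st.r_mean[:, None] * xi_mean[self.pair_mir, :]
        contrib_v = r2[:, None] * xi2[self.pair_mir, :] - contrib_m**2
        np.add.at(M, self.pair_gene, contrib_m)
        np.add.at(V, self.pair_gene, contrib_v)
        return M, V, xi_mean, xi_var

    def _parent_avg(self, means: np.ndarray, inv, W) -> np.ndarray:
        """Inverse-development-weighted parent mean per (probe, stage)."""
        out = np.zeros_like(means)
        for s in self.noninit:
            ps = self.parents[s]
            out[:, s] = means[:, ps] @ inv[s] / W[s]
        return out

    def _gene_contexts(self, s: int, W, K) -> list[tuple[int, float]]:
        """Stages and coefficients through which x_{i,s} enters mRNA priors.

        Returns (stage t, a) pairs such that the interaction input of miR i
        at stage t contains the term ``a * x_{i,s}``.
        """
        out: list[tuple[int, float]] = []
        variant = self.config.interaction_stage
        if variant in ("child", "difference") and len(self.parents[s]):
            out.append((s, K[s] / W[s]))
        if variant in ("parent", "difference"):
            sign = 1.0 if variant == "parent" else -1.0
            for c in self.children[s]:
                out.append((c, sign / W[c]))
        return out

    # ------------------------------------------------------------------
    # conjugate updates

    def update_conjugate(self, group: str, st: PosteriorState) -> PosteriorState:
        """Replace one factor group by its exact mean-field optimum."""
        if group == "set_latents":
            self._update_sets(st)
        elif group == "x":
            self._update_x(st)
        elif group == "y":
            self._update_y(st)
        elif group == "tau":
            self._update_tau(st)
        elif group == "r":
            self._update_r(st)
        elif group == "beta":
            self._update_beta(st)
        elif group == "phi_r":
            self._update_phi_r(st)
        elif group == "lambda":
            self._update_lambda(st)
        elif group == "phi_technical":
            self._update_phi_technical(st)
        else:
            raise ValueError(
                f"unknown conjugate group {group!r}; known: {CONJUGATE_GROUPS}"
            )
        return st

    def _update_sets(self, st: PosteriorState) -> None:
        for tag, um, uv, phis, phir in (
            ("mir", st.u_mir_mean, st.u_mir_var, st.phi_set_mir, st.phi_rep_mir),
            ("mrna", st.u_mrna_mean, st.u_mrna_var, st.phi_set_mrna, st.phi_rep_mrna),
        ):
            fs = float(phis.mean()[0])
            fr = float(phir.mean()[0])
            reps = getattr(self, f"reps_{tag}")
            zsum = getattr(self, f"zsum_{tag}")
            set_stage = getattr(self, f"set_stage_{tag}")
            lat = st.x_mean if tag == "mir" else st.y_mean
            prec = fs + reps * fr
            um[:] = (fs * lat[:, set_stage] + fr * zsum) / prec[None, :]
            uv[:] = 1.0 / prec[None, :]

    def _update_x(self, st: PosteriorState) -> None:
        cfg = self.config
        a0 = self.hyper.normal_prior_precision
        inv, W, pm, K = self._weights(st.delta_mir)
        inv_y, W_y, pm_y, K_y = self._weights(st.delta_mrna)
        lam = st.lam_mir.mean()
        lam_g = st.lam_mrna.mean()
        phis = float(st.phi_set_mir.mean()[0])
        tau = st.tau_mean if cfg.trend_enabled else np.zeros(self.I)

        M, _, xi_mean, _ = self._interaction_moments(st)
        ypar = self._parent_avg(st.y_mean, inv_y, W_y)
        r2 = st.r_mean**2 + st.r_var

        for s in self.stages_topo_indices():
            contexts = self._gene_contexts(s, W_y, K_y)
            sets_here = getattr(self, "sets_in_stage_mir")[s]
            for i in range(self.I):
                P = 0.0
                L = 0.0
                # own stage prior
                if len(self.parents[s]):
                    c1 = lam[i] * pm[s]
                    target = float(st.x_mean[i, self.parents[s]] @ inv[s] / W[s]) + tau[
                        i
                    ] * K[s] / W[s]
                    P += c1
                    L += c1 * target
                else:
                    P += a0
                # children along the miR chain
                for c in self.children[s]:
                    e = float(1.0 / st.delta_mir[self._edge_index(s, c)])
                    a = e / W[c]
                    rest = (
                        float(st.x_mean[i, self.parents[c]] @ inv[c] / W[c])
                        - a * st.x_mean[i, s]
                        + tau[i] * K[c] / W[c]
                    )
                    rho = lam[i] * pm[c]
                    P += rho * a**2
                    L += rho * a * (st.x_mean[i, c] - rest)
                # set-level latents
                if sets_here.size:
                    P += phis * sets_here.size
                    L += phis * float(st.u_mir_mean[i, sets_here].sum())
                # mRNA coupling through the interaction inputs
                pi = self.mir_pairs[i]
                if pi.size:
                    gs = self.pair_gene[pi]
                    for t, a in contexts:
                        rho = lam_g[gs] * pm_y[t]
                        P += a**2 * float(rho @ r2[pi])
                        resid = (
                            st.y_mean[gs, t]
                            - ypar[gs, t]
                            - M[gs, t]
                            + a * st.r_mean[pi] * st.x_mean[i, s]
                        )
                        L += a * float((rho * st.r_mean[pi]) @ resid)
                P = max(P, PRECISION_FLOOR)
                new_mean = L / P
                dx = new_mean - st.x_mean[i, s]
                st.x_mean[i, s] = new_mean
                st.x_var[i, s] = 1.0 / P
                if pi.size and dx != 0.0:
                    gs = self.pair_gene[pi]
                    for t, a in contexts:
                        M[gs, t] += a * st.r_mean[pi] * dx

    def _edge_index(self, p: int, s: int) -> int:
        ids = self.edges_into[s]
        ps = self.parents[s]
        return int(ids[np.flatnonzero(ps == p)[0]])

    def _update_y(self, st: PosteriorState) -> None:
        a0 = self.hyper.normal_prior_precision
        inv, W, pm, K = self._weights(st.delta_mrna)
        lam = st.lam_mrna.mean()
        phis = float(st.phi_set_mrna.mean()[0])
        M, _, _, _ = self._interaction_moments(st)

        for s in self.stages_topo_indices():
            P = np.zeros(self.G)
            L = np.zeros(self.G)
            if len(self.parents[s]):
                c1 = lam * pm[s]
                target = st.y_mean[:, self.parents[s]] @ inv[s] / W[s] + M[:, s]
                P += c1
                L += c1 * target
            else:
                P += a0
            for c in self.children[s]:
                e = float(1.0 / st.delta_mrna[self._edge_index(s, c)])
                a = e / W[c]
                rest = (
                    st.y_mean[:, self.parents[c]] @ inv[c] / W[c]
                    - a * st.y_mean[:, s]
                    + M[:, c]
                )
                rho = lam * pm[c]
                P += rho * a**2
                L += rho * a * (st.y_mean[:, c] - rest)
            sets_here = getattr(self, "sets_in_stage_mrna")[s]
            if sets_here.size:
                P += phis * sets_here.size
                L += phis * st.u_mrna_mean[:, sets_here].sum(axis=1)
            P = np.maximum(P, PRECISION_FLOOR)
            st.y_mean[:, s] = L / P
            st.y_var[:, s] = 1.0 / P

    def _update_tau(self, st: PosteriorState) -> None:
        if not self.config.trend_enabled:
            return
        a0 = self.hyper.normal_prior_precision
        inv, W, pm, K = self._weights(st.delta_mir)
        lam = st.lam_mir.mean()
        P = np.full(self.I, a0)
        L = np.zeros(self.I)
        for s in self.noninit:
            a = K[s] / W[s]
            xpar = st.x_mean[:, self.parents[s]] @ inv[s] / W[s]
            P += lam * pm[s] * a**2
            L += lam * pm[s] * a * (st.x_mean[:, s] - xpar)
        st.tau_mean[:] = L / P
        st.tau_var[:] = 1.0 / P

    def _update_r(self, st: PosteriorState) -> None:
        inv, W, pm, K = self._weights(st.delta_mrna)
        lam = st.lam_mrna.mean()
        phir = float(st.phi_r.mean()[0])
        M, _, xi_mean, xi_var = self._interaction_moments(st)
        ypar = self._parent_avg(st.y_mean, inv, W)
        xi2 = xi_mean**2 + xi_var
        prior_mean = self.C @ st.beta_mean
        ns = self.noninit
        for slot in self.slots:
            j = self.pair_mir[slot]
            g = self.pair_gene[slot]
            lam_g = lam[g]
            P = phir + (lam_g[:, None] * pm[ns][None, :] * xi2[j][:, ns]).sum(axis=1)
            resid = (
                st.y_mean[g][:, ns]
                - ypar[g][:, ns]
                - M[g][:, ns]
                + st.r_mean[slot][:, None] * xi_mean[j][:, ns]
            )
            L = phir * prior_mean[slot] + (
                lam_g[:, None] * pm[ns][None, :] * xi_mean[j][:, ns] * resid
            ).sum(axis=1)
            P = np.maximum(P, PRECISION_FLOOR)
            new_mean = L / P
            M[g[:, None], ns[None, :]] += (new_mean - st.r_mean[slot])[:, None] * xi_mean[
                j
            ][:, ns]
            st.r_mean[slot] = new_mean
            st.r_var[slot] = 1.0 / P

    def _update_beta(self, st: PosteriorState) -> None:
        a0 = self.hyper.normal_prior_precision
        phir = float(st.phi_r.mean()[0])
        for k in range(self.K):
            ck = self.C[:, k]
            rest = self.C @ st.beta_mean - ck * st.beta_mean[k]
            P = a0 + phir * float(ck @ ck)
            L = phir * float(ck @ (st.r_mean - rest))
            P = max(P, PRECISION_FLOOR)
            st.beta_mean[k] = L / P
            st.beta_var[k] = 1.0 / P

    def _update_phi_r(self, st: PosteriorState) -> None:
        a0, b0 = self.hyper.gamma_shape, self.hyper.gamma_rate
        resid = st.r_mean - self.C @ st.beta_mean
        ss = float(
            (resid**2).sum()
            + st.r_var.sum()
            + ((self.C**2) @ st.beta_var).sum()
        )
        counter = [st.n_clamped]
        st.phi_r.set(a0 + self.P / 2.0, b0 + ss / 2.0, counter)
        st.n_clamped = counter[0]

    def _stage_quadratics(self, st: PosteriorState):
        """Expected squared stage-prior residuals Q for both platforms.

        Returns (Q_mir (I,S), Q_mrna (G,S)), zero at initial stages, plus the
        interaction moments reused by callers.
        """
        cfg = self.config
        inv, W, pm, K = self._weights(st.delta_mir)
        inv_y, W_y, pm_y, K_y = self._weights(st.delta_mrna)
        tau = st.tau_mean if cfg.trend_enabled else np.zeros(self.I)
        tau_v = st.tau_var if cfg.trend_enabled else np.zeros(self.I)
        M, V, _, _ = self._interaction_moments(st)

        Q_mir = np.zeros((self.I, self.S))
        Q_mrna = np.zeros((self.G, self.S))
        for s in self.noninit:
            ps = self.parents[s]
            a = K[s] / W[s]
            xpar = st.x_mean[:, ps] @ inv[s] / W[s]
            mean_res = st.x_mean[:, s] - xpar - tau * a
            Q_mir[:, s] = (
                mean_res**2
                + st.x_var[:, s]
                + st.x_var[:, ps] @ (inv[s] / W[s]) ** 2
                + tau_v * a**2
            )
            ps_y = self.parents[s]
            ypar = st.y_mean[:, ps_y] @ inv_y[s] / W_y[s]
            mean_res_y = st.y_mean[:, s] - ypar - M[:, s]
            Q_mrna[:, s] = (
                mean_res_y**2
                + st.y_var[:, s]
                + st.y_var[:, ps_y] @ (inv_y[s] / W_y[s]) ** 2
                + V[:, s]
            )
        return Q_mir, Q_mrna, (pm, pm_y)

    def _update_lambda(self, st: PosteriorState) -> None:
        a0, b0 = self.hyper.gamma_shape, self.hyper.gamma_rate
        Q_mir, Q_mrna, (pm, pm_y) = self._stage_quadratics(st)
        shape = a0 + len(self.noninit) / 2.0
        counter = [st.n_clamped]
        st.lam_mir.set(shape, b0 + 0.5 * (Q_mir[:, self.noninit] @ pm[self.noninit]), counter)
        st.lam_mrna.set(
            shape, b0 + 0.5 * (Q_mrna[:, self.noninit] @ pm_y[self.noninit]), counter
        )
        st.n_clamped = counter[0]

    def _update_phi_technical(self, st: PosteriorState) -> None:
        a0, b0 = self.hyper.gamma_shape, self.hyper.gamma_rate
        counter = [st.n_clamped]
        for tag, um, uv, phi_set, phi_rep, lat_mean, lat_var in (
            ("mir", st.u_mir_mean, st.u_mir_var, st.phi_set_mir, st.phi_rep_mir, st.x_mean, st.x_var),
            ("mrna", st.u_mrna_mean, st.u_mrna_var, st.phi_set_mrna, st.phi_rep_mrna, st.y_mean, st.y_var),
        ):
            set_stage = getattr(self, f"set_stage_{tag}")
            vals = getattr(self, f"data_{tag}")
            obs_set = getattr(self, f"obs_set_{tag}")
            n_probe, n_sets = um.shape
            d = um - lat_mean[:, set_stage]
            ss_set = float((d**2 + uv + lat_var[:, set_stage]).sum())
            phi_set.set(a0 + n_probe * n_sets / 2.0, b0 + ss_set / 2.0, counter)
            dz = vals - um[:, obs_set]
            ss_rep = float((dz**2 + uv[:, obs_set]).sum())
            phi_rep.set(a0 + dz.size / 2.0, b0 + ss_rep / 2.0, counter)
        st.n_clamped = counter[0]

    # ------------------------------------------------------------------
    # development (delta) point updates

    def _delta_objective(self, platform: str, s: int, st: PosteriorState) -> float:
        """The delta-dependent part of the ELBO contributed by stage ``s``."""
        hyper = self.hyper
        ad, bd = hyper.development_shape, hyper.development_rate
        if platform == "mir":
            deltas = st.delta_mir
            Q_fn = self._q_mir_stage
            lam = st.lam_mir.mean()
        else:
            deltas = st.delta_mrna
            Q_fn = self._q_mrna_stage
            lam = st.lam_mrna.mean()
        pm_s, Q = Q_fn(s, st)
        prior = float(((ad - 1.0) * np.log(deltas[self.edges_into[s]])
                       - bd * deltas[self.edges_into[s]]).sum())
        return float(0.5 * lam.size * math.log(pm_s) - 0.5 * pm_s * (lam @ Q) + prior)

    def _q_mir_stage(self, s: int, st: PosteriorState):
        inv, W, pm, K = self._weights(st.delta_mir)
        ps = self.parents[s]
        a = K[s] / W[s]
        tau = st.tau_mean if self.config.trend_enabled else np.zeros(self.I)
        tau_v = st.tau_var if self.config.trend_enabled else np.zeros(self.I)
        xpar = st.x_mean[:, ps] @ inv[s] / W[s]
        mean_res = st.x_mean[:, s] - xpar - tau * a
        Q = (
            mean_res**2
            + st.x_var[:, s]
            + st.x_var[:, ps] @ (inv[s] / W[s]) ** 2
            + tau_v * a**2
        )
        return pm[s], Q

    def _q_mrna_stage(self, s: int, st: PosteriorState):
        M, V, _, _ = self._interaction_moments(st)
        inv, W, pm, K = self._weights(st.delta_mrna)
        ps = self.parents[s]
        ypar = st.y_mean[:, ps] @ inv[s] / W[s]
        mean_res = st.y_mean[:, s] - ypar - M[:, s]
        Q = (
            mean_res**2
            + st.y_var[:, s]
            + st.y_var[:, ps] @ (inv[s] / W[s]) ** 2
            + V[:, s]
        )
        return pm[s], Q

    def update_developments(self, st: PosteriorState) -> PosteriorState:
        """ELBO-maximizing coordinate-wise point updates of every delta.

        Each edge's development is optimized in log space over the bounded
        range; a candidate is accepted only if it does not lower the
        objective, so the ELBO cannot decrease.
        """
        lo, hi = np.log(self.options.delta_bounds[0]), np.log(self.options.delta_bounds[1])
        for platform, deltas in (("mir", st.delta_mir), ("mrna", st.delta_mrna)):
            for s in self.noninit:
                for e in self.edges_into[s]:
                    current = deltas[e]
                    f_cur = self._delta_objective(platform, s, st)

                    def neg(logd: float) -> float:
                        deltas[e] = math.exp(logd)
                        val = self._delta_objective(platform, s, st)
                        return -val

                    res = optimize.minimize_scalar(
                        neg, bounds=(lo, hi), method="bounded",
                        options={"xatol": 1e-6},
                    )
                    if res.success and -res.fun >= f_cur:
                        deltas[e] = math.exp(res.x)
                    else:
                        deltas[e] = current
                        if not res.success:
                            log.warning(
                                "development optimization failed for %s edge %s; kept %.4g",
                                platform, self.edges[e], current,
                            )
        return st

    # ------------------------------------------------------------------
    # ELBO

    def elbo(self, st: PosteriorState) -> float:
        """Evidence lower bound E_q[log joint] - E_q[log q], in closed form."""
        hyper = self.hyper
        a0 = hyper.normal_prior_precision
        total = 0.0

        # observations and set-latent priors (both platforms)
        for tag, um, uv, phi_set, phi_rep, lat_mean, lat_var in (
            ("mir", st.u_mir_mean, st.u_mir_var, st.phi_set_mir, st.phi_rep_mir, st.x_mean, st.x_var),
            ("mrna", st.u_mrna_mean, st.u_mrna_var, st.phi_set_mrna, st.phi_rep_mrna, st.y_mean, st.y_var),
        ):
            set_stage = getattr(self, f"set_stage_{tag}")
            vals = getattr(self, f"data_{tag}")
            obs_set = getattr(self, f"obs_set_{tag}")
            fr = float(phi_rep.mean()[0])
            lr = float(phi_rep.mean_log()[0])
            dz = vals - um[:, obs_set]
            total += 0.5 * dz.size * (lr - LOG2PI)
            total -= 0.5 * fr * float((dz**2 + uv[:, obs_set]).sum())
            fs = float(phi_set.mean()[0])
            ls = float(phi_set.mean_log()[0])
            d = um - lat_mean[:, set_stage]
            total += 0.5 * um.size * (ls - LOG2PI)
            total -= 0.5 * fs * float((d**2 + uv + lat_var[:, set_stage]).sum())

        # stage priors
        Q_mir, Q_mrna, (pm, pm_y) = self._stage_quadratics(st)
        lam = st.lam_mir.mean()
        llam = st.lam_mir.mean_log()
        lam_y = st.lam_mrna.mean()
        llam_y = st.lam_mrna.mean_log()
        for s in self.noninit:
            total += 0.5 * float(np.sum(llam + math.log(pm[s]) - LOG2PI))
            total -= 0.5 * float(lam @ (pm[s] * Q_mir[:, s]))
            total += 0.5 * float(np.sum(llam_y + math.log(pm_y[s]) - LOG2PI))
            total -= 0.5 * float(lam_y @ (pm_y[s] * Q_mrna[:, s]))
        for s in self.init:
            total += 0.5 * self.I * (math.log(a0) - LOG2PI)
            total -= 0.5 * a0 * float((st.x_mean[:, s] ** 2 + st.x_var[:, s]).sum())
            total += 0.5 * self.G * (math.log(a0) - LOG2PI)
            total -= 0.5 * a0 * float((st.y_mean[:, s] ** 2 + st.y_var[:, s]).sum())

        # interaction priors
        fphir = float(st.phi_r.mean()[0])
        lphir = float(st.phi_r.mean_log()[0])
        resid = st.r_mean - self.C @ st.beta_mean
        ss = float((resid**2).sum() + st.r_var.sum() + ((self.C**2) @ st.beta_var).sum())
        total += 0.5 * self.P * (lphir - LOG2PI) - 0.5 * fphir * ss

        # trend and coefficient priors
        if self.config.trend_enabled:
            total += 0.5 * self.I * (math.log(a0) - LOG2PI)
            total -= 0.5 * a0 * float((st.tau_mean**2 + st.tau_var).sum())
        total += 0.5 * self.K * (math.log(a0) - LOG2PI)
        total -= 0.5 * a0 * float((st.beta_mean**2 + st.beta_var).sum())

        # gamma priors on free precisions
        ga, gb = hyper.gamma_shape, hyper.gamma_rate
        norm = ga * math.log(gb) - special.gammaln(ga) if (ga > 0 and gb > 0) else 0.0
        for fac in (
            st.lam_mir, st.lam_mrna, st.phi_set_mir, st.phi_rep_mir,
            st.phi_set_mrna, st.phi_rep_mrna, st.phi_r,
        ):
            if fac.fixed is not None:
                continue
            total += float(
                np.sum(norm + (ga - 1.0) * fac.mean_log() - gb * fac.mean())
            )

        # development priors
        ad, bd = hyper.development_shape, hyper.development_rate
        dn = ad * math.log(bd) - special.gammaln(ad)
        for deltas in (st.delta_mir, st.delta_mrna):
            total += float(np.sum(dn + (ad - 1.0) * np.log(deltas) - bd * deltas))

        # entropies
        half = 0.5 * (1.0 + LOG2PI)
        for var in (st.x_var, st.y_var, st.u_mir_var, st.u_mrna_var, st.r_var, st.beta_var):
            total += var.size * half + 0.5 * float(np.log(var).sum())
        if self.config.trend_enabled:
            total += st.tau_var.size * half + 0.5 * float(np.log(st.tau_var).sum())
        for fac in (
            st.lam_mir, st.lam_mrna, st.phi_set_mir, st.phi_rep_mir,
            st.phi_set_mrna, st.phi_rep_mrna, st.phi_r,
        ):
            total += fac.entropy()
        return float(total)

    # ------------------------------------------------------------------
    # driver

    def sweep(self, st: PosteriorState) -> PosteriorState:
        """One full pass of conjugate updates in the documented order."""
        for group in CONJUGATE_GROUPS:
            self.update_conjugate(group, st)
        return st

    def fit(self, n_iter: int = 200, seed: int = 0) -> PosteriorState:
        """Initialize, then run ``n_iter`` outer iterations of conjugate
        sweep plus development step, recording the ELBO after each."""
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        st = self.initialize(seed)
        last_group = "initialize"
        for it in range(n_iter):
            for group in CONJUGATE_GROUPS:
                last_group = group
                self.update_conjugate(group, st)
            if self.options.update_developments and it >= self.options.delta_warmup:
                last_group = "developments"
                self.update_developments(st)
            bound = self.elbo(st)
            if not math.isfinite(bound):
                raise FloatingPointError(
                    f"non-finite ELBO at iteration {it + 1} "
                    f"(last update: {last_group})"
                )
            st.elbo_trace.append(bound)
            if (
                self.options.early_stop_tol is not None
                and len(st.elbo_trace) >= 2
            ):
                prev = st.elbo_trace[-2]
                if abs(bound - prev) <= self.options.early_stop_tol * abs(prev):
                    break
        if st.n_clamped:
            log.info("clamped %d degenerate gamma rates during fitting", st.n_clamped)
        return st


def fit(
    data: ExpressionDataset,
    order: PartialOrder,
    predictions: PredictionSet,
    hyper: Hyperparameters = Hyperparameters(),
    config: ModelConfig = ModelConfig(),
    n_iter: int = 200,
    seed: int = 0,
    options: FitOptions | None = None,
) -> PosteriorState:
    """Fit the staged interaction model by variational Bayes.

    Convenience wrapper constructing a :class:`VBEngine` and running
    :meth:`VBEngine.fit`; the returned state carries the full ELBO trace.
    """
    engine = VBEngine(data, order, predictions, hyper, config, options)
    return engine.fit(n_iter=n_iter, seed=seed)
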