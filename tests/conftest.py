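"""Shared fixtures: small simulated datasets and fitted posteriors.

Everything is generated programmatically at test time; the tiny profile
(4 miRs, 12 genes, 3 stages) keeps per-test fits below a second.
"""

import numpy as np
import pandas as pd
import pytest

from mirvb.model_core import Hyperparameters
from mirvb.ordering import PartialOrder
from mirvb.preprocessing import ExpressionDataset, ExpressionMatrix
from mirvb.predictions import PredictionSet
from mirvb.synthetic_data import SyntheticConfig, generate
from mirvb.vb_engine import VBEngine


@pytest.fixture(scope="session")
def tiny_sim():
    """One tiny simulated dataset with ground truth (seed 11)."""
    return generate(SyntheticConfig.tiny(), seed=11)


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    """A converged-enough fit of the tiny dataset (60 outer iterations)."""
    dataset, predictions, order, truth = tiny_sim
    engine = VBEngine(dataset, order, predictions)
    state = engine.fit(n_iter=60, seed=11)
    return engine, state, truth


def make_chain_dataset(t, m, mir="mir1", gene="gene1"):
    """A one-miR / one-mRNA fully ordered chain with one observation per
    stage, for analytic reductions."""
    S = len(t)
    stages = [f"s{k}" for k in range(S)]
    order = PartialOrder(
        tuple(stages),
        {stages[k]: frozenset({stages[k - 1]}) for k in range(1, S)},
        {s: (s,) for s in stages},
    )
    obs = [f"{s}_r1" for s in stages]
    design = pd.DataFrame(
        {
            "observation_id": obs,
            "sample_id": stages,
            "stage": stages,
            "set_id": stages,
            "replicate_id": "r1",
        }
    )
    data = ExpressionDataset(
        mir=ExpressionMatrix(pd.DataFrame([t], index=[mir], columns=obs), "miR"),
        mrna=ExpressionMatrix(pd.DataFrame([m], index=[gene], columns=obs), "mRNA"),
        design=design,
    )
    predictions = PredictionSet(["alg"], {(mir, gene): {"alg": -0.5}})
    return data, order, predictions


@pytest.fixture
def chain_factory():
    return make_chain_dataset


def assert_monotone_elbo(trace, tol=1e-6):
    trace = np.asarray(trace, dtype=float)
    diffs = np.diff(trace)
    floor = -tol * np.maximum(np.abs(trace[:-1]), 1.0)
    bad = np.flatnonzero(diffs < floor)
    assert bad.size == 0, (
        f"ELBO decreased at iterations {bad + 1}: {diffs[bad]} (trace length {trace.size})"
    )
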