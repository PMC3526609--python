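"""Ranking of inferred interactions and the evaluation statistics.

Interactions are ranked by the magnitude of the posterior z-score
``z = mean * sqrt(precision)`` of their interaction coefficient; trends by
the same statistic of the per-miR trend parameter (threshold 3 by default).
The Pearson-correlation baselines and the average relative rank statistic
(the mean elementwise ratio of two ascending-sorted rank lists of the same
validated pairs; below 1 means the first ranking places them higher) mirror
the standard way such rankings are benchmarked against a validated-pair
list.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mirvb.preprocessing import ExpressionDataset
from mirvb.vb_engine import PosteriorState

__all__ = [
    "rank_interactions",
    "rank_interaction_table",
    "significant_trends",
    "correlation_ranking",
    "average_relative_rank",
    "validated_rank_lookup",
    "read_validated_pairs",
]


def _finalize_ranking(df: pd.DataFrame, sort_cols, ascending) -> pd.DataFrame:
    out = df.sort_values(sort_cols + ["mir", "gene"], ascending=ascending + [True, True])
    out = out.reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def rank_interactions(
    posterior: PosteriorState,
    negative_only: bool = False,
    by: str = "z",
    predictions=None,
) -> pd.DataFrame:
    """Ranked candidate-interaction table.

    Sorted by |z| descending (``by="z"``, default) or |mean| descending
    (``by="mean"``); with ``negative_only`` positive-mean pairs are dropped
    and the sort is by z ascending (most negative first).  Ties break
    lexicographically on (miR, gene).  Passing the fitted
    :class:`~mirvb.predictions.PredictionSet` fills the ``predicted_by``
    provenance column.
    """
    df = posterior.interaction_posterior()
    if predictions is not None:
        df["predicted_by"] = [
            ",".join(sorted(predictions.entries.get(p, {}))) for p in posterior.pairs
        ]
    else:
        df["predicted_by"] = ""
    return rank_interaction_table(df, negative_only=negative_only, by=by)


def rank_interaction_table(
    df: pd.DataFrame, negative_only: bool = False, by: str = "z"
) -> pd.DataFrame:
    """Rank an interaction-posterior table (columns mir, gene, mean, z)."""
    if by not in ("z", "mean"):
        raise ValueError("by must be 'z' or 'mean'")
    df = df.copy()
    if negative_only:
        df = df[df["mean"] < 0].copy()
        df["_key"] = df["z"] if by == "z" else df["mean"]
        return _finalize_ranking(df, ["_key"], [True]).drop(columns="_key")
    df["_key"] = (df["z"] if by == "z" else df["mean"]).abs()
    return _finalize_ranking(df, ["_key"], [False]).drop(columns="_key")


def significant_trends(posterior: PosteriorState, z_threshold: float = 3.0) -> pd.DataFrame:
    """miRs whose trend posterior mean sits more than ``z_threshold``
    posterior standard deviations from zero, either direction."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    df = posterior.trend_posterior()
    df = df[df["z"].abs() > z_threshold].copy()
    df["direction"] = np.where(df["mean"] > 0, "+", "-")
    df["_key"] = df["z"].abs()
    df = df.sort_values(["_key", "mir"], ascending=[False, True]).drop(columns="_key")
    return df[["mir", "direction", "z"]].reset_index(drop=True)


def correlation_ranking(
    data: ExpressionDataset,
    candidates: Sequence[tuple[str, str]],
    mode: str = "abs",
) -> pd.DataFrame:
    """Pearson-correlation baseline ranking over candidate pairs.

    Correlations are computed on per-sample set-averaged profiles across the
    expression sets shared by the two platforms.  ``mode="abs"`` sorts by
    |r| descending, ``mode="negative"`` by r ascending.
    """
    if mode not in ("abs", "negative"):
        raise ValueError("mode must be 'abs' or 'negative'")
    mir_sets = data.set_averaged("miR")
    mrna_sets = data.set_averaged("mRNA")
    shared = [c for c in mir_sets.columns if c in set(mrna_sets.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared expression sets for correlation")
    mir_sets = mir_sets[shared]
    mrna_sets = mrna_sets[shared]

    rows = []
    for mir, gene in candidates:
        a = mir_sets.loc[mir].to_numpy(dtype=float)
        b = mrna_sets.loc[gene].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"zero-variance profile for pair ({mir}, {gene}); skipped")
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"mir": mir, "gene": gene, "r": r})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no candidate pair had usable profiles")
    if mode == "abs":
        df["_key"] = df["r"].abs()
        return _finalize_ranking(df, ["_key"], [False]).drop(columns="_key")
    return _finalize_ranking(df, ["r"], [True])


def average_relative_rank(
    ranks_a: Sequence[int], ranks_b: Sequence[int]
) -> float:
    """Mean elementwise ratio of two ascending-sorted rank lists.

    Both lists are sorted ascending and divided position by position
    (a/b); the mean ratio estimates how many times fewer candidates must be
    tested under ranking ``a`` to recover the same validated pairs.
    """
    a = np.asarray(sorted(ranks_a), dtype=float)
    b = np.asarray(sorted(ranks_b), dtype=float)
    if a.size != b.size:
        raise ValueError(f"rank lists differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("rank lists are empty")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("ranks must be positive integers")
    return float((a / b).mean())


def validated_rank_lookup(
    ranked: pd.DataFrame, validated_pairs: Iterable[tuple[str, str]]
) -> tuple[list[int], list[tuple[str, str]]]:
    """1-based ranks of validated pairs in a ranking table.

    Returns (ranks of the pairs present, pairs absent from the ranking);
    a validated pair can be absent when it was never a candidate.
    """
    pos = {
        (str(m), str(g)): int(r)
        for m, g, r in zip(ranked["mir"], ranked["gene"], ranked["rank"])
    }
    found: list[int] = []
    missing: list[tuple[str, str]] = []
    for pair in validated_pairs:
        key = (str(pair[0]), str(pair[1]))
        if key in pos:
            found.append(pos[key])
        else:
            missing.append(key)
    return found, missing


def read_validated_pairs(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV (miR id, gene id) of validated pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mir, gene)")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
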