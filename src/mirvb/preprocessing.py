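"""Expression containers and the pre-analysis filtering/scaling pipeline.

The pipeline mirrors standard staged-microarray practice: quantile
normalization within each platform, a probewise one-way ANOVA filter across
stage groups (unadjusted F-test, alpha 0.05), restriction to probes that
participate in at least one predicted targeting interaction, and per-probe
z-scaling (mean 0, sample sd 1, n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirvb.predictions import PredictionSet

__all__ = [
    "ExpressionMatrix",
    "ExpressionDataset",
    "quantile_normalize",
    "anova_filter",
    "restrict_to_predicted",
    "zscale",
    "read_expression_tsv",
    "read_annotation_tsv",
]

ANNOTATION_COLUMNS = ("observation_id", "sample_id", "stage", "set_id", "replicate_id")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x observations log-expression matrix for one platform.

    ``values`` is a DataFrame indexed by unique probe ids with unique
    observation-id columns; missing values are rejected at construction.
    ``platform`` is ``"miR"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in ("miR", "mRNA"):
            raise ValueError(f"platform must be 'miR' or 'mRNA', got {self.platform!r}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing values in expression matrix (e.g. probes {bad})")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate observation ids")

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.values.index]

    @property
    def observation_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def subset(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probes)], self.platform)


@dataclass(frozen=True)
class ExpressionDataset:
    """Paired replicate-level miR and mRNA expression with observation design.

    ``design`` has columns (observation_id, sample_id, stage, set_id,
    replicate_id) and must cover every observation column of both platforms.
    A *set* is one physical array; replicates are repeated measurements
    within a set.
    """

    mir: ExpressionMatrix
    mrna: ExpressionMatrix
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table lacks columns {missing}")
        known = set(self.design["observation_id"].astype(str))
        for mat in (self.mir, self.mrna):
            unmapped = [o for o in mat.observation_ids if o not in known]
            if unmapped:
                raise ValueError(
                    f"{mat.platform} observations missing from design: {unmapped[:5]}"
                )

    def stage_groups(self, observation_ids: Sequence[str]) -> dict[str, str]:
        idx = self.design.set_index(self.design["observation_id"].astype(str))
        return {o: str(idx.loc[o, "stage"]) for o in observation_ids}

    def set_averaged(self, platform: str) -> pd.DataFrame:
        """Average replicate observations within each expression set.

        Returns probes x sets, columns named by set_id, with a matching
        per-set stage available via :meth:`set_stages`.
        """
        mat = self.mir if platform == "miR" else self.mrna
        idx = self.design.set_index(self.design["observation_id"].astype(str))
        sets = idx.loc[mat.observation_ids, "set_id"].astype(str)
        return mat.values.T.groupby(sets.values).mean().T

    def set_stages(self, platform: str) -> dict[str, str]:
        mat = self.mir if platform == "miR" else self.mrna
        idx = self.design.set_index(self.design["observation_id"].astype(str))
        sub = idx.loc[mat.observation_ids]
        return {
            str(s): str(g["stage"].iloc[0])
            for s, g in sub.groupby(sub["set_id"].astype(str))
        }


# ---------------------------------------------------------------------------
# operations


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize observations so all columns share one distribution.

    The reference distribution is the across-column mean of order statistics;
    tied values within a column receive the mean of the reference values
    their ranks span (average-rank convention, as in limma's
    ``normalizeQuantiles``).
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_probe, n_obs = vals.shape
    if n_obs < 2:
        warnings.warn("quantile normalization skipped: single observation")
        return matrix
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    grid = np.arange(1, n_probe + 1, dtype=float)
    for j in range(n_obs):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.platform,
    )


def anova_filter(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> list[str]:
    """Probewise one-way fixed-effects ANOVA filter across groups.

    Retains probe ``i`` iff the F-test p-value for differences in group
    means is below ``alpha`` (unadjusted).  Probes with an undefined F
    statistic (zero between- and within-group variance) are dropped.

    Parameters
    ----------
    groups
        Map from observation id to group label (typically the stage).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")  # alpha=1 disables the filter
    labels = [groups[o] for o in matrix.observation_ids]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("ANOVA filter needs at least 2 groups")
    cols = {g: [i for i, l in enumerate(labels) if l == g] for g in uniq}
    singles = [g for g, idx in cols.items() if len(idx) < 2]
    if singles:
        raise ValueError(
            f"groups with a single observation: {singles}; use a grouping with "
            "replicates (e.g. the grouped-ordered stage labels) for filtering"
        )
    vals = matrix.values.to_numpy(dtype=float)
    samples = [vals[:, idx] for g, idx in cols.items()]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = stats.f_oneway(*samples, axis=1)
    pvals = np.asarray(pvals)
    if alpha >= 1.0:  # disabled filter: keep everything with a defined F
        keep = ~np.isnan(pvals)
    else:
        keep = pvals < alpha  # NaN p (degenerate probe) compares False
    return [p for p, k in zip(matrix.probe_ids, keep) if k]


def restrict_to_predicted(
    mir_ids: Sequence[str],
    gene_ids: Sequence[str],
    predictions: PredictionSet,
) -> tuple[list[str], list[str]]:
    """Keep only miRs and genes involved in >=1 candidate pair among the ids."""
    mirs = set(map(str, mir_ids))
    genes = set(map(str, gene_ids))
    kept_m: set[str] = set()
    kept_g: set[str] = set()
    for m, g in predictions.pairs():
        if m in mirs and g in genes:
            kept_m.add(m)
            kept_g.add(g)
    return (
        [m for m in map(str, mir_ids) if m in kept_m],
        [g for g in map(str, gene_ids) if g in kept_g],
    )


def zscale(matrix: ExpressionMatrix, atol: float = 1e-12) -> ExpressionMatrix:
    """Scale each probe to mean 0 and sample standard deviation 1 (n-1)."""
    vals = matrix.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    zero = sd <= atol
    if zero.any():
        bad = [p for p, z in zip(matrix.probe_ids, zero) if z][:10]
        raise ValueError(
            f"zero-variance probes cannot be z-scaled: {bad} "
            "(they should have been removed by the ANOVA filter)"
        )
    out = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.platform,
    )


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(path: str | Path, platform: str) -> ExpressionMatrix:
    """Read an expression TSV: first column probe id, header of observation ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), platform)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read the observation annotation TSV (observation_id .. replicate_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {missing}")
    return df
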