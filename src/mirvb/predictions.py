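"""Target-prediction tables and prior feature vectors.

Each candidate (miR, gene) pair carries per-algorithm scores (TargetScan
context+ and miRanda mirSVR in the study setting; any quantitative predictor
works).  A pair's fixed feature vector ``c`` is laid out as
``[indicator_alg1, indicator_alg1 * score_alg1, indicator_alg2, ...]``:
the indicator carries the value of mere list inclusion, the score component
refines it, and a zero score remains distinguishable from "not predicted".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "FeatureVector",
    "read_prediction_table",
    "merge_prediction_sets",
    "TARGETSCAN_COLUMNS",
    "MIRANDA_COLUMNS",
]

log = logging.getLogger(__name__)

# Default column names of the two download dialects the study used.
TARGETSCAN_COLUMNS = {"mir": "miRNA", "gene": "Gene Symbol", "score": "context+ score"}
MIRANDA_COLUMNS = {"mir": "mirna_name", "gene": "gene_symbol", "score": "mirsvr_score"}

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def _canonical_gene(gene: str) -> str:
    """Case-insensitive gene matching after stripping transcript versions."""
    return _VERSION_SUFFIX.sub("", str(gene).strip()).upper()


@dataclass(frozen=True)
class FeatureVector:
    """Fixed prior features for one candidate pair.

    ``values`` has length ``2 * n_algorithms``; indicator components are 0/1
    and a score component is 0 whenever its indicator is 0.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        ind = v[0::2]
        if not np.isin(ind, (0.0, 1.0)).all():
            raise ValueError("indicator components must be 0 or 1")
        if np.any((ind == 0) & (v[1::2] != 0)):
            raise ValueError("score component nonzero for unpredicted algorithm")


@dataclass
class PredictionSet:
    """Candidate (miR, gene) pairs with per-algorithm scores.

    ``algorithms`` fixes the feature-vector layout for the lifetime of the
    object; ``entries`` maps each pair to its algorithm -> score map (every
    entry has at least one score).
    """

    algorithms: list[str]
    entries: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, scores in self.entries.items():
            if not scores:
                raise ValueError(f"pair {pair} has no algorithm scores")
            unknown = set(scores) - set(self.algorithms)
            if unknown:
                raise ValueError(f"pair {pair} scored by undeclared algorithms {unknown}")

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.entries

    @property
    def n_features(self) -> int:
        return 2 * len(self.algorithms)

    def feature_vector(self, pair: tuple[str, str]) -> FeatureVector:
        """Features ``(1, score)`` per predicting algorithm, ``(0, 0)`` otherwise."""
        pair = tuple(pair)
        if pair not in self.entries:
            raise KeyError(
                f"pair {pair} is not a candidate (the candidate set is "
                "prediction-restricted)"
            )
        scores = self.entries[pair]
        vec = np.zeros(self.n_features)
        for k, alg in enumerate(self.algorithms):
            if alg in scores:
                vec[2 * k] = 1.0
                vec[2 * k + 1] = scores[alg]
        return FeatureVector(vec)

    def design_matrix(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return np.vstack([self.feature_vector(p).values for p in pairs])

    def restricted(self, mirs: Iterable[str], genes: Iterable[str]) -> "PredictionSet":
        ms, gs = set(mirs), set(genes)
        kept = {
            pair: dict(scores)
            for pair, scores in self.entries.items()
            if pair[0] in ms and pair[1] in gs
        }
        return PredictionSet(list(self.algorithms), kept)

    def to_tsv(self, path: str | Path) -> None:
        """Write the audit table: one row per candidate pair."""
        rows = []
        for (m, g), scores in sorted(self.entries.items()):
            row: dict[str, object] = {"mir": m, "gene": g}
            for alg in self.algorithms:
                row[f"{alg}_predicted"] = int(alg in scores)
                row[f"{alg}_score"] = scores.get(alg, 0.0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_prediction_table(
    path: str | Path,
    algorithm_name: str,
    column_spec: Mapping[str, str] | None = None,
    known_genes: Iterable[str] | None = None,
) -> PredictionSet:
    """Load one algorithm's prediction TSV into a single-algorithm set.

    Duplicate rows for a pair collapse to the single best (most negative)
    score, matching the convention of both context+ and mirSVR where more
    negative means stronger predicted repression.  Rows with unparseable
    scores are skipped and counted; ``known_genes``, if given, maps gene ids
    case-insensitively (transcript-version suffixes stripped) and drops
    unmatched rows with a count.
    """
    if column_spec is None:
        column_spec = (
            MIRANDA_COLUMNS if "mirsvr" in algorithm_name.lower() else TARGETSCAN_COLUMNS
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("mir", "gene", "score"):
        if column_spec[key] not in df.columns:
            raise ValueError(
                f"{path}: column {column_spec[key]!r} (for {key}) not found; "
                f"available: {list(df.columns)}"
            )

    gene_map = None
    if known_genes is not None:
        gene_map = {_canonical_gene(g): str(g) for g in known_genes}

    entries: dict[tuple[str, str], dict[str, float]] = {}
    skipped_scores = 0
    dropped_genes = 0
    for _, row in df.iterrows():
        raw = row[column_spec["score"]]
        try:
            score = float(raw)
        except (TypeError, ValueError):
            skipped_scores += 1
            continue
        if score != score or pd.isna(row[column_spec["mir"]]) or pd.isna(
            row[column_spec["gene"]]
        ):  # NaN score or missing ids (read_csv maps NULL/NA to NaN)
            skipped_scores += 1
            continue
        mir = str(row[column_spec["mir"]]).strip()
        gene = str(row[column_spec["gene"]]).strip()
        if gene_map is not None:
            mapped = gene_map.get(_canonical_gene(gene))
            if mapped is None:
                dropped_genes += 1
                continue
            gene = mapped
        pair = (mir, gene)
        prev = entries.get(pair, {}).get(algorithm_name)
        if prev is None or score < prev:
            entries[pair] = {algorithm_name: score}
    if skipped_scores:
        log.warning("%s: skipped %d rows with unparseable scores", path, skipped_scores)
    if dropped_genes:
        log.warning("%s: dropped %d rows with unmatched gene ids", path, dropped_genes)
    if not entries:
        raise ValueError(f"{path}: no prediction rows could be parsed")
    return PredictionSet([algorithm_name], entries)


def merge_prediction_sets(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Union of pairs across algorithms; algorithm order follows input order."""
    algorithms: list[str] = []
    for s in sets:
        for alg in s.algorithms:
            if alg in algorithms:
                raise ValueError(f"algorithm {alg!r} appears in more than one set")
            algorithms.append(alg)
    entries: dict[tuple[str, str], dict[str, float]] = {}
    for s in sets:
        for pair, scores in s.entries.items():
            entries.setdefault(pair, {}).update(scores)
    return PredictionSet(algorithms, entries)
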