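"""Genomic evidence: reaction bitscores and the step-wise weight transform.

A genome aligned against a sequence-to-reaction reference dataset yields one
bitscore per (query gene, reference sequence) pair.  Those collapse to a
single non-negative bitscore per reaction, which a piecewise-linear transform
maps into the dgFBA weight space [−1, 1]:

* bitscore 0 (no evidence) → weight −1,
* the threshold bitscore ``b_zero`` (default 500) → weight 0,
* bitscores at or above the saturation knot ``b_sat`` (default 1000) → 1.

Sub-threshold scores still carry graded information — a score just shy of the
threshold argues much less strongly against a function than a score of zero —
which is why the transform is linear on both segments rather than a step.
Bitscores are used raw (no normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_B_SAT, DEFAULT_B_ZERO, logger


@dataclass(frozen=True)
class WeightConfig:
    """Knots of the bitscore → weight transform.

    ``b_zero`` is the annotation-confidence threshold (weight 0); model
    accuracy is insensitive to choices in the 200–500 range, and 500 is the
    default.  ``b_sat`` is the saturation knot at which the weight reaches 1.
    """

    b_zero: float = DEFAULT_B_ZERO
    b_sat: float = DEFAULT_B_SAT

    def __post_init__(self) -> None:
        if not (0.0 < self.b_zero < self.b_sat):
            raise ValueError("require 0 < b_zero < b_sat")


def weight_transform(bitscore: float, cfg: WeightConfig = WeightConfig()) -> float:
    """Step-wise linear map from a reaction bitscore to a weight in [−1, 1].

    Linear from (0, −1) to (``b_zero``, 0), then from (``b_zero``, 0) to
    (``b_sat``, 1), constant 1 beyond; continuous and nondecreasing.
    """
    if bitscore < 0:
        raise ValueError(f"bitscore must be non-negative, got {bitscore}")
    if bitscore <= cfg.b_zero:
        return -1.0 + bitscore / cfg.b_zero
    if bitscore <= cfg.b_sat:
        return (bitscore - cfg.b_zero) / (cfg.b_sat - cfg.b_zero)
    return 1.0


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    """Read gene-level alignments (query_id, reference_id, bitscore).

    The column subset is compatible with tabular BLAST/DIAMOND output.
    """
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "reference_id": str})
    required = {"query_id", "reference_id", "bitscore"}
    if not required.issubset(df.columns):
        raise ValueError(f"alignment TSV must have columns {sorted(required)}")
    if (df["bitscore"] < 0).any():
        raise ValueError("alignment bitscores must be non-negative")
    return df


def read_seq_to_reaction_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read the reference-sequence → reaction mapping (reference_id, reaction_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"reference_id", "reaction_id"}.issubset(df.columns):
        raise ValueError("mapping TSV must have columns reference_id, reaction_id")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.reference_id, set()).add(row.reaction_id)
    return mapping


def reaction_bitscores(
    alignments: pd.DataFrame,
    mapping: Mapping[str, Iterable[str]],
    aggregate: str = "max",
) -> dict[str, float]:
    """Collapse gene-level alignment bitscores into per-reaction bitscores.

    Each reference sequence keeps its best query hit; a reaction's bitscore
    then aggregates over its reference sequences (``max`` by default, ``mean``
    as an alternative).  Reactions with no hits are simply absent, which
    downstream code treats as bitscore 0.  Alignment records whose reference
    id is not in the mapping are logged and skipped.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    if len(alignments) == 0:
        return {}
    if (alignments["bitscore"] < 0).any():
        raise ValueError("alignment bitscores must be non-negative")
    best_hits = alignments.groupby("reference_id")["bitscore"].max()
    unresolved = set(best_hits.index) - set(mapping)
    if unresolved:
        logger.info(
            "%d reference ids not in the sequence-to-reaction mapping; skipped",
            len(unresolved),
        )
    per_reaction: dict[str, list[float]] = {}
    for ref_id, score in best_hits.items():
        for rxn_id in mapping.get(ref_id, ()):
            per_reaction.setdefault(rxn_id, []).append(float(score))
    if aggregate == "max":
        return {r: max(scores) for r, scores in per_reaction.items()}
    return {r: sum(scores) / len(scores) for r, scores in per_reaction.items()}


def reaction_weights(
    evidence: Mapping[str, float],
    cfg: WeightConfig = WeightConfig(),
    reaction_ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Transform per-reaction bitscores into dgFBA weights.

    If ``reaction_ids`` is given, every listed reaction gets a weight;
    reactions missing from the evidence table score as bitscore 0 → weight −1.
    """
    ids = list(reaction_ids) if reaction_ids is not None else list(evidence)
    return {rid: weight_transform(float(evidence.get(rid, 0.0)), cfg) for rid in ids}


def read_evidence_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    if not {"reaction_id", "bitscore"}.issubset(df.columns):
        raise ValueError("evidence TSV must have columns reaction_id, bitscore")
    if (df["bitscore"] < 0).any():
        raise ValueError("reaction bitscores must be non-negative")
    return dict(zip(df["reaction_id"], df["bitscore"].astype(float)))


def write_evidence_tsv(evidence: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(evidence.items()), columns=["reaction_id", "bitscore"]
    ).to_csv(path, sep="\t", index=False)


def read_weights_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    if not {"reaction_id", "weight"}.issubset(df.columns):
        raise ValueError("weights TSV must have columns reaction_id, weight")
    return dict(zip(df["reaction_id"], df["weight"].astype(float)))


def write_weights_tsv(weights: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(weights.items()), columns=["reaction_id", "weight"]
    ).to_csv(path, sep="\t", index=False)
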