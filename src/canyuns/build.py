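"""Model assembly: per-condition training, certainty values, and pruning.

The pipeline runs one dgFBA solve per experimentally observed growth
condition on the universal network, records the direction-tagged
flux-carrying reactions (FCRs) of each solution, and converts the counts into
Certainty Values:

    CV(r, d) = (# growth conditions whose solution uses r in direction d)
               / (total # growth conditions used for training)

Because each solution contributes at most one direction per reaction (net
flux), CV_forward + CV_reverse ≤ 1 always holds.  The organism model consists
of exactly the reactions with CV > 0, restricted to the directions that
earned certainty; exchanges and the biomass pseudo-reaction are retained as
structural necessities.  The draft is then evaluated against the phenotype
table and can be pruned: reactions conditionally essential for more
false-positive than true-positive growth predictions have positive "net
benefit", and removing the top-ranked one improves training accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_B_SAT,
    DEFAULT_B_ZERO,
    DEFAULT_BIOMASS_MIN,
    DEFAULT_EPS,
    DEFAULT_GROWTH_THRESHOLD,
    DEFAULT_RAREFACTION_SAMPLES,
    logger,
)
from .dgfba import FCR, fba_growth, growth_call, solve_condition
from .network import (
    FORWARD,
    REVERSE,
    MediaCondition,
    PhenotypeTable,
    UniversalNetwork,
    split_reversible,
)


@dataclass
class CertaintyTable:
    """Direction-specific certainty values over one training run."""

    values: dict[FCR, float]
    n_conditions: int

    def cv(self, reaction_id: str, direction: str) -> float:
        return self.values.get((reaction_id, direction), 0.0)

    def reactions(self) -> set[str]:
        return {rid for rid, _ in self.values}

    def max_directional_sum(self) -> float:
        """max over reactions of CV_forward + CV_reverse (bounded by 1)."""
        if not self.values:
            return 0.0
        return max(
            self.cv(rid, FORWARD) + self.cv(rid, REVERSE)
            for rid in self.reactions()
        )


@dataclass
class TrainingResult:
    """Per-condition dgFBA outcomes over the observed growth conditions."""

    fcr_sets: dict[str, set[FCR]]
    feasible: set[str]
    n_conditions: int

    @property
    def infeasible(self) -> set[str]:
        return set(self.fcr_sets) - self.feasible


@dataclass
class CanyunsModel:
    """An organism-specific model plus all the evidence behind it."""

    network: UniversalNetwork
    certainty: CertaintyTable
    evidence: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, set[FCR]] = field(default_factory=dict)

    def reaction_ids(self) -> set[str]:
        return set(self.network.reactions)

    def evidence_reaction_ids(self) -> set[str]:
        """Reactions in the model that can carry genomic evidence."""
        return {
            r.id for r in self.network.reactions.values() if r.kind == "internal"
        }


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    mcc_degenerate: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when a marginal is empty."""
        denom = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "mcc_degenerate": self.mcc_degenerate,
        }


@dataclass
class NetBenefitRecord:
    """Leverage of removing one reaction from the draft model."""

    reaction_id: str
    fp_corrected: int
    tp_lost: int
    bitscore: float

    @property
    def net_benefit(self) -> int:
        return self.fp_corrected - self.tp_lost


# ---------------------------------------------------------------------------
# Training: per-condition dgFBA and certainty values
# ---------------------------------------------------------------------------

def run_training(
    universal: UniversalNetwork,
    weights: Mapping[str, float],
    media: Mapping[str, MediaCondition],
    phenotypes: PhenotypeTable,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
    eps: float = DEFAULT_EPS,
    canonical: bool = False,
) -> TrainingResult:
    """Solve dgFBA once per observed growth condition and collect FCR sets.

    Only conditions with an observed ``growth`` call are used; an infeasible
    solve contributes no FCRs but still counts in the certainty denominator.
    """
    growth_conditions = [c for c in phenotypes.growth_conditions() if c in media]
    missing = set(phenotypes.growth_conditions()) - set(media)
    if missing:
        raise KeyError(f"growth conditions without media definitions: {sorted(missing)}")
    if not growth_conditions:
        raise ValueError("no observed growth conditions to train on")
    split = split_reversible(universal)
    fcr_sets: dict[str, set[FCR]] = {}
    feasible: set[str] = set()
    for cond_id in growth_conditions:
        sol, fcrs = solve_condition(
            split, weights, media[cond_id],
            biomass_min=biomass_min, eps=eps, canonical=canonical,
        )
        fcr_sets[cond_id] = fcrs
        if sol.optimal:
            feasible.add(cond_id)
    logger.info(
        "training: %d/%d growth conditions feasible under dgFBA",
        len(feasible),
        len(growth_conditions),
    )
    return TrainingResult(
        fcr_sets=fcr_sets, feasible=feasible, n_conditions=len(growth_conditions)
    )


def compute_cvs(
    fcr_sets: Mapping[str, set[FCR]], n_conditions: int | None = None
) -> CertaintyTable:
    """Certainty values: per-direction flux-carrying frequency across conditions."""
    if not fcr_sets:
        raise ValueError("cannot compute certainty values from zero conditions")
    n = n_conditions if n_conditions is not None else len(fcr_sets)
    counts: dict[FCR, int] = {}
    for fcrs in fcr_sets.values():
        for key in fcrs:
            counts[key] = counts.get(key, 0) + 1
    return CertaintyTable(
        values={key: count / n for key, count in counts.items()},
        n_conditions=n,
    )


# ---------------------------------------------------------------------------
# Assembly and evaluation
# ---------------------------------------------------------------------------

def assemble_model(
    universal: UniversalNetwork,
    certainty: CertaintyTable,
    evidence: Mapping[str, float] | None = None,
    provenance: Mapping[str, set[FCR]] | None = None,
) -> CanyunsModel:
    """Build the organism model from the reactions with non-zero certainty.

    Directionality is restricted to the directions that earned certainty: a
    reversible reaction with CV > 0 in only one direction becomes
    irreversible in that direction, while CVs in both directions keep it
    reversible.  Exchange reactions and the biomass reaction are always
    retained regardless of CV (structural necessities); reactions with
    genomic evidence but CV = 0 are excluded.
    """
    unknown = certainty.reactions() - set(universal.reactions)
    if unknown:
        raise KeyError(f"certainty references unknown reactions: {sorted(unknown)}")
    keep: dict[str, tuple[float, float]] = {}
    for rxn in universal.reactions.values():
        if rxn.kind in ("exchange", "biomass"):
            keep[rxn.id] = (rxn.lower_bound, rxn.upper_bound)
            continue
        fwd = certainty.cv(rxn.id, FORWARD) > 0
        rev = certainty.cv(rxn.id, REVERSE) > 0
        if not (fwd or rev):
            continue
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if fwd and not rev:
            lb = max(lb, 0.0)
        elif rev and not fwd:
            ub = min(ub, 0.0)
        keep[rxn.id] = (lb, ub)
    reactions = {}
    for rid, (lb, ub) in keep.items():
        rxn = universal.reactions[rid].copy()
        rxn.lower_bound, rxn.upper_bound = lb, ub
        reactions[rid] = rxn
    met_ids = {m for r in reactions.values() for m in r.stoichiometry}
    network = UniversalNetwork(
        metabolites={m: universal.metabolites[m].copy() for m in met_ids},
        reactions=reactions,
        biomass_id=universal.biomass_id,
        extracellular=universal.extracellular,
    )
    network.validate()
    return CanyunsModel(
        network=network,
        certainty=certainty,
        evidence=dict(evidence or {}),
        provenance={k: set(v) for k, v in (provenance or {}).items()},
    )


def simulate_phenotypes(
    model: CanyunsModel | UniversalNetwork,
    media: Mapping[str, MediaCondition],
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> dict[str, str]:
    """FBA growth calls for every condition (growth iff flux > threshold)."""
    net = model.network if isinstance(model, CanyunsModel) else model
    split = split_reversible(net)
    return {
        cond_id: growth_call(fba_growth(split, cond), threshold)
        for cond_id, cond in media.items()
    }


def evaluate(
    predictions: Mapping[str, str], observed: PhenotypeTable
) -> ConfusionMatrix:
    """Confusion matrix of growth predictions against observed phenotypes."""
    tp = fp = tn = fn = 0
    for cond_id, call in observed.calls.items():
        if cond_id not in predictions:
            raise KeyError(f"no prediction for condition {cond_id!r}")
        predicted = predictions[cond_id]
        if predicted == "growth":
            tp += call == "growth"
            fp += call == "no_growth"
        else:
            tn += call == "no_growth"
            fn += call == "growth"
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    cm.mcc_degenerate = denom == 0
    return cm


# ---------------------------------------------------------------------------
# Conditional essentiality and net-benefit pruning
# ---------------------------------------------------------------------------

def conditional_essentiality(
    model: CanyunsModel,
    media: Mapping[str, MediaCondition],
    predictions: Mapping[str, str] | None = None,
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> dict[str, set[str]]:
    """Single-reaction knockouts per growth-predicted condition.

    A reaction is conditionally essential in a condition when closing it
    drops the FBA biomass optimum to at or below the growth threshold.  Only
    internal reactions are scanned: exchanges and biomass are structural and
    never candidates for removal.  Conditions not predicted to grow are
    skipped.
    """
    if predictions is None:
        predictions = simulate_phenotypes(model, media, threshold)
    candidates = sorted(model.evidence_reaction_ids())
    essential: dict[str, set[str]] = {}
    for cond_id, call in predictions.items():
        if call != "growth":
            continue
        hits: set[str] = set()
        for rid in candidates:
            knocked = model.network.copy()
            knocked.reactions[rid].lower_bound = 0.0
            knocked.reactions[rid].upper_bound = 0.0
            if fba_growth(knocked, media[cond_id]) <= threshold:
                hits.add(rid)
        essential[cond_id] = hits
    return essential


def net_benefit_ranking(
    essential_sets: Mapping[str, set[str]],
    observed: PhenotypeTable,
    evidence: Mapping[str, float] | None = None,
) -> list[NetBenefitRecord]:
    """Rank reactions by the predictions they would fix upon removal.

    ``fp_corrected`` counts false-positive conditions (predicted growth,
    observed no-growth) where the reaction is conditionally essential —
    removing it corrects those calls; ``tp_lost`` counts true positives that
    would break.  Sorted by net benefit descending, then by annotation
    evidence ascending (least-evidence first), matching how a curator picks
    the reaction with maximum leverage and least support.
    """
    evidence = evidence or {}
    records: dict[str, NetBenefitRecord] = {}
    for cond_id, reactions in essential_sets.items():
        call = observed.calls.get(cond_id)
        if call is None:
            raise KeyError(f"no observed phenotype for condition {cond_id!r}")
        for rid in reactions:
            rec = records.setdefault(
                rid,
                NetBenefitRecord(
                    reaction_id=rid,
                    fp_corrected=0,
                    tp_lost=0,
                    bitscore=float(evidence.get(rid, 0.0)),
                ),
            )
            if call == "no_growth":
                rec.fp_corrected += 1
            else:
                rec.tp_lost += 1
    return sorted(
        records.values(),
        key=lambda r: (-r.net_benefit, r.bitscore, r.reaction_id),
    )


def prune(model: CanyunsModel, reaction_ids: Iterable[str]) -> CanyunsModel:
    """Remove reactions from a model (the manual-curation step).

    Certainty values and provenance are carried over for the remaining
    reactions; structural reactions (exchange/biomass) cannot be pruned.
    """
    ids = list(reaction_ids)
    unknown = [r for r in ids if r not in model.network.reactions]
    if unknown:
        raise KeyError(f"cannot prune unknown reactions: {unknown}")
    structural = [
        r for r in ids if model.network.reactions[r].kind in ("exchange", "biomass")
    ]
    if structural:
        raise ValueError(f"cannot prune structural reactions: {structural}")
    network = model.network.copy()
    for rid in ids:
        del network.reactions[rid]
    dropped = set(ids)
    certainty = CertaintyTable(
        values={
            key: v for key, v in model.certainty.values.items() if key[0] not in dropped
        },
        n_conditions=model.certainty.n_conditions,
    )
    return CanyunsModel(
        network=network,
        certainty=certainty,
        evidence=dict(model.evidence),
        provenance={
            c: {key for key in fcrs if key[0] not in dropped}
            for c, fcrs in model.provenance.items()
        },
    )


# ---------------------------------------------------------------------------
# Rarefaction and reference comparison
# ---------------------------------------------------------------------------

def rarefaction(
    fcr_sets: Mapping[str, set[FCR]],
    n_samples: int = DEFAULT_RAREFACTION_SAMPLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Accumulation curve of unique FCRs over random condition subsets.

    For each subset size k = 1..N, ``n_samples`` subsets of k distinct
    conditions are drawn (subsets resampled independently), and the number of
    unique reactions in the union of their FCR sets is recorded.  Returns a
    frame with columns ``k``, ``min``, ``mean``, ``max``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cond_ids = list(fcr_sets)
    reaction_sets = [
        frozenset(rid for rid, _ in fcr_sets[c]) for c in cond_ids
    ]
    n = len(cond_ids)
    rows = []
    for k in range(1, n + 1):
        counts = np.empty(n_samples, dtype=int)
        for s in range(n_samples):
            picked = rng.choice(n, size=k, replace=False)
            union: set[str] = set()
            for i in picked:
                union |= reaction_sets[i]
            counts[s] = len(union)
        rows.append(
            {
                "k": k,
                "min": int(counts.min()),
                "mean": float(counts.mean()),
                "max": int(counts.max()),
            }
        )
    return pd.DataFrame(rows, columns=["k", "min", "mean", "max"])


@dataclass
class DiscoveryReport:
    """Four-way split of model reactions against a reference reconstruction."""

    confirmed: set[str]
    true_discovered: set[str]
    likely_additions: set[str]
    false_discovered: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "confirmed": len(self.confirmed),
            "true_discovered": len(self.true_discovered),
            "likely_additions": len(self.likely_additions),
            "false_discovered": len(self.false_discovered),
        }

    @property
    def discovery_accuracy(self) -> float | None:
        """Among reactions lacking evidence, the fraction found in the reference.

        ``None`` (not applicable) when the model discovered nothing.
        """
        discovered = len(self.true_discovered) + len(self.false_discovered)
        if discovered == 0:
            return None
        return len(self.true_discovered) / discovered

    @property
    def reference_overlap(self) -> float | None:
        total = sum(self.counts.values())
        if total == 0:
            return None
        return (len(self.confirmed) + len(self.true_discovered)) / total


def discovery_metrics(
    model: CanyunsModel,
    reference_ids: Iterable[str],
    evidence: Mapping[str, float] | None = None,
    bitscore_threshold: float = DEFAULT_B_ZERO,
) -> DiscoveryReport:
    """Categorise model reactions by (evidence ≥ threshold?, in reference?).

    * confirmed: evidence and in the reference model;
    * true discovered: no sufficient evidence, yet in the reference;
    * likely additions: evidence, absent from the reference;
    * false discovered: neither.
    """
    evidence = evidence if evidence is not None else model.evidence
    reference = set(reference_ids)
    report = DiscoveryReport(set(), set(), set(), set())
    for rid in model.evidence_reaction_ids():
        has_evidence = float(evidence.get(rid, 0.0)) >= bitscore_threshold
        in_reference = rid in reference
        if has_evidence and in_reference:
            report.confirmed.add(rid)
        elif not has_evidence and in_reference:
            report.true_discovered.add(rid)
        elif has_evidence:
            report.likely_additions.add(rid)
        else:
            report.false_discovered.add(rid)
    return report


def cv_stratified_overlap(
    model: CanyunsModel,
    reference_ids: Iterable[str],
    bins: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    evidence: Mapping[str, float] | None = None,
    bitscore_threshold: float | None = None,
) -> pd.DataFrame:
    """Reference overlap per certainty-value bin.

    Each candidate reaction enters the bin of its maximum directional CV; the
    overlap is the fraction of binned reactions present in the reference.
    With ``bitscore_threshold`` set, only reactions *below* the threshold are
    considered, which stratifies discovery accuracy by certainty.  Bins with
    no members report NaN.
    """
    evidence = evidence if evidence is not None else model.evidence
    reference = set(reference_ids)
    candidates = []
    for rid in model.evidence_reaction_ids():
        if bitscore_threshold is not None and (
            float(evidence.get(rid, 0.0)) >= bitscore_threshold
        ):
            continue
        cv = max(
            model.certainty.cv(rid, FORWARD), model.certainty.cv(rid, REVERSE)
        )
        candidates.append((rid, cv))
    edges = list(bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [
            rid
            for rid, cv in candidates
            if (lo < cv <= hi) or (lo == edges[0] and cv == lo)
        ]
        overlap = (
            sum(rid in reference for rid in members) / len(members)
            if members
            else float("nan")
        )
        rows.append(
            {"cv_low": lo, "cv_high": hi, "n": len(members), "overlap": overlap}
        )
    return pd.DataFrame(rows, columns=["cv_low", "cv_high", "n", "overlap"])


def build_canyuns_model(
    universal: UniversalNetwork,
    evidence: Mapping[str, float],
    media: Mapping[str, MediaCondition],
    phenotypes: PhenotypeTable,
    weights: Mapping[str, float] | None = None,
    b_zero: float = DEFAULT_B_ZERO,
    b_sat: float | None = None,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    eps: float = DEFAULT_EPS,
    canonical: bool = False,
) -> tuple[CanyunsModel, TrainingResult, dict[str, str], ConfusionMatrix]:
    """End-to-end: train, assemble, and evaluate one organism model.

    Returns the assembled model, the per-condition training record, the
    model's growth predictions over all media, and the confusion matrix
    against the observed phenotypes.  ``weights`` may be passed directly
    (e.g. for a parsimonious run with an empty mapping); otherwise they are
    derived from the evidence bitscores.
    """
    from .evidence import WeightConfig, reaction_weights

    if weights is None:
        cfg = WeightConfig(
            b_zero=b_zero,
            b_sat=b_sat if b_sat is not None else max(DEFAULT_B_SAT, 2 * b_zero),
        )
        weights = reaction_weights(
            evidence, cfg, reaction_ids=universal.reactions
        )
    training = run_training(
        universal, weights, media, phenotypes,
        biomass_min=biomass_min, eps=eps, canonical=canonical,
    )
    certainty = compute_cvs(training.fcr_sets, training.n_conditions)
    model = assemble_model(
        universal, certainty, evidence=evidence, provenance=training.fcr_sets
    )
    predictions = simulate_phenotypes(model, media, threshold=growth_threshold)
    confusion = evaluate(predictions, phenotypes)
    logger.info(
        "draft model: %d reactions, accuracy %.3f, MCC %.3f",
        len(model.network.reactions),
        confusion.accuracy,
        confusion.mcc,
    )
    return model, training, predictions, confusion


def write_certainty_tsv(
    model: CanyunsModel, path, evidence: Mapping[str, float] | None = None
) -> None:
    evidence = evidence if evidence is not None else model.evidence
    rows = [
        {
            "reaction_id": rid,
            "direction": direction,
            "cv": cv,
            "bitscore": float(evidence.get(rid, 0.0)),
        }
        for (rid, direction), cv in sorted(model.certainty.values.items())
    ]
    pd.DataFrame(
        rows, columns=["reaction_id", "direction", "cv", "bitscore"]
    ).to_csv(path, sep="\t", index=False)
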