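"""Synthetic universal networks with planted ground truth.

Every stage of the reconstruction pipeline is testable without downloads by
generating toy universal networks in which a known "organism" — a planted
subnetwork of pathways — is hidden among decoy reactions:

* Each pathway runs from its own extracellular carbon source through a linear
  chain of conversions to a shared biomass precursor.  Decoy reactions add
  parsimonious shortcuts (fewer steps to the precursor, the trap that pure
  flux-minimisation falls into) and dead ends.
* Chemistry is abstract: every metabolite carries a single pseudo-element of
  unit mass, so all generated reactions are elementally balanced by
  construction and the free-mass scan returns zero unless a defect is
  injected deliberately.
* Evidence emulates a genome alignment: planted reactions draw high
  bitscores, decoys low ones, with an optional label-noise fraction swapping
  the two classes.
* Phenotypes are computed, not asserted: one media condition per carbon
  source, with the growth call obtained by FBA on the planted subnetwork.

An optional mis-annotation module emulates the classic curation failure (a
well-scoring reaction chain the organism does not actually use, fed by a
co-substrate present in every medium): it acquires certainty during training
and produces a false-positive growth call that net-benefit pruning can fix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .config import DEFAULT_BOUND, DEFAULT_GROWTH_THRESHOLD, DEFAULT_UPTAKE
from .dgfba import fba_growth, growth_call
from .network import (
    MediaCondition,
    Metabolite,
    PhenotypeTable,
    Reaction,
    UniversalNetwork,
    write_media_tsv,
    write_network,
    write_phenotype_tsv,
)
from .evidence import write_evidence_tsv

BIOMASS_ID = "BIOMASS"
_X = {"X": 1}  # unit-mass pseudo-element formula


@dataclass
class SyntheticScenario:
    """A generated benchmark with known ground truth."""

    universal: UniversalNetwork
    truth: set[str]  # reaction ids of the planted subnetwork
    evidence: dict[str, float]
    media: dict[str, MediaCondition]
    phenotypes: PhenotypeTable
    seed: int | None
    misannotated: set[str] = field(default_factory=set)

    def truth_internal(self) -> set[str]:
        """Planted reactions that carry genomic evidence (internal only)."""
        return {
            rid for rid in self.truth
            if self.universal.reactions[rid].kind == "internal"
        }

    def truth_network(self) -> UniversalNetwork:
        """The planted subnetwork as a standalone model."""
        net = self.universal.copy()
        net.reactions = {
            rid: rxn for rid, rxn in net.reactions.items() if rid in self.truth
        }
        return net


def generate_network(
    n_pathways: int = 4,
    pathway_length: int = 3,
    n_decoys: int = 4,
    reversible_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> UniversalNetwork:
    """Build a toy universal network of convergent linear pathways plus decoys.

    Pathway ``i`` is ``EX_src{i}`` → transport ``TR_src{i}`` → steps
    ``PW{i}_{j}`` → the shared biomass precursor.  Decoys alternate between
    shortcut reactions (source straight to the precursor in one step) and
    dead-end reactions.  ``reversible_fraction`` of internal reactions get
    bounds ±1000 instead of [0, 1000].
    """
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    if pathway_length < 1:
        raise ValueError("pathway_length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    metabolites: dict[str, Metabolite] = {
        "bm_c": Metabolite("bm_c", formula=dict(_X), compartment="c")
    }
    reactions: dict[str, Reaction] = {}

    def add_met(mid: str, compartment: str) -> None:
        metabolites[mid] = Metabolite(mid, formula=dict(_X), compartment=compartment)

    for i in range(1, n_pathways + 1):
        src_e, src_c = f"src{i}_e", f"src{i}_c"
        add_met(src_e, "e")
        add_met(src_c, "c")
        reactions[f"EX_src{i}"] = Reaction(
            id=f"EX_src{i}",
            stoichiometry={src_e: -1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
            kind="exchange",
        )
        reactions[f"TR_src{i}"] = Reaction(
            id=f"TR_src{i}",
            stoichiometry={src_e: -1.0, src_c: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        chain = [src_c] + [
            f"m{i}_{j}" for j in range(1, pathway_length)
        ] + ["bm_c"]
        for met in chain[1:-1]:
            add_met(met, "c")
        for j, (a, b) in enumerate(zip(chain[:-1], chain[1:]), start=1):
            rid = f"PW{i}_{j}"
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry={a: -1.0, b: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )

    for k in range(n_decoys):
        i = (k % n_pathways) + 1
        if k % 2 == 0:  # parsimonious shortcut: source -> precursor in one step
            rid = f"DS{k}_src{i}"
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry={f"src{i}_c": -1.0, "bm_c": 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        else:  # dead end off the first pathway intermediate
            tail = f"m{i}_1" if pathway_length > 1 else f"src{i}_c"
            dead = f"dead{k}_c"
            add_met(dead, "c")
            rid = f"DD{k}_src{i}"
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry={tail: -1.0, dead: 1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )

    reactions[BIOMASS_ID] = Reaction(
        id=BIOMASS_ID,
        stoichiometry={"bm_c": -1.0},
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        kind="biomass",
    )

    if reversible_fraction > 0:
        for rid in sorted(reactions):
            rxn = reactions[rid]
            if rxn.kind == "internal" and rng.random() < reversible_fraction:
                rxn.lower_bound = -DEFAULT_BOUND

    net = UniversalNetwork(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=BIOMASS_ID,
        extracellular="e",
    )
    net.validate()
    return net


def inject_mass_loop(
    net: UniversalNetwork,
    seed: int | None = None,
    kind: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[UniversalNetwork, set[str]]:
    """Plant a free-mass defect; the scan on the result must flag it.

    ``kind="imbalanced"`` adds a single net mass-creating reaction (the net
    form of A → A + B); ``kind="cycle"`` adds a stoichiometrically amplifying
    two-reaction loop (A → 2B′, B′ → A) whose members are individually
    unflaggable by elemental checks when B′ lacks a formula.  Returns the
    modified copy and the injected reaction ids.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if kind is None:
        kind = "imbalanced" if rng.random() < 0.5 else "cycle"
    cytosolic = sorted(
        m.id for m in net.metabolites.values()
        if m.compartment != net.extracellular
    )
    anchor = cytosolic[int(rng.integers(len(cytosolic)))]
    out = net.copy()
    if kind == "imbalanced":
        out.metabolites["freegen_c"] = Metabolite(
            "freegen_c", formula=dict(_X), compartment="c"
        )
        out.reactions["FREEGEN"] = Reaction(
            id="FREEGEN",
            stoichiometry={"freegen_c": 1.0},  # net of anchor -> anchor + freegen
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        injected = {"FREEGEN"}
    elif kind == "cycle":
        out.metabolites["amp_c"] = Metabolite("amp_c", formula=None, compartment="c")
        out.reactions["CYCLE_A"] = Reaction(
            id="CYCLE_A",
            stoichiometry={anchor: -1.0, "amp_c": 2.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        out.reactions["CYCLE_B"] = Reaction(
            id="CYCLE_B",
            stoichiometry={"amp_c": -1.0, anchor: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        injected = {"CYCLE_A", "CYCLE_B"}
    else:
        raise ValueError(f"unknown injection kind {kind!r}")
    out.validate()
    return out, injected


def _draw_bitscore(rng: np.random.Generator, cls: str, mean_truth: float, mean_decoy: float) -> float:
    if cls == "truth":
        return float(np.clip(rng.normal(mean_truth, 150.0), 525.0, 2500.0))
    return float(np.clip(rng.normal(mean_decoy, 75.0), 0.0, 475.0))


def generate_scenario(
    n_conditions: int = 8,
    pathway_length: int = 3,
    n_decoys: int = 4,
    reversible_fraction: float = 0.25,
    b_truth_mean: float = 900.0,
    b_decoy_mean: float = 100.0,
    noise_fraction: float = 0.0,
    growth_fraction: float = 0.75,
    with_misannotation: bool = False,
    uptake: float = DEFAULT_UPTAKE,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    seed: int | None = None,
) -> SyntheticScenario:
    """Generate a full benchmark: network, truth, evidence, media, phenotypes.

    One pathway (and one media condition) per carbon source; a
    ``growth_fraction`` of pathways is planted in the organism, the rest stay
    decoys whose conditions the organism cannot grow on.  Phenotype calls are
    produced by FBA on the planted subnetwork with the given threshold, so
    they are exactly reproducible from (truth, media, threshold).
    """
    if n_conditions < 1:
        raise ValueError("the pipeline needs at least one media condition")
    rng = np.random.default_rng(seed)
    universal = generate_network(
        n_pathways=n_conditions,
        pathway_length=pathway_length,
        n_decoys=n_decoys,
        reversible_fraction=reversible_fraction,
        rng=rng,
    )

    misannotated: set[str] = set()
    if with_misannotation:
        for mid, comp in (("co_e", "e"), ("co_c", "c"), ("co2_c", "c")):
            universal.metabolites[mid] = Metabolite(
                mid, formula=dict(_X), compartment=comp
            )
        universal.reactions["EX_co"] = Reaction(
            id="EX_co",
            stoichiometry={"co_e": -1.0},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
            kind="exchange",
        )
        chain = (
            ("MIS_TR_co", {"co_e": -1.0, "co_c": 1.0}),
            ("MIS_FIX1", {"co_c": -1.0, "co2_c": 1.0}),
            ("MIS_FIX2", {"co2_c": -1.0, "bm_c": 1.0}),
        )
        for rid, stoich in chain:
            universal.reactions[rid] = Reaction(
                id=rid, stoichiometry=stoich, lower_bound=0.0, upper_bound=DEFAULT_BOUND
            )
            misannotated.add(rid)
        universal.validate()

    n_growth = max(1, int(round(growth_fraction * n_conditions)))
    planted = set(
        (rng.choice(n_conditions, size=n_growth, replace=False) + 1).tolist()
    )

    truth: set[str] = {BIOMASS_ID}
    truth |= {r.id for r in universal.reactions.values() if r.kind == "exchange"}
    for i in sorted(planted):
        truth.add(f"TR_src{i}")
        truth |= {
            rid for rid in universal.reactions if rid.startswith(f"PW{i}_")
        }

    evidence: dict[str, float] = {}
    for rid in sorted(universal.internal_ids()):
        if rid in misannotated:
            evidence[rid] = _draw_bitscore(rng, "truth", b_truth_mean, b_decoy_mean)
            continue
        cls = "truth" if rid in truth else "decoy"
        if noise_fraction > 0 and rng.random() < noise_fraction:
            cls = "decoy" if cls == "truth" else "truth"
        evidence[rid] = _draw_bitscore(rng, cls, b_truth_mean, b_decoy_mean)

    media: dict[str, MediaCondition] = {}
    for i in range(1, n_conditions + 1):
        cond = MediaCondition(f"cond_{i}", {f"EX_src{i}": float(uptake)})
        if with_misannotation:
            cond.uptake["EX_co"] = float(uptake)
        media[cond.id] = cond
    if with_misannotation:
        media["cond_co"] = MediaCondition("cond_co", {"EX_co": float(uptake)})

    scenario = SyntheticScenario(
        universal=universal,
        truth=truth,
        evidence=evidence,
        media=media,
        phenotypes=PhenotypeTable(calls={}),
        seed=seed,
        misannotated=misannotated,
    )
    truth_net = scenario.truth_network()
    scenario.phenotypes = PhenotypeTable(
        calls={
            cond_id: growth_call(fba_growth(truth_net, cond), growth_threshold)
            for cond_id, cond in media.items()
        }
    )
    return scenario


PRESETS: dict[str, dict] = {
    "small": dict(
        n_conditions=4, pathway_length=3, n_decoys=4,
        reversible_fraction=0.25, noise_fraction=0.0,
    ),
    "noisy": dict(
        n_conditions=8, pathway_length=3, n_decoys=6,
        reversible_fraction=0.25, noise_fraction=0.2, with_misannotation=True,
    ),
    "loops": dict(
        n_conditions=4, pathway_length=3, n_decoys=4,
        reversible_fraction=0.25, noise_fraction=0.0,
    ),
}


def write_scenario(
    scenario: SyntheticScenario, outdir: str | Path, network_format: str = "json"
) -> dict[str, Path]:
    """Serialise a scenario to the file formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = "json" if network_format == "json" else "xml"
    paths = {
        "network": outdir / f"network.{suffix}",
        "evidence": outdir / "evidence.tsv",
        "media": outdir / "media.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth_reactions.txt",
        "meta": outdir / "scenario.json",
    }
    write_network(scenario.universal, paths["network"], format=network_format)
    write_evidence_tsv(scenario.evidence, paths["evidence"])
    write_media_tsv(scenario.media, paths["media"])
    write_phenotype_tsv(scenario.phenotypes, paths["phenotypes"])
    paths["truth"].write_text("\n".join(sorted(scenario.truth)) + "\n")
    paths["meta"].write_text(
        json.dumps(
            {
                "seed": scenario.seed,
                "misannotated": sorted(scenario.misannotated),
                "n_conditions": len(scenario.media),
            },
            indent=1,
        )
        + "\n"
    )
    return paths
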