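"""Stoichiometric network data model, standard-format I/O, and media handling.

The central objects are :class:`UniversalNetwork` — a curated universal
biochemical network holding every reaction an organism *might* catalyse — and
:class:`SplitNetwork`, the non-negative reformulation in which every reversible
reaction is represented as a forward and a reverse component.  All linear
programs in this package (data-guided FBA, parsimonious FBA, the free-mass
scan) are posed over one of these two forms.

Conventions
-----------
* Exchange reactions are written ``1 metabolite <-> nothing`` with a
  coefficient of −1, so negative flux is uptake.  After splitting, the uptake
  direction is therefore the *reverse* component, which is what media
  application constrains.
* Reaction bounds default to 0 / ±1000 mmol gDW⁻¹ h⁻¹.
* Compartments are free-form strings; one configured tag (default ``"e"``)
  marks the extracellular space, which is all the exchange/sink logic needs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .config import DEFAULT_BOUND, logger

REACTION_KINDS = ("internal", "exchange", "sink", "biomass")

FORWARD = "forward"
REVERSE = "reverse"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class MediaError(ValueError):
    """Raised when a media condition references an unusable reaction."""


def parse_formula(text: str | None) -> dict[str, int] | None:
    """Parse an elemental formula string like ``C6H12O6`` into a count map."""
    if text is None or text == "":
        return None
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula: {text!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"unparseable formula: {text!r}")
    return counts


def format_formula(counts: Mapping[str, int] | None) -> str | None:
    if counts is None:
        return None
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items())
    )


@dataclass
class Metabolite:
    id: str
    formula: dict[str, int] | None = None
    charge: int = 0
    compartment: str = "c"

    def copy(self) -> "Metabolite":
        return replace(self, formula=dict(self.formula) if self.formula else None)


@dataclass
class Reaction:
    """A reaction column: signed stoichiometry plus flux bounds and a kind.

    ``kind`` distinguishes ordinary internal reactions from boundary
    pseudo-reactions (exchange, sink) and the biomass objective, which are
    exempt from elemental balancing.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    kind: str = "internal"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class UniversalNetwork:
    """A stoichiometric network with a designated biomass reaction."""

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_id: str
    extracellular: str = "e"

    def copy(self) -> "UniversalNetwork":
        return UniversalNetwork(
            metabolites={k: m.copy() for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            biomass_id=self.biomass_id,
            extracellular=self.extracellular,
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.biomass_id not in self.reactions:
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_id!r} not in network"
            )
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise NetworkValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise NetworkValidationError(
                    f"reaction {rxn.id!r}: lower bound exceeds upper bound"
                )
            if rxn.kind not in REACTION_KINDS:
                raise NetworkValidationError(f"reaction {rxn.id!r}: unknown kind {rxn.kind!r}")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise NetworkValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise NetworkValidationError(
                        f"exchange {rxn.id!r} must touch exactly one metabolite"
                    )
                (met_id, coef), = rxn.stoichiometry.items()
                if self.metabolites[met_id].compartment != self.extracellular:
                    raise NetworkValidationError(
                        f"exchange {rxn.id!r} touches non-extracellular metabolite {met_id!r}"
                    )
                if coef >= 0:
                    raise NetworkValidationError(
                        f"exchange {rxn.id!r} must consume its metabolite "
                        "(coefficient -1; negative flux = uptake)"
                    )

    # -- views --------------------------------------------------------------

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.kind == "exchange"]

    def internal_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.kind == "internal"]

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Return (S, metabolite ids, reaction ids) with S[i, j] = coefficient."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# Split-reversible transform
# ---------------------------------------------------------------------------

@dataclass
class SplitComponent:
    """One direction of a base reaction; flux is non-negative by construction."""

    id: str
    base_id: str
    direction: str  # FORWARD or REVERSE
    stoichiometry: dict[str, float]
    upper_bound: float

    def copy(self) -> "SplitComponent":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class SplitNetwork:
    """Non-negative reformulation of a :class:`UniversalNetwork`.

    Every reversible base reaction appears as two opposing components; the net
    flux of a base reaction is forward-component flux minus reverse-component
    flux.  Irreversible reactions contribute a single component.
    """

    base: UniversalNetwork
    components: dict[str, SplitComponent]

    def copy(self) -> "SplitNetwork":
        return SplitNetwork(
            base=self.base,
            components={k: c.copy() for k, c in self.components.items()},
        )

    @property
    def mapping(self) -> dict[str, tuple[str, str]]:
        return {c.id: (c.base_id, c.direction) for c in self.components.values()}

    def components_of(self, base_id: str) -> dict[str, SplitComponent]:
        return {
            c.direction: c for c in self.components.values() if c.base_id == base_id
        }

    def matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Return (S, metabolite ids, component ids) over split components."""
        met_ids = list(self.base.metabolites)
        comp_ids = list(self.components)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, cid in enumerate(comp_ids):
            for met_id, coef in self.components[cid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(comp_ids))
        )
        return S, met_ids, comp_ids

    def net_fluxes(self, component_fluxes: Mapping[str, float]) -> dict[str, float]:
        """Recombine component fluxes into net base-reaction fluxes.

        Component ids follow the ``<base>__fwd`` / ``<base>__rev`` scheme, so
        fluxes from media-adjusted copies (which may hold an extra uptake
        component) recombine correctly as well.
        """
        net: dict[str, float] = {rid: 0.0 for rid in self.base.reactions}
        for cid, value in component_fluxes.items():
            if cid.endswith("__fwd"):
                net[cid[:-5]] += value
            elif cid.endswith("__rev"):
                net[cid[:-5]] -= value
            else:  # pragma: no cover - component ids are package-generated
                raise KeyError(f"unrecognised split component id {cid!r}")
        return net


def split_reversible(net: UniversalNetwork) -> SplitNetwork:
    """Represent every reversible reaction as two opposing components.

    Forward components keep the base stoichiometry with bound
    ``[0, upper_bound]``; reverse components negate it with bound
    ``[0, -lower_bound]``.  Irreversible reactions pass through as a single
    component.
    """
    net.validate()
    components: dict[str, SplitComponent] = {}
    for rxn in net.reactions.values():
        if rxn.upper_bound > 0:
            cid = f"{rxn.id}__fwd"
            components[cid] = SplitComponent(
                id=cid,
                base_id=rxn.id,
                direction=FORWARD,
                stoichiometry=dict(rxn.stoichiometry),
                upper_bound=rxn.upper_bound,
            )
        if rxn.lower_bound < 0:
            cid = f"{rxn.id}__rev"
            components[cid] = SplitComponent(
                id=cid,
                base_id=rxn.id,
                direction=REVERSE,
                stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
                upper_bound=-rxn.lower_bound,
            )
    return SplitNetwork(base=net, components=components)


# ---------------------------------------------------------------------------
# Media and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class MediaCondition:
    """A growth medium: per exchange reaction, the maximum uptake magnitude."""

    id: str
    uptake: dict[str, float] = field(default_factory=dict)

    def validate(self, net: UniversalNetwork) -> None:
        for ex_id, limit in self.uptake.items():
            rxn = net.reactions.get(ex_id)
            if rxn is None or rxn.kind != "exchange":
                raise MediaError(
                    f"media {self.id!r} references non-exchange reaction {ex_id!r}"
                )
            if limit < 0:
                raise MediaError(
                    f"media {self.id!r}: negative uptake limit for {ex_id!r}"
                )


@dataclass
class PhenotypeTable:
    """Observed binary growth calls per media condition."""

    calls: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.calls.values() if v not in ("growth", "no_growth")}
        if bad:
            raise ValueError(f"unknown phenotype calls: {sorted(bad)}")

    def growth_conditions(self) -> list[str]:
        return [c for c, v in self.calls.items() if v == "growth"]


def apply_media(split: SplitNetwork, media: MediaCondition) -> SplitNetwork:
    """Constrain exchange uptake components to represent one growth medium.

    Uptake components of exchange reactions absent from ``media.uptake`` are
    closed (upper bound 0); listed exchanges receive the stated limit.
    Secretion components and internal reactions are never altered.
    """
    media.validate(split.base)
    out = split.copy()
    for ex_id in split.base.exchange_ids():
        limit = float(media.uptake.get(ex_id, 0.0))
        rev_id = f"{ex_id}__rev"
        comp = out.components.get(rev_id)
        if comp is not None:
            comp.upper_bound = limit
        elif limit > 0:
            # Exchange declared secretion-only in the base network but the
            # medium supplies it: open an uptake component on the fly.
            (met_id, coef), = split.base.reactions[ex_id].stoichiometry.items()
            out.components[rev_id] = SplitComponent(
                id=rev_id,
                base_id=ex_id,
                direction=REVERSE,
                stoichiometry={met_id: -coef},
                upper_bound=limit,
            )
    return out


# ---------------------------------------------------------------------------
# I/O: flat JSON dialect and SBML (via cobrapy / libsbml)
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer network format from {path!r}; pass format=")


def _network_to_dict(net: UniversalNetwork) -> dict:
    return {
        "biomass_id": net.biomass_id,
        "extracellular": net.extracellular,
        "metabolites": [
            {
                "id": m.id,
                "formula": format_formula(m.formula),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in net.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
            }
            for r in net.reactions.values()
        ],
    }


def _network_from_dict(data: dict) -> UniversalNetwork:
    metabolites = {
        m["id"]: Metabolite(
            id=m["id"],
            formula=parse_formula(m.get("formula")),
            charge=int(m.get("charge", 0)),
            compartment=m.get("compartment", "c"),
        )
        for m in data["metabolites"]
    }
    reactions = {
        r["id"]: Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            kind=r.get("kind", "internal"),
        )
        for r in data["reactions"]
    }
    net = UniversalNetwork(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=data["biomass_id"],
        extracellular=data.get("extracellular", "e"),
    )
    net.validate()
    return net


def infer_reaction_kinds(
    net: UniversalNetwork, biomass_id: str | None = None,
    biomass_pattern: str = "biomass",
) -> None:
    """Assign reaction kinds in place for networks read from kind-less formats.

    Exchange = single metabolite in the extracellular compartment with a
    negative coefficient; biomass by explicit id or case-insensitive id
    pattern; everything else internal.
    """
    pattern = biomass_pattern.lower()
    for rxn in net.reactions.values():
        if biomass_id is not None and rxn.id == biomass_id:
            rxn.kind = "biomass"
            continue
        if biomass_id is None and pattern in rxn.id.lower():
            rxn.kind = "biomass"
            continue
        if len(rxn.stoichiometry) == 1:
            (met_id, coef), = rxn.stoichiometry.items()
            met = net.metabolites.get(met_id)
            if met is not None and met.compartment == net.extracellular and coef < 0:
                rxn.kind = "exchange"
                continue
        rxn.kind = "internal"


def read_network(
    path: str | Path,
    format: str | None = None,
    biomass_id: str | None = None,
    biomass_pattern: str = "biomass",
    extracellular: str = "e",
) -> UniversalNetwork:
    """Read a universal network from SBML or the flat JSON dialect.

    The JSON dialect stores reaction kinds and the biomass id explicitly;
    for SBML they are inferred (see :func:`infer_reaction_kinds`).
    """
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            return _network_from_dict(json.load(fh))
    if fmt != "sbml":
        raise ValueError(f"unknown format {fmt!r}")

    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    metabolites = {
        m.id: Metabolite(
            id=m.id,
            formula=parse_formula(m.formula),
            charge=int(m.charge or 0),
            compartment=m.compartment or "c",
        )
        for m in model.metabolites
    }
    reactions = {
        r.id: Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
        )
        for r in model.reactions
    }
    net = UniversalNetwork(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=biomass_id or "",
        extracellular=extracellular,
    )
    infer_reaction_kinds(net, biomass_id=biomass_id, biomass_pattern=biomass_pattern)
    biomass = [r.id for r in net.reactions.values() if r.kind == "biomass"]
    if not biomass:
        raise NetworkValidationError(
            f"no biomass reaction identifiable in {path} "
            f"(pattern {biomass_pattern!r}, explicit id {biomass_id!r})"
        )
    if len(biomass) > 1:
        raise NetworkValidationError(f"multiple biomass candidates: {biomass}")
    net.biomass_id = biomass[0]
    net.validate()
    return net


def write_network(
    net: UniversalNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write a network to SBML (L3/FBC, via libsbml) or the JSON dialect."""
    net.validate()
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_network_to_dict(net), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if fmt != "sbml":
        raise ValueError(f"unknown format {fmt!r}")

    import cobra

    model = cobra.Model("canyuns_network")
    mets = {
        m.id: cobra.Metabolite(
            m.id,
            formula=format_formula(m.formula),
            charge=m.charge,
            compartment=m.compartment,
        )
        for m in net.metabolites.values()
    }
    cobra_rxns = []
    for rxn in net.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        cobra_rxns.append(cr)
    model.add_reactions(cobra_rxns)
    for rxn in net.reactions.values():
        model.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    model.objective = net.biomass_id
    cobra.io.write_sbml_model(model, str(path))


def to_cobra(net: UniversalNetwork):
    """Convert to a cobrapy model (used for cross-checks and export)."""
    import cobra

    model = cobra.Model("canyuns_network")
    mets = {
        m.id: cobra.Metabolite(
            m.id,
            formula=format_formula(m.formula),
            charge=m.charge,
            compartment=m.compartment,
        )
        for m in net.metabolites.values()
    }
    rxns = []
    for rxn in net.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        rxns.append(cr)
    model.add_reactions(rxns)
    for rxn in net.reactions.values():
        model.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    model.objective = net.biomass_id
    return model


# ---------------------------------------------------------------------------
# Tabular inputs: media and phenotype TSVs
# ---------------------------------------------------------------------------

def read_media_tsv(path: str | Path) -> dict[str, MediaCondition]:
    """Read a media table (condition_id, exchange_id, max_uptake)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"condition_id": str, "exchange_id": str})
    required = {"condition_id", "exchange_id", "max_uptake"}
    if not required.issubset(df.columns):
        raise ValueError(f"media TSV must have columns {sorted(required)}")
    conditions: dict[str, MediaCondition] = {}
    for row in df.itertuples(index=False):
        cond = conditions.setdefault(row.condition_id, MediaCondition(row.condition_id))
        cond.uptake[row.exchange_id] = float(row.max_uptake)
    return conditions


def write_media_tsv(conditions: Mapping[str, MediaCondition], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"condition_id": c.id, "exchange_id": ex, "max_uptake": lim}
        for c in conditions.values()
        for ex, lim in c.uptake.items()
    ]
    pd.DataFrame(rows, columns=["condition_id", "exchange_id", "max_uptake"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    """Read growth calls (condition_id, call).

    ``inconclusive`` calls are mapped to ``no_growth`` (and logged), the
    conservative treatment for ambiguous phenotype assays.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"condition_id", "call"}.issubset(df.columns):
        raise ValueError("phenotype TSV must have columns condition_id, call")
    calls: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        call = row.call.strip().lower()
        if call == "inconclusive":
            logger.info("condition %s: inconclusive call treated as no_growth", row.condition_id)
            call = "no_growth"
        if call not in ("growth", "no_growth"):
            raise ValueError(
                f"{path}, line {i}: unknown phenotype call {row.call!r} "
                f"for condition {row.condition_id!r}"
            )
        calls[row.condition_id] = call
    return PhenotypeTable(calls=calls)


def write_phenotype_tsv(table: PhenotypeTable, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"condition_id": c, "call": v} for c, v in table.calls.items()],
        columns=["condition_id", "call"],
    ).to_csv(path, sep="\t", index=False)
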