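"""Universal-network curation: free-mass detection and elemental balancing.

A universal network assembled from heterogeneous sources can create mass from
nothing, either through a single mass-imbalanced reaction or through a
stoichiometrically amplifying loop.  The scan here poses that question as one
LP: close every exchange reaction, attach a capped sink to each
non-extracellular metabolite, and maximise the total sink flux.  A strictly
positive optimum means some metabolite can be produced in a fully closed
system — more rigorous than checking each reaction for elemental balance,
because loops of individually balanced reactions are caught too.

Curation itself is deliberately manual: the scan emits a report and
:func:`remove_reactions` applies an explicit, user-chosen removal list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .config import DEFAULT_EPS, DEFAULT_SINK_CAP, logger
from .dgfba import FluxSolution, LinearProgramSpec, solve
from .network import Metabolite, Reaction, UniversalNetwork


@dataclass
class ImbalanceReport:
    """Elemental book-keeping for one reaction.

    ``status`` is one of ``balanced``, ``imbalanced``, ``uncheckable`` (some
    participant has no formula) or ``exempt`` (boundary/biomass
    pseudo-reactions are not expected to balance).  ``imbalance`` maps each
    element to its net coefficient; positive means created.
    """

    reaction_id: str
    status: str
    imbalance: dict[str, float] = field(default_factory=dict)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


@dataclass
class FreeMassReport:
    """Outcome of the closed-network sink-maximisation scan."""

    objective: float
    active_sinks: set[str]
    culprit_reactions: set[str]
    sink_fluxes: dict[str, float] = field(default_factory=dict)
    reaction_fluxes: dict[str, float] = field(default_factory=dict)
    per_sink_culprits: dict[str, set[str]] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.active_sinks


def mass_balance_check(
    rxn: Reaction, metabolites: Mapping[str, Metabolite]
) -> ImbalanceReport:
    """Net elemental change of one reaction (positive = element created)."""
    if rxn.kind != "internal":
        return ImbalanceReport(rxn.id, "exempt")
    totals: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = metabolites[met_id]
        if met.formula is None:
            return ImbalanceReport(rxn.id, "uncheckable")
        for element, count in met.formula.items():
            totals[element] = totals.get(element, 0.0) + coef * count
    imbalance = {el: v for el, v in totals.items() if abs(v) > 1e-9}
    status = "imbalanced" if imbalance else "balanced"
    return ImbalanceReport(rxn.id, status, imbalance)


def _closed_scan_spec(
    net: UniversalNetwork, sink_cap: float
) -> tuple[LinearProgramSpec, list[str]]:
    """LP for the scan: native variables, exchanges pinned to 0, sinks added."""
    S, met_ids, rxn_ids = net.stoichiometric_matrix()
    lower = np.array([net.reactions[r].lower_bound for r in rxn_ids])
    upper = np.array([net.reactions[r].upper_bound for r in rxn_ids])
    for j, rid in enumerate(rxn_ids):
        if net.reactions[rid].kind in ("exchange", "sink"):
            lower[j] = 0.0
            upper[j] = 0.0
    met_index = {m: i for i, m in enumerate(met_ids)}
    sink_mets = [
        m.id for m in net.metabolites.values() if m.compartment != net.extracellular
    ]
    cols = sparse.csr_matrix(
        (
            [-1.0] * len(sink_mets),
            ([met_index[m] for m in sink_mets], range(len(sink_mets))),
        ),
        shape=(len(met_ids), len(sink_mets)),
    )
    spec = LinearProgramSpec(
        component_ids=rxn_ids + [f"SNK_{m}" for m in sink_mets],
        objective=np.concatenate(
            [np.zeros(len(rxn_ids)), np.ones(len(sink_mets))]
        ),
        S=sparse.hstack([S, cols], format="csr"),
        lower=np.concatenate([lower, np.zeros(len(sink_mets))]),
        upper=np.concatenate([upper, np.full(len(sink_mets), sink_cap)]),
        met_ids=met_ids,
    )
    return spec, sink_mets


def free_mass_scan(
    net: UniversalNetwork,
    eps: float = DEFAULT_EPS,
    sink_cap: float = DEFAULT_SINK_CAP,
    per_sink: bool = False,
) -> FreeMassReport:
    """Detect thermodynamically infeasible mass generation in a closed network.

    One sink (metabolite → ∅, bounds [0, ``sink_cap``]) is attached to every
    non-extracellular metabolite, every exchange flux is fixed to zero in both
    directions, and total sink flux is maximised subject to ``S v = 0``.  Any
    objective above zero flags free-mass generation; the non-sink reactions
    carrying flux in the optimum are reported as culprits.

    The optimal objective is unique, but the supporting flux pattern need not
    be; ``per_sink=True`` additionally re-solves with each active sink
    maximised alone, giving a per-metabolite culprit breakdown.
    """
    net.validate()
    spec, sink_mets = _closed_scan_spec(net, sink_cap)
    sol = solve(spec)
    if not sol.optimal:  # v = 0 is always feasible, so this is a solver defect
        raise RuntimeError(f"free-mass scan did not solve: {sol.status}")
    n_rxn = len(net.reactions)
    rxn_ids = spec.component_ids[:n_rxn]
    sink_fluxes = {
        m: sol.fluxes[f"SNK_{m}"]
        for m in sink_mets
        if sol.fluxes[f"SNK_{m}"] > eps
    }
    reaction_fluxes = {
        r: sol.fluxes[r] for r in rxn_ids if abs(sol.fluxes[r]) > eps
    }
    objective = float(sol.objective_value)
    if abs(objective) <= eps:
        objective = 0.0
    report = FreeMassReport(
        objective=objective,
        active_sinks=set(sink_fluxes),
        culprit_reactions=set(reaction_fluxes),
        sink_fluxes=sink_fluxes,
        reaction_fluxes=reaction_fluxes,
    )
    if per_sink:
        for met in report.active_sinks:
            sub = _closed_scan_spec(net, sink_cap)[0]
            c = np.zeros(len(sub.component_ids))
            c[sub.component_ids.index(f"SNK_{met}")] = 1.0
            sub.objective = c
            sub_sol = solve(sub)
            if sub_sol.optimal:
                report.per_sink_culprits[met] = {
                    r for r in rxn_ids if abs(sub_sol.fluxes[r]) > eps
                }
    if report.clean:
        logger.info("free-mass scan: network is clean (objective 0)")
    else:
        logger.warning(
            "free-mass scan: objective %.3f with %d active sinks, %d culprit reactions",
            report.objective,
            len(report.active_sinks),
            len(report.culprit_reactions),
        )
    return report


def remove_reactions(
    net: UniversalNetwork, ids: Iterable[str]
) -> UniversalNetwork:
    """Copy of the network without the listed reactions.

    Metabolites left dangling are retained: the universal network serves many
    organisms and a metabolite unused here may matter in another context.
    """
    ids = list(ids)
    unknown = [r for r in ids if r not in net.reactions]
    if unknown:
        raise KeyError(f"cannot remove unknown reactions: {unknown}")
    out = net.copy()
    for rid in ids:
        del out.reactions[rid]
    return out


def write_free_mass_report(report: FreeMassReport, path: str | Path) -> None:
    """Ranked TSV report: metabolite_id, sink_flux, culprit_reaction_ids."""
    import pandas as pd

    rows = []
    for met in sorted(
        report.active_sinks, key=lambda m: -report.sink_fluxes.get(m, 0.0)
    ):
        culprits = report.per_sink_culprits.get(met, report.culprit_reactions)
        rows.append(
            {
                "metabolite_id": met,
                "sink_flux": report.sink_fluxes.get(met, 0.0),
                "culprit_reaction_ids": ";".join(sorted(culprits)),
            }
        )
    pd.DataFrame(
        rows, columns=["metabolite_id", "sink_flux", "culprit_reaction_ids"]
    ).to_csv(path, sep="\t", index=False)
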