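"""Data-guided flux balance analysis (dgFBA) and plain/parsimonious FBA.

dgFBA is an LP over the split (non-negative) network that maximises
``sum_r w_r * v_r`` subject to steady state ``S v = 0``, component bounds, and
a required minimum biomass flux.  The weights ``w_r`` in [−1, 1] come from
genomic evidence: reactions with strong evidence are maximised, reactions with
weak or no evidence are minimised, each in proportion to its weight.  With all
weights at −1 the objective reduces to minimising total flux, i.e.
parsimonious FBA.

The resulting flux distribution is not a biological flux prediction; it is
read out in a binary way as the set of direction-tagged flux-carrying
reactions (FCRs) for one growth condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .config import DEFAULT_BIOMASS_MIN, DEFAULT_EPS, logger
from .network import (
    FORWARD,
    REVERSE,
    MediaCondition,
    SplitNetwork,
    UniversalNetwork,
    apply_media,
    split_reversible,
)

#: Weight assigned to reactions absent from the evidence table (no evidence).
NO_EVIDENCE_WEIGHT = -1.0

FCR = tuple[str, str]  # (base reaction id, FORWARD | REVERSE)


class SolverError(RuntimeError):
    """Numerical failure inside the LP solver (distinct from infeasibility)."""


@dataclass
class LinearProgramSpec:
    """A fully-specified LP: maximise ``objective @ v`` s.t. ``S v = 0``."""

    component_ids: list[str]
    objective: np.ndarray
    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    met_ids: list[str]
    biomass_component: str | None = None

    def __post_init__(self) -> None:
        n = len(self.component_ids)
        assert self.S.shape[1] == n == len(self.objective)
        assert len(self.lower) == n == len(self.upper)


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def solve(spec: LinearProgramSpec, solver_cfg: Mapping | None = None) -> FluxSolution:
    """Solve an LP spec with the HiGHS simplex/dual backend (deterministic).

    Infeasibility is a regular outcome (``status == "infeasible"``); genuine
    numerical failures raise :class:`SolverError` so they are never mistaken
    for an empty flux distribution.
    """
    options = dict(solver_cfg or {})
    method = options.pop("method", "highs")
    res = linprog(
        c=-spec.objective,
        A_eq=spec.S,
        b_eq=np.zeros(spec.S.shape[0]),
        bounds=np.column_stack([spec.lower, spec.upper]),
        method=method,
        options=options or None,
    )
    if res.status == 0:
        fluxes = dict(zip(spec.component_ids, res.x))
        return FluxSolution("optimal", fluxes, float(-res.fun))
    if res.status == 2:
        return FluxSolution("infeasible")
    if res.status == 3:
        return FluxSolution("unbounded")
    raise SolverError(f"LP solver failure (status {res.status}): {res.message}")


def build_dgfba(
    split: SplitNetwork,
    weights: Mapping[str, float],
    media: MediaCondition | None = None,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
) -> LinearProgramSpec:
    """Assemble the dgFBA LP for one growth condition.

    Both split components of a reversible reaction inherit the base reaction's
    weight; reactions absent from ``weights`` default to −1 (no evidence).
    The biomass component receives a lower bound of ``biomass_min`` so that
    every solution represents growth.
    """
    constrained = apply_media(split, media) if media is not None else split
    S, met_ids, comp_ids = constrained.matrix()
    c = np.array(
        [
            float(
                weights.get(
                    constrained.components[cid].base_id, NO_EVIDENCE_WEIGHT
                )
            )
            for cid in comp_ids
        ]
    )
    if np.any(c < -1.0) or np.any(c > 1.0):
        raise ValueError("reaction weights must lie in [-1, 1]")
    lower = np.zeros(len(comp_ids))
    upper = np.array(
        [constrained.components[cid].upper_bound for cid in comp_ids]
    )
    biomass_comp = f"{split.base.biomass_id}__fwd"
    if biomass_comp not in constrained.components:
        raise ValueError(
            f"biomass reaction {split.base.biomass_id!r} has no forward component"
        )
    lower[comp_ids.index(biomass_comp)] = biomass_min
    return LinearProgramSpec(
        component_ids=comp_ids,
        objective=c,
        S=S,
        lower=lower,
        upper=upper,
        met_ids=met_ids,
        biomass_component=biomass_comp,
    )


def build_pfba(
    split: SplitNetwork,
    media: MediaCondition | None = None,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
) -> LinearProgramSpec:
    """Parsimonious FBA as the all-weights-−1 degenerate case of dgFBA."""
    return build_dgfba(split, weights={}, media=media, biomass_min=biomass_min)


def extract_fcrs(
    sol: FluxSolution, split: SplitNetwork, eps: float = DEFAULT_EPS
) -> set[FCR]:
    """Direction-tagged flux-carrying reactions of one optimal solution.

    Components are recombined into net base-reaction fluxes first, so a
    forward/reverse pair circulating equal flux cancels out and is *not*
    reported.  Each base reaction therefore contributes at most one direction.
    """
    if not sol.optimal:
        raise ValueError(f"cannot extract FCRs from a {sol.status} solution")
    net = split.net_fluxes(sol.fluxes)
    fcrs: set[FCR] = set()
    for base_id, value in net.items():
        if value > eps:
            fcrs.add((base_id, FORWARD))
        elif value < -eps:
            fcrs.add((base_id, REVERSE))
    return fcrs


def saturated_components(
    sol: FluxSolution, spec: LinearProgramSpec, tol: float = 1e-6
) -> list[str]:
    """Internal-loop report: components whose flux sits at the upper bound.

    A closed loop of positive-weight reactions is objective-improving up to
    the flux caps, so after a dgFBA solve any component pinned at its bound is
    worth inspecting for inflated FCR sets.
    """
    if not sol.optimal:
        return []
    out = []
    for cid, ub in zip(spec.component_ids, spec.upper):
        if ub > 0 and sol.fluxes[cid] >= ub - tol:
            out.append(cid)
    return out


def fba_growth(
    net: UniversalNetwork | SplitNetwork,
    media: MediaCondition | None = None,
    biomass_id: str | None = None,
) -> float:
    """Plain FBA: maximise biomass flux under a medium; 0.0 if infeasible."""
    split = net if isinstance(net, SplitNetwork) else split_reversible(net)
    constrained = apply_media(split, media) if media is not None else split
    S, met_ids, comp_ids = constrained.matrix()
    biomass_comp = f"{biomass_id or split.base.biomass_id}__fwd"
    if biomass_comp not in constrained.components:
        raise ValueError(f"biomass component {biomass_comp!r} missing")
    c = np.zeros(len(comp_ids))
    c[comp_ids.index(biomass_comp)] = 1.0
    spec = LinearProgramSpec(
        component_ids=comp_ids,
        objective=c,
        S=S,
        lower=np.zeros(len(comp_ids)),
        upper=np.array([constrained.components[k].upper_bound for k in comp_ids]),
        met_ids=met_ids,
        biomass_component=biomass_comp,
    )
    sol = solve(spec)
    if not sol.optimal:
        return 0.0
    return float(sol.objective_value)


def growth_call(flux: float, threshold: float) -> str:
    """Binary growth call: growth iff biomass flux strictly exceeds threshold."""
    return "growth" if flux > threshold else "no_growth"


def canonicalize(spec: LinearProgramSpec, sol: FluxSolution) -> FluxSolution:
    """Tie-break alternate optima by minimising total unweighted flux.

    Re-solves with the weighted objective pinned at its optimum (within a
    small tolerance) while minimising ``sum(v)``.  This removes gratuitous
    flux circulation — e.g. a positively-weighted cycle pumped to its bounds —
    that an LP solver may include in one of many equally-optimal solutions.
    Optional, and off by default in the pipeline: the plain single solve is
    the method's canonical behaviour.
    """
    if not sol.optimal:
        return sol
    tol = 1e-7 * max(1.0, abs(sol.objective_value))
    res = linprog(
        c=np.ones(len(spec.component_ids)),
        A_eq=spec.S,
        b_eq=np.zeros(spec.S.shape[0]),
        A_ub=-spec.objective.reshape(1, -1),
        b_ub=np.array([-(sol.objective_value - tol)]),
        bounds=np.column_stack([spec.lower, spec.upper]),
        method="highs",
    )
    if res.status != 0:  # keep the primary optimum on any secondary hiccup
        logger.warning("canonicalization pass failed (status %s); keeping primary solution",
                       res.status)
        return sol
    return FluxSolution(
        "optimal", dict(zip(spec.component_ids, res.x)), sol.objective_value
    )


def solve_condition(
    split: SplitNetwork,
    weights: Mapping[str, float],
    media: MediaCondition,
    biomass_min: float = DEFAULT_BIOMASS_MIN,
    eps: float = DEFAULT_EPS,
    canonical: bool = False,
) -> tuple[FluxSolution, set[FCR]]:
    """Convenience: build + solve dgFBA for one condition and extract FCRs."""
    spec = build_dgfba(split, weights, media=media, biomass_min=biomass_min)
    sol = solve(spec)
    if not sol.optimal:
        logger.info("condition %s: dgFBA %s", media.id, sol.status)
        return sol, set()
    if canonical:
        sol = canonicalize(spec, sol)
    return sol, extract_fcrs(sol, split, eps=eps)
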