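"""Shared test utilities: network builders and independent oracles.

The oracles here are deliberately naive and independent of the package's
solver path: LP optima by exhaustive enumeration of basic solutions, and FBA
via cobrapy (GLPK) for cross-checks of the scipy-based implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from canyuns.network import (
    MediaCondition,
    Metabolite,
    Reaction,
    UniversalNetwork,
)


def make_network(
    metabolites: dict[str, str],
    reactions: list[tuple],
    biomass_id: str = "BIOMASS",
    formulas: dict[str, str] | None = None,
) -> UniversalNetwork:
    """Compact builder: metabolites {id: compartment}, reactions as tuples
    (id, stoichiometry, lb, ub, kind)."""
    from canyuns.network import parse_formula

    formulas = formulas or {}
    mets = {
        mid: Metabolite(
            mid,
            formula=parse_formula(formulas.get(mid, "X")),
            compartment=comp,
        )
        for mid, comp in metabolites.items()
    }
    rxns = {}
    for rid, stoich, lb, ub, kind in reactions:
        rxns[rid] = Reaction(
            id=rid,
            stoichiometry={k: float(v) for k, v in stoich.items()},
            lower_bound=float(lb),
            upper_bound=float(ub),
            kind=kind,
        )
    net = UniversalNetwork(
        metabolites=mets, reactions=rxns, biomass_id=biomass_id, extracellular="e"
    )
    net.validate()
    return net


def two_route_network() -> tuple[UniversalNetwork, MediaCondition, dict[str, float]]:
    """Two parallel routes from one carbon source to biomass.

    Route P is a single low-evidence reaction (weight −1); route Q is two
    high-evidence reactions (weight +1 each).  Parsimony prefers P, evidence
    prefers Q.
    """
    net = make_network(
        metabolites={"a_e": "e", "a_c": "c", "q_c": "c", "b_c": "c"},
        reactions=[
            ("EX_a", {"a_e": -1}, -1000, 1000, "exchange"),
            ("TR_a", {"a_e": -1, "a_c": 1}, 0, 1000, "internal"),
            ("P", {"a_c": -1, "b_c": 1}, 0, 1000, "internal"),
            ("Q1", {"a_c": -1, "q_c": 1}, 0, 1000, "internal"),
            ("Q2", {"q_c": -1, "b_c": 1}, 0, 1000, "internal"),
            ("BIOMASS", {"b_c": -1}, 0, 1000, "biomass"),
        ],
    )
    media = MediaCondition("glc", {"EX_a": 10.0})
    weights = {"P": -1.0, "Q1": 1.0, "Q2": 1.0}
    return net, media, weights


def brute_force_lp(c, S, lower, upper, sense: str = "max") -> float | None:
    """LP optimum of {S v = 0, lower <= v <= upper} by vertex enumeration.

    Enumerates every basic solution (basis columns solved exactly, non-basic
    variables pinned at either bound) — exponential, for tiny problems only.
    Returns None if no feasible basic solution exists.
    """
    A = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    c = np.asarray(c, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    m, n = A.shape
    if m:
        from scipy.linalg import qr

        rank = np.linalg.matrix_rank(A)
        _, _, piv = qr(A.T, pivoting=True)
        A = A[sorted(piv[:rank])]
    m = A.shape[0]
    best = None
    for basis in itertools.combinations(range(n), m):
        AB = A[:, basis]
        if m and abs(np.linalg.det(AB)) < 1e-10:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for pattern in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.empty(n)
            for j, p in zip(nonbasic, pattern):
                x[j] = lower[j] if p == 0 else upper[j]
            if m:
                rhs = -A[:, nonbasic] @ x[nonbasic] if nonbasic else np.zeros(m)
                xB = np.linalg.solve(AB, rhs)
                x[list(basis)] = xB
            if np.any(x < lower - 1e-7) or np.any(x > upper + 1e-7):
                continue
            val = float(c @ x)
            if best is None or (val > best if sense == "max" else val < best):
                best = val
    return best


def cobra_fba(net: UniversalNetwork, media: MediaCondition | None = None,
              knockout: str | None = None) -> float:
    """Independent FBA oracle through cobrapy/GLPK; 0.0 if infeasible."""
    from canyuns.network import to_cobra

    model = to_cobra(net)
    if media is not None:
        for ex_id in net.exchange_ids():
            rxn = model.reactions.get_by_id(ex_id)
            rxn.lower_bound = -float(media.uptake.get(ex_id, 0.0))
    if knockout is not None:
        model.reactions.get_by_id(knockout).bounds = (0.0, 0.0)
    value = model.slim_optimize(error_value=0.0)
    return float(value if np.isfinite(value) else 0.0)
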