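"""Shared fixtures: small metabolic networks and expression tables.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from coccoa.model_io import (
    ExpressionTable,
    MetabolicNetwork,
    MetaboliteFoldChangeTable,
    PhysiologyTable,
    Reaction,
    Species,
    parse_gpr,
)

LN2 = math.log(2.0)


def expr_from_lnfc(lnfc: dict[str, float], pvalue: float = 0.001) -> ExpressionTable:
    """Expression table with the given natural-log fold changes."""
    genes = sorted(lnfc)
    return ExpressionTable.from_frame(
        pd.DataFrame(
            {
                "gene": genes,
                "log2fc": [lnfc[g] / LN2 for g in genes],
                "pvalue": [pvalue] * len(genes),
            }
        )
    )


def met_table_from_lnfc(lnfc: dict[str, float], pvalue: float = 0.001) -> MetaboliteFoldChangeTable:
    mets = sorted(lnfc)
    return MetaboliteFoldChangeTable.from_frame(
        pd.DataFrame(
            {
                "metabolite": mets,
                "log2fc": [lnfc[m] / LN2 for m in mets],
                "pvalue": [pvalue] * len(mets),
            }
        )
    )


def chain_network(n: int = 4, prefix: str = "M") -> MetabolicNetwork:
    """Linear pathway: boundary input -> M1 -> ... -> Mn -> boundary output.

    Reaction R{i} consumes M{i} (gene g{i}); R_in has no gene.
    """
    mets = [Species(f"{prefix}{i+1}") for i in range(n)]
    rxns = [Reaction("R_in", {mets[0].id: 1.0})]
    for i in range(n):
        stoich = {mets[i].id: -1.0}
        if i + 1 < n:
            stoich[mets[i + 1].id] = 1.0
        rxns.append(Reaction(f"R{i+1}", stoich, gpr=parse_gpr(f"g{i+1}")))
    return MetabolicNetwork(mets, rxns)


@pytest.fixture
def chain4() -> MetabolicNetwork:
    return chain_network(4)


@pytest.fixture
def chain4_expr() -> ExpressionTable:
    rng = np.random.default_rng(7)
    return expr_from_lnfc({f"g{i+1}": float(v) for i, v in enumerate(rng.normal(0, 0.5, 4))})


def branched_network() -> MetabolicNetwork:
    """Uptake -> A; A splits to B and C; both rejoin into D; D exits.

    6 internal reactions + 2 exchanges; used for FVA brute-force checks.
    """
    sp = [Species(m) for m in "ABCD"]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, reversible=True, lower_bound=-1000, upper_bound=1000),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("g_ab"), upper_bound=1000),
        Reaction("R_AC", {"A": -1.0, "C": 1.0}, gpr=parse_gpr("g_ac"), upper_bound=6.0),
        Reaction("R_BD", {"B": -1.0, "D": 1.0}, gpr=parse_gpr("g_bd"), upper_bound=1000),
        Reaction("R_CD", {"C": -1.0, "D": 1.0}, gpr=parse_gpr("g_cd"), upper_bound=1000),
        Reaction("EX_D", {"D": -1.0}, lower_bound=0, upper_bound=1000),
    ]
    return MetabolicNetwork(sp, rxns)


@pytest.fixture
def branched() -> MetabolicNetwork:
    return branched_network()


def physiology_for(uptake: dict[str, tuple[float, float]]) -> PhysiologyTable:
    return PhysiologyTable(bounds=uptake)


def brute_force_flux_ranges(network: MetabolicNetwork, lb: dict, ub: dict) -> dict:
    """Independent FVA oracle: enumerate the vertices of the flux polytope.

    Fixes (n - m) fluxes at a bound in all combinations, solves the square
    mass-balance system for the rest, keeps feasible solutions, and takes
    per-reaction extremes.  Exponential — only for toy networks.
    """
    import itertools

    internal = [m.id for m in network.metabolites if not m.boundary]
    rids = [r.id for r in network.reactions]
    m, n = len(internal), len(rids)
    S = np.zeros((m, n))
    for j, rxn in enumerate(network.reactions):
        for met, coef in rxn.stoichiometry.items():
            if met in internal:
                S[internal.index(met), j] += coef
    lo = np.array([lb.get(r, network.reaction(r).lower_bound) for r in rids])
    hi = np.array([ub.get(r, network.reaction(r).upper_bound) for r in rids])
    best_min = {r: np.inf for r in rids}
    best_max = {r: -np.inf for r in rids}
    free_count = n - np.linalg.matrix_rank(S)
    for fixed in itertools.combinations(range(n), free_count):
        rest = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lo[j], hi[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            A = S[:, rest]
            b = -S[:, fixed] @ np.array(choice)
            sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            v[rest] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lo - 1e-8) or np.any(v > hi + 1e-8):
                continue
            for j, r in enumerate(rids):
                best_min[r] = min(best_min[r], v[j])
                best_max[r] = max(best_max[r], v[j])
    return {r: (best_min[r], best_max[r]) for r in rids}
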