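"""Functional reaction directions from physiology-constrained flux analysis.

Before expression fold changes can be mapped onto producing/consuming
reactions, every reaction needs one functional direction per comparison.
Reversible reactions are resolved with flux variability analysis (FVA)
under the measured exchange-flux (and growth-rate) constraints of each
condition: reactions that cannot carry flux are *blocked*, reactions whose
feasible flux range straddles zero are *ambiguous*, and reactions whose
unambiguous directions differ between the two conditions are
*inconsistent*.  All three classes are pruned; the survivors are
re-oriented so that flux is positive in the assigned direction.

Linear programs are solved with the HiGHS solver via
:func:`scipy.optimize.linprog`; results are solver-independent within the
stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import (
    CoccoaError,
    MetabolicNetwork,
    PhysiologyTable,
    Reaction,
)

__all__ = [
    "FluxVariabilityResult",
    "DirectionAssignment",
    "constrain_and_fba",
    "flux_variability",
    "assign_directions",
    "orient_network",
]

FORWARD = "forward"
BACKWARD = "backward"
BLOCKED = "blocked"
AMBIGUOUS = "ambiguous"
INCONSISTENT = "inconsistent-across-conditions"


@dataclass
class FluxVariabilityResult:
    """Per-reaction feasible flux range (mmol gDW^-1 h^-1) in one condition."""

    condition: str
    ranges: pd.DataFrame  # index: reaction id; columns: minimum, maximum

    def __post_init__(self) -> None:
        bad = self.ranges["minimum"] > self.ranges["maximum"] + 1e-9
        if bad.any():
            raise CoccoaError(
                f"FVA range with min > max for {self.ranges.index[bad][0]!r}"
            )


@dataclass
class DirectionAssignment:
    """Direction label per reaction plus the surviving directed set."""

    labels: dict[str, str]
    tolerance: float = 1e-6

    @property
    def surviving(self) -> dict[str, str]:
        return {r: l for r, l in self.labels.items() if l in (FORWARD, BACKWARD)}

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.labels.values():
            out[label] = out.get(label, 0) + 1
        return out


def _build_lp(
    network: MetabolicNetwork,
    physiology: PhysiologyTable | None,
    condition: str | None,
    growth_reaction: str | None,
):
    """Assemble the steady-state LP: S v = 0, bounds from model + physiology."""
    internal = [m.id for m in network.metabolites if not m.boundary]
    met_idx = {m: i for i, m in enumerate(internal)}
    rxns = network.reactions
    S = np.zeros((len(internal), len(rxns)))
    lb = np.empty(len(rxns))
    ub = np.empty(len(rxns))
    for j, rxn in enumerate(rxns):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.stoichiometry.items():
            i = met_idx.get(met)
            if i is not None:
                S[i, j] += coef
    if physiology is not None:
        if condition is None:
            raise CoccoaError("a condition label is required with a physiology table")
        if condition not in physiology.bounds:
            raise CoccoaError(f"condition {condition!r} not in physiology table")
        rid_idx = {r.id: j for j, r in enumerate(rxns)}
        for rid, (lo, hi) in physiology.bounds[condition].items():
            if rid not in rid_idx:
                raise CoccoaError(f"physiology references unknown reaction {rid!r}")
            j = rid_idx[rid]
            lb[j], ub[j] = lo, hi
        growth = physiology.growth_rate.get(condition)
        if growth is not None and growth_reaction is not None:
            if growth_reaction not in rid_idx:
                raise CoccoaError(f"unknown growth reaction {growth_reaction!r}")
            j = rid_idx[growth_reaction]
            lb[j] = ub[j] = growth
    return S, lb, ub


def _physiology_echo(physiology: PhysiologyTable | None, condition: str | None) -> str:
    if physiology is None or condition not in (physiology.bounds if physiology else {}):
        return ""
    rows = "; ".join(
        f"{r}∈[{lo:g},{hi:g}]" for r, (lo, hi) in sorted(physiology.bounds[condition].items())
    )
    g = physiology.growth_rate.get(condition)
    if g is not None:
        rows += f"; growth={g:g}"
    return rows


def _solve(S, lb, ub, c, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res


def constrain_and_fba(
    network: MetabolicNetwork,
    physiology: PhysiologyTable | None,
    objective: str,
    condition: str | None = None,
    growth_reaction: str | None = None,
    maximize: bool = True,
) -> pd.Series:
    """Flux balance analysis: optimal flux distribution for ``objective``.

    Maximizes (or minimizes) the flux through the objective reaction
    subject to steady-state mass balance and the model bounds overridden
    by the condition's physiology rows.  Returns fluxes indexed by
    reaction id.
    """
    rids = [r.id for r in network.reactions]
    if objective not in rids:
        raise CoccoaError(f"objective reaction {objective!r} not in model")
    S, lb, ub = _build_lp(network, physiology, condition, growth_reaction)
    c = np.zeros(len(rids))
    c[rids.index(objective)] = -1.0 if maximize else 1.0
    res = _solve(S, lb, ub, c)
    if res.status != 0:
        echo = _physiology_echo(physiology, condition)
        raise CoccoaError(
            "flux balance problem infeasible"
            + (f" under physiology constraints: {echo}" if echo else "")
        )
    return pd.Series(res.x, index=rids, name=condition or "flux")


def flux_variability(
    network: MetabolicNetwork,
    physiology: PhysiologyTable | None,
    objective: str | None = None,
    optimality_fraction: float = 0.0,
    condition: str | None = None,
    growth_reaction: str | None = None,
) -> FluxVariabilityResult:
    """Per-reaction min/max flux under the condition's constraints.

    With ``optimality_fraction`` > 0 and an objective reaction given, the
    objective flux is additionally required to stay at or above that
    fraction of its FBA optimum (the classical FVA protocol); the default
    0.0 explores the full feasible space defined by the measured
    physiology, which is the appropriate protocol when growth and exchange
    rates are measurements rather than an optimization target.
    """
    if not 0.0 <= optimality_fraction <= 1.0:
        raise CoccoaError("optimality_fraction must lie in [0, 1]")
    rids = [r.id for r in network.reactions]
    S, lb, ub = _build_lp(network, physiology, condition, growth_reaction)
    if optimality_fraction > 0.0:
        if objective is None:
            raise CoccoaError("an objective is required when optimality_fraction > 0")
        opt = constrain_and_fba(
            network, physiology, objective, condition, growth_reaction
        )[objective]
        j = rids.index(objective)
        lb = lb.copy()
        lb[j] = max(lb[j], optimality_fraction * opt)
    mins = np.empty(len(rids))
    maxs = np.empty(len(rids))
    for j in range(len(rids)):
        c = np.zeros(len(rids))
        c[j] = 1.0
        lo = _solve(S, lb, ub, c)
        c[j] = -1.0
        hi = _solve(S, lb, ub, c)
        if lo.status != 0 or hi.status != 0:
            echo = _physiology_echo(physiology, condition)
            raise CoccoaError(
                f"FVA subproblem infeasible for reaction {rids[j]!r}"
                + (f" under physiology constraints: {echo}" if echo else "")
            )
        mins[j] = lo.fun
        maxs[j] = -hi.fun
    # clip solver noise so that min <= max holds exactly
    mins = np.minimum(mins, maxs)
    frame = pd.DataFrame({"minimum": mins, "maximum": maxs}, index=pd.Index(rids, name="reaction"))
    return FluxVariabilityResult(condition=condition or "condition", ranges=frame)


def _classify(vmin: float, vmax: float, tol: float) -> str:
    if abs(vmin) <= tol and abs(vmax) <= tol:
        return BLOCKED
    if vmin >= -tol and vmax > tol:
        return FORWARD
    if vmax <= tol and vmin < -tol:
        return BACKWARD
    return AMBIGUOUS


def assign_directions(
    fva_a: FluxVariabilityResult,
    fva_b: FluxVariabilityResult,
    tolerance: float = 1e-6,
) -> DirectionAssignment:
    """Combine two conditions' FVA ranges into one direction label per reaction.

    blocked: no flux possible in either condition; ambiguous: the feasible
    range straddles zero in at least one condition; inconsistent: clean but
    opposite directions in the two conditions (also covers directional in
    one condition / blocked in the other); forward/backward: the same clean
    direction in both.  Only forward/backward reactions survive pruning.
    """
    if set(fva_a.ranges.index) != set(fva_b.ranges.index):
        raise CoccoaError("FVA results cover different reaction sets")
    labels: dict[str, str] = {}
    for rid in fva_a.ranges.index:
        ca = _classify(*fva_a.ranges.loc[rid], tolerance)
        cb = _classify(*fva_b.ranges.loc[rid], tolerance)
        if ca == BLOCKED and cb == BLOCKED:
            labels[rid] = BLOCKED
        elif AMBIGUOUS in (ca, cb):
            labels[rid] = AMBIGUOUS
        elif ca == cb:
            labels[rid] = ca
        else:
            labels[rid] = INCONSISTENT
    return DirectionAssignment(labels=labels, tolerance=tolerance)


def orient_network(
    network: MetabolicNetwork, assignment: DirectionAssignment
) -> MetabolicNetwork:
    """Drop pruned reactions and flip backward ones to positive-flux form.

    Flipping negates the stoichiometry and mirrors the bounds, so in the
    oriented network every surviving reaction's substrates/products reflect
    its functional direction.
    """
    surviving = assignment.surviving
    reactions: list[Reaction] = []
    for rxn in network.reactions:
        label = surviving.get(rxn.id)
        if label is None:
            continue
        if label == FORWARD:
            reactions.append(
                Reaction(
                    id=rxn.id,
                    stoichiometry=dict(rxn.stoichiometry),
                    reversible=False,
                    gpr=rxn.gpr,
                    lower_bound=max(0.0, rxn.lower_bound),
                    upper_bound=rxn.upper_bound,
                    name=rxn.name,
                )
            )
        else:
            reactions.append(
                Reaction(
                    id=rxn.id,
                    stoichiometry={m: -c for m, c in rxn.stoichiometry.items()},
                    reversible=False,
                    gpr=rxn.gpr,
                    lower_bound=max(0.0, -rxn.upper_bound),
                    upper_bound=-rxn.lower_bound,
                    name=rxn.name,
                )
            )
    used = {m for r in reactions for m in r.stoichiometry}
    metabolites = [m for m in network.metabolites if m.id in used]
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions, id=network.id)
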