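"""Mapping gene-level fold changes to representative per-reaction changes.

A reaction's representative transcript ratio Δ = ln(T/T*) stands in for
the fold change of its maximum catalytic capacity (Vmax).  The mapping
rules follow the three GPR shapes:

* single enzyme — the gene's own ln-ratio;
* isoenzymes (OR) — the arithmetic mean of the member ln-ratios, i.e. the
  geometric mean of the ratios;
* complexes (AND) — the lowest fold change among the measured subunits
  (the most limiting subunit), read as the minimum of T/T*.

Only significantly changed transcripts participate; insignificant genes
are treated as absent (not as ratio 1), so a node whose measured children
all drop out propagates "no data" rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .model_io import (
    CoccoaError,
    ExpressionTable,
    GeneAssociation,
    GeneLeaf,
    GprAnd,
    GprNode,
    GprOr,
    MetabolicNetwork,
    Reaction,
)

__all__ = [
    "ReactionDelta",
    "SideAggregate",
    "filter_significant",
    "reaction_delta",
    "reaction_deltas",
    "side_delta",
]

ComplexRule = Literal["min_ratio", "min_abs"]
IsoenzymeRule = Literal["geometric", "arithmetic"]


@dataclass(frozen=True)
class ReactionDelta:
    """Representative natural-log transcript ratio of one reaction.

    ``delta`` is None when no gene of the reaction survived the
    significance filter ("no data" is a value, not an error).
    ``genes`` are the measured genes that entered the evaluation;
    ``n_significant`` counts them.
    """

    reaction_id: str
    delta: float | None
    genes: frozenset[str] = frozenset()

    @property
    def has_data(self) -> bool:
        return self.delta is not None

    @property
    def n_significant(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SideAggregate:
    """Aggregate Δ over one side (production or consumption) of a metabolite.

    ``value`` is the arithmetic mean of the ln-deltas of the side's
    reactions that have data (the geometric mean of their ratios), or None
    when no reaction on the side has data.
    """

    metabolite: str
    side: str
    value: float | None
    genes: frozenset[str]
    n_reactions: int
    n_with_data: int

    @property
    def has_data(self) -> bool:
        return self.value is not None


def filter_significant(expr: ExpressionTable, alpha: float = 0.05) -> ExpressionTable:
    """Keep transcripts with differential-expression P <= alpha.

    The boundary is inclusive; alpha = 1 disables filtering entirely (the
    relaxation check).
    """
    if not 0 < alpha <= 1:
        raise CoccoaError("alpha must lie in (0, 1]")
    keep = expr.data[expr.data["pvalue"] <= alpha].reset_index(drop=True)
    return ExpressionTable(keep, expr.reference)


def _eval_node(
    node: GprNode,
    lnfc: Mapping[str, float],
    complex_rule: ComplexRule,
    isoenzyme_rule: IsoenzymeRule,
) -> tuple[float | None, frozenset[str]]:
    if isinstance(node, GeneLeaf):
        if node.gene in lnfc:
            return lnfc[node.gene], frozenset({node.gene})
        return None, frozenset()
    values: list[float] = []
    genes: set[str] = set()
    for child in node.children:  # type: ignore[attr-defined]
        v, g = _eval_node(child, lnfc, complex_rule, isoenzyme_rule)
        if v is not None:
            values.append(v)
            genes.update(g)
    if not values:
        return None, frozenset()
    if isinstance(node, GprAnd):
        # the most limiting subunit: smallest T/T* (ln is monotone), or
        # optionally the smallest |ln T/T*|
        if complex_rule == "min_ratio":
            return min(values), frozenset(genes)
        return min(values, key=abs), frozenset(genes)
    if isinstance(node, GprOr):
        if isoenzyme_rule == "geometric":
            return sum(values) / len(values), frozenset(genes)
        return math.log(sum(math.exp(v) for v in values) / len(values)), frozenset(genes)
    raise CoccoaError(f"unknown GPR node type {type(node).__name__}")


def reaction_delta(
    reaction: Reaction,
    expr: ExpressionTable,
    complex_rule: ComplexRule = "min_ratio",
    isoenzyme_rule: IsoenzymeRule = "geometric",
) -> ReactionDelta:
    """Evaluate a reaction's GPR tree over filtered gene ln-ratios.

    ``expr`` is expected to be significance-filtered already.  Leaves with
    no surviving measurement are dropped from their node; a node with no
    surviving children propagates "no data".
    """
    gpr: GeneAssociation = reaction.gpr
    if gpr.empty:
        return ReactionDelta(reaction.id, None)
    value, genes = _eval_node(gpr.root, expr.lnfc_map(), complex_rule, isoenzyme_rule)
    return ReactionDelta(reaction.id, value, genes)


def reaction_deltas(
    network: MetabolicNetwork,
    expr: ExpressionTable,
    complex_rule: ComplexRule = "min_ratio",
    isoenzyme_rule: IsoenzymeRule = "geometric",
) -> dict[str, ReactionDelta]:
    """Representative Δ for every reaction of the (oriented) network."""
    lnfc = expr.lnfc_map()  # built once; reaction_delta would rebuild it per call
    out: dict[str, ReactionDelta] = {}
    for r in network.reactions:
        if r.gpr.empty:
            out[r.id] = ReactionDelta(r.id, None)
        else:
            value, genes = _eval_node(r.gpr.root, lnfc, complex_rule, isoenzyme_rule)
            out[r.id] = ReactionDelta(r.id, value, genes)
    return out


def side_delta(
    metabolite: str,
    side: Literal["production", "consumption"],
    network: MetabolicNetwork,
    deltas: Mapping[str, ReactionDelta],
    adjustment: Mapping[str, float] | None = None,
) -> SideAggregate:
    """Aggregate Δ over the producing or consuming reactions of a metabolite.

    The network must already be direction-oriented (signed stoichiometry
    reflects functional direction).  With ``adjustment``, each reaction's
    Δ is corrected by its ln(KM/KM*) term before averaging.  Raises if the
    metabolite is not part of the network.
    """
    if side not in ("production", "consumption"):
        raise CoccoaError(f"unknown side {side!r}")
    met_ids = {m.id for m in network.metabolites}
    if metabolite not in met_ids:
        raise CoccoaError(f"metabolite {metabolite!r} not in network")
    want_product = side == "production"
    values: list[float] = []
    genes: set[str] = set()
    n_side = 0
    for rxn in network.reactions:
        coef = rxn.stoichiometry.get(metabolite, 0.0)
        if coef == 0 or (coef > 0) != want_product:
            continue
        n_side += 1
        d = deltas.get(rxn.id)
        if d is not None and d.has_data:
            v = d.delta
            if adjustment is not None:
                v = v - adjustment.get(rxn.id, 0.0)
            values.append(v)
            genes.update(d.genes)
    value = sum(values) / len(values) if values else None
    return SideAggregate(
        metabolite=metabolite,
        side=side,
        value=value,
        genes=frozenset(genes),
        n_reactions=n_side,
        n_with_data=len(values),
    )
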