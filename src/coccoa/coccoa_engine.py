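"""Concentration change coupling scores over the directed metabolic graph.

The score of a metabolite S estimates its natural-log concentration fold
change from the representative transcript fold changes of reactions at
increasing network distance:

* degree 0 (kinetics only, flux homeostasis):  score = -Δcons(S)
* degree 1 (mass balance):                     score = Δprod(S) - Δcons(S)
  optionally + ln(R/R*) when the precursor R was measured
* degree n: the unresolved precursor ratio ln(R/R*) is recursively
  replaced by the degree-1 relationship of R (upstream expansion), and the
  flux ratio of consuming reactions is recursively resolved through the
  consumers' products (downstream expansion), to chosen upstream and
  downstream distances.

At branch points each branch carries weight 1/(number of branches),
multiplied along the path (the equal flux-split heuristic: mass balance
distributes flux across branches and the split ratios are assumed
constant).  Recursion truncates early at any metabolite with a measured
fold change (its ln-ratio is used and the path stops), never revisits a
metabolite within one path, and never routes through currency metabolites
(configurable cofactor list).

A reaction with "no data" (no significant transcripts) contributes zero
to path sums and nothing to gene counts; a metabolite receives a score
only if at least one contributing reaction has data — this is why the
number of scoreable metabolites varies with the coupling degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx

from .expression_mapping import ReactionDelta, SideAggregate, side_delta
from .model_io import CoccoaError, MetabolicNetwork

__all__ = [
    "DEFAULT_CURRENCY",
    "DirectedBipartiteGraph",
    "CoCCoAScore",
    "KineticAdjustment",
    "build_graph",
    "score_degree0",
    "score_degree1",
    "score_degree_n",
    "score_grid",
]

#: Highly connected cofactors excluded as path-through nodes (they remain
#: reaction participants for GPR purposes).  Configurable, not hard-coded
#: into the traversal.
DEFAULT_CURRENCY = frozenset(
    {
        "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
        "co2", "h2o", "pi", "ppi", "h", "o2", "nh4", "coa",
    }
)


def _currency_key(met_id: str) -> str:
    key = met_id.lower()
    for suffix in ("_c", "_e", "_m", "_x", "_n", "_g", "_r", "_v", "_p"):
        if key.endswith(suffix):
            key = key[: -len(suffix)]
            break
    return key.strip("[]")


@dataclass(frozen=True)
class KineticAdjustment:
    """Optional per-reaction ln(KM/KM*) corrections.

    When post-translational regulation changes an enzyme's affinity, the
    constant-KM assumption breaks; supplying the KM ratios replaces each
    reaction term Δ by Δ - ln(KM/KM*).  Default: empty (KM constant).
    """

    table: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn, v in self.table.items():
            if not (v == v and abs(v) != float("inf")):
                raise CoccoaError(f"non-finite KM adjustment for {rxn!r}")


@dataclass(frozen=True)
class CoCCoAScore:
    """One coupling score with full provenance."""

    metabolite: str
    upstream_distance: int
    downstream_distance: int
    score: float
    gene_ids: frozenset[str]
    path_count: int = 0
    used_measured_neighbors: bool = False
    truncation_metabolites: frozenset[str] = frozenset()

    @property
    def degree(self) -> int:
        return max(self.upstream_distance, self.downstream_distance)


class DirectedBipartiteGraph:
    """Metabolite/reaction bipartite graph after pruning and re-orientation.

    Substrate edges run metabolite -> reaction, product edges reaction ->
    metabolite; each reaction node carries its :class:`ReactionDelta`.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        deltas: Mapping[str, ReactionDelta],
        currency: frozenset[str] = DEFAULT_CURRENCY,
    ) -> None:
        self.network = network
        self.deltas = dict(deltas)
        self.currency_keys = frozenset(c.lower() for c in currency)
        self._producers: dict[str, list[str]] = {m.id: [] for m in network.metabolites}
        self._consumers: dict[str, list[str]] = {m.id: [] for m in network.metabolites}
        self._substrates: dict[str, list[str]] = {}
        self._products: dict[str, list[str]] = {}
        for rxn in network.reactions:
            subs, prods = [], []
            for met, coef in sorted(rxn.stoichiometry.items()):
                if coef < 0:
                    self._consumers[met].append(rxn.id)
                    subs.append(met)
                else:
                    self._producers[met].append(rxn.id)
                    prods.append(met)
            self._substrates[rxn.id] = subs
            self._products[rxn.id] = prods
        for d in self._producers.values():
            d.sort()
        for d in self._consumers.values():
            d.sort()
        self._side_cache: dict[tuple, SideAggregate] = {}

    # -- topology ------------------------------------------------------------

    def is_currency(self, met: str) -> bool:
        return _currency_key(met) in self.currency_keys

    def metabolites(self) -> list[str]:
        return sorted(self._producers)

    def producers(self, met: str) -> list[str]:
        return self._producers[met]

    def consumers(self, met: str) -> list[str]:
        return self._consumers[met]

    def upstream_branches(self, met: str, visited: frozenset[str]) -> list[tuple[str, str]]:
        """(producing reaction, precursor substrate) pairs, path-eligible."""
        out = []
        for rid in self._producers[met]:
            for sub in self._substrates[rid]:
                if sub not in visited and not self.is_currency(sub):
                    out.append((rid, sub))
        return out

    def downstream_branches(self, met: str, visited: frozenset[str]) -> list[tuple[str, str]]:
        """(consuming reaction, successor product) pairs, path-eligible."""
        out = []
        for rid in self._consumers[met]:
            for prod in self._products[rid]:
                if prod not in visited and not self.is_currency(prod):
                    out.append((rid, prod))
        return out

    def side(
        self,
        met: str,
        side: Literal["production", "consumption"],
        adjustment: KineticAdjustment | None = None,
    ) -> SideAggregate:
        key = (met, side, None if adjustment is None else id(adjustment))
        agg = self._side_cache.get(key)
        if agg is None:
            agg = side_delta(
                met, side, self.network, self.deltas,
                None if adjustment is None else adjustment.table,
            )
            self._side_cache[key] = agg
        return agg

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for met in self.metabolites():
            g.add_node(met, bipartite="metabolite")
        for rxn in self.network.reactions:
            g.add_node(rxn.id, bipartite="reaction", delta=self.deltas.get(rxn.id))
            for sub in self._substrates[rxn.id]:
                g.add_edge(sub, rxn.id)
            for prod in self._products[rxn.id]:
                g.add_edge(rxn.id, prod)
        return g

    def component_genes(self, met: str) -> frozenset[str]:
        """All genes of the weakly connected component containing ``met``."""
        g = self.to_networkx()
        genes: set[str] = set()
        for node in nx.node_connected_component(g.to_undirected(), met):
            d = self.deltas.get(node)
            if d is not None:
                genes.update(d.genes)
        return frozenset(genes)


def build_graph(
    network: MetabolicNetwork,
    deltas: Mapping[str, ReactionDelta],
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> DirectedBipartiteGraph:
    """Assemble the scoring graph from an oriented network and its deltas."""
    return DirectedBipartiteGraph(network, deltas, currency)


class _Accumulator:
    """Mutable bookkeeping shared by one score computation."""

    __slots__ = ("genes", "paths", "truncations", "any_data")

    def __init__(self) -> None:
        self.genes: set[str] = set()
        self.paths = 0
        self.truncations: set[str] = set()
        self.any_data = False

    def absorb(self, agg: SideAggregate) -> float:
        if agg.has_data:
            self.any_data = True
            self.genes.update(agg.genes)
            return agg.value
        return 0.0


def _up_term(
    graph: DirectedBipartiteGraph,
    met: str,
    budget: int,
    visited: frozenset[str],
    weight: float,
    measured: Mapping[str, float] | None,
    adjustment: KineticAdjustment | None,
    acc: _Accumulator,
) -> float:
    """Estimate of weight * ln(met/met*) from upstream expansion."""
    if measured is not None and met in measured:
        acc.truncations.add(met)
        acc.paths += 1
        return weight * measured[met]
    if budget == 0:
        acc.paths += 1
        return 0.0
    prod = acc.absorb(graph.side(met, "production", adjustment))
    cons = acc.absorb(graph.side(met, "consumption", adjustment))
    total = weight * (prod - cons)
    branches = graph.upstream_branches(met, visited)
    if not branches:
        acc.paths += 1
        return total
    w = weight / len(branches)
    for _rid, precursor in branches:
        total += _up_term(
            graph, precursor, budget - 1, visited | {met}, w, measured, adjustment, acc
        )
    return total


def _down_term(
    graph: DirectedBipartiteGraph,
    met: str,
    budget: int,
    visited: frozenset[str],
    weight: float,
    measured: Mapping[str, float] | None,
    adjustment: KineticAdjustment | None,
    acc: _Accumulator,
) -> float:
    """Estimate of weight * ln(V/V*) of the flux consuming ``met``.

    At steady state that flux equals the consumption flux of the
    successor product P, giving Δcons(P) + ln(P/P*); the successor ratio
    is measured, dropped, or resolved one step further downstream (where
    the Δcons(P) terms telescope on unbranched paths).
    """
    branches = graph.downstream_branches(met, visited)
    if not branches:
        acc.paths += 1
        return 0.0
    w = weight / len(branches)
    total = 0.0
    for _rid, succ in branches:
        cons = acc.absorb(graph.side(succ, "consumption", adjustment))
        if measured is not None and succ in measured:
            acc.truncations.add(succ)
            acc.paths += 1
            total += w * (cons + measured[succ])
        elif budget == 1:
            acc.paths += 1
            total += w * cons
        else:
            total += _down_term(
                graph, succ, budget - 1, visited | {met}, w, measured, adjustment, acc
            )
    return total


def score_degree_n(
    metabolite: str,
    graph: DirectedBipartiteGraph,
    d_up: int,
    d_down: int,
    measured: Mapping[str, float] | None = None,
    adjustment: KineticAdjustment | None = None,
) -> CoCCoAScore | None:
    """General coupling score with separate upstream/downstream distances.

    ``measured`` maps metabolite ids to their *natural-log* fold changes;
    any metabolite present there truncates the recursion.  (0, 0) is the
    degree-0 score.  Returns None when no contributing reaction has data.
    """
    if d_up < 0 or d_down < 0:
        raise CoccoaError("network distances must be non-negative")
    if metabolite not in graph._producers:
        raise CoccoaError(f"metabolite {metabolite!r} not in graph")
    acc = _Accumulator()
    cons = acc.absorb(graph.side(metabolite, "consumption", adjustment))
    total = -cons
    if d_up >= 1:
        prod = acc.absorb(graph.side(metabolite, "production", adjustment))
        total += prod
        branches = graph.upstream_branches(metabolite, frozenset({metabolite}))
        if branches:
            w = 1.0 / len(branches)
            for _rid, precursor in branches:
                total += _up_term(
                    graph,
                    precursor,
                    d_up - 1,
                    frozenset({metabolite}),
                    w,
                    measured,
                    adjustment,
                    acc,
                )
    if d_down >= 1:
        total += _down_term(
            graph, metabolite, d_down, frozenset({metabolite}), 1.0, measured, adjustment, acc
        )
    if not acc.any_data:
        return None
    return CoCCoAScore(
        metabolite=metabolite,
        upstream_distance=d_up,
        downstream_distance=d_down,
        score=total,
        gene_ids=frozenset(acc.genes),
        path_count=acc.paths,
        used_measured_neighbors=bool(acc.truncations),
        truncation_metabolites=frozenset(acc.truncations),
    )


def score_degree0(metabolite: str, graph: DirectedBipartiteGraph) -> CoCCoAScore | None:
    """Kinetics-only score -Δcons(S) under flux homeostasis (ln V/V* = 0)."""
    score = score_degree_n(metabolite, graph, 0, 0)
    if score is None:
        return None
    cons = graph.side(metabolite, "consumption")
    if not cons.has_data:
        return None
    return score


def score_degree1(
    metabolite: str,
    graph: DirectedBipartiteGraph,
    measured: Mapping[str, float] | None = None,
    adjustment: KineticAdjustment | None = None,
) -> CoCCoAScore | None:
    """Mass-balance score Δprod(S) - Δcons(S) (+ measured precursor ratios).

    Without ``measured`` this omits the ln(R/R*) term, i.e. assumes the
    precursor concentration is unchanged.
    """
    return score_degree_n(metabolite, graph, 1, 0, measured, adjustment)


def score_grid(
    metabolite: str,
    graph: DirectedBipartiteGraph,
    max_distance: int = 4,
    measured: Mapping[str, float] | None = None,
    adjustment: KineticAdjustment | None = None,
) -> list[CoCCoAScore]:
    """Degree-0 plus all (d_up, d_down) in {1..max_distance}^2 scores.

    ``max_distance`` 4 yields the 16-score grid plus the degree-0 score.
    Scores that cannot be computed (no data) are simply absent from the
    returned list.
    """
    if max_distance < 1:
        raise CoccoaError("max_distance must be >= 1")
    out: list[CoCCoAScore] = []
    s0 = score_degree0(metabolite, graph)
    if s0 is not None:
        out.append(s0)
    for d_up in range(1, max_distance + 1):
        for d_down in range(1, max_distance + 1):
            s = score_degree_n(metabolite, graph, d_up, d_down, measured, adjustment)
            if s is not None:
                out.append(s)
    return out
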