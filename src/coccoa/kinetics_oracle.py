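"""Synthetic Michaelis-Menten kinetic networks as ground truth.

The scoring model approximates the exact steady-state relationship of
irreversible single-substrate MM kinetics, V = Vmax * S / (KM + S), in
log-fold-change space.  This module builds small kinetic networks whose
two-condition steady states are solved exactly, providing:

* ground-truth metabolite ln fold changes to validate every scoring
  operation against,
* pipeline-consumable fixtures (SBML + TSV, exercising the full I/O
  path),
* the error surface of the V << Vmax approximation as a function of the
  saturation levels s = V/Vmax and s* = V*/Vmax* in the two conditions.

Exact inversion of the MM rate law gives S = KM * V / (Vmax - V) =
KM * s / (1 - s), hence

    ln(S/S*)_exact  = ln(s/s*) + ln((1-s*)/(1-s))
    ln(S/S*)_approx = ln(V/V*) - ln(Vmax/Vmax*) = ln(s/s*)

The approximation error therefore depends only on the saturation pair:
the predicted concentration fold change is off by the factor
(1-s)/(1-s*), i.e. a relative error |s - s*| / (1 - s*), exactly zero
whenever the saturation level is unchanged between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import model_io
from .model_io import (
    CoccoaError,
    ExpressionTable,
    GeneAssociation,
    GeneLeaf,
    MetabolicNetwork,
    MetaboliteFoldChangeTable,
    PhysiologyTable,
    Reaction,
    Species,
)

__all__ = [
    "KineticReaction",
    "KineticNetworkSpec",
    "SteadyStateResult",
    "PerturbationDataset",
    "generate_network",
    "apply_perturbation",
    "solve_steady_state",
    "perturb_and_compare",
    "approximation_error",
    "approximation_error_surface",
    "to_metabolic_network",
    "to_physiology",
    "write_fixture_bundle",
]

REFERENCE = "reference"
PERTURBED = "perturbed"
CONDITIONS = (REFERENCE, PERTURBED)


@dataclass(frozen=True)
class KineticReaction:
    """One irreversible MM reaction (or a fixed-flux boundary input).

    ``substrate``/``product`` of None mark boundary exchanges.  Inputs
    carry a fixed flux per condition instead of MM parameters.
    """

    id: str
    substrate: str | None
    product: str | None
    km: float = 1.0
    vmax: Mapping[str, float] = field(default_factory=dict)  # condition -> Vmax
    flux: Mapping[str, float] | None = None  # fixed input flux per condition
    gene: str | None = None

    @property
    def is_input(self) -> bool:
        return self.flux is not None

    def rate(self, s: float, condition: str) -> float:
        if self.is_input:
            return self.flux[condition]
        return self.vmax[condition] * s / (self.km + s)


@dataclass(frozen=True)
class KineticNetworkSpec:
    """Topology + MM parameters of a synthetic kinetic network."""

    metabolites: tuple[str, ...]
    reactions: tuple[KineticReaction, ...]
    topology: str = "chain"
    seed: int | None = None

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            if not rxn.is_input:
                if rxn.km <= 0:
                    raise CoccoaError(f"KM must be positive in {rxn.id!r}")
                for cond in CONDITIONS:
                    if rxn.vmax[cond] <= 0:
                        raise CoccoaError(f"Vmax must be positive in {rxn.id!r}")

    def gene_lnfc(self) -> dict[str, float]:
        """Per-gene ln fold changes implied by the Vmax ratios."""
        out: dict[str, float] = {}
        for rxn in self.reactions:
            if rxn.gene is not None and not rxn.is_input:
                out[rxn.gene] = math.log(rxn.vmax[PERTURBED] / rxn.vmax[REFERENCE])
        return out


@dataclass(frozen=True)
class SteadyStateResult:
    """Exact two-condition steady state of a kinetic network."""

    concentrations: dict[str, dict[str, float]]  # condition -> met -> S
    fluxes: dict[str, dict[str, float]]  # condition -> rxn -> V
    saturation: dict[str, dict[str, float]]  # condition -> rxn -> V/Vmax
    residual: float

    def ln_concentration_ratios(self) -> dict[str, float]:
        ref, per = self.concentrations[REFERENCE], self.concentrations[PERTURBED]
        return {m: math.log(per[m] / ref[m]) for m in ref}

    def ln_flux_ratios(self) -> dict[str, float]:
        ref, per = self.fluxes[REFERENCE], self.fluxes[PERTURBED]
        return {r: math.log(per[r] / ref[r]) for r in ref if ref[r] > 0 and per[r] > 0}


def generate_network(
    topology: str,
    n_metabolites: int,
    saturation_target: float = 0.01,
    seed: int | None = None,
    km_range: tuple[float, float] = (0.1, 10.0),
    input_flux: float = 1.0,
) -> KineticNetworkSpec:
    """Random MM network with baseline saturation near ``saturation_target``.

    Topologies: ``chain`` (linear pathway), ``branch`` (one split into two
    parallel chains that remain separate), ``dag`` (a layered random DAG).
    KM values are log-uniform in ``km_range``; each enzymatic reaction's
    Vmax is set so its baseline saturation V/Vmax is log-uniform within a
    factor two of the target.  Reproducible under ``seed``.
    """
    if n_metabolites < 2:
        raise CoccoaError("need at least 2 metabolites")
    if not 0 < saturation_target < 1:
        raise CoccoaError("saturation_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    def draw_km() -> float:
        lo, hi = km_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def draw_sat() -> float:
        return float(
            np.exp(rng.uniform(np.log(saturation_target / 2), np.log(saturation_target * 2)))
        )

    mets = tuple(f"M{i+1}" for i in range(n_metabolites))
    reactions: list[KineticReaction] = []
    flux_both = {REFERENCE: input_flux, PERTURBED: input_flux}

    def enzymatic(rid: str, sub: str, prod: str | None, flux_through: float) -> KineticReaction:
        vmax = flux_through / draw_sat()
        return KineticReaction(
            id=rid,
            substrate=sub,
            product=prod,
            km=draw_km(),
            vmax={REFERENCE: vmax, PERTURBED: vmax},
            gene=f"g_{rid}",
        )

    if topology == "chain":
        reactions.append(KineticReaction("R_in", None, mets[0], flux=flux_both))
        for i in range(n_metabolites):
            prod = mets[i + 1] if i + 1 < n_metabolites else None
            reactions.append(enzymatic(f"R{i+1}", mets[i], prod, input_flux))
    elif topology == "branch":
        # M1 feeds two parallel chains of (n-1)//2 and the remainder
        reactions.append(KineticReaction("R_in", None, mets[0], flux=flux_both))
        rest = list(mets[1:])
        half = len(rest) // 2 or 1
        arms = [rest[:half], rest[half:]] if rest[half:] else [rest]
        for a, arm in enumerate(arms):
            flux_arm = input_flux / len(arms)
            prev = mets[0]
            for i, met in enumerate(arm):
                reactions.append(enzymatic(f"R{a+1}_{i+1}", prev, met, flux_arm))
                prev = met
            reactions.append(enzymatic(f"R{a+1}_out", prev, None, flux_arm))
    elif topology == "dag":
        # layered random DAG: each metabolite after the first consumes from
        # one randomly chosen earlier metabolite; every terminal metabolite
        # drains to the boundary
        reactions.append(KineticReaction("R_in", None, mets[0], flux=flux_both))
        out_degree = {m: 0 for m in mets}
        for i in range(1, n_metabolites):
            j = int(rng.integers(0, i))
            reactions.append(enzymatic(f"R{i}", mets[j], mets[i], input_flux))
            out_degree[mets[j]] += 1
        for i, met in enumerate(mets):
            if out_degree[met] == 0:
                reactions.append(enzymatic(f"R_out{i+1}", met, None, input_flux))
        # flux through a reaction is not input_flux when splits occur; scale
        # Vmax by the actual baseline flux after a provisional solve
        spec = KineticNetworkSpec(mets, tuple(reactions), topology="dag", seed=seed)
        state = solve_steady_state(spec)
        fixed: list[KineticReaction] = []
        for rxn in spec.reactions:
            if rxn.is_input:
                fixed.append(rxn)
                continue
            v = state.fluxes[REFERENCE][rxn.id]
            vmax = v / draw_sat()
            fixed.append(replace(rxn, vmax={REFERENCE: vmax, PERTURBED: vmax}))
        return KineticNetworkSpec(mets, tuple(fixed), topology="dag", seed=seed)
    else:
        raise CoccoaError(f"unknown topology {topology!r}")

    return KineticNetworkSpec(mets, tuple(reactions), topology=topology, seed=seed)


def apply_perturbation(
    spec: KineticNetworkSpec, gene_lnfc: Mapping[str, float]
) -> KineticNetworkSpec:
    """Scale each gene's Vmax in the perturbed condition by exp(lnfc)."""
    reactions = []
    for rxn in spec.reactions:
        if rxn.gene is not None and rxn.gene in gene_lnfc and not rxn.is_input:
            vmax = dict(rxn.vmax)
            vmax[PERTURBED] = vmax[REFERENCE] * math.exp(gene_lnfc[rxn.gene])
            reactions.append(replace(rxn, vmax=vmax))
        else:
            reactions.append(rxn)
    return replace(spec, reactions=tuple(reactions))


def _consumers_of(spec: KineticNetworkSpec, met: str) -> list[KineticReaction]:
    return [r for r in spec.reactions if r.substrate == met]


def _producers_of(spec: KineticNetworkSpec, met: str) -> list[KineticReaction]:
    return [r for r in spec.reactions if r.product == met]


def _solve_condition(spec: KineticNetworkSpec, condition: str) -> tuple[dict, dict, float]:
    mets = list(spec.metabolites)

    # fast exact path: when every metabolite has exactly one consumer the
    # fluxes are fixed by mass balance and S = KM*V/(Vmax-V) in closed form
    if all(len(_consumers_of(spec, m)) == 1 for m in mets):
        flux: dict[str, float] = {r.id: r.flux[condition] for r in spec.reactions if r.is_input}
        conc: dict[str, float] = {}
        remaining = set(mets)
        while remaining:
            progressed = False
            for met in sorted(remaining):
                prods = _producers_of(spec, met)
                if not all(p.id in flux for p in prods):
                    continue
                influx = sum(flux[p.id] for p in prods)
                (consumer,) = _consumers_of(spec, met)
                vmax = consumer.vmax[condition]
                if influx >= vmax:
                    raise CoccoaError(
                        f"no steady state: flux {influx:g} exceeds Vmax of {consumer.id!r}"
                    )
                conc[met] = consumer.km * influx / (vmax - influx)
                flux[consumer.id] = influx
                remaining.discard(met)
                progressed = True
            if not progressed:
                break
        if not remaining:
            return conc, flux, 0.0

    # general case: damped Newton-type root finding on log-concentrations
    def residual(x: np.ndarray) -> np.ndarray:
        conc = dict(zip(mets, np.exp(x)))
        res = []
        for met in mets:
            influx = sum(
                r.rate(conc.get(r.substrate, 0.0), condition) for r in _producers_of(spec, met)
            )
            outflux = sum(r.rate(conc[met], condition) for r in _consumers_of(spec, met))
            res.append(influx - outflux)
        return np.asarray(res)

    x0 = np.zeros(len(mets))
    for i, met in enumerate(mets):
        consumers = _consumers_of(spec, met)
        if consumers:
            r0 = consumers[0]
            guess = r0.km * 0.05 / 0.95
            x0[i] = math.log(guess)
    sol = root(residual, x0, method="hybr", tol=1e-13)
    res_norm = float(np.max(np.abs(residual(sol.x))))
    if not sol.success or res_norm > 1e-10:
        raise CoccoaError(
            f"steady state not found for condition {condition!r} (residual {res_norm:.2e})"
        )
    conc = dict(zip(mets, np.exp(sol.x)))
    flux = {
        r.id: r.rate(conc.get(r.substrate, 0.0), condition) if not r.is_input else r.flux[condition]
        for r in spec.reactions
    }
    return conc, flux, res_norm


def solve_steady_state(spec: KineticNetworkSpec) -> SteadyStateResult:
    """Exact steady state of both conditions; raises if none exists.

    Mass-balance residuals are verified to 1e-10; all concentrations are
    positive by construction (solved in log space / closed form).
    """
    concentrations, fluxes, saturation = {}, {}, {}
    worst = 0.0
    for cond in CONDITIONS:
        conc, flux, res = _solve_condition(spec, cond)
        concentrations[cond] = conc
        fluxes[cond] = flux
        saturation[cond] = {
            r.id: flux[r.id] / r.vmax[cond] for r in spec.reactions if not r.is_input
        }
        for rid, s in saturation[cond].items():
            if s >= 1.0:
                raise CoccoaError(f"no steady state: reaction {rid!r} saturated (s={s:g})")
        worst = max(worst, res)
    return SteadyStateResult(concentrations, fluxes, saturation, worst)


@dataclass(frozen=True)
class PerturbationDataset:
    """One perturbation draw packaged as pipeline inputs plus ground truth."""

    spec: KineticNetworkSpec
    expression: ExpressionTable
    truth: MetaboliteFoldChangeTable
    state: SteadyStateResult

    def truth_ln(self) -> dict[str, float]:
        return self.truth.lnfc_map()


def perturb_and_compare(
    spec: KineticNetworkSpec,
    n_draws: int,
    seed: int | None = None,
    lnfc_magnitude: tuple[float, float] = (math.log(2), math.log(4)),
) -> tuple[list[PerturbationDataset], int]:
    """Random enzyme-expression perturbations with exact concentration truth.

    Each draw assigns every enzyme gene a ln fold change of random sign
    and magnitude uniform in ``lnfc_magnitude``, solves both steady
    states, and emits an :class:`ExpressionTable` plus the true metabolite
    fold-change table.  Draws without a steady state are skipped; the
    second return value counts them.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(r.gene for r in spec.reactions if r.gene is not None)
    out: list[PerturbationDataset] = []
    skipped = 0
    while len(out) < n_draws:
        lnfc = {
            g: float(rng.choice([-1.0, 1.0]) * rng.uniform(*lnfc_magnitude)) for g in genes
        }
        perturbed = apply_perturbation(spec, lnfc)
        try:
            state = solve_steady_state(perturbed)
        except CoccoaError:
            skipped += 1
            if skipped > 50 * max(n_draws, 1):
                raise CoccoaError("too many infeasible perturbation draws")
            continue
        expr = ExpressionTable.from_frame(
            pd.DataFrame(
                {
                    "gene": genes,
                    "log2fc": [lnfc[g] / math.log(2) for g in genes],
                    "pvalue": [1e-6] * len(genes),
                }
            )
        )
        ratios = state.ln_concentration_ratios()
        truth = MetaboliteFoldChangeTable.from_frame(
            pd.DataFrame(
                {
                    "metabolite": list(spec.metabolites),
                    "log2fc": [ratios[m] / math.log(2) for m in spec.metabolites],
                    "pvalue": [1e-6] * len(spec.metabolites),
                }
            )
        )
        out.append(PerturbationDataset(perturbed, expr, truth, state))
    return out, skipped


# ---------------------------------------------------------------------------
# Approximation error of the V << Vmax log-linear relation
# ---------------------------------------------------------------------------


def approximation_error(s: float, s_star: float) -> float:
    """Relative error of the approximate concentration fold change.

    The approximation predicts S/S* = s/s* while the exact MM inversion
    gives S/S* = (s/s*) * (1-s*)/(1-s); the relative error of the
    predicted fold change is |exp(approx - exact) - 1| = |s - s*|/(1 - s*).
    Zero exactly on the diagonal s = s*.
    """
    if not (0 < s < 1) or not (0 < s_star < 1):
        raise CoccoaError("saturation levels must lie in (0, 1)")
    return abs(s - s_star) / (1.0 - s_star)


def approximation_error_surface(
    s_grid: Sequence[float], s_star_grid: Sequence[float]
) -> pd.DataFrame:
    """Error matrix over a (s, s*) saturation grid (rows: s, columns: s*)."""
    data = [[approximation_error(s, ss) for ss in s_star_grid] for s in s_grid]
    return pd.DataFrame(
        data,
        index=pd.Index(list(s_grid), name="saturation"),
        columns=pd.Index(list(s_star_grid), name="saturation_ref"),
    )


# ---------------------------------------------------------------------------
# Pipeline-format export
# ---------------------------------------------------------------------------


def to_metabolic_network(spec: KineticNetworkSpec) -> MetabolicNetwork:
    """Express the kinetic network in the genome-scale model vocabulary.

    Boundary exchanges keep only their internal participant; each
    enzymatic reaction carries a single-gene GPR.
    """
    species = [Species(id=m, name=m, compartment="c") for m in spec.metabolites]
    reactions = []
    for rxn in spec.reactions:
        stoich: dict[str, float] = {}
        if rxn.substrate is not None:
            stoich[rxn.substrate] = -1.0
        if rxn.product is not None:
            stoich[rxn.product] = 1.0
        gpr = GeneAssociation(GeneLeaf(rxn.gene)) if rxn.gene else GeneAssociation(None)
        ub = max(r.vmax.get(c, 0.0) for r in spec.reactions if not r.is_input for c in CONDITIONS)
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry=stoich,
                reversible=False,
                gpr=gpr,
                lower_bound=0.0,
                upper_bound=ub if not rxn.is_input else rxn.flux[REFERENCE],
                name=rxn.id,
            )
        )
    return MetabolicNetwork(metabolites=species, reactions=reactions, id="kinetic_fixture")


def to_physiology(spec: KineticNetworkSpec) -> PhysiologyTable:
    """Exchange-flux bounds per condition (inputs fixed at their flux)."""
    bounds: dict[str, dict[str, tuple[float, float]]] = {c: {} for c in CONDITIONS}
    for rxn in spec.reactions:
        if rxn.is_input:
            for cond in CONDITIONS:
                v = rxn.flux[cond]
                bounds[cond][rxn.id] = (v, v)
    return PhysiologyTable(bounds=bounds)


def write_fixture_bundle(dataset: PerturbationDataset, directory: str | Path) -> dict[str, Path]:
    """Write one perturbation dataset as SBML + TSV pipeline inputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": directory / "model.xml",
        "expression": directory / "expression.tsv",
        "metabolites": directory / "metabolites.tsv",
        "physiology": directory / "physiology.tsv",
    }
    model_io.write_sbml(to_metabolic_network(dataset.spec), paths["model"])
    model_io.write_expression(dataset.expression, paths["expression"])
    model_io.write_metabolite_foldchanges(dataset.truth, paths["metabolites"])
    model_io.write_physiology(to_physiology(dataset.spec), paths["physiology"])
    return paths
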