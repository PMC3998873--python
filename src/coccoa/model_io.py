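"""Reading and writing the standard inputs and outputs of a CoCCoA run.

The pipeline consumes four kinds of input:

* a genome-scale metabolic model (SBML; stoichiometry, reversibility,
  gene-protein-reaction associations),
* a comparative transcriptome table (gene, log2 fold change, P-value),
* a measured metabolite fold-change table (metabolite, log2 fold change,
  P-value),
* a physiology table of measured exchange-flux bounds (and optionally the
  growth rate) per condition.

All tables are tab-delimited UTF-8 text with a header row and '.' decimal
separator.  Fold changes enter on the log2 scale (the convention of the
source transcriptomics/metabolomics studies) and are converted to natural
log exactly once, at ingestion; every internal quantity is in natural-log
space.

Measured metabolite names are linked to model species through an explicit
two-column mapping file; there is no fuzzy matching.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

LN2 = math.log(2.0)

__all__ = [
    "CoccoaError",
    "ParseError",
    "ValidationError",
    "GprNode",
    "GeneLeaf",
    "GprAnd",
    "GprOr",
    "GeneAssociation",
    "parse_gpr",
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "ExpressionTable",
    "MetaboliteFoldChangeTable",
    "PhysiologyTable",
    "read_sbml",
    "write_sbml",
    "read_expression",
    "write_expression",
    "read_metabolite_foldchanges",
    "write_metabolite_foldchanges",
    "read_physiology",
    "write_physiology",
    "read_mapping",
    "write_scores",
    "read_scores",
    "merge_compartment_pools",
    "load_config",
    "config_hash",
]


class CoccoaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CoccoaError):
    """A file could not be parsed (malformed SBML, bad GPR string, ...)."""


class ValidationError(CoccoaError):
    """Input parsed but violates an invariant of its table/model type."""


# ---------------------------------------------------------------------------
# Gene-protein-reaction association trees
# ---------------------------------------------------------------------------


class GprNode:
    """Node of a boolean gene-association expression tree.

    AND nodes encode enzyme complexes (all subunits required), OR nodes
    encode isoenzymes (any one suffices); leaves are gene identifiers.
    """

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class GeneLeaf(GprNode):
    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return bool(present.get(self.gene, False))

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class GprAnd(GprNode):
    children: tuple[GprNode, ...]

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return all(c.evaluate(present) for c in self.children)

    def to_string(self) -> str:
        return "(" + " and ".join(c.to_string() for c in self.children) + ")"


@dataclass(frozen=True)
class GprOr(GprNode):
    children: tuple[GprNode, ...]

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return any(c.evaluate(present) for c in self.children)

    def to_string(self) -> str:
        return "(" + " or ".join(c.to_string() for c in self.children) + ")"


@dataclass(frozen=True)
class GeneAssociation:
    """A possibly-empty GPR tree.

    ``root is None`` means a spontaneous or orphan reaction with no
    associated genes.
    """

    root: GprNode | None = None

    @property
    def empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def evaluate(self, present: Mapping[str, bool]) -> bool:
        return True if self.root is None else self.root.evaluate(present)

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str, context: str = "") -> GeneAssociation:
    """Parse a GPR string such as ``"(g1 and g2) or g3"`` into a tree.

    Grammar (case-insensitive keywords, ``or`` binds loosest)::

        expr   := term   ('or' term)*
        term   := factor ('and' factor)*
        factor := '(' expr ')' | GENE

    An empty/whitespace string yields an empty association.  ``context``
    (typically a reaction id) is included in error messages.
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return GeneAssociation(None)
    pos = 0

    def err(msg: str) -> ParseError:
        where = f" in GPR of {context!r}" if context else ""
        return ParseError(f"malformed gene association{where}: {msg} ({text!r})")

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_factor() -> GprNode:
        tok = peek()
        if tok is None:
            raise err("unexpected end of expression")
        if tok == "(":
            advance()
            node = parse_expr()
            if peek() != ")":
                raise err("missing closing parenthesis")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise err(f"unexpected token {tok!r}")
        return GeneLeaf(advance())

    def parse_term() -> GprNode:
        children = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else GprAnd(tuple(children))

    def parse_expr() -> GprNode:
        children = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            children.append(parse_term())
        return children[0] if len(children) == 1 else GprOr(tuple(children))

    root = parse_expr()
    if pos != len(tokens):
        raise err(f"trailing tokens starting at {tokens[pos]!r}")
    return GeneAssociation(root)


# ---------------------------------------------------------------------------
# Metabolic network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """A metabolite species of the model (one per compartment instance)."""

    id: str
    name: str = ""
    compartment: str = ""
    boundary: bool = False


@dataclass
class Reaction:
    """A model reaction.

    ``stoichiometry`` maps metabolite id to its signed coefficient as
    written (negative = substrate, positive = product).  Bounds are fluxes
    in mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    gpr: GeneAssociation = field(default_factory=GeneAssociation)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""

    @property
    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass
class MetabolicNetwork:
    """Stoichiometry + GPR + bounds for a whole metabolic model."""

    metabolites: list[Species]
    reactions: list[Reaction]
    genes: frozenset[str] = frozenset()
    id: str = "model"

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = frozenset().union(
                frozenset(), *(r.gpr.genes() for r in self.reactions)
            )
        self.validate()

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids in model")
        seen_rxn: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_rxn:
                raise ValidationError(f"duplicate reaction id {rxn.id!r}")
            seen_rxn.add(rxn.id)
            for met, coef in rxn.stoichiometry.items():
                if met not in met_ids:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
                if coef == 0:
                    raise ValidationError(
                        f"reaction {rxn.id!r} has zero coefficient for {met!r}"
                    )
            if not rxn.reversible and rxn.lower_bound < 0:
                raise ValidationError(
                    f"irreversible reaction {rxn.id!r} has negative lower bound"
                )
            if not rxn.gpr.genes() <= self.genes:
                raise ValidationError(
                    f"reaction {rxn.id!r} GPR references genes outside the model gene set"
                )

    # -- convenience lookups -------------------------------------------------

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def species(self, mid: str) -> Species:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def _sbml():
    import libsbml

    return libsbml


def _gpr_from_fbc_association(assoc, libsbml, gp_labels: Mapping[str, str]) -> GprNode:
    if isinstance(assoc, libsbml.GeneProductRef):
        ref = assoc.getGeneProduct()
        return GeneLeaf(gp_labels.get(ref, ref))
    if isinstance(assoc, libsbml.FbcAnd):
        return GprAnd(
            tuple(
                _gpr_from_fbc_association(assoc.getAssociation(i), libsbml, gp_labels)
                for i in range(assoc.getNumAssociations())
            )
        )
    if isinstance(assoc, libsbml.FbcOr):
        return GprOr(
            tuple(
                _gpr_from_fbc_association(assoc.getAssociation(i), libsbml, gp_labels)
                for i in range(assoc.getNumAssociations())
            )
        )
    raise ParseError(f"unsupported fbc association node {type(assoc).__name__}")


_NOTES_GA = re.compile(
    r"GENE[_ ]ASSOCIATION\s*:\s*([^<\n]*)", flags=re.IGNORECASE
)


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML (level 2 or 3) model into a :class:`MetabolicNetwork`.

    GPRs are taken from the fbc package when present, otherwise from the
    legacy ``GENE_ASSOCIATION:`` notes field.  Flux bounds come from fbc
    bound parameters, legacy kinetic-law ``LOWER_BOUND``/``UPPER_BOUND``
    parameters, or default to (0, 1000) / (-1000, 1000) by reversibility.
    """
    libsbml = _sbml()
    path = Path(path)
    if not path.exists():
        raise CoccoaError(f"SBML file not found: {path}")
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        e = doc.getError(0)
        raise ParseError(
            f"malformed SBML in {path.name}: line {e.getLine()}: {e.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ParseError(f"malformed SBML in {path.name}: no <model> element")

    fbc_model = model.getPlugin("fbc")
    gp_labels: dict[str, str] = {}
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gp_labels[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites = [
        Species(
            id=s.getId(),
            name=s.getName() or "",
            compartment=s.getCompartment() or "",
            boundary=bool(s.getBoundaryCondition()),
        )
        for s in model.getListOfSpecies()
    ]

    reactions: list[Reaction] = []
    for rxn in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rxn.getNumReactants()):
            ref = rxn.getReactant(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for i in range(rxn.getNumProducts()):
            ref = rxn.getProduct(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        reversible = rxn.getReversible()
        lb, ub = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None and fbc_rxn.isSetLowerFluxBound():
            p = model.getParameter(fbc_rxn.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
            p = model.getParameter(fbc_rxn.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
        elif rxn.isSetKineticLaw():
            kl = rxn.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()

        gpr = GeneAssociation(None)
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            assoc = fbc_rxn.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = GeneAssociation(_gpr_from_fbc_association(assoc, libsbml, gp_labels))
        else:
            notes = rxn.getNotesString() if rxn.isSetNotes() else ""
            m = _NOTES_GA.search(notes)
            if m:
                gpr = parse_gpr(m.group(1).strip(), context=rxn.getId())

        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                reversible=reversible,
                gpr=gpr,
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName() or "",
            )
        )

    return MetabolicNetwork(
        metabolites=metabolites, reactions=reactions, id=model.getId() or "model"
    )


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the network as SBML L2V4 in the legacy COBRA style.

    GPRs go into a ``GENE_ASSOCIATION:`` notes field; bounds into
    kinetic-law parameters — the dialect historically used by genome-scale
    yeast reconstructions, readable by any constraint-based toolbox.
    """
    libsbml = _sbml()
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(network.id)
    comps = sorted({m.compartment or "c" for m in network.metabolites})
    for cid in comps:
        c = model.createCompartment()
        c.setId(cid)
        c.setSize(1.0)
    for met in network.metabolites:
        s = model.createSpecies()
        s.setId(met.id)
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment or "c")
        s.setBoundaryCondition(met.boundary)
        s.setInitialConcentration(1.0)
    for rxn in network.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.reversible)
        for met, coef in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coef))
        if not rxn.gpr.empty:
            r.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>GENE_ASSOCIATION: {rxn.gpr.to_string()}</p></body>"
            )
        kl = r.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pid, value in (("LOWER_BOUND", rxn.lower_bound), ("UPPER_BOUND", rxn.upper_bound)):
            p = kl.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setUnits("mmol_per_gDW_per_hr")
        p = kl.createParameter()
        p.setId("FLUX_VALUE")
        p.setValue(0.0)
        p.setUnits("mmol_per_gDW_per_hr")
    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise CoccoaError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Fold-change tables
# ---------------------------------------------------------------------------


def _read_tsv(
    path: str | Path,
    required: Sequence[str],
    key: str,
    numeric: Sequence[str] = (),
    unique_key: bool = True,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CoccoaError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValidationError(
                f"{path.name}: non-numeric value in column {col!r} at line {row}"
            )
        df[col] = pd.to_numeric(df[col])
    if unique_key:
        dup = df[required[0]].duplicated()
        if dup.any():
            raise ValidationError(
                f"{path.name}: duplicated {key} id {df[required[0]][dup].iloc[0]!r}"
            )
    return df


@dataclass
class ExpressionTable:
    """Per-gene comparative expression: log2 fold change and P-value.

    ``lnfc`` (natural-log ratio T/T*) is derived from ``log2fc`` once at
    construction; downstream code never touches log2 again.
    """

    data: pd.DataFrame  # columns: gene, log2fc, pvalue, lnfc
    reference: str = "reference"

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference: str = "reference") -> "ExpressionTable":
        df = df.copy()
        if not {"gene", "log2fc", "pvalue"} <= set(df.columns):
            raise ValidationError("expression table needs columns gene, log2fc, pvalue")
        if df["gene"].duplicated().any():
            raise ValidationError("duplicate gene ids in expression table")
        if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
            raise ValidationError("expression P-values must lie in [0, 1]")
        if not pd.Series(df["log2fc"]).map(math.isfinite).all():
            raise ValidationError("expression fold changes must be finite")
        df["lnfc"] = df["log2fc"] * LN2
        return cls(df[["gene", "log2fc", "pvalue", "lnfc"]].reset_index(drop=True), reference)

    def lnfc_map(self) -> dict[str, float]:
        return dict(zip(self.data["gene"], self.data["lnfc"]))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MetaboliteFoldChangeTable:
    """Measured metabolite log2 fold changes with significance P-values."""

    data: pd.DataFrame  # columns: metabolite, log2fc, pvalue, lnfc

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetaboliteFoldChangeTable":
        df = df.copy()
        if not {"metabolite", "log2fc", "pvalue"} <= set(df.columns):
            raise ValidationError(
                "metabolite table needs columns metabolite, log2fc, pvalue"
            )
        if df["metabolite"].duplicated().any():
            raise ValidationError("duplicate metabolite ids in fold-change table")
        if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
            raise ValidationError("metabolite P-values must lie in [0, 1]")
        if not pd.Series(df["log2fc"]).map(math.isfinite).all():
            raise ValidationError("metabolite fold changes must be finite")
        df["lnfc"] = df["log2fc"] * LN2
        return cls(df[["metabolite", "log2fc", "pvalue", "lnfc"]].reset_index(drop=True))

    def lnfc_map(self) -> dict[str, float]:
        return dict(zip(self.data["metabolite"], self.data["lnfc"]))

    def filtered(self, alpha: float) -> "MetaboliteFoldChangeTable":
        """Keep metabolites with significance P <= alpha."""
        keep = self.data[self.data["pvalue"] <= alpha].reset_index(drop=True)
        return MetaboliteFoldChangeTable(keep)

    def rename(self, mapping: Mapping[str, str]) -> "MetaboliteFoldChangeTable":
        """Translate measured names to model species ids via the mapping file.

        Unmapped rows are dropped (the mapping is the explicit contract for
        which measurements participate).
        """
        df = self.data.copy()
        df["metabolite"] = df["metabolite"].map(mapping)
        df = df[df["metabolite"].notna()].reset_index(drop=True)
        if df["metabolite"].duplicated().any():
            raise ValidationError("metabolite mapping produced duplicate species ids")
        return MetaboliteFoldChangeTable(df)

    def __len__(self) -> int:
        return len(self.data)


def read_expression(path: str | Path, reference: str = "reference") -> ExpressionTable:
    df = _read_tsv(path, ["gene", "log2fc", "pvalue"], "gene", numeric=["log2fc", "pvalue"])
    return ExpressionTable.from_frame(df, reference)


def write_expression(table: ExpressionTable, path: str | Path, header: str | None = None) -> None:
    _write_tsv(table.data[["gene", "log2fc", "pvalue"]], path, header)


def read_metabolite_foldchanges(path: str | Path) -> MetaboliteFoldChangeTable:
    df = _read_tsv(
        path, ["metabolite", "log2fc", "pvalue"], "metabolite", numeric=["log2fc", "pvalue"]
    )
    return MetaboliteFoldChangeTable.from_frame(df)


def write_metabolite_foldchanges(
    table: MetaboliteFoldChangeTable, path: str | Path, header: str | None = None
) -> None:
    _write_tsv(table.data[["metabolite", "log2fc", "pvalue"]], path, header)


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------


@dataclass
class PhysiologyTable:
    """Measured exchange-flux bounds (and growth rate) per condition.

    Uptake follows the constraint-based sign convention: a negative
    exchange flux.  Bounds are carried verbatim from the TSV.
    """

    bounds: dict[str, dict[str, tuple[float, float]]]  # condition -> rxn -> (lb, ub)
    growth_rate: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, rows in self.bounds.items():
            for rxn, (lb, ub) in rows.items():
                if lb > ub:
                    raise ValidationError(
                        f"physiology: lower > upper for {rxn!r} in condition {cond!r}"
                    )
            self.growth_rate.setdefault(cond, None)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.bounds)


def read_physiology(path: str | Path) -> PhysiologyTable:
    """Read a physiology TSV with columns condition, reaction, lower, upper.

    Rows with reaction ``growth`` set the measured growth rate (h^-1) of
    that condition instead of a flux bound (lower = upper = rate, or a
    range).
    """
    df = _read_tsv(
        path,
        ["condition", "reaction", "lower", "upper"],
        "condition",
        numeric=["lower", "upper"],
        unique_key=False,
    )
    bounds: dict[str, dict[str, tuple[float, float]]] = {}
    growth: dict[str, float | None] = {}
    for _, row in df.iterrows():
        cond = str(row["condition"])
        rxn = str(row["reaction"])
        lb, ub = float(row["lower"]), float(row["upper"])
        if rxn == "growth":
            growth[cond] = 0.5 * (lb + ub)
            continue
        bounds.setdefault(cond, {})[rxn] = (lb, ub)
    return PhysiologyTable(bounds=bounds, growth_rate=growth)


def write_physiology(table: PhysiologyTable, path: str | Path, header: str | None = None) -> None:
    rows = []
    for cond in table.conditions:
        for rxn, (lb, ub) in sorted(table.bounds[cond].items()):
            rows.append((cond, rxn, lb, ub))
        g = table.growth_rate.get(cond)
        if g is not None:
            rows.append((cond, "growth", g, g))
    df = pd.DataFrame(rows, columns=["condition", "reaction", "lower", "upper"])
    _write_tsv(df, path, header)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read the measured-name -> model-species-id mapping (columns
    ``measured``, ``species``)."""
    df = _read_tsv(path, ["measured", "species"], "measured")
    return dict(zip(df["measured"], df["species"]))


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "metabolite",
    "degree",
    "upstream_distance",
    "downstream_distance",
    "score",
    "n_genes",
    "gene_ids",
    "used_measured_neighbors",
]


def write_scores(scores: Iterable, path: str | Path, header: str | None = None) -> None:
    """Write CoCCoA scores as a TSV (see :data:`SCORE_COLUMNS`).

    ``scores`` is an iterable of :class:`coccoa.coccoa_engine.CoCCoAScore`.
    Gene ids are semicolon-joined in deterministic (sorted) order.
    """
    rows = []
    for s in scores:
        rows.append(
            {
                "metabolite": s.metabolite,
                "degree": s.degree,
                "upstream_distance": s.upstream_distance,
                "downstream_distance": s.downstream_distance,
                "score": s.score,
                "n_genes": len(s.gene_ids),
                "gene_ids": ";".join(sorted(s.gene_ids)),
                "used_measured_neighbors": int(s.used_measured_neighbors),
            }
        )
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    _write_tsv(df, path, header)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"score table missing column {col!r}")
    df["gene_ids"] = df["gene_ids"].fillna("")
    return df


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Compartment pooling
# ---------------------------------------------------------------------------

_COMP_SUFFIX = re.compile(r"(_[a-z]{1,3}|\[[a-z]{1,3}\])$")


def _pool_key(species: Species) -> str:
    if species.name:
        return species.name
    return _COMP_SUFFIX.sub("", species.id)


def merge_compartment_pools(network: MetabolicNetwork) -> MetabolicNetwork:
    """Merge all compartment instances of each species into one pool.

    Measured concentrations usually cannot distinguish compartments; this
    collapses e.g. cytosolic and mitochondrial pyruvate into one node whose
    producing/consuming reactions are the union of both.  Pure transport
    reactions (which cancel out) are dropped.  Pool ids are the shared
    species name (or the id with its compartment suffix stripped).
    """
    key_of = {m.id: _pool_key(m) for m in network.metabolites}
    pooled_species: dict[str, Species] = {}
    for m in network.metabolites:
        k = key_of[m.id]
        if k not in pooled_species:
            pooled_species[k] = Species(id=k, name=m.name or k, compartment="pool",
                                        boundary=m.boundary)
    reactions: list[Reaction] = []
    for rxn in network.reactions:
        stoich: dict[str, float] = {}
        for met, coef in rxn.stoichiometry.items():
            k = key_of[met]
            stoich[k] = stoich.get(k, 0.0) + coef
        stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
        if not stoich and rxn.stoichiometry:
            continue  # pure transport between merged pools
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry=stoich,
                reversible=rxn.reversible,
                gpr=rxn.gpr,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                name=rxn.name,
            )
        )
    used = {m for r in reactions for m in r.stoichiometry}
    species = [s for k, s in sorted(pooled_species.items()) if k in used]
    return MetabolicNetwork(metabolites=species, reactions=reactions, id=network.id)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Deterministic short hash of a configuration mapping."""
    blob = yaml.safe_dump(dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
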