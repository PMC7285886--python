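"""Core data structures for constraint-based whole-body metabolic models.

A :class:`StoichiometricModel` is the universal substrate of every operation
in this package: a list of metabolites (rows of the stoichiometric matrix S),
a list of reactions (columns of S) with flux bounds in mmol/day/person,
optional gene-protein-reaction (GPR) Boolean rules, and coupling constraints
that tie the flux magnitude of a reaction to a multiple of an anchor
(typically an organ's biomass objective function).

Identifier grammar
------------------
Metabolite ids are ``<base>[<compartment>]`` (e.g. ``glc_D[bc]``); organ-owned
metabolites and reactions carry an organ prefix ending in an underscore
(``Liver_glc_D[c]``, ``Heart_EX_A[bc]_[e]``). Reversibility is stored only via
the bounds: a reaction is reversible iff ``lb < 0``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

# Package-wide numerical conventions.
DEFAULT_BIG = 1.0e6       # default bound magnitude, mmol/day/person
FLUX_ZERO_TOL = 1.0e-6    # |v| below this is treated as zero everywhere
DEFAULT_COUPLING_FACTOR = 20000.0

_MET_ID_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")


def split_met_id(met_id: str) -> tuple[str, str]:
    """Split ``glc_D[bc]`` into ``('glc_D', 'bc')``."""
    m = _MET_ID_RE.match(met_id)
    if not m:
        raise ValueError(f"metabolite id {met_id!r} lacks a [compartment] suffix")
    return m.group("base"), m.group("comp")


def strip_organ_prefix(ident: str, organ_tags: Iterable[str]) -> tuple[Optional[str], str]:
    """Return ``(tag, rest)`` if *ident* starts with a registered organ tag.

    Organ tags include their trailing underscore (``'Liver_'``); the registry
    decides what counts as a prefix, not the underscore position.
    """
    for tag in organ_tags:
        if ident.startswith(tag):
            return tag, ident[len(tag):]
    return None, ident


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

class GprExpression:
    """Boolean AND/OR tree over gene identifiers.

    Parsed from strings like ``"(g1 and g2) or g3"`` (case-insensitive
    keywords). ``str()`` produces a canonical parenthesised form that parses
    back to an equivalent tree.
    """

    __slots__ = ("op", "children", "gene")

    def __init__(self, op: str, children: Optional[list] = None, gene: Optional[str] = None):
        self.op = op              # 'and' | 'or' | 'gene'
        self.children = children or []
        self.gene = gene

    # -- construction ------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "GprExpression":
        tokens = re.findall(r"\(|\)|[^\s()]+", text)
        if not tokens:
            raise ValueError("empty GPR expression")
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def parse_or():
            nonlocal pos
            node = parse_and()
            kids = [node]
            while peek() is not None and peek().lower() == "or":
                pos += 1
                kids.append(parse_and())
            return kids[0] if len(kids) == 1 else cls("or", kids)

        def parse_and():
            nonlocal pos
            node = parse_atom()
            kids = [node]
            while peek() is not None and peek().lower() == "and":
                pos += 1
                kids.append(parse_atom())
            return kids[0] if len(kids) == 1 else cls("and", kids)

        def parse_atom():
            nonlocal pos
            tok = peek()
            if tok is None:
                raise ValueError(f"truncated GPR expression: {text!r}")
            if tok == "(":
                pos += 1
                node = parse_or()
                if peek() != ")":
                    raise ValueError(f"unbalanced parentheses in GPR: {text!r}")
                pos += 1
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise ValueError(f"malformed GPR expression: {text!r}")
            pos += 1
            return cls("gene", gene=tok)

        root = parse_or()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in GPR expression: {text!r}")
        return root

    # -- queries -----------------------------------------------------------
    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: set[str], relax_and_to_or: bool = False) -> bool:
        """Truth value given a set of present genes.

        With ``relax_and_to_or`` complexes (AND nodes) count as satisfied when
        any subunit is present — the rule used when mapping proteomic evidence
        into organ core reaction sets.
        """
        if self.op == "gene":
            return self.gene in present
        vals = (c.evaluate(present, relax_and_to_or) for c in self.children)
        if self.op == "or" or (self.op == "and" and relax_and_to_or):
            return any(vals)
        return all(vals)

    def __str__(self) -> str:
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        parts = []
        for c in self.children:
            s = str(c)
            if c.op != "gene":
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __repr__(self) -> str:
        return f"GprExpression({str(self)!r})"


def evaluate_gpr(gpr, present_genes: Iterable[str], relax_and_to_or: bool = False) -> bool:
    """Evaluate a GPR (string or tree) against a set of present genes."""
    if isinstance(gpr, str):
        gpr = GprExpression.parse(gpr)
    return gpr.evaluate(set(present_genes), relax_and_to_or)


# ---------------------------------------------------------------------------
# Metabolites, reactions, coupling
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    molecular_weight: Optional[float] = None  # g/mmol-scale mass (g/mol numerically)

    def __post_init__(self):
        if not self.compartment:
            self.compartment = split_met_id(self.id)[1]

    @property
    def base_id(self) -> str:
        return split_met_id(self.id)[0]

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment, self.formula,
                          self.charge, self.molecular_weight)


# boundary-reaction id prefixes, after any organ prefix is stripped
_EXCHANGE_PREFIXES = ("EX_", "Diet_EX_")
_DEMAND_PREFIXES = ("DM_",)
_SINK_PREFIXES = ("sink_", "SK_")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = -DEFAULT_BIG
    ub: float = DEFAULT_BIG
    gpr: Optional[str] = None
    subsystem: Optional[str] = None
    organ: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def is_boundary(self) -> bool:
        """Exchange/demand/sink: exactly one metabolite crosses the boundary."""
        return len(self.stoichiometry) == 1

    def _stem(self) -> str:
        stem = self.id
        if self.organ and stem.startswith(self.organ):
            stem = stem[len(self.organ):]
        return stem

    @property
    def boundary_kind(self) -> Optional[str]:
        if not self.is_boundary:
            return None
        stem = self._stem()
        if stem.startswith(_DEMAND_PREFIXES):
            return "demand"
        if stem.startswith(_SINK_PREFIXES):
            return "sink"
        if stem.startswith(_EXCHANGE_PREFIXES):
            return "exchange"
        return "exchange"  # single-metabolite reaction acts as an exchange

    def gpr_tree(self) -> Optional[GprExpression]:
        return GprExpression.parse(self.gpr) if self.gpr else None

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lb, self.ub,
                        self.gpr, self.subsystem, self.organ)

    def reaction_string(self) -> str:
        def side(items):
            return " + ".join(
                (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items)
        lhs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        rhs = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "->"
        return f"{side(lhs)} {arrow} {side(rhs)}"


@dataclass
class CouplingConstraint:
    """|v_coupled| <= factor * v_anchor, encoded as two linear inequalities:
    v_i - c*v_anchor <= 0 and v_i + c*v_anchor >= 0."""
    coupled_reaction: str
    anchor_reaction: str
    factor: float = DEFAULT_COUPLING_FACTOR


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class StoichiometricModel:
    """Ordered metabolites and reactions plus the derived sparse S matrix."""

    def __init__(self, model_id: str = "model"):
        self.id = model_id
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self.compartments: dict[str, str] = {}
        self.coupling: list[CouplingConstraint] = []
        self.objective: dict[str, float] = {}
        self.annotations: dict = {}
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}

    # -- container plumbing -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self._met_index:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)
        self.compartments.setdefault(met.compartment, met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self._rxn_index:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)
        return rxn

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        drop = set(rxn_ids)
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.objective = {k: v for k, v in self.objective.items() if k not in drop}
        self.coupling = [c for c in self.coupling
                         if c.coupled_reaction not in drop and c.anchor_reaction not in drop]

    def prune_unused_metabolites(self) -> None:
        used = set()
        for r in self.reactions:
            used |= set(r.stoichiometry)
        self.metabolites = [m for m in self.metabolites if m.id in used]
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}

    def get_metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def get_reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set(self.annotations.get("genes", ()))
        for r in self.reactions:
            if r.gpr:
                out |= GprExpression.parse(r.gpr).genes()
        return out

    def boundary_reactions(self, kinds: Iterable[str] = ("exchange", "demand", "sink")):
        kinds = set(kinds)
        return [r for r in self.reactions if r.boundary_kind in kinds]

    @property
    def S(self) -> sp.csc_matrix:
        """Sparse stoichiometric matrix (metabolites x reactions)."""
        rows, cols, data = [], [], []
        midx = self._met_index
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                rows.append(midx[m])
                cols.append(j)
                data.append(c)
        return sp.csc_matrix((data, (rows, cols)),
                             shape=(len(self.metabolites), len(self.reactions)))

    def copy(self, model_id: Optional[str] = None) -> "StoichiometricModel":
        m = StoichiometricModel(model_id or self.id)
        for met in self.metabolites:
            m.add_metabolite(met.copy())
        for rxn in self.reactions:
            m.add_reaction(rxn.copy())
        m.compartments = dict(self.compartments)
        m.coupling = [CouplingConstraint(c.coupled_reaction, c.anchor_reaction, c.factor)
                      for c in self.coupling]
        m.objective = dict(self.objective)
        m.annotations = json.loads(json.dumps(self.annotations))
        return m

    def __repr__(self) -> str:
        return (f"<StoichiometricModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, {len(self.coupling)} coupling constraints>")

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "compartments": self.compartments,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment,
                 "formula": m.formula, "charge": m.charge,
                 "molecular_weight": m.molecular_weight}
                for m in self.metabolites
            ],
            "reactions": [
                {"id": r.id, "stoichiometry": r.stoichiometry, "lb": r.lb, "ub": r.ub,
                 "gpr": r.gpr, "subsystem": r.subsystem, "organ": r.organ}
                for r in self.reactions
            ],
            "coupling": [
                {"coupled_reaction": c.coupled_reaction,
                 "anchor_reaction": c.anchor_reaction, "factor": c.factor}
                for c in self.coupling
            ],
            "objective": self.objective,
            "annotations": self.annotations,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StoichiometricModel":
        m = cls(d.get("id", "model"))
        for md in d["metabolites"]:
            m.add_metabolite(Metabolite(
                md["id"], md.get("name", ""), md.get("compartment", ""),
                md.get("formula"), md.get("charge"), md.get("molecular_weight")))
        for rd in d["reactions"]:
            m.add_reaction(Reaction(
                rd["id"], {k: float(v) for k, v in rd["stoichiometry"].items()},
                float(rd["lb"]), float(rd["ub"]),
                rd.get("gpr"), rd.get("subsystem"), rd.get("organ")))
        m.compartments.update(d.get("compartments", {}))
        for cd in d.get("coupling", []):
            m.coupling.append(CouplingConstraint(
                cd["coupled_reaction"], cd["anchor_reaction"], float(cd["factor"])))
        m.objective = {k: float(v) for k, v in d.get("objective", {}).items()}
        m.annotations = dict(d.get("annotations", {}))
        return m


def write_json(model: StoichiometricModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=False)


def read_json(path) -> StoichiometricModel:
    with open(path) as fh:
        return StoichiometricModel.from_dict(json.load(fh))


def write_tsv(model: StoichiometricModel, reactions_path, metabolites_path) -> None:
    rx = pd.DataFrame([
        {"id": r.id, "stoichiometry": json.dumps(r.stoichiometry), "lb": r.lb,
         "ub": r.ub, "gpr": r.gpr or "", "subsystem": r.subsystem or "",
         "organ": r.organ or ""}
        for r in model.reactions
    ])
    mx = pd.DataFrame([
        {"id": m.id, "name": m.name, "compartment": m.compartment,
         "formula": m.formula or "", "charge": "" if m.charge is None else m.charge,
         "molecular_weight": "" if m.molecular_weight is None else m.molecular_weight}
        for m in model.metabolites
    ])
    rx.to_csv(reactions_path, sep="\t", index=False)
    mx.to_csv(metabolites_path, sep="\t", index=False)


def read_tsv(reactions_path, metabolites_path, model_id: str = "model") -> StoichiometricModel:
    m = StoichiometricModel(model_id)
    mx = pd.read_csv(metabolites_path, sep="\t", dtype=str).fillna("")
    for _, row in mx.iterrows():
        m.add_metabolite(Metabolite(
            row["id"], row.get("name", ""), row.get("compartment", ""),
            row.get("formula") or None,
            int(row["charge"]) if row.get("charge") else None,
            float(row["molecular_weight"]) if row.get("molecular_weight") else None))
    rx = pd.read_csv(reactions_path, sep="\t", dtype=str).fillna("")
    for _, row in rx.iterrows():
        m.add_reaction(Reaction(
            row["id"], {k: float(v) for k, v in json.loads(row["stoichiometry"]).items()},
            float(row["lb"]), float(row["ub"]),
            row.get("gpr") or None, row.get("subsystem") or None, row.get("organ") or None))
    return m


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2 (lossy fields carried in a sidecar JSON)
# ---------------------------------------------------------------------------

def _sbml_id(ident: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "__", ident)


def write_sbml(model: StoichiometricModel, path: str, sidecar: bool = True) -> None:
    """Write SBML L3 + FBC v2. Original bracketed ids go into the `name`
    attribute; coupling constraints, organ tags and annotations go into a
    sidecar JSON (`<path>.sidecar.json`)."""
    import libsbml

    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(_sbml_id(model.id))
    fbc = sbml.getPlugin("fbc")
    fbc.setStrict(False)

    for code, desc in model.compartments.items():
        c = sbml.createCompartment()
        c.setId(_sbml_id(code))
        c.setName(desc)
        c.setConstant(True)

    for met in model.metabolites:
        s = sbml.createSpecies()
        s.setId("M_" + _sbml_id(met.id))
        s.setName(met.id)
        s.setCompartment(_sbml_id(met.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        sf = s.getPlugin("fbc")
        if met.formula:
            sf.setChemicalFormula(met.formula)
        if met.charge is not None:
            sf.setCharge(int(met.charge))

    def bound_param(value, stem, idx):
        p = sbml.createParameter()
        p.setId(f"{stem}_{idx}")
        p.setValue(float(value))
        p.setConstant(True)
        return p.getId()

    for i, rxn in enumerate(model.reactions):
        r = sbml.createReaction()
        r.setId("R_" + _sbml_id(rxn.id))
        r.setName(rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                sr = r.createReactant()
            else:
                sr = r.createProduct()
            sr.setSpecies("M_" + _sbml_id(met_id))
            sr.setStoichiometry(abs(float(coeff)))
            sr.setConstant(True)
        rf = r.getPlugin("fbc")
        rf.setLowerFluxBound(bound_param(rxn.lb, "lb", i))
        rf.setUpperFluxBound(bound_param(rxn.ub, "ub", i))
        if rxn.gpr:
            ga = rf.createGeneProductAssociation()
            ga.setAssociation(rxn.gpr.replace(" AND ", " and ").replace(" OR ", " or "))

    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fbc.setActiveObjectiveId("obj")
        for rid, coeff in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + _sbml_id(rid))
            fo.setCoefficient(float(coeff))

    libsbml.writeSBMLToFile(doc, str(path))

    if sidecar:
        side = {
            "coupling": [{"coupled_reaction": c.coupled_reaction,
                          "anchor_reaction": c.anchor_reaction,
                          "factor": c.factor} for c in model.coupling],
            "organs": {r.id: r.organ for r in model.reactions if r.organ},
            "subsystems": {r.id: r.subsystem for r in model.reactions if r.subsystem},
            "annotations": model.annotations,
            "molecular_weights": {m.id: m.molecular_weight for m in model.metabolites
                                  if m.molecular_weight is not None},
        }
        with open(str(path) + ".sidecar.json", "w") as fh:
            json.dump(side, fh, indent=1)


def read_sbml(path: str, model_id: Optional[str] = None) -> StoichiometricModel:
    import libsbml
    import os

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML parse error in {path}: "
                         f"{doc.getError(0).getMessage()}")
    sbml = doc.getModel()
    m = StoichiometricModel(model_id or sbml.getId() or "model")

    for i in range(sbml.getNumCompartments()):
        c = sbml.getCompartment(i)
        m.compartments[c.getName() or c.getId()] = c.getName() or c.getId()

    species_name = {}
    for i in range(sbml.getNumSpecies()):
        s = sbml.getSpecies(i)
        orig = s.getName() or s.getId()
        species_name[s.getId()] = orig
        sf = s.getPlugin("fbc")
        m.add_metabolite(Metabolite(
            orig, compartment=split_met_id(orig)[1],
            formula=(sf.getChemicalFormula() or None) if sf else None,
            charge=sf.getCharge() if sf and sf.isSetCharge() else None))

    params = {sbml.getParameter(i).getId(): sbml.getParameter(i).getValue()
              for i in range(sbml.getNumParameters())}

    for i in range(sbml.getNumReactions()):
        r = sbml.getReaction(i)
        orig = r.getName() or r.getId()
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[species_name[sr.getSpecies()]] = stoich.get(
                species_name[sr.getSpecies()], 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[species_name[sr.getSpecies()]] = stoich.get(
                species_name[sr.getSpecies()], 0.0) + sr.getStoichiometry()
        rf = r.getPlugin("fbc")
        lb = params.get(rf.getLowerFluxBound(), -DEFAULT_BIG) if rf else -DEFAULT_BIG
        ub = params.get(rf.getUpperFluxBound(), DEFAULT_BIG) if rf else DEFAULT_BIG
        gpr = None
        if rf and rf.getGeneProductAssociation():
            gpr = rf.getGeneProductAssociation().getAssociation().toInfix()
            gpr = gpr.replace("(", " ( ").replace(")", " ) ")
            gpr = str(GprExpression.parse(gpr))
        m.add_reaction(Reaction(orig, stoich, lb, ub, gpr))

    fbcm = sbml.getPlugin("fbc")
    if fbcm and fbcm.getActiveObjective():
        obj = fbcm.getActiveObjective()
        rid_by_sbml = {"R_" + _sbml_id(r.id): r.id for r in m.reactions}
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            m.objective[rid_by_sbml.get(fo.getReaction(), fo.getReaction())] = fo.getCoefficient()

    sidecar_path = str(path) + ".sidecar.json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            side = json.load(fh)
        for cd in side.get("coupling", []):
            m.coupling.append(CouplingConstraint(
                cd["coupled_reaction"], cd["anchor_reaction"], float(cd["factor"])))
        for rid, organ in side.get("organs", {}).items():
            if m.has_reaction(rid):
                m.get_reaction(rid).organ = organ
        for rid, subsystem in side.get("subsystems", {}).items():
            if m.has_reaction(rid):
                m.get_reaction(rid).subsystem = subsystem
        for mid, mw in side.get("molecular_weights", {}).items():
            if m.has_metabolite(mid):
                m.get_metabolite(mid).molecular_weight = mw
        m.annotations.update(side.get("annotations", {}))
    return m


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    code: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}

    def __repr__(self) -> str:
        if self.ok:
            return "<ValidationReport: ok>"
        return f"<ValidationReport: {len(self.violations)} violations {sorted(self.codes())}>"


def validate_model(model: StoichiometricModel) -> ValidationReport:
    """Report every structural invariant violation; never mutates the model."""
    report = ValidationReport()
    add = report.violations.append

    seen_mets: set[str] = set()
    for met in model.metabolites:
        if met.id in seen_mets:
            add(Violation("duplicate metabolite id", met.id))
        seen_mets.add(met.id)
        try:
            base, comp = split_met_id(met.id)
        except ValueError:
            add(Violation("bad metabolite id", met.id))
            continue
        if comp != met.compartment:
            add(Violation("compartment mismatch",
                          f"{met.id}: field {met.compartment!r} != suffix {comp!r}"))
        if met.compartment not in model.compartments:
            add(Violation("unregistered compartment", f"{met.id}: {met.compartment!r}"))

    seen_rxns: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen_rxns:
            add(Violation("duplicate reaction id", rxn.id))
        seen_rxns.add(rxn.id)
        if rxn.lb > rxn.ub:
            add(Violation("bounds inverted", f"{rxn.id}: lb={rxn.lb} > ub={rxn.ub}"))
        if not rxn.stoichiometry:
            add(Violation("empty stoichiometry", rxn.id))
        for met_id in rxn.stoichiometry:
            if met_id not in seen_mets and not model.has_metabolite(met_id):
                add(Violation("dangling metabolite reference", f"{rxn.id}: {met_id}"))
        if rxn.gpr:
            try:
                GprExpression.parse(rxn.gpr)
            except ValueError as exc:
                add(Violation("malformed GPR", f"{rxn.id}: {exc}"))

    for rid in model.objective:
        if not model.has_reaction(rid):
            add(Violation("objective on missing reaction", rid))

    for c in model.coupling:
        if c.factor <= 0:
            add(Violation("non-positive coupling factor",
                          f"{c.coupled_reaction}: {c.factor}"))
        if not model.has_reaction(c.coupled_reaction):
            add(Violation("dangling coupling reaction", c.coupled_reaction))
        if not model.has_reaction(c.anchor_reaction):
            add(Violation("dangling coupling anchor", c.anchor_reaction))
    return report


def set_default_bounds(model: StoichiometricModel, big: float = DEFAULT_BIG) -> StoichiometricModel:
    """Apply the default bound magnitude (1e6 mmol/day/person).

    Irreversible reactions (lb >= 0) get [max(lb,0), min(ub,big)]; reversible
    get [max(lb,-big), min(ub,big)]; infinite bounds are replaced by +-big.
    Finite user bounds tighter than big are preserved. Mutates in place and
    returns the model.
    """
    if big <= 0:
        raise ValueError(f"big must be positive, got {big}")
    for rxn in model.reactions:
        lb, ub = rxn.lb, rxn.ub
        if not math.isfinite(ub) or ub > big:
            ub = big
        if rxn.reversible:
            if not math.isfinite(lb) or lb < -big:
                lb = -big
        else:
            lb = max(lb, 0.0)
            if not math.isfinite(lb):
                lb = 0.0
        rxn.lb, rxn.ub = float(lb), float(ub)
    return model


def snapshot_default_bounds(model: StoichiometricModel) -> None:
    """Record current bounds as the defaults used by constraint-coverage
    bookkeeping (see :func:`wholebody.pscm.constraint_coverage`)."""
    model.annotations["default_bounds"] = {
        r.id: [r.lb, r.ub] for r in model.reactions}


def reactions_lost_by_gene_deletion(model: StoichiometricModel,
                                    deleted_genes: Iterable[str]) -> set[str]:
    """Reactions whose GPR holds on the full gene set but fails after deletion."""
    deleted = set(deleted_genes)
    if not deleted:
        return set()
    all_genes = model.genes
    lost: set[str] = set()
    for rxn in model.reactions:
        if not rxn.gpr:
            continue
        tree = GprExpression.parse(rxn.gpr)
        if not (tree.genes() & deleted):
            continue
        if tree.evaluate(all_genes) and not tree.evaluate(all_genes - deleted):
            lost.add(rxn.id)
    return lost


def knock_out_genes(model: StoichiometricModel, genes: Iterable[str]) -> set[str]:
    """Close (lb=ub=0) every reaction lost by deleting *genes*; returns them."""
    lost = reactions_lost_by_gene_deletion(model, genes)
    for rid in lost:
        r = model.get_reaction(rid)
        r.lb = r.ub = 0.0
    return lost
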