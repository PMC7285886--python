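"""Multi-organ meta-model assembly: organ replication, biofluid wiring,
biomass composition, and organ extraction.

The anatomy is declarative data: a list of :class:`OrganSpec` (which organ
touches which biofluid, in which direction) and a :class:`BiofluidMap`
(the biofluid compartments and the directed flows between them, e.g. the
unidirectional luminal chain diet -> lumen -> small-intestinal lumen ->
large-intestinal lumen -> feces). Organ reactions and metabolites carry an
organ prefix (``Liver_``); biofluid metabolites are unprefixed
(``glc_D[bc]``). Organ-biofluid transport reactions follow the
``<Organ>_EX_<met>[<fluid>]_[e]`` naming convention, written so that positive
flux moves the metabolite from the biofluid into the organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import (DEFAULT_BIG, GprExpression, Metabolite, Reaction,
                    StoichiometricModel, evaluate_gpr, split_met_id)

# ---------------------------------------------------------------------------
# Biofluid compartments (the 13 canonical codes) and anatomy types
# ---------------------------------------------------------------------------

BIOFLUID_COMPARTMENTS: list[tuple[str, str]] = [
    ("d", "Diet"),
    ("lu", "Lumen"),
    ("luSI", "Lumen, small intestine"),
    ("luLI", "Lumen, large intestine"),
    ("fe", "Feces"),
    ("bc", "Blood, circulation"),
    ("bp", "Blood, portal vein"),
    ("bd", "Bile duct"),
    ("csf", "Cerebrospinal fluid"),
    ("u", "Urine"),
    ("sw", "Sweat"),
    ("mi", "Breast milk (female only)"),
    ("a", "Air"),
]

LUMINAL_CHAIN = ("d", "lu", "luSI", "luLI", "fe")


@dataclass
class Flow:
    """Directed inter-biofluid flow; *metabolites* restricts it to a subset
    of base ids (None = every metabolite present in the source fluid)."""
    src: str
    dst: str
    metabolites: Optional[set[str]] = None


@dataclass
class BiofluidLink:
    """One organ-biofluid connection.

    direction: 'both', 'uptake', 'secrete', or 'filter' (glomerular
    filtration: a forced one-way fluid-to-fluid transfer plus a reabsorptive
    uptake transport — used for the kidney/urine interface).
    secrete_whitelist widens an 'uptake' link to bidirectional for the listed
    base ids (e.g. metabolites enterocytes may secrete back into the lumen).
    bbb_filtered applies blood-brain-barrier filtering to the link.
    """
    compartment: str
    direction: str = "both"
    secrete_whitelist: set[str] = field(default_factory=set)
    bbb_filtered: bool = False
    filter_source: str = "bc"  # for direction='filter': fluid filtered from


@dataclass
class OrganSpec:
    name: str
    tag: str                      # organ prefix including trailing underscore
    sex: str = "both"             # both | male | female
    biofluids: list[BiofluidLink] = field(default_factory=list)
    organelles_absent: list[str] = field(default_factory=list)
    weight_fraction: float = 0.0  # organ mass / body mass
    biomass_variant: str = "maintenance"  # full | maintenance | noTrTr

    def __post_init__(self):
        if self.weight_fraction < 0:
            raise ValueError(f"{self.name}: weight_fraction must be >= 0")
        if self.biomass_variant not in ("full", "maintenance", "noTrTr"):
            raise ValueError(f"{self.name}: unknown biomass variant "
                             f"{self.biomass_variant!r}")


@dataclass
class BiofluidMap:
    compartments: list[tuple[str, str]] = field(
        default_factory=lambda: list(BIOFLUID_COMPARTMENTS))
    flows: list[Flow] = field(default_factory=list)
    # per-fluid metabolite policy, by base id
    restricted: dict[str, set[str]] = field(default_factory=dict)   # only these
    excluded: dict[str, set[str]] = field(default_factory=dict)     # never these
    # boundary kind per fluid: 'diet' (uptake), 'excretion', 'air' (reversible)
    boundary: dict[str, str] = field(default_factory=dict)

    def codes(self) -> list[str]:
        return [c for c, _ in self.compartments]

    def allows(self, fluid: str, base: str) -> bool:
        if fluid in self.restricted and base not in self.restricted[fluid]:
            return False
        return base not in self.excluded.get(fluid, ())

    def validate(self) -> None:
        """The luminal chain must be acyclic and unidirectional."""
        import networkx as nx

        codes = set(self.codes())
        for f in self.flows:
            if f.src not in codes or f.dst not in codes:
                raise ValueError(f"flow {f.src}->{f.dst} uses unknown compartment")
        g = nx.DiGraph((f.src, f.dst) for f in self.flows
                       if f.src in LUMINAL_CHAIN and f.dst in LUMINAL_CHAIN)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("luminal chain contains a cycle")


def default_biofluid_map() -> BiofluidMap:
    """The canonical anatomy: full luminal chain, CSF return to blood, bile
    duct draining into the small-intestinal lumen."""
    return BiofluidMap(
        flows=[Flow("d", "lu"), Flow("lu", "luSI"), Flow("luSI", "luLI"),
               Flow("luLI", "fe"), Flow("csf", "bc"), Flow("bd", "luSI")],
        boundary={"d": "diet", "fe": "excretion", "u": "excretion",
                  "sw": "excretion", "mi": "excretion", "a": "air"},
    )


@dataclass
class WholeBodyObjective:
    """Organ-weight-derived coefficients of the whole-body maintenance
    reaction: one dimensionless weight per organ dummy-objective metabolite."""
    coefficients: dict[str, float]

    def __post_init__(self):
        for tag, coeff in self.coefficients.items():
            if coeff <= 0:
                raise ValueError(f"coefficient for {tag!r} must be > 0, got {coeff}")


# ---------------------------------------------------------------------------
# Reference biomass stoichiometries (reference-male whole-body composition)
# ---------------------------------------------------------------------------

# biomass_maintenance: negative = consumed, positive = produced (per flux unit)
REFERENCE_BIOMASS_MAINTENANCE: dict[str, float] = {
    "h2o": -20.6508, "atp": -20.7045, "glu_L": -0.38587, "asp_L": -0.35261,
    "gtp": -0.036117, "ala_L": -0.50563, "asn_L": -0.27942, "cys_L": -0.046571,
    "gln_L": -0.326, "gly": -0.53889, "ser_L": -0.39253, "thr_L": -0.31269,
    "lys_L": -0.59211, "arg_L": -0.35926, "met_L": -0.15302,
    "pail_hs": -0.023315, "ctp": -0.039036, "pchol_hs": -0.15446,
    "pe_hs": -0.055374, "chsterol": -0.020401, "pglyc_hs": -0.002914,
    "clpn_hs": -0.011658, "utp": -0.053446, "g6p": -0.27519,
    "his_L": -0.12641, "tyr_L": -0.15967, "ile_L": -0.28608,
    "leu_L": -0.54554, "trp_L": -0.013306, "phe_L": -0.25947,
    "pro_L": -0.41248, "ps_hs": -0.005829, "sphmyln_hs": -0.017486,
    "val_L": -0.35261,
    "h": 20.6508, "adp": 20.6508, "pi": 20.6508,
    "lipid_membrane": 1.0, "proteome": 1.0, "transcriptome": 1.0,
}

_AMINO_ACIDS = ("glu_L", "asp_L", "ala_L", "asn_L", "cys_L", "gln_L", "gly",
                "ser_L", "thr_L", "lys_L", "arg_L", "met_L", "his_L", "tyr_L",
                "ile_L", "leu_L", "trp_L", "phe_L", "pro_L", "val_L")

# noTrTr: no transcription or translation — devoid of amino acids and of
# nucleotides other than ATP; no proteome/transcriptome products.
REFERENCE_BIOMASS_NOTRTR: dict[str, float] = {
    k: v for k, v in REFERENCE_BIOMASS_MAINTENANCE.items()
    if k not in _AMINO_ACIDS + ("gtp", "ctp", "utp", "proteome", "transcriptome")
}

REFERENCE_DEGRADATION: dict[str, dict[str, float]] = {
    "LIPID_DEGRx": {
        "lipid_membrane": -1.0,
        "pail_hs": 0.023315, "pchol_hs": 0.154463, "pe_hs": 0.055374,
        "chsterol": 0.020401, "pglyc_hs": 0.002914, "clpn_hs": 0.011658,
        "ps_hs": 0.005829, "sphmyln_hs": 0.017486,
    },
    "PROTEOME_DEGRx": {
        "proteome": -1.0,
        "glu_L": 0.385872, "asp_L": 0.352607, "ala_L": 0.505626,
        "asn_L": 0.279425, "cys_L": 0.046571, "gln_L": 0.325996,
        "gly": 0.538891, "ser_L": 0.392525, "thr_L": 0.31269,
        "lys_L": 0.592114, "arg_L": 0.35926, "met_L": 0.153018,
        "his_L": 0.126406, "tyr_L": 0.159671, "ile_L": 0.286078,
        "leu_L": 0.545544, "trp_L": 0.013306, "phe_L": 0.259466,
        "pro_L": 0.412484, "val_L": 0.352607,
    },
    "TRANSCRIPTOME_DEGRx": {
        "transcriptome": -1.0,
        "amp": 0.053446, "cmp": 0.039036, "gmp": 0.036117, "ump": 0.053446,
    },
}

REFERENCE_BIOMASS_TABLE = {
    "maintenance": REFERENCE_BIOMASS_MAINTENANCE,
    # the full regenerative biomass string is not printed separately; organs
    # with regenerative capacity reuse the maintenance composition here
    "full": REFERENCE_BIOMASS_MAINTENANCE,
    "noTrTr": REFERENCE_BIOMASS_NOTRTR,
    "degradation": REFERENCE_DEGRADATION,
}

# Whole_body_objective_rxn coefficients for the reference male, keyed by
# organ tag (dimensionless; derived from fractional organ weights).
REFERENCE_WHOLE_BODY_COEFFICIENTS: dict[str, float] = {
    "Adipocytes_": 21.4286, "Agland_": 0.02, "Brain_": 2.0,
    "Colon_": 0.428571, "Heart_": 0.472857, "Kidney_": 0.442857,
    "Liver_": 2.57143, "Lung_": 0.765714, "Muscle_": 40.0,
    "Pancreas_": 0.142857, "Prostate_": 0.0228571,
    "Pthyroidgland_": 0.000171429, "Retina_": 0.000465714,
    "Scord_": 0.0428571, "sIEC_": 0.914286, "Skin_": 3.71429,
    "Spleen_": 0.257143, "Stomach_": 0.214286, "Testis_": 0.05,
    "Thyroidgland_": 0.0285714, "Urinarybladder_": 0.0642857,
    "Bcells_": 0.00212143, "CD4Tcells_": 0.0117857, "Nkcells_": 0.00353571,
    "Monocyte_": 0.00392857, "Platelet_": 0.0285714, "RBC_": 3.53571,
    "Gall_": 0.0142857,
}

WHOLE_BODY_OBJECTIVE_ID = "Whole_body_objective_rxn"
_VARIANT_NAMES = {"maintenance": "biomass_maintenance",
                  "noTrTr": "biomass_maintenance_noTrTr",
                  "full": "biomass_reaction"}


# ---------------------------------------------------------------------------
# Replication and wiring
# ---------------------------------------------------------------------------

def filter_organs_by_sex(organs: Iterable[OrganSpec], sex: str) -> list[OrganSpec]:
    return [o for o in organs if sex == "both" or o.sex in ("both", sex)]


def replicate_base(base: StoichiometricModel, organs: list[OrganSpec],
                   sex: str = "both") -> StoichiometricModel:
    """Duplicate the base network once per organ with organ-prefixed ids.

    Reactions in an organ's absent organelles are closed (lb=ub=0); organs not
    matching *sex* are skipped entirely.
    """
    organs = filter_organs_by_sex(organs, sex)
    tags = [o.tag for o in organs]
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate organ tags")

    meta = StoichiometricModel(f"{base.id}_meta_{sex}")
    meta.compartments = dict(base.compartments)
    meta.annotations["organ_tags"] = tags
    for organ in organs:
        absent = set(organ.organelles_absent)
        for met in base.metabolites:
            meta.add_metabolite(Metabolite(
                f"{organ.tag}{met.base_id}[{met.compartment}]",
                met.name, met.compartment, met.formula, met.charge,
                met.molecular_weight))
        for rxn in base.reactions:
            stoich = {f"{organ.tag}{split_met_id(m)[0]}[{split_met_id(m)[1]}]": c
                      for m, c in rxn.stoichiometry.items()}
            lb, ub = rxn.lb, rxn.ub
            if any(split_met_id(m)[1] in absent for m in rxn.stoichiometry):
                lb = ub = 0.0
            meta.add_reaction(Reaction(f"{organ.tag}{rxn.id}", stoich, lb, ub,
                                       rxn.gpr, rxn.subsystem, organ.tag))
    return meta


def bbb_permits(met: Metabolite, allowed: Iterable[str], blocked: Iterable[str],
                mass_cutoff: float = 500.0) -> bool:
    """Blood-brain-barrier rule: explicit lists first, then the small-molecule
    heuristic (molecular mass below 500 Da; unknown mass is permissive)."""
    allowed, blocked = set(allowed), set(blocked)
    tail = met.base_id
    if ((tail in allowed or _strip_any_prefix(tail, allowed))
            and (tail in blocked or _strip_any_prefix(tail, blocked))):
        raise ValueError(f"{met.id}: in both BBB allowed and blocked lists")
    if tail in blocked or _strip_any_prefix(tail, blocked):
        return False
    if tail in allowed or _strip_any_prefix(tail, allowed):
        return True
    if met.molecular_weight is None:
        return True
    return met.molecular_weight < mass_cutoff


def _strip_any_prefix(base: str, names: set[str]) -> bool:
    return any(base == n or base.endswith("_" + n) for n in names)


def wire_biofluids(meta: StoichiometricModel, organs: list[OrganSpec],
                   bmap: BiofluidMap, bbb_allowed: Iterable[str] = (),
                   bbb_blocked: Iterable[str] = (),
                   big: float = DEFAULT_BIG) -> StoichiometricModel:
    """Create organ-biofluid transports, inter-fluid flows, and boundary
    exchanges (diet uptake, fecal/urinary excretion, CSF return)."""
    bmap.validate()
    codes = set(bmap.codes())
    for code, desc in bmap.compartments:
        meta.compartments.setdefault(code, desc)
    bbb_allowed, bbb_blocked = set(bbb_allowed), set(bbb_blocked)

    def organ_e_bases(organ: OrganSpec) -> list[tuple[str, Metabolite]]:
        out = []
        for met in meta.metabolites:
            if met.compartment == "e" and met.base_id.startswith(organ.tag):
                out.append((met.base_id[len(organ.tag):], met))
        return out

    def ensure_fluid_met(base: str, fluid: str, like: Metabolite) -> str:
        mid = f"{base}[{fluid}]"
        if not meta.has_metabolite(mid):
            meta.add_metabolite(Metabolite(mid, like.name, fluid, like.formula,
                                           like.charge, like.molecular_weight))
        return mid

    fluid_bases: dict[str, dict[str, Metabolite]] = {c: {} for c in codes}

    for organ in organs:
        if organ.tag not in (meta.annotations.get("organ_tags") or [o.tag for o in organs]):
            continue
        bases = organ_e_bases(organ)
        for link in organ.biofluids:
            if link.compartment not in codes:
                raise ValueError(f"{organ.name}: unknown biofluid "
                                 f"{link.compartment!r}")
            for base, met in bases:
                if not bmap.allows(link.compartment, base):
                    continue
                if link.bbb_filtered and not bbb_permits(met, bbb_allowed, bbb_blocked):
                    continue
                fluid_bases[link.compartment].setdefault(base, met)
                if link.direction == "filter":
                    src_fluid = link.filter_source
                    src_id = ensure_fluid_met(base, src_fluid, met)
                    dst_id = ensure_fluid_met(base, link.compartment, met)
                    fluid_bases[src_fluid].setdefault(base, met)
                    meta.add_reaction(Reaction(
                        f"{organ.tag}FILT_{base}", {src_id: -1.0, dst_id: 1.0},
                        0.0, big, organ=organ.tag, subsystem="filtration"))
                    lb, ub = 0.0, big  # reabsorption: uptake only
                else:
                    if link.direction == "both":
                        lb, ub = -big, big
                    elif link.direction == "uptake":
                        lb, ub = 0.0, big
                        if base in link.secrete_whitelist:
                            lb = -big
                    elif link.direction == "secrete":
                        lb, ub = -big, 0.0
                    else:
                        raise ValueError(f"unknown direction {link.direction!r}")
                fid = ensure_fluid_met(base, link.compartment, met)
                meta.add_reaction(Reaction(
                    f"{organ.tag}EX_{base}[{link.compartment}]_[e]",
                    {fid: -1.0, met.id: 1.0}, lb, ub,
                    organ=organ.tag, subsystem="biofluid transport"))

    # inter-fluid flows
    all_known: dict[str, Metabolite] = {}
    for c in codes:
        all_known.update(fluid_bases.get(c, {}))
    for flow in bmap.flows:
        if flow.metabolites is not None:
            src_known = {b: all_known[b] for b in flow.metabolites if b in all_known}
        elif flow.src in LUMINAL_CHAIN:
            # the gastrointestinal chain can carry anything any organ exchanges
            src_known = dict(all_known)
        else:
            src_known = dict(fluid_bases.get(flow.src, {}))
        for base, met in sorted(src_known.items()):
            if not (bmap.allows(flow.src, base) and bmap.allows(flow.dst, base)):
                continue
            sid = ensure_fluid_met(base, flow.src, met)
            did = ensure_fluid_met(base, flow.dst, met)
            fluid_bases[flow.src].setdefault(base, met)
            fluid_bases[flow.dst].setdefault(base, met)
            meta.add_reaction(Reaction(
                f"TR_{base}_{flow.src}_{flow.dst}", {sid: -1.0, did: 1.0},
                0.0, big, subsystem="biofluid flow"))

    # boundary reactions
    for fluid, kind in bmap.boundary.items():
        if fluid not in codes:
            continue
        for base, met in sorted(fluid_bases.get(fluid, {}).items()):
            mid = f"{base}[{fluid}]"
            if not meta.has_metabolite(mid):
                continue
            if kind == "diet":
                meta.add_reaction(Reaction(f"Diet_EX_{base}[{fluid}]",
                                           {mid: -1.0}, -big, 0.0,
                                           subsystem="diet exchange"))
            elif kind == "air":
                meta.add_reaction(Reaction(f"EX_{base}[{fluid}]",
                                           {mid: -1.0}, -big, big,
                                           subsystem="air exchange"))
            else:
                meta.add_reaction(Reaction(f"EX_{base}[{fluid}]",
                                           {mid: -1.0}, 0.0, big,
                                           subsystem="excretion"))
    return meta


def add_storage(meta: StoichiometricModel, organ: OrganSpec,
                metabolites: Iterable[str], phase: str = "feeding",
                big: float = DEFAULT_BIG) -> StoichiometricModel:
    """Add (or re-phase) organ storage reactions.

    feeding: storage acts as a demand (lb=0, ub=1e6) — metabolites may be
    deposited; fasting: storage acts as a supply-only sink (lb=-1e6, ub=0).
    """
    if phase not in ("feeding", "fasting"):
        raise ValueError(f"unknown phase {phase!r}")
    for base in metabolites:
        mid = f"{organ.tag}{base}[c]"
        if not meta.has_metabolite(mid):
            raise KeyError(f"storage metabolite {mid!r} not in model")
        rid = f"{organ.tag}sink_{base}[c]"
        if meta.has_reaction(rid):
            rxn = meta.get_reaction(rid)
        else:
            rxn = meta.add_reaction(Reaction(rid, {mid: -1.0}, 0.0, big,
                                             organ=organ.tag, subsystem="storage"))
        if phase == "feeding":
            rxn.lb, rxn.ub = 0.0, big
        else:
            rxn.lb, rxn.ub = -big, 0.0
    return meta


def compose_biomass(organ: OrganSpec, stoich_table: Optional[Mapping] = None,
                    model: Optional[StoichiometricModel] = None) -> list[Reaction]:
    """Build the organ's biomass reaction (variant per OrganSpec), the
    macromolecule degradation reactions, and the dummy-objective product.

    With *model* given, precursors are checked against the organ's
    metabolites (KeyError when absent) and the reactions plus any new
    macromolecule/dummy metabolites are added to the model.
    """
    table = dict(stoich_table) if stoich_table is not None else REFERENCE_BIOMASS_TABLE
    variant = organ.biomass_variant
    stoich_base = table[variant]
    degradation = table.get("degradation", {})
    name = _VARIANT_NAMES[variant]
    dummy_base = f"biomass_{'maintenance' if variant != 'noTrTr' else 'maintenance_noTrTr'}_dummy_objective"
    # the dummy metabolite name tracks the printed convention
    if variant == "full":
        dummy_base = "biomass_maintenance_dummy_objective"

    tag = organ.tag
    macros = set(degradation)  # reaction names
    macro_products = {m for d in degradation.values() for m, c in d.items() if c < 0}

    def prefixed(base: str) -> str:
        return f"{tag}{base}[c]"

    reactions = []
    stoich = {prefixed(b): c for b, c in stoich_base.items()}
    stoich[prefixed(dummy_base)] = 1.0
    reactions.append(Reaction(f"{tag}{name}", stoich, 0.0, DEFAULT_BIG,
                              organ=tag, subsystem="biomass"))
    present_macros = {b for b, c in stoich_base.items() if b in macro_products and c > 0}
    for degr_name, degr_stoich in degradation.items():
        if not any(b in present_macros for b, c in degr_stoich.items() if c < 0):
            continue
        reactions.append(Reaction(
            f"{tag}{degr_name}", {prefixed(b): c for b, c in degr_stoich.items()},
            0.0, DEFAULT_BIG, organ=tag, subsystem="biomass"))

    if model is not None:
        produced = {m for r in reactions for m, c in r.stoichiometry.items() if c > 0}
        missing = []
        for r in reactions:
            for mid, coeff in r.stoichiometry.items():
                if coeff < 0 and not model.has_metabolite(mid) and mid not in produced:
                    missing.append(mid)
        if missing:
            raise KeyError(f"{organ.name}: missing biomass precursors "
                           f"{sorted(set(missing))}")
        for r in reactions:
            for mid in r.stoichiometry:
                if not model.has_metabolite(mid):
                    model.add_metabolite(Metabolite(mid, compartment="c"))
            model.add_reaction(r)
    return reactions


def compose_whole_body_maintenance(model: StoichiometricModel,
                                   objective: WholeBodyObjective,
                                   exclude_organs: Iterable[str] = ()) -> Reaction:
    """Add the whole-body maintenance reaction consuming every organ's
    dummy-objective metabolite at its weight-derived coefficient, and register
    it as the model objective."""
    exclude = set(exclude_organs)
    stoich: dict[str, float] = {}
    for tag, coeff in sorted(objective.coefficients.items()):
        if tag in exclude:
            continue
        dummies = [m.id for m in model.metabolites
                   if m.id.startswith(tag) and "_dummy_objective" in m.id]
        if not dummies:
            raise KeyError(f"no dummy-objective metabolite for organ tag {tag!r}")
        stoich[dummies[0]] = -float(coeff)
    rxn = Reaction(WHOLE_BODY_OBJECTIVE_ID, stoich, 0.0, DEFAULT_BIG,
                   subsystem="whole-body objective")
    if model.has_reaction(rxn.id):
        model.remove_reactions([rxn.id])
    model.add_reaction(rxn)
    model.objective = {rxn.id: 1.0}
    return rxn


# ---------------------------------------------------------------------------
# Proteomics -> core reactions
# ---------------------------------------------------------------------------

def proteomics_to_core(expression: pd.DataFrame, gprs,
                       threshold: float = 0.2) -> dict[str, set[str]]:
    """Map a gene-by-organ expression table to per-organ core reaction ids.

    Expression is scaled to [0, 1] by the table maximum; a gene is present in
    an organ iff its scaled value >= threshold (default 0.2). A reaction
    enters the organ core if its GPR is satisfiable given the present genes,
    with protein complexes relaxed: one complex subunit suffices for core
    inclusion.
    """
    if (expression.values < 0).any():
        raise ValueError("negative expression values")
    mx = float(expression.values.max()) if expression.size else 1.0
    scaled = expression / mx if mx > 1.0 else expression

    if isinstance(gprs, StoichiometricModel):
        gprs = {r.id: r.gpr for r in gprs.reactions if r.gpr}
    parsed = {rid: GprExpression.parse(g) for rid, g in gprs.items() if g}

    core: dict[str, set[str]] = {}
    for organ in scaled.columns:
        present = set(scaled.index[scaled[organ] >= threshold])
        core[organ] = {rid for rid, tree in parsed.items()
                       if tree.evaluate(present, relax_and_to_or=True)}
    return core


# ---------------------------------------------------------------------------
# Organ extraction
# ---------------------------------------------------------------------------

def extract_organ_model(wbm: StoichiometricModel, tag: str) -> StoichiometricModel:
    """Standalone organ model: the organ's reactions with its biofluid
    transports converted into boundary exchanges (negative flux = uptake)."""
    if not any(r.organ == tag or r.id.startswith(tag) for r in wbm.reactions):
        raise KeyError(f"unknown organ tag {tag!r}")

    organ = StoichiometricModel(f"{wbm.id}_{tag.rstrip('_')}")
    organ.compartments = dict(wbm.compartments)
    kept: set[str] = set()
    for rxn in wbm.reactions:
        if not (rxn.organ == tag or rxn.id.startswith(tag)):
            continue
        organ_mets = {m: c for m, c in rxn.stoichiometry.items()
                      if split_met_id(m)[0].startswith(tag)}
        fluid_mets = {m: c for m, c in rxn.stoichiometry.items()
                      if m not in organ_mets}
        if not organ_mets:
            continue  # pure fluid-to-fluid reactions (e.g. filtration) drop out
        if fluid_mets:
            # transport becomes a boundary exchange; flip sign so that
            # negative flux = uptake, the usual exchange convention
            stoich = {m: -c for m, c in organ_mets.items()}
            new = Reaction(rxn.id, stoich, -rxn.ub, -rxn.lb, rxn.gpr,
                           rxn.subsystem, tag)
        else:
            new = rxn.copy()
        for mid in new.stoichiometry:
            if not organ.has_metabolite(mid):
                organ.add_metabolite(wbm.get_metabolite(mid).copy())
        organ.add_reaction(new)
        kept.add(rxn.id)

    organ.coupling = [c for c in wbm.coupling
                      if c.coupled_reaction in kept and c.anchor_reaction in kept]
    bof = [r.id for r in organ.reactions if "biomass" in r.id.lower()
           and "DEGR" not in r.id and "dummy" not in r.id]
    if bof:
        organ.objective = {bof[0]: 1.0}
    return organ
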